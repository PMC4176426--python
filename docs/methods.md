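# Methods

## The net-return model

The activity of a single group of species is valued twice on the same
hectare: as a damage cost and as an ecosystem service, with the net
return their difference. Both sides are monetised:

* **Damage cost.** A bird-damage rate `r` (fraction of the crop lost)
  translates to money through the chain
  `r × nuts_per_tree × nut_value × trees_per_ha`, with
  `nut_value = nut_mass_g / 1000 × price_per_kg`. At the 2012 defaults
  (1.3 g, $5.05 kg⁻¹, 1268 nuts per tree, 250 trees ha⁻¹) one nut is
  worth $0.006565 — displayed as ≈$0.007, but carried unrounded because
  chaining the display value does not reproduce the per-tree figures.
* **Service value.** The replacement-cost method prices the birds'
  post-harvest removal of mummified nuts as the cheapest human
  alternative: mechanical shaking (≈20 s per tree, driver wage plus a
  $38 hr⁻¹ machinery hire rate) or hand-poling (minutes per tree at the
  2012 minimum wage, $15.96 hr⁻¹). When birds remove only a fraction
  `f` of mummy nuts the service is a *reduced cost*: the grower still
  removes the remaining `1 − f`, so the value is the full cost minus
  the residual cost.

### Rounding convention

Per-tree monetary values are rounded half-up to the cent before scaling
by planting density, making per-hectare figures exact multiples of
$2.50 at 250 trees ha⁻¹ ($0.83/tree at 10% loss, $57.50/ha at 2.8%,
$67.50/ha for 1 minute of poling, and so on). The unrounded chain is
exposed alongside, for two reasons: the cent-rounded map is a step
function and therefore not invertible (break-even solvers invert the
unrounded chain and report the rounded cost at the solution), and
sensitivity curves use the unrounded series so the two lines are exactly
straight and their crossover follows from linear interpolation between
bracketing grid points. A handful of published per-hectare figures
($82.50 and $52.50 for mechanical shaking, $72.75 for edge damage)
cannot be reproduced under any single rounding convention — this
convention gives $80.00, $52.50-at-a-different-fraction and $72.50
respectively — so those numbers are treated as parameter inputs where a
comparison needs them (e.g. the $25 lower net-return bound), never as
derived quantities.

## Loss attribution

Netted branches exclude birds, so their nut losses estimate the
non-bird baseline (storms, tree health, natural abortion): the mean of
per-branch loss rates with its SEM. On open branches, some nuts vanish
entirely and cannot be assigned by inspecting bite marks; the
attribution rule assigns `round(disappearances × baseline)` nuts
(half-up, so 50 × 5.9% → 3) to non-bird causes and the remainder to
birds. Attribution conserves counts on every record by construction.

Two rate summaries are deliberately distinct and both exposed: the
**mean of per-branch rates** (each branch an equally weighted sampling
unit, the presentation used for field results, SEM across branches) and
the **pooled per-nut rate** (lost nuts over total nuts), which is what
the stratum contrast models. The default summary is the mean of branch
rates. For the degenerate one-branch stratum the SEM is reported as 0
with a warning rather than raising: the estimate is valid, its
uncertainty is simply not estimable.

### Stratum contrast

The published analysis fitted a binomial GLM with row location nested
in block as random factors (SPSS). Random-effects machinery is out of
scope here; the contrast is a fixed-effects binomial likelihood-ratio
test on pooled per-nut counts: deviance
`G = 2 [ℓ(p̂₁, p̂₂) − ℓ(p̂)]` with the per-stratum and pooled MLEs,
compared to χ² with (strata − 1) df. `G` is non-negative and zero
exactly when the pooled stratum rates coincide. The same function
contrasts blocks by passing `group_by="block_id"`. This preserves the
scientific question (is damage/removal higher at edges?) with a fully
specified statistic; because the raw field data are not deposited, the
published χ² values are not reproduction targets.

## Synthetic experiments

The raw per-branch data exist only as a journal supplement without an
accession, so the generator emulates the experiment's design and
reported statistics: 2 blocks × 2 row locations × 2 treatments × 15
branches per cell per phase (120 branches per phase, 60 netted / 60
open, matching the published design); branch nut loads as a discretised
normal with mean 98 and sd 38.3 (= SEM 3.5 × √120), truncated at 1 — a
Poisson at mean 98 would be far under-dispersed relative to the implied
sd; binomial bird losses at stratum rates (pre-harvest edge 3.5%,
interior 2%; post-harvest edge 55%, interior 16.2%) and binomial
non-bird losses at phase rates (5.9% pre, 6.1% post). The post-harvest
interior rate is back-solved so the pooled removal averages ≈35.6%;
only the pooled and edge values were published. Mummy-nut loads reuse
the pre-harvest load distribution scaled by 0.15 (unreported in the
field study; an explicit, overridable assumption).

A configurable share of losses (default 0.3 of bird losses) is recorded
as complete disappearances. The disappearances also include the
matching non-bird share (`hidden_bird × b/(1−b)` at phase non-bird rate
`b`), so that the composition of disappearances equals what the
attribution rule assumes — the non-bird share of disappearances is the
baseline. This makes attribution unbiased on generated data: parameter
recovery then checks the pipeline's estimation noise, not a built-in
modelling mismatch. If disappearances were drawn from bird losses only,
the attribution rule would systematically shave ~`u·b` off every
recovered bird rate (≈0.4 SEM at the post-harvest edge), which is a
property of the attribution rule on mis-specified data, not of the
implementation.

What passing recovery tests show: with the assumed binomial/normal
structure, the pipeline recovers stratum rates within 3 SEM in ≥99% of
seeded replicates and orders edge above interior net returns in ≥95%.
What they do not show: robustness to real-data features the generator
omits — overdispersion from bird flocking, spatial correlation along
rows, block-level heterogeneity (the published block effects), or
non-binomial loss processes.

## Numerical choices

* Half-up rounding (`floor(x + 0.5)` with a 1e-9 epsilon against float
  representation error) for cents and whole nuts; season totals rounded
  to the dollar.
* Stratum summaries sort per-branch rates before aggregating so results
  are exactly invariant to record order.
* The deviance is computed with `xlogy` (0·log 0 = 0), clipped at 0
  against negative float residue; binomial coefficients cancel and are
  omitted.
* Extrapolated removal fractions are capped at 1; with `mode="auto"`
  the stratified trade-off switches from reduced-cost to
  full-replacement valuation once the extrapolated fraction reaches
  0.9 (birds effectively replacing the removal pass, the threshold the
  "over 90% removed" edge scenario implies).
* Break-even with a zero service value returns rate 0; degenerate
  empty strata are omitted from summaries with a warning and raise
  `InsufficientDataError` in the contrast.

## Problem sizes

The default synthetic experiment is the study's own size (240 branches
across both phases). Coverage properties use 200 seeded replicates for
parameter recovery and 100 for the edge/interior ordering; the
acceptance script uses 50 replicates per seed for its rate summaries.
These sizes give Monte-Carlo error well inside the tested tolerances.

## Known limitations

* All currency is 2012 AUD; no discounting, price forecasting or
  labour-market structure beyond flat hourly rates.
* The fixed-effects contrast ignores the nesting of rows in blocks; a
  strong block effect would inflate its statistic relative to a
  random-effects fit.
* The netted baseline is assumed unaffected by the netting itself, as
  in the original design; this is untestable from these data.
* The generator's independence assumptions (branch-level binomials) are
  optimistic; real bird damage is likely clumped, so real SEMs would be
  larger than synthetic ones at the same rates.
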