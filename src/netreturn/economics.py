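"""Monetary valuation chains for damage costs and replacement costs.

The valuation chain runs nut → tree → hectare: a nut is worth
``mass_g / 1000 × price_per_kg`` (AUD$0.0065665 at the 2012 defaults,
displayed as ≈$0.007); a damage rate scales that by the mean crop per
tree; per-tree values are rounded half-up to the cent and multiplied by
planting density to give per-hectare figures (exact multiples of $2.50
at 250 trees ha⁻¹). Unrounded values are carried alongside rounded ones
because the break-even solvers invert the unrounded maps.

Replacement costs price a removal method as
``(wage + machine hire) × time_per_tree``; partial removal by birds is
valued as the reduction in that cost (the grower only removes the
remainder).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from netreturn.experiment_data import EconomicParams, ReplacementModel


def round_to_cent(x: float) -> float:
    """Round a non-negative dollar amount half-up to the cent."""
    if x < 0:
        raise ValueError("monetary amounts are non-negative here")
    # epsilon guards against float representations like 26.599999…
    return math.floor(x * 100.0 + 0.5 + 1e-9) / 100.0


@dataclass(frozen=True)
class DamageCost:
    """Cost of a crop damage rate, per nut / tree / hectare.

    ``per_tree`` and ``per_ha`` follow the cent-rounding convention;
    the ``*_unrounded`` fields carry the exact linear chain.
    ``crop_value_fraction`` expresses the per-hectare cost as a share of
    total crop value at the stated yield.
    """

    rate: float
    per_nut_value: float
    per_tree: float
    per_ha: float
    per_tree_unrounded: float
    per_ha_unrounded: float
    crop_value_fraction: float
    trees_per_ha: float


@dataclass(frozen=True)
class ReplacementCost:
    """Cost of removing all mummy nuts with one human-derived method."""

    method: str
    hourly_rate_total: float
    per_tree: float
    per_ha: float
    per_tree_unrounded: float
    per_ha_unrounded: float
    trees_per_ha: float


def per_nut_value(econ: EconomicParams, *, display: bool = False) -> float:
    """Value of a single nut in AUD: ``nut_mass_g/1000 × price_per_kg``.

    Defaults give 0.0065665, displayed as ≈$0.007. The unrounded value is
    what valuation chains use; ``display=True`` rounds to 3 decimals for
    presentation only.
    """
    value = econ.nut_mass_g / 1000.0 * econ.price_per_kg
    return round(value, 3) if display else value


def damage_cost(rate: float, econ: EconomicParams) -> DamageCost:
    """Monetary cost of losing ``rate`` of the crop to damage.

    At the defaults a 10% loss costs $0.83 per tree; the 2.8% plantation
    mean bird damage costs $57.50 ha⁻¹, 0.8% of crop value at 1.5 t ha⁻¹.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be within [0, 1], got {rate}")
    nut = per_nut_value(econ)
    per_tree_exact = rate * econ.nuts_per_tree * nut
    per_tree = round_to_cent(per_tree_exact)
    per_ha = per_tree * econ.trees_per_ha
    crop_value = econ.yield_t_per_ha * 1000.0 * econ.price_per_kg
    return DamageCost(
        rate=rate,
        per_nut_value=nut,
        per_tree=per_tree,
        per_ha=per_ha,
        per_tree_unrounded=per_tree_exact,
        per_ha_unrounded=per_tree_exact * econ.trees_per_ha,
        crop_value_fraction=per_ha / crop_value,
        trees_per_ha=econ.trees_per_ha,
    )


def replacement_cost(model: ReplacementModel, econ: EconomicParams) -> ReplacementCost:
    """Replacement-cost value of full mummy-nut removal by ``model``.

    One minute of hand-poling at $15.96 hr⁻¹ costs $0.27 per tree
    ($67.50 ha⁻¹); a 5-minute visit costs $332.50 ha⁻¹; mechanical
    shaking at a $63 hr⁻¹ total rate and 20 s per tree costs $87.50 ha⁻¹.
    """
    hourly = model.wage_per_hr + model.machine_hire_per_hr
    per_tree_exact = hourly * model.time_per_tree_s / 3600.0
    per_tree = round_to_cent(per_tree_exact)
    return ReplacementCost(
        method=model.method,
        hourly_rate_total=hourly,
        per_tree=per_tree,
        per_ha=per_tree * econ.trees_per_ha,
        per_tree_unrounded=per_tree_exact,
        per_ha_unrounded=per_tree_exact * econ.trees_per_ha,
        trees_per_ha=econ.trees_per_ha,
    )


def reduced_cost_saving(full_cost: ReplacementCost, removal_fraction: float) -> float:
    """Grower saving per hectare when birds remove ``removal_fraction``.

    The grower still pays to remove the remaining ``1 − removal_fraction``
    of mummy nuts; the saving is the full per-hectare cost minus that
    residual cost (residual per-tree cost rounded to the cent before
    scaling). Saving + residual equals the full cost exactly.
    """
    if not 0.0 <= removal_fraction <= 1.0:
        raise ValueError(f"removal_fraction must be within [0, 1], got {removal_fraction}")
    residual_per_tree = round_to_cent(full_cost.per_tree_unrounded * (1.0 - removal_fraction))
    residual_per_ha = residual_per_tree * full_cost.trees_per_ha
    return full_cost.per_ha - residual_per_ha


def linear_removal_extrapolation(
    observed_fraction: float, observed_months: float, target_months: float
) -> float:
    """Extrapolate a removal fraction linearly in time, capped at 1.

    Birds removing 36% of mummy nuts in the 3-month experiment project to
    60% over the 5 months until the next flowering.
    """
    if observed_months <= 0 or target_months <= 0:
        raise ValueError("durations must be strictly positive")
    if not 0.0 <= observed_fraction <= 1.0:
        raise ValueError(f"observed_fraction must be within [0, 1], got {observed_fraction}")
    return min(1.0, observed_fraction * target_months / observed_months)


def control_program_cost(
    days: float, hours_per_day: float, wage_per_hr: float, area_ha: float
) -> tuple[float, float]:
    """Season cost of a labour-based control program (e.g. bird shooters).

    Returns ``(season_total, per_ha)``: the total rounded to the dollar,
    the per-hectare figure unrounded. 120 days × 8 h at $15.96 hr⁻¹ is
    $15,322 per season, about $1 ha⁻¹ over a 15,500-ha estate.
    """
    if days < 0 or hours_per_day < 0 or wage_per_hr < 0:
        raise ValueError("days, hours and wage must be non-negative")
    if area_ha <= 0:
        raise ValueError("area_ha must be strictly positive")
    total = float(math.floor(days * hours_per_day * wage_per_hr + 0.5 + 1e-9))
    return total, total / area_ha
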