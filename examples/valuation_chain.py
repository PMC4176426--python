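"""Price a bird-damage rate and the replacement cost of mummy-nut removal.

The chain runs nut → tree → hectare: a 1.3 g almond at $5.05/kg is worth
≈$0.007, so a damage rate scales to a per-tree cost via the mean crop
(1268 nuts) and to a per-hectare cost via planting density (250 trees).
"""

from netreturn import (
    EconomicParams,
    ReplacementModel,
    damage_cost,
    per_nut_value,
    reduced_cost_saving,
    replacement_cost,
)

econ = EconomicParams()  # 2012 study defaults

print(f"per-nut value:            ${per_nut_value(econ):.6f} (≈${per_nut_value(econ, display=True)})")

for rate, label in [(0.028, "plantation-mean bird damage"), (0.059, "non-bird loss")]:
    cost = damage_cost(rate, econ)
    print(
        f"{label} ({rate:.1%}): ${cost.per_tree:.2f}/tree, ${cost.per_ha:.2f}/ha "
        f"({100 * cost.crop_value_fraction:.1f}% of crop value)"
    )

print()
for model, label in [
    (ReplacementModel.handpole(1.0), "hand-poling, 1 min/tree"),
    (ReplacementModel.handpole(5.0), "hand-poling, 5 min/tree"),
    (ReplacementModel.mechanical(), "mechanical shaking, 20 s/tree at $58/hr"),
]:
    cost = replacement_cost(model, econ)
    print(f"{label}: ${cost.per_tree:.2f}/tree, ${cost.per_ha:.2f}/ha")

# Birds removed 36% of mummy nuts in the 3-month experiment: the grower
# only pays to remove the remaining 64%, so partial removal is a saving.
full = replacement_cost(ReplacementModel.handpole(5.0), econ)
print(f"\nsaving from 36% removal by birds (hand-poling): ${reduced_cost_saving(full, 0.36):.2f}/ha")
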