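"""Locate break-even points and trace the damage-vs-service trade-off.

Net return is service value minus damage cost per hectare. The break-even
damage rate is where the damage chain equals a given service value; the
sensitivity curve traces both sides over a parameter grid and finds the
crossover by linear interpolation.
"""

import numpy as np

from netreturn import (
    EconomicParams,
    ReplacementModel,
    breakeven_damage_rate,
    breakeven_replacement_rate,
    damage_cost,
    net_return,
    replacement_cost,
    sensitivity_curves,
)

econ = EconomicParams()
handpole = ReplacementModel.handpole(5.0)

damage = damage_cost(0.028, econ)
service = replacement_cost(handpole, econ).per_ha
result = net_return(damage, service)
print(
    f"net return (hand-poling): ${result.service_value_per_ha:.2f} − "
    f"${result.damage_cost_per_ha:.2f} = ${result.net_return_per_ha:+.2f}/ha"
)

be = breakeven_damage_rate(87.50, econ)
print(f"break-even damage rate at $87.50/ha service: {be.rate:.1%}")
rate = breakeven_replacement_rate(87.50, ReplacementModel.mechanical(), econ)
print(f"hourly shaker rate meeting $87.50/ha damage: ${rate:.2f}/hr")

curve = sensitivity_curves(
    "damage_rate", np.linspace(0, 0.20, 41), econ, service_value_per_ha=service
)
print(
    f"damage-rate sweep vs hand-poling value: crossover at "
    f"{curve.crossover:.1%} damage — below that, net return is positive"
)
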