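"""Net returns, break-even solvers and sensitivity curves.

The net return of animal activity is the ecosystem-service value minus
the damage cost, per hectare; positive when the benefit outweighs the
cost. Break-even points solve the unrounded valuation chains (the
cent-rounded maps are step functions and not invertible), and
sensitivity curves trace damage cost and service value across a
parameter grid, locating the crossover where the net return changes
sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from netreturn.damage_attribution import summarize
from netreturn.economics import (
    DamageCost,
    ReplacementCost,
    damage_cost,
    linear_removal_extrapolation,
    per_nut_value,
    reduced_cost_saving,
    replacement_cost,
)
from netreturn.experiment_data import BranchRecord, EconomicParams, ReplacementModel

#: Named almond-price scenarios (AUD kg⁻¹): 2012 wholesale, expected 2013,
#: and a hypothetical 2013–14 price repeating the 2012–13 growth.
PRICE_SCENARIOS = {"2012": 5.05, "2013": 6.38, "2014_hypothetical": 8.04}

SensitivityAxis = Literal[
    "damage_rate", "replacement_hourly_rate", "minutes_per_tree", "price_per_kg"
]


@dataclass(frozen=True)
class TradeoffResult:
    """Damage cost vs service value for one scenario, per hectare."""

    scenario: str
    damage_cost_per_ha: float
    service_value_per_ha: float
    net_return_per_ha: float
    removal_fraction_observed: float | None = None
    removal_fraction_extrapolated: float | None = None
    valuation_mode: str | None = None


@dataclass(frozen=True)
class BreakevenDamage:
    """Damage rate at which damage cost equals a service value."""

    rate: float
    damage: DamageCost  # cent-rounded cost chain evaluated at `rate`


@dataclass(frozen=True)
class SensitivityCurve:
    """Damage-cost and service-value series over a parameter grid."""

    axis: str
    grid: tuple[float, ...]
    damage_costs: tuple[float, ...]
    service_values: tuple[float, ...]
    crossover: float | None


def net_return(
    damage: DamageCost | float, service_value_per_ha: float, scenario: str = ""
) -> TradeoffResult:
    """Net return per hectare: service value minus damage cost.

    ``damage`` may be a :class:`~netreturn.economics.DamageCost` (its
    rounded per-hectare figure is used) or a bare per-hectare amount.
    The sign is preserved — a negative net return means the damage
    outweighs the service.
    """
    damage_per_ha = damage.per_ha if isinstance(damage, DamageCost) else float(damage)
    if damage_per_ha < 0 or service_value_per_ha < 0:
        raise ValueError("costs and service values are non-negative")
    return TradeoffResult(
        scenario=scenario,
        damage_cost_per_ha=damage_per_ha,
        service_value_per_ha=service_value_per_ha,
        net_return_per_ha=service_value_per_ha - damage_per_ha,
    )


def breakeven_damage_rate(service_value_per_ha: float, econ: EconomicParams) -> BreakevenDamage:
    """Damage rate at which the unrounded damage cost equals the service value.

    Solves ``r × nuts_per_tree × per_nut_value × trees_per_ha == service``;
    at the defaults a $87.50 ha⁻¹ service value breaks even near 4.2%
    damage. The returned :class:`BreakevenDamage` carries the
    cent-rounded cost chain at the solved rate alongside.
    """
    if service_value_per_ha < 0:
        raise ValueError("service value must be non-negative")
    per_ha_slope = econ.trees_per_ha * econ.nuts_per_tree * per_nut_value(econ)
    rate = service_value_per_ha / per_ha_slope
    return BreakevenDamage(rate=rate, damage=damage_cost(min(rate, 1.0), econ))


def breakeven_replacement_rate(
    damage: DamageCost | float, model: ReplacementModel, econ: EconomicParams
) -> float:
    """Hourly rate at which a removal method's value meets a damage cost.

    Solves ``h × time_per_tree/3600 × trees_per_ha == damage per ha`` on
    the unrounded replacement chain: an $87.50 ha⁻¹ damage cost meets
    mechanical shaking (20 s per tree, 250 trees ha⁻¹) at $63 hr⁻¹.
    """
    damage_per_ha = damage.per_ha if isinstance(damage, DamageCost) else float(damage)
    if damage_per_ha < 0:
        raise ValueError("damage cost must be non-negative")
    hours_per_ha = model.time_per_tree_s / 3600.0 * econ.trees_per_ha
    return damage_per_ha / hours_per_ha


def _interpolate_crossover(
    grid: np.ndarray, damage: np.ndarray, service: np.ndarray
) -> float | None:
    gap = service - damage
    if np.all(gap > 0) or np.all(gap < 0):
        return None
    for i in range(len(grid) - 1):
        a, b = gap[i], gap[i + 1]
        if a == 0.0:
            return float(grid[i])
        if a * b < 0:
            # linear interpolation between the bracketing grid points
            return float(grid[i] + (grid[i + 1] - grid[i]) * a / (a - b))
    return float(grid[-1]) if gap[-1] == 0.0 else None


def sensitivity_curves(
    axis: SensitivityAxis,
    grid: Sequence[float],
    econ: EconomicParams,
    *,
    model: ReplacementModel | None = None,
    damage_rate: float = 0.028,
    service_value_per_ha: float | None = None,
) -> SensitivityCurve:
    """Damage-cost and service-value series over a grid of one parameter.

    The varying parameter is named by ``axis``; everything else is held
    fixed. ``damage_rate`` fixes the damage side when the axis varies the
    service side (and vice versa the service value is taken from
    ``model``, or ``service_value_per_ha`` directly). Series use the
    unrounded per-hectare chains, so they are straight lines and the
    crossover — the parameter value where net return changes sign —
    follows from linear interpolation between bracketing grid points.
    """
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size < 2:
        raise ValueError("grid needs at least 2 points")
    if np.any(np.diff(grid_arr) <= 0):
        raise ValueError("grid must be strictly increasing")

    def fixed_service() -> float:
        if service_value_per_ha is not None:
            return float(service_value_per_ha)
        if model is None:
            raise ValueError("provide a ReplacementModel or service_value_per_ha")
        return replacement_cost(model, econ).per_ha_unrounded

    def fixed_damage() -> float:
        return damage_cost(damage_rate, econ).per_ha_unrounded

    if axis == "damage_rate":
        damage_series = np.array(
            [damage_cost(r, econ).per_ha_unrounded for r in grid_arr]
        )
        service_series = np.full_like(grid_arr, fixed_service())
    elif axis == "price_per_kg":
        damage_series = np.array(
            [
                damage_cost(
                    damage_rate,
                    EconomicParams(
                        price_per_kg=p,
                        nut_mass_g=econ.nut_mass_g,
                        nuts_per_tree=econ.nuts_per_tree,
                        trees_per_ha=econ.trees_per_ha,
                        yield_t_per_ha=econ.yield_t_per_ha,
                    ),
                ).per_ha_unrounded
                for p in grid_arr
            ]
        )
        service_series = np.full_like(grid_arr, fixed_service())
    elif axis == "replacement_hourly_rate":
        if model is None:
            raise ValueError("replacement_hourly_rate axis needs a ReplacementModel")
        hours_per_ha = model.time_per_tree_s / 3600.0 * econ.trees_per_ha
        service_series = grid_arr * hours_per_ha
        damage_series = np.full_like(grid_arr, fixed_damage())
    elif axis == "minutes_per_tree":
        if model is None:
            raise ValueError("minutes_per_tree axis needs a ReplacementModel")
        hourly = model.wage_per_hr + model.machine_hire_per_hr
        service_series = grid_arr * 60.0 / 3600.0 * hourly * econ.trees_per_ha
        damage_series = np.full_like(grid_arr, fixed_damage())
    else:
        raise ValueError(f"unknown axis {axis!r}")

    return SensitivityCurve(
        axis=axis,
        grid=tuple(grid_arr),
        damage_costs=tuple(damage_series),
        service_values=tuple(service_series),
        crossover=_interpolate_crossover(grid_arr, damage_series, service_series),
    )


def plot_sensitivity(curve: SensitivityCurve, path: str) -> None:
    """Save the two-line trade-off figure (damage dashed, service solid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.grid, curve.damage_costs, "k--", label="damage cost")
    ax.plot(curve.grid, curve.service_values, "k-", label="service value")
    if curve.crossover is not None:
        ax.axvline(curve.crossover, color="r", lw=0.8, label="break-even")
    ax.set_xlabel(curve.axis.replace("_", " "))
    ax.set_ylabel("AUD ha$^{-1}$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stratified_tradeoff(
    records: Iterable[BranchRecord],
    econ: EconomicParams,
    model: ReplacementModel,
    *,
    mode: Literal["full", "reduced", "auto"] = "auto",
    observed_months: float = 3.0,
    target_months: float = 5.0,
    full_replacement_threshold: float = 0.9,
) -> list[TradeoffResult]:
    """Edge vs interior net returns from an attributed experiment.

    Per row-location stratum: the damage cost comes from the stratum's
    pre-harvest mean bird-damage rate; the removal fraction is the
    post-harvest mean bird-removal rate, extrapolated linearly from the
    experiment duration to the horizon of the next flowering. Service
    value is either the full replacement cost (``'full'``), the
    reduced-cost saving for partial removal (``'reduced'``), or — with
    ``'auto'`` — the full cost once the extrapolated removal fraction
    reaches ``full_replacement_threshold`` (birds effectively replacing
    the removal pass) and the saving otherwise.

    Records must be attributed first (no unattributed losses) and both
    phases must contain open branches in each stratum.
    """
    records = list(records)
    pre = {s.stratum: s for s in summarize(records, "pre_harvest", "row_location", "bird")}
    post = {s.stratum: s for s in summarize(records, "post_harvest", "row_location", "bird")}
    full = replacement_cost(model, econ)
    results = []
    for stratum in ("edge", "interior"):
        if stratum not in pre or stratum not in post:
            raise ValueError(f"missing phase data for stratum {stratum!r}")
        dmg = damage_cost(pre[stratum].mean_rate, econ)
        observed = post[stratum].mean_rate
        extrapolated = linear_removal_extrapolation(observed, observed_months, target_months)
        use_full = mode == "full" or (
            mode == "auto" and extrapolated >= full_replacement_threshold
        )
        if use_full:
            service = full.per_ha
            mode_used = "full"
        else:
            service = reduced_cost_saving(full, extrapolated)
            mode_used = "reduced"
        results.append(
            TradeoffResult(
                scenario=f"{stratum}/{model.method}",
                damage_cost_per_ha=dmg.per_ha,
                service_value_per_ha=service,
                net_return_per_ha=service - dmg.per_ha,
                removal_fraction_observed=observed,
                removal_fraction_extrapolated=extrapolated,
                valuation_mode=mode_used,
            )
        )
    return results
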