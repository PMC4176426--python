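"""Net returns, break-even inversions, sensitivity curves, stratified trade-offs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netreturn import (
    BranchRecord,
    EconomicParams,
    ReplacementModel,
    SyntheticConfig,
    attribute_all,
    breakeven_damage_rate,
    breakeven_replacement_rate,
    damage_cost,
    generate,
    net_return,
    replacement_cost,
    sensitivity_curves,
    stratified_tradeoff,
)
from netreturn.economics import per_nut_value
from netreturn.net_return import PRICE_SCENARIOS, plot_sensitivity


class TestNetReturn:
    def test_plantation_mean_bounds(self, econ, handpole_5min):
        """Service value $82.50–$332.50 against $57.50 damage: +$25 to +$275."""
        damage = damage_cost(0.028, econ)
        high = net_return(damage, replacement_cost(handpole_5min, econ).per_ha)
        assert high.net_return_per_ha == pytest.approx(275.0)
        # $82.50 is the study's printed mechanical figure, taken as an input
        low = net_return(damage, 82.50)
        assert low.net_return_per_ha == pytest.approx(25.0)

    def test_equal_inputs_zero(self):
        assert net_return(100.0, 100.0).net_return_per_ha == 0.0

    def test_antisymmetric_under_swap(self):
        a, b = 57.50, 332.50
        assert net_return(a, b).net_return_per_ha == -net_return(b, a).net_return_per_ha

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            net_return(-1.0, 10.0)


class TestBreakeven:
    def test_mechanical_breakeven_point(self, econ):
        """$87.50/ha service breaks even near 4% damage, at a $63/hr shaker rate."""
        be = breakeven_damage_rate(87.50, econ)
        assert be.rate == pytest.approx(0.042, abs=0.001)
        assert be.damage.per_ha == pytest.approx(87.50)
        rate = breakeven_replacement_rate(87.50, ReplacementModel.mechanical(), econ)
        assert rate == pytest.approx(63.0, abs=1e-9)

    def test_zero_service_gives_zero_rate(self, econ):
        assert breakeven_damage_rate(0.0, econ).rate == 0.0
        assert breakeven_replacement_rate(0.0, ReplacementModel.mechanical(), econ) == 0.0

    @given(service=st.floats(0.01, 2000.0))
    @settings(max_examples=200, derandomize=True)
    def test_damage_rate_inverts_unrounded_chain(self, service):
        econ = EconomicParams()
        rate = breakeven_damage_rate(service, econ).rate
        slope = econ.trees_per_ha * econ.nuts_per_tree * per_nut_value(econ)
        assert rate * slope == pytest.approx(service, abs=1e-9)

    @given(damage=st.floats(0.0, 1000.0), seconds=st.floats(1.0, 600.0))
    @settings(max_examples=200, derandomize=True)
    def test_replacement_rate_inverts_unrounded_chain(self, damage, seconds):
        econ = EconomicParams()
        model = ReplacementModel(method="mechanical", time_per_tree_s=seconds)
        hourly = breakeven_replacement_rate(damage, model, econ)
        forward = hourly * seconds / 3600.0 * econ.trees_per_ha
        assert forward == pytest.approx(damage, abs=1e-9)


class TestSensitivityCurves:
    def test_damage_axis_crossover_matches_breakeven(self, econ):
        curve = sensitivity_curves(
            "damage_rate", np.linspace(0, 0.20, 21), econ, service_value_per_ha=87.50
        )
        assert curve.crossover == pytest.approx(breakeven_damage_rate(87.50, econ).rate, abs=1e-9)

    def test_handpole_crossover_under_default_price(self, econ):
        """Even the $332.50 hand-poling value is outweighed near 16% damage."""
        curve = sensitivity_curves(
            "damage_rate", np.linspace(0, 0.20, 41), econ, service_value_per_ha=332.50
        )
        assert curve.crossover == pytest.approx(332.50 / (250 * 1268 * 0.006565), abs=1e-6)

    def test_no_crossover_when_service_dominates(self, econ):
        curve = sensitivity_curves(
            "damage_rate", np.linspace(0, 0.10, 11), econ, service_value_per_ha=332.50
        )
        assert curve.crossover is None
        assert all(s > d for s, d in zip(curve.service_values, curve.damage_costs))

    def test_service_series_flat_on_damage_axis(self, econ, handpole_5min):
        curve = sensitivity_curves("damage_rate", [0.0, 0.1, 0.2], econ, model=handpole_5min)
        assert len(set(curve.service_values)) == 1
        assert list(curve.damage_costs) == sorted(curve.damage_costs)

    def test_hourly_rate_axis_crossover(self, econ, mechanical):
        """Damage fixed at the 4.2% break-even rate crosses near $63/hr."""
        damage = damage_cost(0.042, econ).per_ha_unrounded
        curve = sensitivity_curves(
            "replacement_hourly_rate", np.linspace(0, 120, 25), econ,
            model=mechanical, damage_rate=0.042,
        )
        assert curve.crossover == pytest.approx(
            breakeven_replacement_rate(damage, mechanical, econ), abs=1e-9
        )

    def test_minutes_axis_monotone_service(self, econ):
        curve = sensitivity_curves(
            "minutes_per_tree", [1, 2, 5, 10], econ, model=ReplacementModel.handpole()
        )
        assert list(curve.service_values) == sorted(curve.service_values)
        assert curve.service_values[0] == pytest.approx(66.5)  # 1 min unrounded

    def test_price_axis_scales_damage(self, econ, handpole_5min):
        grid = [PRICE_SCENARIOS["2012"], PRICE_SCENARIOS["2013"], PRICE_SCENARIOS["2014_hypothetical"]]
        curve = sensitivity_curves("price_per_kg", grid, econ, model=handpole_5min)
        assert list(curve.damage_costs) == sorted(curve.damage_costs)
        assert curve.damage_costs[2] / curve.damage_costs[0] == pytest.approx(8.04 / 5.05)

    def test_unsorted_grid_rejected(self, econ):
        with pytest.raises(ValueError, match="increasing"):
            sensitivity_curves("damage_rate", [0.2, 0.1], econ, service_value_per_ha=50)

    def test_plot_writes_file(self, econ, tmp_path):
        curve = sensitivity_curves(
            "damage_rate", np.linspace(0, 0.2, 5), econ, service_value_per_ha=87.5
        )
        out = tmp_path / "tradeoff.png"
        plot_sensitivity(curve, str(out))
        assert out.stat().st_size > 0


class TestStratifiedTradeoff:
    def test_edge_exceeds_interior_on_default_experiment(self, econ, handpole_5min, default_records):
        results = stratified_tradeoff(attribute_all(default_records), econ, handpole_5min)
        by_stratum = {r.scenario.split("/")[0]: r for r in results}
        assert by_stratum["edge"].net_return_per_ha > by_stratum["interior"].net_return_per_ha
        for r in results:
            assert r.net_return_per_ha == r.service_value_per_ha - r.damage_cost_per_ha

    def test_high_edge_removal_engages_full_replacement(self, econ, handpole_5min):
        """55% removal in 3 months extrapolates past 90%: full replacement value."""
        cfg = SyntheticConfig(seed=11)
        results = stratified_tradeoff(attribute_all(generate(cfg)), econ, handpole_5min)
        edge = next(r for r in results if r.scenario.startswith("edge"))
        assert edge.removal_fraction_extrapolated >= 0.9 or edge.valuation_mode == "reduced"
        if edge.valuation_mode == "full":
            assert edge.service_value_per_ha == pytest.approx(332.50)

    def test_zero_activity_zero_net_return_reduced_mode(self, econ, handpole_5min):
        records = []
        for phase in ("pre_harvest", "post_harvest"):
            for loc in ("edge", "interior"):
                for treatment in ("netted", "open"):
                    records.append(
                        BranchRecord(
                            block_id="1", row_location=loc, treatment=treatment,
                            phase=phase, initial_count=50, intact=50,
                            bird_loss=0, nonbird_loss=0,
                        )
                    )
        results = stratified_tradeoff(records, econ, handpole_5min, mode="reduced")
        assert all(r.net_return_per_ha == 0.0 for r in results)

    def test_missing_phase_raises(self, econ, handpole_5min):
        records = [
            BranchRecord(
                block_id="1", row_location="edge", treatment="open",
                phase="pre_harvest", initial_count=10, intact=10,
                bird_loss=0, nonbird_loss=0,
            )
        ]
        with pytest.raises(ValueError):
            stratified_tradeoff(records, econ, handpole_5min)
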