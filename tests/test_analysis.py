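"""Arm comparison, ICER classification, DSA, scenarios, price sweep, reports."""

import numpy as np
import pandas as pd
import pytest

from hivsim import (
    ArmResults,
    compare_arms,
    load_parameters,
    perturb,
    price_sweep,
    render_report,
    run_cohort,
    run_dsa,
    run_paired,
    run_structural_scenarios,
)
from hivsim.analysis import TABLE_ROWS, _classify
from conftest import identical_arm_overrides


def _manual_results(arm, means, n=500_000, seed=1, fp="fp"):
    return ArmResults(arm=arm, n=n, seed=seed, fingerprint=fp, means=means)


class TestCompareArms:
    def test_published_table_arithmetic(self):
        """Feeding the published cohort means through the comparison
        pipeline reproduces the published increments."""
        dtg = _manual_results("DTG", {
            "total_cost": 390_001.0, "qaly_disc": 10.75, "ly_undisc": 18.06,
            "cost_art": 323_660.0, "months_line1": 39.7, "aids_free_years": 8.62,
            "no_resistance_pct": 88.72})
        ral = _manual_results("RAL", {
            "total_cost": 382_735.0, "qaly_disc": 10.41, "ly_undisc": 17.30,
            "cost_art": 315_506.0, "months_line1": 36.1, "aids_free_years": 8.25,
            "no_resistance_pct": 55.84})
        inc = compare_arms(dtg, ral)
        assert inc.delta_cost == pytest.approx(7266.0)
        assert inc.deltas["ly_undisc"] == pytest.approx(0.76)
        assert inc.deltas["cost_art"] == pytest.approx(8154.0)
        assert inc.deltas["months_line1"] == pytest.approx(3.6)
        assert inc.deltas["aids_free_years"] == pytest.approx(0.37)
        assert inc.deltas["no_resistance_pct"] == pytest.approx(32.88)
        assert inc.icer == pytest.approx(7266.0 / (10.75 - 10.41))

    def test_identical_results_are_equivalent(self):
        means = {"total_cost": 100.0, "qaly_disc": 5.0}
        inc = compare_arms(_manual_results("DTG", means), _manual_results("RAL", means))
        assert inc.dominance == "equivalent" and inc.icer is None
        assert all(v == 0.0 for v in inc.deltas.values())

    def test_mismatched_runs_rejected(self):
        a = _manual_results("DTG", {"total_cost": 1.0, "qaly_disc": 1.0}, seed=1)
        b = _manual_results("RAL", {"total_cost": 1.0, "qaly_disc": 1.0}, seed=2)
        with pytest.raises(ValueError, match="not comparable"):
            compare_arms(a, b)

    @pytest.mark.parametrize("dc, dq, icer, label", [
        (7266.0, 0.34, 7266.0 / 0.34, None),   # dearer, more effective: ratio
        (-1000.0, 0.2, None, "dominant"),      # cheaper, more effective
        (1000.0, -0.2, None, "dominated"),     # dearer, less effective
        (-1000.0, -0.2, 5000.0, None),         # cheaper, less effective: ratio
        (0.0, 0.0, None, "equivalent"),
        (0.0, 0.2, None, "dominant"),
        (0.0, -0.2, None, "dominated"),
        (1000.0, 0.0, None, "dominated"),
        (-1000.0, 0.0, None, "dominant"),
    ])
    def test_icer_classification_is_exhaustive(self, dc, dq, icer, label):
        got_icer, got_label = _classify(dc, dq)
        assert got_label == label
        if icer is None:
            assert got_icer is None
        else:
            assert got_icer == pytest.approx(icer)


class TestDsa:
    def test_noop_spec_reproduces_base_icer(self, params):
        spec = [{"path": "costs/art_monthly/OBT2.2", "low": 2491.0, "high": 2491.0}]
        results = run_dsa(params, spec, n=800, seed=3)
        r = results[0]
        assert r.icer_low == r.icer_high == r.icer_base

    def test_invalid_path_aborts_before_simulating(self, params):
        with pytest.raises(KeyError):
            run_dsa(params, [{"path": "nope/nope", "low": 0, "high": 1}], n=800, seed=3)

    def test_tornado_ordering_and_ranges(self, params):
        specs = [
            {"path": "costs/art_monthly/OBT2.2", "low": 2291.0, "high": 2740.0},
            {"path": "efficacy/line1_dtg/suppression_rate_y1", "low": 0.64, "high": 0.78},
            {"path": "oi/duration_months", "low": 1, "high": 3},
        ]
        results = run_dsa(params, specs, n=800, seed=3)
        assert sorted(r.path for r in results) == sorted(s["path"] for s in specs)
        ranges = [r.range for r in results]
        assert ranges == sorted(ranges, reverse=True)
        assert all(r >= 0 for r in ranges)

    def test_default_specs_cover_published_bounds(self, params):
        by_path = {s["path"]: s for s in params.dsa}
        assert by_path["efficacy/line1_dtg/suppression_rate_y1"]["low"] == 0.64
        assert by_path["efficacy/line1_dtg/suppression_rate_y1"]["high"] == 0.78
        assert by_path["costs/art_monthly/OBT2.2"]["high"] == 2740.0
        assert by_path["costs/art_monthly/OBT2.2"]["low"] == 2291.0


@pytest.fixture(scope="module")
def scenario_table(params):
    return run_structural_scenarios(params, n=2500, seed=5)


@pytest.fixture(scope="module")
def sweep(params):
    return price_sweep(params, (0.8, 1.0, 1.2), n=2000, seed=7)


class TestScenarios:
    def test_all_scenarios_present(self, scenario_table):
        assert {"base", "horizon_15y", "oi_duration_1m", "no_resistance",
                "discount_0pct", "discount_6pct", "terminal_decline_worst",
                "terminal_no_decline"} == set(scenario_table["scenario"])

    def test_no_resistance_world(self, scenario_table):
        row = scenario_table.set_index("scenario").loc["no_resistance"]
        assert row["dtg_no_resistance_pct"] == 100.0
        assert row["ral_no_resistance_pct"] == 100.0
        base = scenario_table.set_index("scenario").loc["base"]
        # the resistance barrier is part of DTG's advantage: removing
        # resistance shrinks the incremental QALY gain
        assert row["delta_qaly"] < base["delta_qaly"]

    def test_zero_discount_scenario_equates_discounted_and_undiscounted(self, params):
        p = perturb(params, "discount/rate_early", 0.0)
        p = perturb(p, "discount/rate_late", 0.0)
        res = run_cohort("DTG", p, 400, seed=5)
        assert res.means["total_cost"] == pytest.approx(
            res.means["total_cost_undisc"], rel=1e-12)
        assert res.means["ly_disc"] == pytest.approx(res.means["ly_undisc"], rel=1e-12)

    def test_horizon_scenario_censors_at_fifteen_years(self, params):
        p = perturb(params, "simulation/horizon_months", 180)
        res = run_cohort("DTG", p, 400, seed=5)
        assert res.means["ly_undisc"] <= 15.0 + 1e-9


class TestPriceSweep:
    def test_default_grid_includes_published_extremes(self, params):
        import inspect
        from hivsim.analysis import price_sweep as ps
        defaults = inspect.signature(ps).parameters["multipliers"].default
        assert 0.8 in defaults and 1.2 in defaults

    def test_unit_multiplier_reproduces_base_case(self, params, sweep):
        _, _, base = run_paired(params, 2000, seed=7)
        row = sweep.set_index("multiplier").loc[1.0]
        assert row["delta_cost"] == pytest.approx(base.delta_cost, rel=1e-12)
        assert row["icer"] == pytest.approx(base.icer, rel=1e-12)

    def test_icer_monotone_in_price(self, sweep):
        icers = sweep.sort_values("multiplier")["icer"].to_numpy()
        assert (np.diff(icers) > 0).all()

    def test_health_outcomes_price_invariant(self, sweep):
        assert sweep["delta_qaly"].nunique() == 1

    def test_only_dtg_component_scaled(self, params):
        p = perturb(params, "costs/art_monthly/DTG", 612.0 * 0.8)
        assert p.costs.art_monthly["RAL"] == 612.0

    def test_invalid_multiplier_rejected(self, params):
        with pytest.raises(ValueError):
            price_sweep(params, (0.0, 1.0), n=10, seed=1)


class TestRenderReport:
    def test_report_round_trip_and_consistency(self, tmp_path, params):
        base = run_paired(params, 300, seed=11)
        sweep = price_sweep(params, (0.9, 1.1), n=300, seed=11)
        written = render_report(tmp_path, base, sweep=sweep, params=params)
        table = pd.read_csv(written["base_case"])
        assert list(table["outcome"]) == list(TABLE_ROWS)
        a, b, inc = base
        for _, row in table.iterrows():
            assert row["DTG"] == pytest.approx(a.means[row["outcome"]], rel=1e-9)
            assert row["incremental"] == pytest.approx(
                row["DTG"] - row["RAL"], rel=1e-9, abs=1e-9)
        reloaded = pd.read_csv(written["price_sweep"])
        num_cols = ["multiplier", "delta_cost", "delta_qaly", "icer"]
        pd.testing.assert_frame_equal(
            reloaded[num_cols], sweep[num_cols], check_exact=False, rtol=1e-12)
        # parameter dump reloads to the identical bundle
        again = load_parameters(None)
        import yaml
        from hivsim import ModelParameters
        with open(written["parameters"]) as fh:
            dumped = ModelParameters.from_dict(yaml.safe_load(fh))
        assert dumped == params == again

    def test_crn_null_report(self, tmp_path, params):
        p = load_parameters(identical_arm_overrides(params))
        base = run_paired(p, 200, seed=13)
        written = render_report(tmp_path, base)
        table = pd.read_csv(written["base_case"])
        assert (table["incremental"] == 0.0).all()
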