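"""Event loop, reproducibility, calibration, and the replay oracle."""

import numpy as np
import pandas as pd
import pytest

from hivsim import (
    CalibrationError,
    ScriptedDraws,
    Slot,
    calibrate_resistance,
    compare_arms,
    line_art_cost,
    line_sequence,
    load_parameters,
    perturb,
    run_cohort,
    run_paired,
    sample_cohort,
    simulate_patient,
)
from hivsim.cohort import PatientState, patient_from_row
from hivsim.strata import OI_TYPES, ROUTINE_STRATA
from conftest import identical_arm_overrides, quiet_overrides


class TestDegenerateClosedForms:
    def test_event_free_run_has_closed_form_accruals(self, params):
        """No events, flat routine price, 120-month horizon: life years and
        costs follow from arithmetic."""
        over = quiet_overrides()
        over["costs"] = {"routine_monthly": {
            s: {"no_history": 300.0, "history": 300.0} for s in ROUTINE_STRATA}}
        over["simulation"] = {"horizon_months": 120}
        p = load_parameters(over)
        res = run_cohort("DTG", p, 50, seed=2, collect_patients=True)
        pts = res.patients
        assert np.allclose(pts["ly_undisc"], 10.0, atol=1e-9)
        expected = 120 * (612.0 + 986.0 + 300.0 + 18.0)
        assert np.allclose(pts["total_cost_undisc"], expected, rtol=1e-12)
        # CD4 climbs past 200 everywhere almost immediately, but patients
        # starting below 200 spend early months at lower utilities; patients
        # starting above stay at 0.900 throughout
        high = pts[sample_cohort(50, p.cohort, 2)["cd4"].to_numpy() > 200]
        assert np.allclose(high["qaly_undisc"], 9.0, atol=1e-9)

    def test_determinism(self, params):
        a = run_cohort("DTG", params, 400, seed=7, collect_patients=True)
        b = run_cohort("DTG", params, 400, seed=7, collect_patients=True)
        assert a.means == b.means and a.ses == b.ses
        pd.testing.assert_frame_equal(a.patients, b.patients)

    def test_single_patient_equals_cohort_of_one(self, params):
        seed = 55
        row = sample_cohort(1, params.cohort, seed).iloc[0]
        outcome = simulate_patient(patient_from_row(row), "DTG", params, seed)
        res = run_cohort("DTG", params, 1, seed, collect_patients=True)
        pts = res.patients.iloc[0]
        assert outcome.health_undiscounted.life_years == pytest.approx(pts["ly_undisc"])
        assert outcome.health_discounted.qalys == pytest.approx(pts["qaly_disc"])
        assert outcome.costs_discounted.total == pytest.approx(pts["total_cost"])


class TestCommonRandomNumbers:
    def test_identical_arms_give_exactly_zero_increments(self, params):
        p = load_parameters(identical_arm_overrides(params))
        _, _, inc = run_paired(p, 400, seed=3)
        assert all(v == 0.0 for v in inc.deltas.values())
        assert inc.dominance == "equivalent" and inc.icer is None

    def test_baseline_draws_shared_across_arms(self, params):
        """The cohort is a function of the seed only, never the arm."""
        pd.testing.assert_frame_equal(
            sample_cohort(500, params.cohort, 9), sample_cohort(500, params.cohort, 9))

    def test_cost_only_perturbation_leaves_health_untouched(self, params):
        base = run_cohort("DTG", params, 800, seed=13)
        dearer = run_cohort("DTG", perturb(params, "costs/art_monthly/OBT2.2", 2740.0),
                            800, seed=13)
        assert dearer.means["qaly_disc"] == base.means["qaly_disc"]
        assert dearer.means["ly_undisc"] == base.means["ly_undisc"]
        assert dearer.means["total_cost"] > base.means["total_cost"]


def test_monte_carlo_standard_error_scaling(params):
    """Quadrupling n should roughly halve the standard error."""
    p = perturb(params, "simulation/horizon_months", 180)
    small = run_cohort("DTG", p, 2000, seed=17)
    large = run_cohort("DTG", p, 8000, seed=19)
    for key in ("qaly_disc", "total_cost"):
        ratio = small.ses[key] / large.ses[key]
        assert 1.5 < ratio < 2.6


class TestScriptedPaths:
    def test_forced_failure_cascade_matches_hand_ledger(self, params):
        """A patient failing every line on schedule: line-1 failure with
        resistance at month 11, second-line failure at 23, salvage failure
        at 35, then failing the last line until the 40-month horizon.
        Accruals must match the hand-computed ledger exactly."""
        p = perturb(params, "simulation/horizon_months", 40)
        patient = PatientState(id=0, age_months=480, sex="M", cd4=350.0)
        draws = ScriptedDraws({(11, Slot.RESISTANCE): 0.0})
        out = simulate_patient(patient, "DTG", p, draws)

        assert out.ini_resistant_after_line1 and out.exited_first_line
        assert out.months_per_line == {"DTG+OBT1": 12, "OBT2.2": 12, "Salvage 2": 16}
        assert out.death_cause is None
        assert not out.reached_aids
        assert out.aids_free_years == pytest.approx(40 / 12)

        und = out.costs_undiscounted
        assert und.art == pytest.approx(12 * 1598.0 + 12 * 2491.0 + 16 * 2491.0)
        assert und.routine == pytest.approx(40 * 377.0)   # CD4 stays in 201-350
        assert und.tests == pytest.approx(40 * 18.0 + 3 * 300.0)  # 3 genotypes
        assert und.switch == pytest.approx(2 * 400.0)     # terminal exit is not a switch
        assert und.oi == 0.0 and und.death == 0.0
        assert out.health_undiscounted.life_years == pytest.approx(40 / 12)
        assert out.health_undiscounted.qalys == pytest.approx(40 * 0.9 / 12)
        # discounting: every component shrinks, none grows
        dis = out.costs_discounted
        for f in ("art", "routine", "tests", "switch"):
            assert 0 < getattr(dis, f) < getattr(und, f)

    def test_event_free_patient_stays_put(self, quiet_params):
        p = perturb(quiet_params, "simulation/horizon_months", 24)
        patient = PatientState(id=3, age_months=500, sex="F", cd4=420.0)
        out = simulate_patient(patient, "RAL", p, ScriptedDraws({}))
        assert out.months_per_line == {"RAL+OBT1": 24}
        assert not out.exited_first_line
        assert out.health_undiscounted.life_years == pytest.approx(2.0)


class TestReplayOracle:
    def test_accruals_match_brute_force_replay_of_state_log(self, params):
        """With discounting off, an independent month-by-month replay of the
        logged states must reproduce every patient's life years, QALYs and
        cost components (no double counting, no missed months)."""
        p = perturb(params, "discount/rate_early", 0.0)
        p = perturb(p, "discount/rate_late", 0.0)
        res = run_cohort("DTG", p, 300, seed=29, collect_patients=True, log_states=True)
        states, pts = res.states, res.patients.set_index("id")

        label_cost = {}
        for resistant in (False, True):
            for line in line_sequence("DTG", resistant, p):
                label_cost[line.label] = line_art_cost(line, p)
        util4 = [p.utilities.by_cd4[s] for s in ("le50", "s51_100", "s101_200", "gt200")]
        util_oi = [p.utilities.by_oi[t] for t in OI_TYPES]
        routine = {s: p.costs.routine_monthly[s] for s in ROUTINE_STRATA}
        oi_cost = [p.costs.oi_event[t] for t in OI_TYPES]

        def stratum6(cd4):
            for edge, name in zip((50, 100, 200, 350, 500),
                                  ("le50", "s51_100", "s101_200", "s201_350", "s351_500")):
                if cd4 <= edge:
                    return name
            return "gt500"

        def util(cd4, oi_type):
            base = util4[min(np.searchsorted([50, 100, 200], cd4, side="left"), 3)]
            return min(base, util_oi[oi_type]) if oi_type >= 0 else base

        replay = {}
        for row in states.itertuples():
            acc = replay.setdefault(row.id, dict.fromkeys(
                ("ly", "qaly", "art", "routine", "oi", "death", "tests", "switch"), 0.0))
            acc["ly"] += 1 / 12
            acc["qaly"] += util(row.cd4, row.oi_type) / 12
            acc["art"] += label_cost[row.label]
            acc["routine"] += routine[stratum6(row.cd4)][
                "history" if row.oi_history else "no_history"]
            acc["tests"] += p.costs.lab_monthly + (
                p.costs.genotype_test if row.virologic_failure else 0.0)
            acc["switch"] += p.costs.switch_cost if row.switching else 0.0
            if row.oi_onset_type >= 0:
                acc["oi"] += oi_cost[row.oi_onset_type]
            if row.dying:
                if row.recent_oi:
                    acc["death"] += p.costs.death["history_le30d"]
                elif row.oi_history:
                    acc["death"] += p.costs.death["history_gt30d"]
                else:
                    acc["death"] += p.costs.death["no_history"]

        for pid, acc in replay.items():
            row = pts.loc[pid]
            assert acc["ly"] == pytest.approx(row["ly_undisc"], rel=1e-9)
            assert acc["qaly"] == pytest.approx(row["qaly_undisc"], rel=1e-9)
            for comp in ("art", "routine", "oi", "death", "tests", "switch"):
                assert acc[comp] == pytest.approx(row[f"cost_{comp}_undisc"],
                                                  rel=1e-9, abs=1e-9), (pid, comp)


class TestCalibration:
    def test_target_one_needs_no_resistance(self, params):
        probs = calibrate_resistance({"DTG": 1.0}, params, n=5000, seed=3)
        assert probs["DTG"] < 0.02

    def test_closed_form_recovery_without_competing_exits(self):
        """With death, AEs and OIs off, every first-line exit is virologic,
        so the no-resistance proportion is 1 - p and calibration must
        recover p."""
        zeros = {s: 0.0 for s in ROUTINE_STRATA}
        p = load_parameters({
            "oi": {"hazards_monthly": {t: dict(zeros) for t in OI_TYPES}},
            "mortality": {"background": [[15, 0.0, 0.0]],
                          "hiv_excess_annual": dict(zeros)},
            "ae": {"discontinuation_monthly": 0.0},
        })
        probs = calibrate_resistance({"DTG": 0.7}, p, n=10_000, seed=5)
        assert probs["DTG"] == pytest.approx(0.3, abs=0.02)

    def test_unattainable_target_reports_range(self, params):
        with pytest.raises(CalibrationError, match="attainable range"):
            calibrate_resistance({"DTG": 0.05}, params, n=5000, seed=7)

    def test_invalid_target_rejected(self, params):
        with pytest.raises(ValueError):
            calibrate_resistance({"DTG": 0.0}, params, n=100, seed=1)


def test_fingerprint_guard_between_arms(params):
    a = run_cohort("DTG", params, 50, seed=1)
    b = run_cohort("RAL", perturb(params, "costs/switch_cost", 999.0), 50, seed=1)
    with pytest.raises(ValueError, match="not comparable"):
        compare_arms(a, b)
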