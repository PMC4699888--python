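"""Per-patient monthly event loop and cohort-level execution.

Each simulated month applies, in a fixed contract order: (1) death draws,
(2) opportunistic-infection resolution and onset, (3) virologic evaluation
(the week-48 endpoint at month 12 on a line; monthly late-failure risk once
suppressed beyond it), (4) adverse-event discontinuation, (5) line
transition (with the resistance draw at a first-line virologic exit),
(6) CD4 update, and (7) cost/QALY accrual with discounting. The death month
is inclusive: the dying patient accrues that month's care, tests, ART and
utility (state frozen at month start, opportunistic-infection events
excepted) plus the one-off death cost. Dead patients never transition;
survivors past the age cap or a finite horizon are censored without a death
cost.

The loop is vectorized across patients; every random draw comes from the
counter-based streams in :mod:`hivsim.rng`, so results are deterministic,
independent of execution order, and paired across arms (common random
numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientState, sample_cohort
from .dynamics import MortalityTables, oi_hazard_matrix, sample_oi_type
from .economics import CostAccrual, CostTables, QalyAccrual
from .parameters import ModelParameters, discount_factor, fingerprint, perturb
from .rng import CounterRng, Slot
from .strata import OI_TYPES, routine_stratum_index
from .treatment import YEAR1_EVAL_MONTH, line_art_cost

__all__ = [
    "PatientOutcome",
    "ArmResults",
    "run_cohort",
    "simulate_patient",
    "simulate_first_line",
    "calibrate_resistance",
    "CalibrationError",
]

_CAT_INDEX = {"first": 0, "second": 1, "salvage": 2}
_DEATH_CAUSES = {1: "HIV/AIDS", 2: "HIV/AIDS including OI", 3: "other"}
_COMPONENTS = ("art", "routine", "oi", "death", "tests", "switch")


class CalibrationError(RuntimeError):
    """Raised when a calibration target is outside the attainable range."""


@dataclass
class PatientOutcome:
    """Lifetime accruals and clinical outcomes for one simulated patient."""

    costs_undiscounted: CostAccrual
    costs_discounted: CostAccrual
    health_undiscounted: QalyAccrual
    health_discounted: QalyAccrual
    months_per_line: dict[str, int]
    oi_counts: dict[str, int]
    reached_aids: bool
    aids_free_years: float
    death_cause: str | None
    exited_first_line: bool
    ini_resistant_after_line1: bool


@dataclass
class ArmResults:
    """Cohort-level means (and Monte Carlo standard errors) for one arm."""

    arm: str
    n: int
    seed: int
    fingerprint: str
    means: dict[str, float]
    ses: dict[str, float] = field(default_factory=dict)
    patients: pd.DataFrame | None = None
    states: pd.DataFrame | None = None


class _PathTables:
    """Per-(resistance path, line position) parameter matrices for one arm.

    Row 0 is the no-resistance path, row 1 the INI-resistance path; the
    shorter path is right-padded with its final line (never reached: the
    position saturates once the last line has failed).
    """

    def __init__(self, arm: str, params: ModelParameters):
        alg = params.algorithm[arm]
        paths = [alg.sequence(False), alg.sequence(True)]
        self.plen = np.array([len(p) for p in paths])
        width = int(self.plen.max())

        def mat(fn, dtype=float):
            out = np.zeros((2, width), dtype)
            for r, seq in enumerate(paths):
                vals = [fn(line) for line in seq]
                vals += [vals[-1]] * (width - len(vals))
                out[r] = vals
            return out

        eff = lambda line: params.efficacy[line.efficacy]
        self.supp = mat(lambda l: eff(l).suppression_rate_y1)
        self.late1 = mat(lambda l: eff(l).late_failure_monthly_48_96)
        self.late2 = mat(lambda l: eff(l).late_failure_monthly_after96)
        self.g1 = mat(lambda l: eff(l).cd4_gain_y1)
        self.g2 = mat(lambda l: eff(l).cd4_gain_y2)
        self.glater = mat(lambda l: eff(l).cd4_gain_later)
        self.art = mat(lambda l: line_art_cost(l, params))
        self.cat = mat(lambda l: _CAT_INDEX[l.category], np.int64)
        self.labels = [
            [l.label for l in seq] + [seq[-1].label] * (width - len(seq)) for seq in paths
        ]


def _simulate(cohort: pd.DataFrame, arm: str, params: ModelParameters, draws,
              *, stop_after_line1: bool = False, log_states: bool = False) -> dict:
    """Run the monthly event loop; return raw per-patient accrual arrays."""
    n = len(cohort)
    pt = _PathTables(arm, params)
    ct = CostTables(params)
    mt = MortalityTables(params)
    hazards = oi_hazard_matrix(params)
    hist_mult = params.oi.history_multiplier
    duration = params.oi.duration_months
    ae_p = params.ae_discontinuation_monthly
    p_res = params.resistance_prob_on_failure[arm]
    cd4_cap = params.progression.cd4_cap
    scenario = params.progression.terminal_scenario
    pr = params.progression
    macs_table = np.array(
        [pr.macs_decline_monthly[s] for s in
         ("le50", "s51_100", "s101_200", "s201_350", "s351_500", "gt500")]
    )
    sim = params.simulation
    age_cap_m = sim.age_cap_years * 12

    ids = cohort["id"].to_numpy(np.int64)
    age_m = cohort["age_months"].to_numpy(np.int32).copy()
    sex_idx = (cohort["sex"].to_numpy() == "F").astype(np.int64)
    cd4 = np.clip(cohort["cd4"].to_numpy(float).copy(), 0.0, cd4_cap)
    oi_hist = cohort["oi_history"].to_numpy(bool).copy()

    hard_cap = sim.horizon_months if sim.horizon_months is not None else int(
        max(age_cap_m - age_m.min(), 1) + 1
    )
    df = discount_factor(np.arange(hard_cap), params.discount)
    dfc = df if params.discount.apply_to in ("costs", "both") else np.ones(hard_cap)
    dfq = df if params.discount.apply_to in ("qalys", "both") else np.ones(hard_cap)

    alive = np.ones(n, bool)
    death_cause = np.full(n, -1, np.int8)       # -1 alive, 0 censored, 1/2/3 causes
    res = np.zeros(n, bool)
    pos = np.zeros(n, np.int64)
    mol = np.zeros(n, np.int32)                 # 0-based months on line at month start
    responder = np.zeros(n, bool)
    suppressed = np.zeros(n, bool)
    failing_last = np.zeros(n, bool)
    oi_type = np.full(n, -1, np.int8)
    oi_left = np.zeros(n, np.int16)
    since_oi = np.full(n, 9999, np.int32)
    line1_gain = np.zeros(n)
    cum_line_gain = np.zeros(n)
    reached_aids = oi_hist | (cd4 < 200.0)
    aids_free_m = np.zeros(n, np.int32)
    exited_l1 = np.zeros(n, bool)
    exit_l1_vir = np.zeros(n, bool)
    resp_l1 = np.zeros(n, bool)
    months_cat = np.zeros((n, 3), np.int32)
    oi_counts = np.zeros((n, len(OI_TYPES)), np.int32)
    und = {c: np.zeros(n) for c in _COMPONENTS}
    dis = {c: np.zeros(n) for c in _COMPONENTS}
    art_first_und = np.zeros(n)
    art_first_dis = np.zeros(n)
    ly_und = np.zeros(n)
    ly_dis = np.zeros(n)
    q_und = np.zeros(n)
    q_dis = np.zeros(n)
    state_log: list[tuple] = []

    for m in range(hard_cap):
        act = np.flatnonzero(alive)
        if act.size == 0:
            break
        over = age_m[act] >= age_cap_m
        if over.any():
            cidx = act[over]
            alive[cidx] = False
            death_cause[cidx] = 0
            act = act[~over]
            if act.size == 0:
                break

        a_ids = ids[act]
        strat6 = routine_stratum_index(cd4[act])
        active_pre = oi_type[act] >= 0

        # (1) death draws (HIV tested first, inflated during an active OI)
        u_hiv = draws.uniform(a_ids, m, Slot.DEATH_HIV)
        u_bg = draws.uniform(a_ids, m, Slot.DEATH_BACKGROUND)
        hiv_death = u_hiv < mt.hiv_prob(strat6, active_pre)
        bg_death = ~hiv_death & (u_bg < mt.background_prob(age_m[act] // 12, sex_idx[act]))
        dying = hiv_death | bg_death
        live = ~dying

        # (2) OI resolution (episode expired at the previous month end) ...
        resolving = active_pre & (oi_left[act] == 0)
        if resolving.any():
            ridx = act[resolving]
            oi_type[ridx] = -1
            oi_hist[ridx] = True
            since_oi[ridx] = 0
        # ... then at most one new onset, dying patients included
        u_oi = draws.uniform(a_ids, m, Slot.OI_ONSET)
        new_t = sample_oi_type(u_oi, strat6, oi_hist[act], hazards, hist_mult)
        new_t = np.where(oi_type[act] < 0, new_t, -1)
        onset = new_t >= 0
        if onset.any():
            oidx = act[onset]
            tsel = new_t[onset]
            oi_type[oidx] = tsel
            oi_left[oidx] = duration
            oi_counts[oidx, tsel] += 1

        r_pre = res[act].astype(np.int64)
        p_pre = pos[act].copy()
        mol_a = mol[act]
        failing_pre = failing_last[act].copy()

        # (3) virologic evaluation
        u_y1 = draws.uniform(a_ids, m, Slot.YEAR1_SUPPRESSION)
        resp_new = u_y1 < pt.supp[r_pre, p_pre]
        newline = live & (mol_a == 0) & ~failing_pre
        if newline.any():
            nidx = act[newline]
            responder[nidx] = resp_new[newline]
            suppressed[nidx] = resp_new[newline]
            firstline = newline & (p_pre == 0)
            resp_l1[act[firstline]] = resp_new[firstline]
        supp_a = suppressed[act]
        y1fail = live & ~failing_pre & (mol_a == YEAR1_EVAL_MONTH) & ~responder[act]
        u_lf = draws.uniform(a_ids, m, Slot.LATE_FAILURE)
        late_rate = np.where(mol_a < 24, pt.late1[r_pre, p_pre], pt.late2[r_pre, p_pre])
        latefail = live & supp_a & (mol_a >= 12) & (u_lf < late_rate)
        virfail = y1fail | latefail
        if latefail.any():
            suppressed[act[latefail]] = False

        # (4) adverse-event discontinuation (no successor on the final line)
        u_ae = draws.uniform(a_ids, m, Slot.AE_DISCONTINUATION)
        final_line = p_pre == (pt.plen[r_pre] - 1)
        ae = live & ~virfail & ~failing_pre & ~final_line & (u_ae < ae_p)

        # (5) transitions
        to_terminal = virfail & final_line
        if to_terminal.any():
            failing_last[act[to_terminal]] = True
        switching = (virfail | ae) & ~final_line
        u_res = draws.uniform(a_ids, m, Slot.RESISTANCE)
        res_acq = switching & virfail & (p_pre == 0) & (u_res < p_res)
        if res_acq.any():
            res[act[res_acq]] = True
        l1exit = switching & (p_pre == 0)
        if l1exit.any():
            exited_l1[act[l1exit]] = True
            exit_l1_vir[act[l1exit]] = virfail[l1exit]
        if switching.any():
            pos[act[switching]] += 1

        # (6) CD4 update: gains on suppressive therapy (subsequent-line and
        # absolute caps), plateau on failing therapy, terminal decline after
        # the last line has failed
        month1 = mol_a + 1
        g1 = pt.g1[r_pre, p_pre]
        gain = np.where(
            month1 <= 2, g1 * (2.0 / 3.0) / 2.0,
            np.where(month1 <= 11, g1 / 27.0,
                     np.where(month1 <= 23, pt.g2[r_pre, p_pre] / 12.0,
                              pt.glater[r_pre, p_pre] / 12.0)),
        )
        allowed = np.where(p_pre > 0,
                           np.maximum(line1_gain[act] - cum_line_gain[act], 0.0), np.inf)
        gain = np.minimum(np.minimum(gain, allowed), cd4_cap - cd4[act])
        gain = np.where(live & supp_a & ~failing_pre, np.maximum(gain, 0.0), 0.0)
        cd4[act] += gain
        line1_gain[act] += gain * (p_pre == 0)
        cum_line_gain[act] += gain * (p_pre > 0)
        if switching.any():
            cum_line_gain[act[switching]] = 0.0
        tmask = live & failing_pre
        if tmask.any():
            tcd4 = cd4[act[tmask]]
            if scenario == "no_decline":
                dec = 0.0
            elif scenario == "macs_decline":
                dec = -macs_table[routine_stratum_index(tcd4)]
            else:
                dec = -pr.terminal_decline_monthly
            cd4[act[tmask]] = np.clip(tcd4 + dec, 0.0, cd4_cap)

        # (7) accrual — all patients alive at month start, death month included
        cd4_now = cd4[act]
        strat_now = routine_stratum_index(cd4_now)
        hist_now = oi_hist[act]
        art_m = pt.art[r_pre, p_pre]
        routine_m = ct.routine[strat_now, hist_now.astype(int)]
        tests_m = ct.lab_monthly + ct.genotype_test * virfail
        oi_m = np.where(onset, ct.oi_event[np.clip(new_t, 0, None)], 0.0)
        switch_m = ct.switch_cost * switching
        recent = (oi_type[act] >= 0) | (since_oi[act] <= 1)
        death_m = np.where(dying, ct.death[ct.death_cost_key(recent, hist_now)], 0.0)
        fc, fq = dfc[m], dfq[m]
        np.add.at(und["art"], act, art_m)
        np.add.at(dis["art"], act, art_m * fc)
        firstmask = p_pre == 0
        np.add.at(art_first_und, act, art_m * firstmask)
        np.add.at(art_first_dis, act, art_m * firstmask * fc)
        for name, vals in (("routine", routine_m), ("oi", oi_m), ("death", death_m),
                           ("tests", tests_m), ("switch", switch_m)):
            np.add.at(und[name], act, vals)
            np.add.at(dis[name], act, vals * fc)
        u_health = ct.utility(cd4_now, oi_type[act])
        np.add.at(ly_und, act, 1.0 / 12.0)
        np.add.at(ly_dis, act, fq / 12.0)
        np.add.at(q_und, act, u_health / 12.0)
        np.add.at(q_dis, act, u_health * fq / 12.0)
        months_cat[act, pt.cat[r_pre, p_pre]] += 1
        now_aids = (oi_type[act] >= 0) | (cd4_now < 200.0)
        newly_aids = now_aids & ~reached_aids[act]
        if newly_aids.any():
            reached_aids[act[newly_aids]] = True
        free = ~reached_aids[act]
        aids_free_m[act[free]] += 1
        if log_states:
            state_log.append((m, act.copy(), cd4_now.copy(), oi_type[act].copy(),
                              hist_now.copy(), r_pre.copy(), p_pre.copy(),
                              virfail.copy(), switching.copy(), new_t.copy(),
                              dying.copy(), recent.copy()))

        # end-of-month bookkeeping
        if dying.any():
            didx = act[dying]
            alive[didx] = False
            death_cause[didx] = np.where(hiv_death[dying], np.where(recent[dying], 2, 1), 3)
        lidx = act[live]
        mol[act[live & ~switching]] += 1
        mol[act[switching]] = 0
        ticking = lidx[oi_type[lidx] >= 0]
        oi_left[ticking] -= 1
        waiting = lidx[(oi_type[lidx] < 0) & oi_hist[lidx]]
        since_oi[waiting] += 1
        age_m[act] += 1
        if stop_after_line1:
            done = act[live & exited_l1[act]]
            if done.size:
                alive[done] = False
                death_cause[done] = 0

    # survivors at a finite horizon (or frozen first-line exiters) are censored
    death_cause[alive] = 0

    states = None
    if log_states:
        frames = []
        for (m, act, c, ot, hi, r, p, vf, sw, nt, dy, rc) in state_log:
            frames.append(pd.DataFrame({
                "month": m, "id": ids[act], "cd4": c, "oi_type": ot,
                "oi_history": hi, "resistant_path": r.astype(bool), "position": p,
                "label": [pt.labels[rr][pp] for rr, pp in zip(r, p)],
                "category": pt.cat[r, p],
                "virologic_failure": vf, "switching": sw, "oi_onset_type": nt,
                "dying": dy, "recent_oi": rc,
            }))
        states = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    return {
        "ids": ids, "death_cause": death_cause, "res": res,
        "exited_l1": exited_l1, "exit_l1_vir": exit_l1_vir, "resp_l1": resp_l1,
        "months_cat": months_cat, "oi_counts": oi_counts,
        "reached_aids": reached_aids, "aids_free_m": aids_free_m,
        "und": und, "dis": dis,
        "art_first_und": art_first_und, "art_first_dis": art_first_dis,
        "ly_und": ly_und, "ly_dis": ly_dis, "q_und": q_und, "q_dis": q_dis,
        "states": states, "path_tables": pt,
    }


def _results_from_raw(arm: str, raw: dict, params: ModelParameters, n: int, seed: int,
                      collect_patients: bool) -> ArmResults:
    und, dis = raw["und"], raw["dis"]
    total_und = sum(und.values())
    total_dis = sum(dis.values())
    dead = raw["death_cause"] >= 1
    ndead = int(dead.sum())
    exited = raw["exited_l1"]
    nexit = int(exited.sum())

    means = {
        "total_cost": float(total_dis.mean()),
        "total_cost_undisc": float(total_und.mean()),
        "ly_undisc": float(raw["ly_und"].mean()),
        "ly_disc": float(raw["ly_dis"].mean()),
        "qaly_disc": float(raw["q_dis"].mean()),
        "qaly_undisc": float(raw["q_und"].mean()),
        "months_line1": float(raw["months_cat"][:, 0].mean()),
        "months_line2": float(raw["months_cat"][:, 1].mean()),
        "months_salvage": float(raw["months_cat"][:, 2].mean()),
        "aids_pct": float(raw["reached_aids"].mean() * 100.0),
        "aids_free_years": float(raw["aids_free_m"].mean() / 12.0),
        "no_resistance_pct": float((~raw["res"][exited]).mean() * 100.0) if nexit else float("nan"),
        "line1_year1_response_pct": float(raw["resp_l1"].mean() * 100.0),
        "cost_art": float(dis["art"].mean()),
        "cost_art_first_line": float(raw["art_first_dis"].mean()),
        "cost_art_subsequent": float((dis["art"] - raw["art_first_dis"]).mean()),
        "cost_care": float(dis["routine"].mean()),
        "cost_death": float(dis["death"].mean()),
        "cost_tests": float(dis["tests"].mean()),
        "cost_oi": float(dis["oi"].mean()),
        "cost_switch": float(dis["switch"].mean()),
    }
    for t_idx, t in enumerate(OI_TYPES):
        means[f"oi_{t}_pct"] = float((raw["oi_counts"][:, t_idx] > 0).mean() * 100.0)
    for code, name in ((1, "death_hiv_pct"), (2, "death_hiv_oi_pct"), (3, "death_other_pct")):
        means[name] = float((raw["death_cause"][dead] == code).mean() * 100.0) if ndead else float("nan")
    # the printed convention reports HIV/AIDS inclusive of the OI subset
    if ndead:
        means["death_hiv_pct"] += means["death_hiv_oi_pct"]

    sqrt_n = np.sqrt(n)
    ses = {
        "ly_undisc": float(raw["ly_und"].std(ddof=1) / sqrt_n) if n > 1 else 0.0,
        "qaly_disc": float(raw["q_dis"].std(ddof=1) / sqrt_n) if n > 1 else 0.0,
        "total_cost": float(total_dis.std(ddof=1) / sqrt_n) if n > 1 else 0.0,
    }

    patients = None
    if collect_patients:
        cols = {
            "id": raw["ids"], "ly_undisc": raw["ly_und"], "ly_disc": raw["ly_dis"],
            "qaly_undisc": raw["q_und"], "qaly_disc": raw["q_dis"],
            "total_cost": total_dis, "total_cost_undisc": total_und,
            "death_cause": raw["death_cause"], "ini_resistant": raw["res"],
            "exited_first_line": exited, "reached_aids": raw["reached_aids"],
            "aids_free_years": raw["aids_free_m"] / 12.0,
        }
        for c in _COMPONENTS:
            cols[f"cost_{c}"] = dis[c]
            cols[f"cost_{c}_undisc"] = und[c]
        for t_idx, t in enumerate(OI_TYPES):
            cols[f"oi_{t}"] = raw["oi_counts"][:, t_idx]
        for c_idx, c in enumerate(("line1", "line2", "salvage")):
            cols[f"months_{c}"] = raw["months_cat"][:, c_idx]
        patients = pd.DataFrame(cols)

    return ArmResults(arm=arm, n=n, seed=seed, fingerprint=fingerprint(params),
                      means=means, ses=ses, patients=patients, states=raw["states"])


def run_cohort(arm: str, params: ModelParameters, n: int | None = None,
               seed: int | None = None, *, collect_patients: bool = False,
               log_states: bool = False, draws=None,
               stop_after_line1: bool = False) -> ArmResults:
    """Simulate ``n`` independent patients through the given arm.

    ``n`` and ``seed`` default to the simulation settings in ``params``.
    Identical ``(arm, params, n, seed)`` reproduce identical results; the
    seed also fixes the baseline cohort, which is arm-invariant (common
    random numbers).
    """
    if arm not in params.algorithm:
        raise KeyError(f"unknown arm '{arm}'; configured arms: {sorted(params.algorithm)}")
    n = params.simulation.n_patients if n is None else int(n)
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    seed = params.simulation.seed if seed is None else int(seed)
    cohort = sample_cohort(n, params.cohort, seed)
    if draws is None:
        draws = CounterRng(seed)
    raw = _simulate(cohort, arm, params, draws,
                    stop_after_line1=stop_after_line1, log_states=log_states)
    return _results_from_raw(arm, raw, params, n, seed, collect_patients)


def simulate_patient(patient: PatientState, arm: str, params: ModelParameters,
                     rng) -> PatientOutcome:
    """Run one patient through the monthly loop.

    ``rng`` is either an integer seed (the patient re-uses its counter-based
    substream keyed by its id) or a draw source such as
    :class:`~hivsim.rng.ScriptedDraws`.
    """
    draws = CounterRng(rng) if isinstance(rng, int) else rng
    cohort = pd.DataFrame({
        "id": [patient.id], "age_months": np.array([patient.age_months], np.int32),
        "sex": [patient.sex], "cd4": [patient.cd4],
        "suppressed": [patient.suppressed], "oi_history": [patient.oi_history],
        "log10_vl": [patient.log10_vl],
    })
    raw = _simulate(cohort, arm, params, draws, log_states=True)
    und, dis = raw["und"], raw["dis"]
    months_per_line: dict[str, int] = {}
    if raw["states"] is not None and len(raw["states"]):
        months_per_line = raw["states"]["label"].value_counts().to_dict()
    cause_code = int(raw["death_cause"][0])
    return PatientOutcome(
        costs_undiscounted=CostAccrual(*(float(und[c][0]) for c in _COMPONENTS)),
        costs_discounted=CostAccrual(*(float(dis[c][0]) for c in _COMPONENTS)),
        health_undiscounted=QalyAccrual(float(raw["ly_und"][0]), float(raw["q_und"][0])),
        health_discounted=QalyAccrual(float(raw["ly_dis"][0]), float(raw["q_dis"][0])),
        months_per_line={k: int(v) for k, v in months_per_line.items()},
        oi_counts={t: int(raw["oi_counts"][0, i]) for i, t in enumerate(OI_TYPES)},
        reached_aids=bool(raw["reached_aids"][0]),
        aids_free_years=float(raw["aids_free_m"][0] / 12.0),
        death_cause=_DEATH_CAUSES.get(cause_code),
        exited_first_line=bool(raw["exited_l1"][0]),
        ini_resistant_after_line1=bool(raw["res"][0]),
    )


def simulate_first_line(arm: str, params: ModelParameters, n: int, seed: int) -> dict:
    """Simulate the first-line phase only and summarise how patients leave it.

    Patients are followed until they exit line 1 (virologic failure or
    adverse-event switch), die, or are censored. The no-resistance
    proportion is measured among patients who leave the line alive.
    """
    cohort = sample_cohort(n, params.cohort, seed)
    raw = _simulate(cohort, arm, params, CounterRng(seed), stop_after_line1=True)
    exited = raw["exited_l1"]
    nexit = int(exited.sum())
    return {
        "n": n,
        "n_exited_alive": nexit,
        "no_resistance_pct": float((~raw["res"][exited]).mean() * 100.0) if nexit else float("nan"),
        "virologic_exit_fraction": float(raw["exit_l1_vir"][exited].mean()) if nexit else float("nan"),
        "year1_response_pct": float(raw["resp_l1"].mean() * 100.0),
        "died_on_line1_pct": float((raw["death_cause"] >= 1).mean() * 100.0),
    }


def calibrate_resistance(targets: dict[str, float], params: ModelParameters,
                         n: int = 20_000, seed: int = 1234,
                         tol: float = 0.005) -> dict[str, float]:
    """Solve for per-arm resistance-acquisition probabilities.

    For each arm, bisection on the probability of acquiring INI resistance
    at a first-line virologic failure until the simulated post-first-line
    no-resistance proportion (at reduced ``n``, fixed ``seed``) matches the
    target proportion within ``tol`` (default 0.5 percentage points).
    Targets are proportions in (0, 1]. Raises :class:`CalibrationError`
    with the attainable range when a target cannot be reached.
    """
    out: dict[str, float] = {}
    for arm, target in targets.items():
        if not 0.0 < target <= 1.0:
            raise ValueError(f"target for {arm} must be in (0, 1]: {target}")

        def measured(p: float) -> float:
            pp = perturb(params, f"resistance/prob_on_failure/{arm}", float(p))
            return simulate_first_line(arm, pp, n, seed)["no_resistance_pct"] / 100.0

        floor = measured(1.0)  # every virologic first-line exit acquires resistance
        if target < floor - tol:
            raise CalibrationError(
                f"{arm}: target no-resistance {target:.4f} below attainable range "
                f"[{floor:.4f}, 1.0] (every first-line virologic failure already "
                "acquires resistance at probability 1)"
            )
        lo, hi = 0.0, 1.0  # measured is non-increasing in p; measured(0) == 1
        best_p, best_val = 1.0, floor
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            val = measured(mid)
            if abs(val - target) < abs(best_val - target):
                best_p, best_val = mid, val
            if abs(val - target) <= tol and hi - lo < 0.02:
                break
            if val > target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-4:
                break
        if abs(best_val - target) > tol:
            raise CalibrationError(
                f"{arm}: bisection stalled at p={best_p:.4f} "
                f"(measured {best_val:.4f} vs target {target:.4f})"
            )
        out[arm] = best_p
    return out
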