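"""Arm comparison, incremental cost-effectiveness, and sensitivity analyses.

The base-case surface is a paired comparison of the two strategies run on
the same seed (common random numbers): per-outcome deltas, the incremental
cost-effectiveness ratio computed from unrounded cohort means, and a
dominance classification when the cost and QALY deltas disagree in sign.
On top of that sit the one-way deterministic sensitivity analysis (each
parameter re-run at its low and high value, results tornado-ordered by
ICER range), a set of structural scenarios (horizon, OI duration,
no-resistance world, discount rates, terminal CD4 decline), and a price
sweep on the DTG drug component.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .engine import ArmResults, run_cohort
from .parameters import ModelParameters, dump_parameters, perturb

__all__ = [
    "IncrementalResults",
    "DsaResult",
    "compare_arms",
    "run_paired",
    "run_dsa",
    "run_structural_scenarios",
    "price_sweep",
    "render_report",
    "TABLE_ROWS",
]

#: Outcome rows of the base-case report, in print order.
TABLE_ROWS = (
    "total_cost", "ly_undisc", "ly_disc", "qaly_disc",
    "months_line1", "months_line2", "months_salvage",
    "oi_bacterial_pct", "oi_fungal_pct", "oi_protozoal_pct", "oi_viral_pct",
    "oi_other_pct", "aids_pct", "aids_free_years", "no_resistance_pct",
    "death_hiv_pct", "death_hiv_oi_pct", "death_other_pct",
    "cost_art", "cost_art_first_line", "cost_art_subsequent", "cost_care",
    "cost_death", "cost_tests", "cost_oi", "cost_switch",
)


@dataclass
class IncrementalResults:
    """Deltas (first arm minus second) and the ICER or dominance label."""

    arm_a: str
    arm_b: str
    deltas: dict[str, float]
    icer: float | None
    dominance: str | None  # dominant | dominated | equivalent | None

    @property
    def delta_cost(self) -> float:
        return self.deltas["total_cost"]

    @property
    def delta_qaly(self) -> float:
        return self.deltas["qaly_disc"]

    @property
    def delta_ly(self) -> float:
        return self.deltas["ly_undisc"]


@dataclass
class DsaResult:
    """One tornado bar: ICER at the low and high value of one parameter."""

    path: str
    low: object
    high: object
    icer_low: float | None
    icer_high: float | None
    dominance_low: str | None
    dominance_high: str | None
    icer_base: float | None
    range: float = field(init=False)

    def __post_init__(self):
        vals = [v for v in (self.icer_low, self.icer_high) if v is not None]
        self.range = float(max(vals) - min(vals)) if len(vals) == 2 else float("inf")


def _classify(delta_cost: float, delta_qaly: float) -> tuple[float | None, str | None]:
    """Exhaustive ICER/dominance classification over the sign quadrants."""
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return None, "equivalent"
    if delta_qaly > 0.0 and delta_cost <= 0.0:
        return None, "dominant"        # cheaper (or equal) and more effective
    if delta_qaly < 0.0 and delta_cost >= 0.0:
        return None, "dominated"       # dearer (or equal) and less effective
    if delta_qaly == 0.0:
        return None, "dominated" if delta_cost > 0 else "dominant"
    return float(delta_cost / delta_qaly), None


def compare_arms(a: ArmResults, b: ArmResults) -> IncrementalResults:
    """Incremental outcomes of arm ``a`` over arm ``b``.

    Both results must come from the same cohort: equal n, seed and
    parameter fingerprint (the common-random-numbers pairing contract).
    The ICER is computed from unrounded means.
    """
    if (a.n, a.seed, a.fingerprint) != (b.n, b.seed, b.fingerprint):
        raise ValueError(
            "arms are not comparable: (n, seed, fingerprint) differ: "
            f"{(a.n, a.seed, a.fingerprint)} vs {(b.n, b.seed, b.fingerprint)}"
        )
    deltas = {k: a.means[k] - b.means[k] for k in a.means if k in b.means}
    icer, dominance = _classify(deltas["total_cost"], deltas["qaly_disc"])
    return IncrementalResults(arm_a=a.arm, arm_b=b.arm, deltas=deltas,
                              icer=icer, dominance=dominance)


def run_paired(params: ModelParameters, n: int | None = None,
               seed: int | None = None, arms: tuple[str, str] = ("DTG", "RAL"),
               **kwargs) -> tuple[ArmResults, ArmResults, IncrementalResults]:
    """Run both arms on the shared seed and compare them."""
    a = run_cohort(arms[0], params, n, seed, **kwargs)
    b = run_cohort(arms[1], params, n, seed, **kwargs)
    return a, b, compare_arms(a, b)


def run_dsa(base_params: ModelParameters, specs: list[dict] | None = None,
            n: int | None = None, seed: int | None = None) -> list[DsaResult]:
    """One-way deterministic sensitivity analysis.

    Each spec ``{path, low, high}`` is re-run with the addressed parameter
    at its low and at its high value; both arms are re-simulated on the
    shared seed per scenario. Results are tornado-ordered (largest ICER
    range first). All paths are validated before any simulation starts.
    """
    specs = base_params.dsa if specs is None else specs
    perturbed: list[tuple[dict, ModelParameters, ModelParameters]] = []
    for spec in specs:  # validate everything up front
        perturbed.append((
            spec,
            perturb(base_params, spec["path"], copy.deepcopy(spec["low"])),
            perturb(base_params, spec["path"], copy.deepcopy(spec["high"])),
        ))
    *_, base_inc = run_paired(base_params, n, seed)
    results = []
    for spec, p_low, p_high in perturbed:
        *_, inc_low = run_paired(p_low, n, seed)
        *_, inc_high = run_paired(p_high, n, seed)
        results.append(DsaResult(
            path=spec["path"], low=spec["low"], high=spec["high"],
            icer_low=inc_low.icer, icer_high=inc_high.icer,
            dominance_low=inc_low.dominance, dominance_high=inc_high.dominance,
            icer_base=base_inc.icer,
        ))
    results.sort(key=lambda r: r.range, reverse=True)
    return results


#: Structural scenarios: name -> parameter overrides expressed as perturb paths.
_SCENARIOS: dict[str, dict[str, object]] = {
    "base": {},
    "horizon_15y": {"simulation/horizon_months": 180},
    "oi_duration_1m": {"oi/duration_months": 1},
    "no_resistance": {"resistance/prob_on_failure/DTG": 0.0,
                      "resistance/prob_on_failure/RAL": 0.0},
    "discount_0pct": {"discount/rate_early": 0.0, "discount/rate_late": 0.0},
    "discount_6pct": {"discount/rate_early": 0.06, "discount/rate_late": 0.06},
    "terminal_decline_worst": {"progression/terminal_scenario": "macs_decline"},
    "terminal_no_decline": {"progression/terminal_scenario": "no_decline"},
}


def run_structural_scenarios(base_params: ModelParameters, n: int | None = None,
                             seed: int | None = None) -> pd.DataFrame:
    """Re-run the paired comparison under each structural scenario."""
    rows = []
    for name, overrides in _SCENARIOS.items():
        params = base_params
        for path, value in overrides.items():
            params = perturb(params, path, value)
        a, b, inc = run_paired(params, n, seed)
        rows.append({
            "scenario": name,
            "delta_cost": inc.delta_cost,
            "delta_qaly": inc.delta_qaly,
            "delta_ly_undisc": inc.delta_ly,
            "icer": inc.icer,
            "dominance": inc.dominance,
            "dtg_total_cost": a.means["total_cost"],
            "ral_total_cost": b.means["total_cost"],
            "dtg_qaly": a.means["qaly_disc"],
            "ral_qaly": b.means["qaly_disc"],
            "dtg_no_resistance_pct": a.means["no_resistance_pct"],
            "ral_no_resistance_pct": b.means["no_resistance_pct"],
        })
    return pd.DataFrame(rows)


def price_sweep(base_params: ModelParameters,
                multipliers: tuple[float, ...] = (0.8, 0.9, 1.0, 1.1, 1.2),
                n: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Re-run the paired comparison with the DTG drug-component price scaled.

    Only the DTG molecule's monthly price moves (the RAL component is priced
    separately); background-therapy and salvage prices are untouched. With
    shared seeds the QALY delta is exactly invariant, so the ICER is
    monotone in the multiplier.
    """
    if any(m <= 0 for m in multipliers):
        raise ValueError("price multipliers must be > 0")
    base_price = base_params.costs.art_monthly["DTG"]
    rows = []
    for mult in multipliers:
        params = perturb(base_params, "costs/art_monthly/DTG", base_price * mult)
        _, _, inc = run_paired(params, n, seed)
        rows.append({
            "multiplier": mult,
            "dtg_monthly_price": base_price * mult,
            "delta_cost": inc.delta_cost,
            "delta_qaly": inc.delta_qaly,
            "icer": inc.icer if inc.icer is not None else inc.delta_cost / inc.delta_qaly
            if inc.delta_qaly else float("nan"),
            "dominance": inc.dominance,
        })
    return pd.DataFrame(rows)


def render_report(outdir, base: tuple[ArmResults, ArmResults, IncrementalResults],
                  dsa: list[DsaResult] | None = None,
                  scenarios: pd.DataFrame | None = None,
                  sweep: pd.DataFrame | None = None,
                  params: ModelParameters | None = None) -> dict[str, str]:
    """Write the report files; return {artifact name: path}.

    The base-case table has one row per outcome and columns for each arm
    plus the incremental; companion files hold the tornado table, scenario
    table, price sweep, and a run-metadata log (seed, n, parameter
    fingerprint and full parameter dump) for provenance.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a, b, inc = base
    written: dict[str, str] = {}

    table = pd.DataFrame({
        "outcome": list(TABLE_ROWS),
        a.arm: [a.means[k] for k in TABLE_ROWS],
        b.arm: [b.means[k] for k in TABLE_ROWS],
        "incremental": [inc.deltas[k] for k in TABLE_ROWS],
    })
    path = outdir / "base_case.csv"
    table.to_csv(path, index=False)
    written["base_case"] = str(path)

    if dsa is not None:
        dsa_df = pd.DataFrame([{
            "path": r.path, "low": yaml.safe_dump(r.low, default_flow_style=True).strip(),
            "high": yaml.safe_dump(r.high, default_flow_style=True).strip(),
            "icer_low": r.icer_low, "icer_high": r.icer_high,
            "dominance_low": r.dominance_low, "dominance_high": r.dominance_high,
            "icer_base": r.icer_base, "range": r.range,
        } for r in dsa])
        path = outdir / "dsa_tornado.csv"
        dsa_df.to_csv(path, index=False)
        written["dsa_tornado"] = str(path)

    if scenarios is not None:
        path = outdir / "scenarios.csv"
        scenarios.to_csv(path, index=False)
        written["scenarios"] = str(path)

    if sweep is not None:
        path = outdir / "price_sweep.csv"
        sweep.to_csv(path, index=False)
        written["price_sweep"] = str(path)

    meta = {
        "arms": [a.arm, b.arm],
        "n": a.n,
        "seed": a.seed,
        "parameter_fingerprint": a.fingerprint,
        "icer": inc.icer,
        "dominance": inc.dominance,
        "mc_standard_errors": {a.arm: a.ses, b.arm: b.ses},
    }
    path = outdir / "run_metadata.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    written["run_metadata"] = str(path)
    if params is not None:
        path = outdir / "parameters.yaml"
        dump_parameters(params, path)
        written["parameters"] = str(path)
    return written
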