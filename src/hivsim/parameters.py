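"""Model parameterization: types, config I/O, validation, perturbation.

The full parameter bundle (:class:`ModelParameters`) is loaded from a nested
key-value YAML file. A complete bundled default file reproduces the
base case; a user file only needs to state overrides. Unknown keys are
rejected so a typo cannot silently fall back to a default. Every parameter
is addressable by a ``/``-separated path (e.g.
``costs/art_monthly/OBT2.2``), which is the handle the sensitivity-analysis
machinery uses to perturb one entry at a time.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
from dataclasses import dataclass, field

import yaml

from .strata import OI_TYPES, ROUTINE_STRATA, UTILITY_STRATA

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "DiscountSettings",
    "EfficacyBlock",
    "RegimenLine",
    "TreatmentAlgorithm",
    "CostTable",
    "UtilityTable",
    "BaselineProfile",
    "OiModel",
    "MortalityModel",
    "ProgressionSettings",
    "SimulationSettings",
    "ModelParameters",
    "load_parameters",
    "default_parameters",
    "dump_parameters",
    "perturb",
    "list_paths",
    "discount_factor",
    "fingerprint",
]

ARMS = ("DTG", "RAL")
LINE_CATEGORIES = ("first", "second", "salvage")
TERMINAL_SCENARIOS = ("base", "macs_decline", "no_decline")


class ConfigurationError(ValueError):
    """A config file is structurally unusable (missing/unknown sections)."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DiscountSettings:
    """Tiered annual discounting: ``rate_early`` up to ``switch_year``,
    ``rate_late`` thereafter, compounded piecewise-continuously so the
    factor has no jump at the boundary."""

    rate_early: float = 0.04
    rate_late: float = 0.02
    switch_year: float = 30.0
    apply_to: str = "both"


@dataclass
class EfficacyBlock:
    """Virologic and immunologic efficacy of one treatment line.

    ``suppression_rate_y1`` is the annual (week-48) suppression probability
    with its 95% CI; late-failure rates are monthly probabilities of rebound
    for weeks 48-96 and beyond week 96; CD4 gains are cells/uL accrued per
    year on suppressive therapy (year 1, year 2, later).
    """

    suppression_rate_y1: float
    suppression_ci: tuple[float, float]
    late_failure_monthly_48_96: float
    late_failure_monthly_after96: float
    cd4_gain_y1: float
    cd4_gain_y2: float
    cd4_gain_later: float


@dataclass
class RegimenLine:
    """One treatment line: label, ART price components, efficacy reference."""

    label: str
    cost_components: tuple[str, ...]
    efficacy: str
    category: str  # first | second | salvage

    @property
    def is_salvage(self) -> bool:
        return self.category == "salvage"


@dataclass
class TreatmentAlgorithm:
    """Successor table for one arm: line 1, then the branch selected by the
    INI-resistance status acquired at first-line virologic failure."""

    line1: RegimenLine
    no_resistance: tuple[RegimenLine, ...]
    ini_resistance: tuple[RegimenLine, ...]

    def sequence(self, ini_resistant: bool) -> tuple[RegimenLine, ...]:
        branch = self.ini_resistance if ini_resistant else self.no_resistance
        return (self.line1, *branch)


@dataclass
class CostTable:
    art_monthly: dict[str, float]
    art_bounds: dict[str, tuple[float, float]]
    routine_monthly: dict[str, dict[str, float]]
    oi_event: dict[str, float]
    death: dict[str, float]
    switch_cost: float
    lab_monthly: float
    genotype_test: float


@dataclass
class UtilityTable:
    by_cd4: dict[str, float]
    by_oi: dict[str, float]


@dataclass
class BaselineProfile:
    """Distributional profile of the entry cohort (all assumption knobs)."""

    age_mean_years: float = 43.0
    age_sd_years: float = 10.0
    age_min_years: float = 18.0
    age_max_years: float = 75.0
    proportion_male: float = 0.68
    cd4_log_mean: float = 5.2983
    cd4_log_sd: float = 0.8
    cd4_min: float = 10.0
    cd4_max: float = 750.0
    proportion_suppressed_at_entry: float = 0.0
    oi_history_proportion: float = 0.25
    log10_vl_mean: float = 4.2
    log10_vl_sd: float = 0.7


@dataclass
class OiModel:
    duration_months: int
    history_multiplier: float
    hazards_monthly: dict[str, dict[str, float]]


@dataclass
class MortalityModel:
    """Background life table plus CD4-dependent HIV excess mortality."""

    background: list[tuple[float, float, float]]  # (age_from, qx male, qx female)
    hiv_excess_annual: dict[str, float]
    acute_oi_multiplier: float


@dataclass
class ProgressionSettings:
    cd4_cap: float
    terminal_decline_monthly: float          # cells/uL lost per month (magnitude)
    macs_decline_monthly: dict[str, float]   # steeper decline by stratum (magnitude)
    terminal_scenario: str


@dataclass
class SimulationSettings:
    n_patients: int = 500_000
    seed: int = 2015
    horizon_months: int | None = None
    age_cap_years: int = 100


@dataclass
class ModelParameters:
    """The complete, validated parameter bundle."""

    discount: DiscountSettings
    efficacy: dict[str, EfficacyBlock]
    algorithm: dict[str, TreatmentAlgorithm]
    costs: CostTable
    utilities: UtilityTable
    alt_utilities: dict[str, dict[str, float]]
    cohort: BaselineProfile
    oi: OiModel
    mortality: MortalityModel
    progression: ProgressionSettings
    resistance_prob_on_failure: dict[str, float]
    ae_discontinuation_monthly: float
    simulation: SimulationSettings
    dsa: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return _to_dict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        return _from_dict(data)


# ---------------------------------------------------------------------------
# dict <-> dataclass conversion
# ---------------------------------------------------------------------------

def _line_from_dict(d: dict) -> RegimenLine:
    return RegimenLine(
        label=str(d["label"]),
        cost_components=tuple(d["cost_components"]),
        efficacy=str(d["efficacy"]),
        category=str(d["category"]),
    )


def _line_to_dict(line: RegimenLine) -> dict:
    return {
        "label": line.label,
        "cost_components": list(line.cost_components),
        "efficacy": line.efficacy,
        "category": line.category,
    }


def _from_dict(data: dict) -> ModelParameters:
    try:
        d = data["discount"]
        discount = DiscountSettings(
            rate_early=float(d["rate_early"]),
            rate_late=float(d["rate_late"]),
            switch_year=float(d["switch_year"]),
            apply_to=str(d["apply_to"]),
        )
        efficacy = {
            key: EfficacyBlock(
                suppression_rate_y1=float(b["suppression_rate_y1"]),
                suppression_ci=(float(b["suppression_ci"][0]), float(b["suppression_ci"][1])),
                late_failure_monthly_48_96=float(b["late_failure_monthly_48_96"]),
                late_failure_monthly_after96=float(b["late_failure_monthly_after96"]),
                cd4_gain_y1=float(b["cd4_gain_y1"]),
                cd4_gain_y2=float(b["cd4_gain_y2"]),
                cd4_gain_later=float(b["cd4_gain_later"]),
            )
            for key, b in data["efficacy"].items()
        }
        algorithm = {
            arm: TreatmentAlgorithm(
                line1=_line_from_dict(spec["line1"]),
                no_resistance=tuple(_line_from_dict(x) for x in spec["no_resistance"]),
                ini_resistance=tuple(_line_from_dict(x) for x in spec["ini_resistance"]),
            )
            for arm, spec in data["algorithm"].items()
        }
        c = data["costs"]
        costs = CostTable(
            art_monthly={k: float(v) for k, v in c["art_monthly"].items()},
            art_bounds={k: (float(v[0]), float(v[1])) for k, v in c["art_bounds"].items()},
            routine_monthly={
                s: {h: float(v) for h, v in row.items()} for s, row in c["routine_monthly"].items()
            },
            oi_event={k: float(v) for k, v in c["oi_event"].items()},
            death={k: float(v) for k, v in c["death"].items()},
            switch_cost=float(c["switch_cost"]),
            lab_monthly=float(c["lab_monthly"]),
            genotype_test=float(c["genotype_test"]),
        )
        u = data["utilities"]
        utilities = UtilityTable(
            by_cd4={k: float(v) for k, v in u["by_cd4"].items()},
            by_oi={k: float(v) for k, v in u["by_oi"].items()},
        )
        alt_utilities = {
            "by_cd4": {k: float(v) for k, v in data["alt_utilities"]["by_cd4"].items()}
        }
        cohort = BaselineProfile(**{k: float(v) for k, v in data["cohort"].items()})
        o = data["oi"]
        oi = OiModel(
            duration_months=int(o["duration_months"]),
            history_multiplier=float(o["history_multiplier"]),
            hazards_monthly={
                t: {s: float(v) for s, v in row.items()} for t, row in o["hazards_monthly"].items()
            },
        )
        m = data["mortality"]
        mortality = MortalityModel(
            background=[(float(r[0]), float(r[1]), float(r[2])) for r in m["background"]],
            hiv_excess_annual={k: float(v) for k, v in m["hiv_excess_annual"].items()},
            acute_oi_multiplier=float(m["acute_oi_multiplier"]),
        )
        p = data["progression"]
        progression = ProgressionSettings(
            cd4_cap=float(p["cd4_cap"]),
            terminal_decline_monthly=float(p["terminal_decline_monthly"]),
            macs_decline_monthly={k: float(v) for k, v in p["macs_decline_monthly"].items()},
            terminal_scenario=str(p["terminal_scenario"]),
        )
        resistance = {k: float(v) for k, v in data["resistance"]["prob_on_failure"].items()}
        ae = float(data["ae"]["discontinuation_monthly"])
        s = data["simulation"]
        horizon = s["horizon_months"]
        simulation = SimulationSettings(
            n_patients=int(s["n_patients"]),
            seed=int(s["seed"]),
            horizon_months=None if horizon is None else int(horizon),
            age_cap_years=int(s["age_cap_years"]),
        )
        dsa = copy.deepcopy(data.get("dsa", []))
    except KeyError as exc:  # missing required section or key
        raise ConfigurationError(f"missing required configuration entry: {exc}") from exc
    params = ModelParameters(
        discount=discount,
        efficacy=efficacy,
        algorithm=algorithm,
        costs=costs,
        utilities=utilities,
        alt_utilities=alt_utilities,
        cohort=cohort,
        oi=oi,
        mortality=mortality,
        progression=progression,
        resistance_prob_on_failure=resistance,
        ae_discontinuation_monthly=ae,
        simulation=simulation,
        dsa=dsa,
    )
    validate(params)
    return params


def _to_dict(params: ModelParameters) -> dict:
    d = params.discount
    c = params.costs
    return {
        "discount": {
            "rate_early": d.rate_early,
            "rate_late": d.rate_late,
            "switch_year": d.switch_year,
            "apply_to": d.apply_to,
        },
        "efficacy": {
            key: {
                "suppression_rate_y1": b.suppression_rate_y1,
                "suppression_ci": list(b.suppression_ci),
                "late_failure_monthly_48_96": b.late_failure_monthly_48_96,
                "late_failure_monthly_after96": b.late_failure_monthly_after96,
                "cd4_gain_y1": b.cd4_gain_y1,
                "cd4_gain_y2": b.cd4_gain_y2,
                "cd4_gain_later": b.cd4_gain_later,
            }
            for key, b in params.efficacy.items()
        },
        "algorithm": {
            arm: {
                "line1": _line_to_dict(alg.line1),
                "no_resistance": [_line_to_dict(x) for x in alg.no_resistance],
                "ini_resistance": [_line_to_dict(x) for x in alg.ini_resistance],
            }
            for arm, alg in params.algorithm.items()
        },
        "costs": {
            "art_monthly": dict(c.art_monthly),
            "art_bounds": {k: list(v) for k, v in c.art_bounds.items()},
            "routine_monthly": {s: dict(row) for s, row in c.routine_monthly.items()},
            "oi_event": dict(c.oi_event),
            "death": dict(c.death),
            "switch_cost": c.switch_cost,
            "lab_monthly": c.lab_monthly,
            "genotype_test": c.genotype_test,
        },
        "utilities": {
            "by_cd4": dict(params.utilities.by_cd4),
            "by_oi": dict(params.utilities.by_oi),
        },
        "alt_utilities": {"by_cd4": dict(params.alt_utilities["by_cd4"])},
        "cohort": {k: getattr(params.cohort, k) for k in (
            "age_mean_years", "age_sd_years", "age_min_years", "age_max_years",
            "proportion_male", "cd4_log_mean", "cd4_log_sd", "cd4_min", "cd4_max",
            "proportion_suppressed_at_entry", "oi_history_proportion",
            "log10_vl_mean", "log10_vl_sd",
        )},
        "oi": {
            "duration_months": params.oi.duration_months,
            "history_multiplier": params.oi.history_multiplier,
            "hazards_monthly": {t: dict(row) for t, row in params.oi.hazards_monthly.items()},
        },
        "mortality": {
            "background": [list(r) for r in params.mortality.background],
            "hiv_excess_annual": dict(params.mortality.hiv_excess_annual),
            "acute_oi_multiplier": params.mortality.acute_oi_multiplier,
        },
        "progression": {
            "cd4_cap": params.progression.cd4_cap,
            "terminal_decline_monthly": params.progression.terminal_decline_monthly,
            "macs_decline_monthly": dict(params.progression.macs_decline_monthly),
            "terminal_scenario": params.progression.terminal_scenario,
        },
        "resistance": {"prob_on_failure": dict(params.resistance_prob_on_failure)},
        "ae": {"discontinuation_monthly": params.ae_discontinuation_monthly},
        "simulation": {
            "n_patients": params.simulation.n_patients,
            "seed": params.simulation.seed,
            "horizon_months": params.simulation.horizon_months,
            "age_cap_years": params.simulation.age_cap_years,
        },
        "dsa": copy.deepcopy(params.dsa),
    }


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check(cond: bool, msg: str, errors: list[str]) -> None:
    if not cond:
        errors.append(msg)


def validate(params: ModelParameters) -> None:
    """Check every model invariant; raise :class:`ValidationError` listing
    each offending key and value."""
    e: list[str] = []
    d = params.discount
    _check(0.0 <= d.rate_early <= 1.0, f"discount/rate_early out of [0,1]: {d.rate_early}", e)
    _check(0.0 <= d.rate_late <= 1.0, f"discount/rate_late out of [0,1]: {d.rate_late}", e)
    _check(d.switch_year > 0, f"discount/switch_year must be > 0: {d.switch_year}", e)
    _check(d.apply_to in ("costs", "qalys", "both"),
           f"discount/apply_to must be costs|qalys|both: {d.apply_to}", e)

    for key, b in params.efficacy.items():
        for name in ("suppression_rate_y1", "late_failure_monthly_48_96",
                     "late_failure_monthly_after96"):
            v = getattr(b, name)
            _check(0.0 <= v <= 1.0, f"efficacy/{key}/{name} out of [0,1]: {v}", e)
        lo, hi = b.suppression_ci
        _check(lo <= b.suppression_rate_y1 <= hi,
               f"efficacy/{key}/suppression_ci must bracket the point estimate: "
               f"[{lo}, {hi}] vs {b.suppression_rate_y1}", e)
        for name in ("cd4_gain_y1", "cd4_gain_y2", "cd4_gain_later"):
            v = getattr(b, name)
            _check(v >= 0, f"efficacy/{key}/{name} must be >= 0: {v}", e)

    for arm, alg in params.algorithm.items():
        lines = alg.sequence(False) + alg.sequence(True)
        _check(len(alg.no_resistance) >= 1, f"algorithm/{arm}: empty no_resistance branch", e)
        _check(len(alg.ini_resistance) >= 1, f"algorithm/{arm}: empty ini_resistance branch", e)
        for line in lines:
            _check(line.efficacy in params.efficacy,
                   f"algorithm/{arm}: line '{line.label}' references unknown "
                   f"efficacy block '{line.efficacy}'", e)
            _check(line.category in LINE_CATEGORIES,
                   f"algorithm/{arm}: line '{line.label}' has invalid category "
                   f"'{line.category}'", e)
            for comp in line.cost_components:
                _check(comp in params.costs.art_monthly,
                       f"algorithm/{arm}: line '{line.label}' references unknown "
                       f"ART cost component '{comp}'", e)

    c = params.costs
    for k, v in c.art_monthly.items():
        _check(v >= 0, f"costs/art_monthly/{k} must be >= 0: {v}", e)
    _check(set(c.routine_monthly) == set(ROUTINE_STRATA),
           f"costs/routine_monthly must cover strata {ROUTINE_STRATA}", e)
    for s, row in c.routine_monthly.items():
        _check(set(row) == {"no_history", "history"},
               f"costs/routine_monthly/{s} must have no_history and history", e)
        for h, v in row.items():
            _check(v >= 0, f"costs/routine_monthly/{s}/{h} must be >= 0: {v}", e)
    _check(set(c.oi_event) == set(OI_TYPES), f"costs/oi_event must cover {OI_TYPES}", e)
    _check(set(c.death) == {"no_history", "history_gt30d", "history_le30d"},
           "costs/death must have no_history, history_gt30d, history_le30d", e)
    for table in (c.oi_event, c.death):
        for k, v in table.items():
            _check(v >= 0, f"cost entry {k} must be >= 0: {v}", e)
    for name in ("switch_cost", "lab_monthly", "genotype_test"):
        v = getattr(c, name)
        _check(v >= 0, f"costs/{name} must be >= 0: {v}", e)

    u = params.utilities
    _check(set(u.by_cd4) == set(UTILITY_STRATA),
           f"utilities/by_cd4 must cover strata {UTILITY_STRATA}", e)
    _check(set(u.by_oi) == set(OI_TYPES), f"utilities/by_oi must cover {OI_TYPES}", e)
    for k, v in {**u.by_cd4, **u.by_oi}.items():
        _check(0.0 <= v <= 1.0, f"utility {k} out of [0,1]: {v}", e)
    if set(u.by_cd4) == set(UTILITY_STRATA):
        seq = [u.by_cd4[s] for s in UTILITY_STRATA]
        _check(all(a <= b for a, b in zip(seq, seq[1:])),
               f"utilities/by_cd4 must be non-decreasing in CD4: {seq}", e)
    for k, v in params.alt_utilities["by_cd4"].items():
        _check(0.0 <= v <= 1.0, f"alt_utilities/by_cd4/{k} out of [0,1]: {v}", e)

    p = params.cohort
    for name in ("proportion_male", "proportion_suppressed_at_entry", "oi_history_proportion"):
        v = getattr(p, name)
        _check(0.0 <= v <= 1.0, f"cohort/{name} out of [0,1]: {v}", e)
    _check(p.age_min_years >= 18, f"cohort/age_min_years must be >= 18: {p.age_min_years}", e)
    _check(p.age_min_years <= p.age_max_years, "cohort age_min > age_max", e)
    _check(p.cd4_min >= 0, f"cohort/cd4_min must be >= 0: {p.cd4_min}", e)
    _check(p.cd4_min <= p.cd4_max, "cohort cd4_min > cd4_max", e)

    o = params.oi
    _check(o.duration_months >= 1, f"oi/duration_months must be >= 1: {o.duration_months}", e)
    _check(o.history_multiplier >= 0, "oi/history_multiplier must be >= 0", e)
    _check(set(o.hazards_monthly) == set(OI_TYPES), f"oi/hazards_monthly must cover {OI_TYPES}", e)
    for t, row in o.hazards_monthly.items():
        _check(set(row) == set(ROUTINE_STRATA),
               f"oi/hazards_monthly/{t} must cover strata {ROUTINE_STRATA}", e)
        for s, v in row.items():
            _check(0.0 <= v <= 1.0, f"oi/hazards_monthly/{t}/{s} out of [0,1]: {v}", e)

    m = params.mortality
    _check(len(m.background) >= 1, "mortality/background life table is empty", e)
    ages = [r[0] for r in m.background]
    _check(ages == sorted(ages), "mortality/background must be sorted by age", e)
    for r in m.background:
        _check(0.0 <= r[1] <= 1.0 and 0.0 <= r[2] <= 1.0,
               f"mortality/background qx out of [0,1] at age {r[0]}", e)
    _check(set(m.hiv_excess_annual) == set(ROUTINE_STRATA),
           f"mortality/hiv_excess_annual must cover strata {ROUTINE_STRATA}", e)
    for k, v in m.hiv_excess_annual.items():
        _check(0.0 <= v <= 1.0, f"mortality/hiv_excess_annual/{k} out of [0,1]: {v}", e)
    _check(m.acute_oi_multiplier >= 1.0,
           f"mortality/acute_oi_multiplier must be >= 1: {m.acute_oi_multiplier}", e)

    pr = params.progression
    _check(pr.cd4_cap > 0, f"progression/cd4_cap must be > 0: {pr.cd4_cap}", e)
    _check(pr.terminal_decline_monthly >= 0,
           "progression/terminal_decline_monthly is a magnitude and must be >= 0", e)
    _check(set(pr.macs_decline_monthly) == set(ROUTINE_STRATA),
           f"progression/macs_decline_monthly must cover strata {ROUTINE_STRATA}", e)
    for k, v in pr.macs_decline_monthly.items():
        _check(v >= pr.terminal_decline_monthly,
               f"progression/macs_decline_monthly/{k} must be at least as steep as the "
               f"base decline: {v} < {pr.terminal_decline_monthly}", e)
    _check(pr.terminal_scenario in TERMINAL_SCENARIOS,
           f"progression/terminal_scenario must be one of {TERMINAL_SCENARIOS}: "
           f"{pr.terminal_scenario}", e)

    for arm in params.algorithm:
        _check(arm in params.resistance_prob_on_failure,
               f"resistance/prob_on_failure missing arm {arm}", e)
    for k, v in params.resistance_prob_on_failure.items():
        _check(0.0 <= v <= 1.0, f"resistance/prob_on_failure/{k} out of [0,1]: {v}", e)
    _check(0.0 <= params.ae_discontinuation_monthly <= 1.0,
           f"ae/discontinuation_monthly out of [0,1]: {params.ae_discontinuation_monthly}", e)

    s = params.simulation
    _check(s.n_patients >= 1, f"simulation/n_patients must be >= 1: {s.n_patients}", e)
    _check(s.horizon_months is None or s.horizon_months >= 1,
           f"simulation/horizon_months must be >= 1 or null: {s.horizon_months}", e)
    _check(s.age_cap_years > 0, "simulation/age_cap_years must be > 0", e)

    for spec in params.dsa:
        _check(set(spec) == {"path", "low", "high"},
               f"dsa entry must have path/low/high: {spec}", e)

    if e:
        raise ValidationError("invalid parameters:\n  " + "\n  ".join(e))


# ---------------------------------------------------------------------------
# Loading / merging / serialization
# ---------------------------------------------------------------------------

#: Config tree nodes whose child keys are data, not schema, and therefore may
#: legitimately differ from the defaults (custom algorithms, extra efficacy
#: blocks, extra priced components).
_OPEN_NODES = {"algorithm", "efficacy", "costs/art_monthly", "costs/art_bounds", "dsa"}


def _default_dict() -> dict:
    text = (
        importlib.resources.files("hivsim").joinpath("data/default_config.yaml").read_text()
    )
    return yaml.safe_load(text)


def _under_open_node(path: str) -> bool:
    return any(path == o or path.startswith(o + "/") for o in _OPEN_NODES)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    """Deep-merge ``override`` into ``base``; unknown keys are rejected
    unless they sit under an open node (where child keys are data)."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}/{key}" if path else str(key)
        if key not in base:
            if _under_open_node(here):
                out[key] = copy.deepcopy(value)
                continue
            known = ", ".join(sorted(map(str, base)))
            raise ConfigurationError(f"unknown configuration key '{here}' (known: {known})")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_parameters(config_source=None) -> ModelParameters:
    """Load the parameter bundle.

    ``config_source`` may be ``None`` (bundled base-case defaults), a path to
    a YAML override file, or an already-parsed override mapping. Any key
    absent from the override takes its base-case default; unknown keys are
    rejected with the offending path named.
    """
    base = _default_dict()
    if config_source is None:
        merged = base
    else:
        if isinstance(config_source, dict):
            override = config_source
        else:
            with open(config_source) as fh:
                override = yaml.safe_load(fh)
        if override is None:
            override = {}
        if not isinstance(override, dict):
            raise ConfigurationError("configuration file must contain a mapping at top level")
        merged = _merge(base, override)
    return ModelParameters.from_dict(merged)


def default_parameters() -> ModelParameters:
    """The bundled base case."""
    return load_parameters(None)


def dump_parameters(params: ModelParameters, path=None) -> str:
    """Canonical YAML serialization (provenance logging; round-trips through
    :func:`load_parameters` to an equal bundle)."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=True, default_flow_style=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def fingerprint(params: ModelParameters) -> str:
    """Short stable hash of the serialized parameter bundle."""
    return hashlib.sha256(dump_parameters(params).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Path addressing and perturbation
# ---------------------------------------------------------------------------

def _leaf_paths(node, prefix: str = "") -> list[str]:
    paths = []
    if isinstance(node, dict):
        for k, v in node.items():
            paths.extend(_leaf_paths(v, f"{prefix}/{k}" if prefix else str(k)))
    elif isinstance(node, list) and node and isinstance(node[0], (dict, list)):
        for i, v in enumerate(node):
            paths.extend(_leaf_paths(v, f"{prefix}/{i}"))
    else:
        paths.append(prefix)
    return paths


def list_paths(params: ModelParameters) -> list[str]:
    """All addressable parameter paths (``/``-separated)."""
    return _leaf_paths(params.to_dict())


def _resolve_parent(tree: dict, path: str):
    parts = path.split("/")
    node = tree
    for part in parts[:-1]:
        if isinstance(node, list):
            node = node[int(part)]
        elif isinstance(node, dict) and part in node:
            node = node[part]
        else:
            raise KeyError(path)
    return node, parts[-1]


def perturb(params: ModelParameters, path: str, value=None, bound: str | None = None) -> ModelParameters:
    """Return a copy of ``params`` with the entry at ``path`` replaced.

    Either an explicit ``value`` is given, or ``bound`` selects the "low" or
    "high" end of the entry's published uncertainty range (the suppression CI
    for efficacy rates; the min/max regimen price for ART components). The
    input bundle is never modified; the result is re-validated.
    """
    tree = params.to_dict()
    try:
        parent, leaf = _resolve_parent(tree, path)
        if isinstance(parent, list):
            current = parent[int(leaf)]
        else:
            current = parent[leaf]
    except (KeyError, IndexError, ValueError):
        sample = "\n  ".join(list_paths(params)[:25])
        raise KeyError(
            f"unknown parameter path '{path}'; valid paths look like:\n  {sample}\n  ..."
        ) from None

    if value is None:
        if bound not in ("low", "high"):
            raise ValueError("perturb needs either a value or bound='low'|'high'")
        value = _bound_value(params, path, bound)
    if isinstance(current, dict) != isinstance(value, dict):
        raise ValueError(f"type mismatch at '{path}': cannot replace {type(current).__name__} "
                         f"with {type(value).__name__}")
    if isinstance(parent, list):
        parent[int(leaf)] = value
    else:
        parent[leaf] = value
    return ModelParameters.from_dict(tree)


def _bound_value(params: ModelParameters, path: str, bound: str):
    idx = 0 if bound == "low" else 1
    parts = path.split("/")
    if parts[0] == "efficacy" and parts[-1] == "suppression_rate_y1":
        return params.efficacy[parts[1]].suppression_ci[idx]
    if parts[:2] == ["costs", "art_monthly"] and parts[2] in params.costs.art_bounds:
        return params.costs.art_bounds[parts[2]][idx]
    raise ValueError(f"no published uncertainty bound registered for path '{path}'")


# ---------------------------------------------------------------------------
# Discounting
# ---------------------------------------------------------------------------

def discount_factor(month_index: int, settings: DiscountSettings):
    """Discount factor for a cash flow or utility accrued in ``month_index``.

    Annual-rate semantics with fractional exponents: ``(1+r_early)^(-m/12)``
    within the first ``switch_year`` years, continuing piecewise from the
    accumulated factor at the switch boundary with ``r_late`` thereafter.
    Accepts scalars or arrays; months must be >= 0.
    """
    import numpy as np

    m = np.asarray(month_index, dtype=float)
    if np.any(m < 0):
        raise ValueError("month_index must be >= 0")
    years = m / 12.0
    early = (1.0 + settings.rate_early) ** (-np.minimum(years, settings.switch_year))
    late = (1.0 + settings.rate_late) ** (-np.maximum(years - settings.switch_year, 0.0))
    out = early * late
    return float(out) if np.isscalar(month_index) else out
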