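"""Monthly cost and quality-adjusted life-year accrual.

Costs fall into six components: ART (the regimen's monthly component sum),
routine HIV care (CD4 stratum x OI history), one-off OI episode costs at
onset, one-off death costs keyed by OI-history recency, laboratory tests
(a monthly amortised schedule plus a genotype test at each virologic
failure), and line-switch costs. Utilities are CD4-stratified; during an
active OI episode the episode utility replaces the CD4 utility, except that
a patient is never made better off by an OI (the minimum of the two
applies). Life years accrue 1/12 per month alive; there is no half-cycle
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import DiscountSettings, ModelParameters, discount_factor
from .strata import OI_TYPES, ROUTINE_STRATA, UTILITY_STRATA, routine_stratum_index, utility_stratum_index

__all__ = [
    "CostAccrual",
    "QalyAccrual",
    "CostTables",
    "monthly_cost",
    "monthly_qaly",
    "apply_discounting",
]


@dataclass
class CostAccrual:
    """Per-patient cost components (EUR). ``total`` is always the component sum."""

    art: float = 0.0
    routine: float = 0.0
    oi: float = 0.0
    death: float = 0.0
    tests: float = 0.0
    switch: float = 0.0

    @property
    def total(self) -> float:
        return self.art + self.routine + self.oi + self.death + self.tests + self.switch

    def __add__(self, other: "CostAccrual") -> "CostAccrual":
        return CostAccrual(*(getattr(self, f) + getattr(other, f)
                             for f in ("art", "routine", "oi", "death", "tests", "switch")))


@dataclass
class QalyAccrual:
    """Per-patient health accrual: life years and utility-weighted years."""

    life_years: float = 0.0
    qalys: float = 0.0

    def __add__(self, other: "QalyAccrual") -> "QalyAccrual":
        return QalyAccrual(self.life_years + other.life_years, self.qalys + other.qalys)


class CostTables:
    """Vectorized lookups pre-baked from the cost/utility configuration."""

    def __init__(self, params: ModelParameters):
        c = params.costs
        # (stratum, history) -> monthly routine cost
        self.routine = np.array(
            [[c.routine_monthly[s]["no_history"], c.routine_monthly[s]["history"]]
             for s in ROUTINE_STRATA]
        )
        self.oi_event = np.array([c.oi_event[t] for t in OI_TYPES])
        # death cost keyed 0 = no history, 1 = history > 30 days, 2 = <= 30 days
        self.death = np.array([c.death["no_history"], c.death["history_gt30d"],
                               c.death["history_le30d"]])
        self.switch_cost = c.switch_cost
        self.lab_monthly = c.lab_monthly
        self.genotype_test = c.genotype_test
        self.util_cd4 = np.array([params.utilities.by_cd4[s] for s in UTILITY_STRATA])
        self.util_oi = np.array([params.utilities.by_oi[t] for t in OI_TYPES])

    def routine_cost(self, cd4: np.ndarray, oi_history: np.ndarray) -> np.ndarray:
        return self.routine[routine_stratum_index(cd4), oi_history.astype(int)]

    def utility(self, cd4: np.ndarray, active_oi_type: np.ndarray) -> np.ndarray:
        """Health-state utility: CD4-stratum utility, replaced by the OI
        utility during an active episode unless the CD4 utility is lower."""
        base = self.util_cd4[utility_stratum_index(cd4)]
        active = active_oi_type >= 0
        oi_u = self.util_oi[np.clip(active_oi_type, 0, len(OI_TYPES) - 1)]
        return np.where(active, np.minimum(base, oi_u), base)

    def death_cost_key(self, active_or_recent_oi: np.ndarray,
                       oi_history: np.ndarray) -> np.ndarray:
        """0/1/2 index into the death-cost table given OI recency."""
        return np.where(active_or_recent_oi, 2, np.where(oi_history, 1, 0))


def monthly_cost(cd4: float, oi_history: bool, line_art_cost: float,
                 params: ModelParameters, *, oi_onset_type: str | None = None,
                 virologic_failure: bool = False, switching: bool = False,
                 dying: bool = False, recent_oi: bool = False) -> CostAccrual:
    """Undiscounted cost increment for one patient-month (scalar surface).

    ``recent_oi`` marks an episode active in, or resolved at most one month
    before, the death month (the <=30 days death-cost key).
    """
    tables = CostTables(params)
    cd4a = np.asarray([cd4], dtype=float)
    hist = np.asarray([oi_history])
    out = CostAccrual(
        art=float(line_art_cost),
        routine=float(tables.routine_cost(cd4a, hist)[0]),
        tests=tables.lab_monthly + (tables.genotype_test if virologic_failure else 0.0),
        switch=tables.switch_cost if switching else 0.0,
    )
    if oi_onset_type is not None:
        if oi_onset_type not in OI_TYPES:
            raise KeyError(f"unknown OI type '{oi_onset_type}'")
        out.oi = params.costs.oi_event[oi_onset_type]
    if dying:
        key = int(tables.death_cost_key(np.asarray([recent_oi]), hist)[0])
        out.death = float(tables.death[key])
    return out


def monthly_qaly(cd4: float, active_oi_type: str | None,
                 params: ModelParameters) -> QalyAccrual:
    """Health increment for one patient-month alive (scalar surface)."""
    tables = CostTables(params)
    oi_idx = OI_TYPES.index(active_oi_type) if active_oi_type is not None else -1
    u = float(tables.utility(np.asarray([cd4], dtype=float), np.asarray([oi_idx]))[0])
    return QalyAccrual(life_years=1.0 / 12.0, qalys=u / 12.0)


def apply_discounting(increment, month_index: int, settings: DiscountSettings):
    """Scale every component of a cost or health increment by the discount
    factor for ``month_index``. The undiscounted input is left untouched."""
    f = discount_factor(month_index, settings)
    if isinstance(increment, CostAccrual):
        return CostAccrual(*(getattr(increment, n) * f
                             for n in ("art", "routine", "oi", "death", "tests", "switch")))
    if isinstance(increment, QalyAccrual):
        return QalyAccrual(increment.life_years * f, increment.qalys * f)
    raise TypeError(f"cannot discount {type(increment).__name__}")
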