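"""Disease dynamics: CD4 trajectory, opportunistic infections, mortality.

CD4 recovery on suppressive therapy is front-loaded: two thirds of the
first-year gain accrue in the first two months, the remaining third is
spread uniformly over months 3-11, then the year-2 and later annual gains
are spread over their twelve months. Counts are capped (default 1,000
cells/uL) and, on subsequent lines, the cumulative gain per line cannot
exceed the total realized on the first line. On failing therapy before the
last line the count plateaus; once the last line has failed it declines
linearly (scenario-dependent slope) and is floored at zero.

Opportunistic infections arrive as per-type monthly Bernoulli events with
CD4-stratum-specific hazards, doubled (configurable) by an OI history; at
most one OI is active at a time and an episode lasts a fixed number of
months. Mortality combines an age/sex background life table with
CD4-stratified HIV excess mortality, the HIV component inflated during an
active episode.
"""

from __future__ import annotations

import numpy as np

from .parameters import EfficacyBlock, ModelParameters
from .strata import OI_TYPES, ROUTINE_STRATA, routine_stratum_index

__all__ = [
    "monthly_cd4_gain",
    "cd4_gain_schedule",
    "terminal_cd4_decline",
    "monthly_from_annual",
    "oi_hazard_matrix",
    "sample_oi_type",
    "MortalityTables",
]


def cd4_gain_schedule(eff: EfficacyBlock, month_on_line):
    """Monthly CD4 gain (cells/uL) on suppressive therapy.

    ``month_on_line`` is 1-based (the first month on the line is month 1).
    Months 1-2 each deliver half of two thirds of the first-year gain;
    months 3-11 spread the remaining third; months 12-23 spread the year-2
    gain; later months spread the subsequent annual gain. The per-month
    amounts over months 1-11 sum exactly to the annual first-year gain.
    """
    m = np.asarray(month_on_line)
    if np.any(m < 1):
        raise ValueError("month_on_line is 1-based and must be >= 1")
    out = np.select(
        [m <= 2, m <= 11, m <= 23],
        [
            (2.0 / 3.0) * eff.cd4_gain_y1 / 2.0,
            (1.0 / 3.0) * eff.cd4_gain_y1 / 9.0,
            eff.cd4_gain_y2 / 12.0,
        ],
        default=eff.cd4_gain_later / 12.0,
    )
    return float(out) if np.isscalar(month_on_line) else out


def monthly_cd4_gain(eff: EfficacyBlock, month_on_line: int, suppressed: bool,
                     line_position: int, first_line_total_gain: float,
                     cumulative_gain_this_line: float, params: ModelParameters) -> float:
    """Scalar CD4 gain for one patient-month, with the subsequent-line cap.

    Returns 0 when not suppressed. On lines after the first, the cumulative
    gain on the line is capped at the total gain realized on the first line.
    (The cap against the absolute CD4 ceiling is applied by the caller,
    which knows the current count.)
    """
    if not suppressed:
        return 0.0
    gain = cd4_gain_schedule(eff, month_on_line)
    if line_position > 0:
        gain = min(gain, max(first_line_total_gain - cumulative_gain_this_line, 0.0))
    return float(gain)


def terminal_cd4_decline(cd4, scenario: str, params: ModelParameters):
    """Monthly CD4 change (<= 0) for patients failing the last line.

    ``base`` applies the configured constant decline; ``macs_decline``
    applies the steeper stratum-specific observational-cohort table (worst
    case); ``no_decline`` returns 0.
    """
    pr = params.progression
    cd4 = np.asarray(cd4, dtype=float)
    if scenario == "no_decline":
        out = np.zeros_like(cd4)
    elif scenario == "base":
        out = np.full_like(cd4, -pr.terminal_decline_monthly)
    elif scenario == "macs_decline":
        table = np.array([pr.macs_decline_monthly[s] for s in ROUTINE_STRATA])
        out = -table[routine_stratum_index(cd4)]
    else:
        raise ValueError(f"unknown terminal-decline scenario '{scenario}'")
    return float(out) if out.ndim == 0 else out


def monthly_from_annual(q):
    """Convert an annual event probability to the equivalent monthly one."""
    return 1.0 - (1.0 - np.asarray(q, dtype=float)) ** (1.0 / 12.0)


def oi_hazard_matrix(params: ModelParameters) -> np.ndarray:
    """Monthly OI hazards as a (type, CD4 stratum) matrix (no history)."""
    return np.array(
        [[params.oi.hazards_monthly[t][s] for s in ROUTINE_STRATA] for t in OI_TYPES]
    )


def sample_oi_type(u: np.ndarray, stratum_idx: np.ndarray, oi_history: np.ndarray,
                   hazards: np.ndarray, history_multiplier: float) -> np.ndarray:
    """Exclusive monthly OI allocation from a single uniform per patient.

    Per-type hazards (scaled by the history multiplier where applicable) are
    stacked in the fixed type order; the uniform selects at most one type.
    Returns the type index, or -1 for no onset.
    """
    haz = hazards[:, stratum_idx] * np.where(oi_history, history_multiplier, 1.0)
    cum = np.cumsum(haz, axis=0)
    hit = u[None, :] < cum
    onset = hit.any(axis=0)
    return np.where(onset, hit.argmax(axis=0), -1)


class MortalityTables:
    """Pre-baked monthly mortality lookups for the engine.

    Background probabilities are an (age band, sex) matrix; HIV excess is a
    vector over CD4 strata. HIV death is tested first each month; the HIV
    component is multiplied by the acute-OI factor during active episodes.
    """

    def __init__(self, params: ModelParameters):
        m = params.mortality
        self.band_lo = np.array([r[0] for r in m.background])
        self.bg_monthly = monthly_from_annual(
            np.array([[r[1], r[2]] for r in m.background])
        )
        self.hiv_monthly = monthly_from_annual(
            np.array([m.hiv_excess_annual[s] for s in ROUTINE_STRATA])
        )
        self.acute_oi_multiplier = m.acute_oi_multiplier

    def background_prob(self, age_years: np.ndarray, sex_idx: np.ndarray) -> np.ndarray:
        band = np.clip(
            np.searchsorted(self.band_lo, age_years, side="right") - 1, 0, len(self.band_lo) - 1
        )
        return self.bg_monthly[band, sex_idx]

    def hiv_prob(self, stratum_idx: np.ndarray, active_oi: np.ndarray) -> np.ndarray:
        p = self.hiv_monthly[stratum_idx] * np.where(active_oi, self.acute_oi_multiplier, 1.0)
        return np.clip(p, 0.0, 1.0)
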