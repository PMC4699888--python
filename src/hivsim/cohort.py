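"""Synthetic baseline cohort generation.

The entry population emulates a treatment-experienced, integrase-inhibitor-
naive cohort entering in virological failure: middle-aged, majority male,
with an advanced-disease CD4 distribution (truncated log-normal, median
around 200 cells/uL) and a quarter carrying an opportunistic-infection
history. No patient-level trial data are ingested; every attribute is drawn
from the configurable :class:`~hivsim.parameters.BaselineProfile`.

Sampling is by inverse-CDF transform of one counter-based uniform per
attribute per patient, keyed by ``(seed, patient id)``. Truncation is
therefore exact and each patient's baseline is byte-identical across arms
and across runs that share a seed - the common-random-numbers contract that
paired arm comparisons rely on.

Baseline viral load is carried as a descriptive attribute only; no model
rate depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import BaselineProfile
from .rng import BaselineSlot, CounterRng

__all__ = ["PatientState", "sample_cohort", "export_cohort", "import_cohort"]

#: Baseline columns of a cohort table, in storage order.
COHORT_COLUMNS = ("id", "age_months", "sex", "cd4", "suppressed", "oi_history", "log10_vl")


@dataclass
class PatientState:
    """One simulated individual's tracked attributes.

    Baseline fields are set at entry; the remainder evolve during
    simulation. Dead patients never transition.
    """

    id: int
    age_months: int
    sex: str                       # "M" | "F"
    cd4: float
    suppressed: bool = False
    oi_history: bool = False
    log10_vl: float = 4.0
    line_index: int = 0
    months_on_line: int = 0
    ini_resistant: bool = False
    active_oi: tuple[str, int] | None = None   # (type, months_remaining)
    months_since_last_oi: int | None = None
    alive: bool = True
    cd4_gain_used_line1: float = 0.0


def _truncated_normal_ppf(u: np.ndarray, mean: float, sd: float,
                          lo: float, hi: float) -> np.ndarray:
    if hi <= lo or sd <= 0:
        return np.full_like(u, lo if hi <= lo else mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def sample_cohort(n: int, profile: BaselineProfile, seed: int) -> pd.DataFrame:
    """Draw ``n`` baseline patients from ``profile``.

    Returns a DataFrame with one row per patient (columns
    ``COHORT_COLUMNS``), ordered by patient id. Identical
    ``(n, profile, seed)`` yield identical cohorts.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = CounterRng(seed)
    ids = np.arange(n, dtype=np.int64)

    age_years = _truncated_normal_ppf(
        rng.baseline(ids, BaselineSlot.AGE),
        profile.age_mean_years, profile.age_sd_years,
        profile.age_min_years, profile.age_max_years,
    )
    age_months = np.floor(age_years * 12.0 + 0.5).astype(np.int32)

    sex = np.where(rng.baseline(ids, BaselineSlot.SEX) < profile.proportion_male, "M", "F")

    # CD4: log-normal truncated to [cd4_min, cd4_max]; inverse transform on
    # the log scale.
    if profile.cd4_max <= profile.cd4_min:
        cd4 = np.full(n, float(profile.cd4_min))
    else:
        log_cd4 = _truncated_normal_ppf(
            rng.baseline(ids, BaselineSlot.CD4),
            profile.cd4_log_mean, profile.cd4_log_sd,
            np.log(max(profile.cd4_min, 1e-9)), np.log(profile.cd4_max),
        )
        cd4 = np.clip(np.exp(log_cd4), profile.cd4_min, profile.cd4_max)

    oi_history = rng.baseline(ids, BaselineSlot.OI_HISTORY) < profile.oi_history_proportion
    suppressed = (
        rng.baseline(ids, BaselineSlot.SUPPRESSED) < profile.proportion_suppressed_at_entry
    )
    log10_vl = profile.log10_vl_mean + profile.log10_vl_sd * stats.norm.ppf(
        rng.baseline(ids, BaselineSlot.VIRAL_LOAD)
    )

    return pd.DataFrame(
        {
            "id": ids,
            "age_months": age_months,
            "sex": sex,
            "cd4": cd4,
            "suppressed": suppressed,
            "oi_history": oi_history,
            "log10_vl": log10_vl,
        }
    )


def export_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV so the identical population can be
    replayed across runs."""
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def import_cohort(path) -> pd.DataFrame:
    """Read a cohort previously written by :func:`export_cohort`."""
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file is missing columns: {sorted(missing)}")
    df = df.loc[:, list(COHORT_COLUMNS)]
    df["id"] = df["id"].astype(np.int64)
    df["age_months"] = df["age_months"].astype(np.int32)
    df["cd4"] = df["cd4"].astype(float)
    df["suppressed"] = df["suppressed"].astype(bool)
    df["oi_history"] = df["oi_history"].astype(bool)
    return df


def patient_from_row(row) -> PatientState:
    """Convert one cohort-table row into a :class:`PatientState`."""
    return PatientState(
        id=int(row["id"]),
        age_months=int(row["age_months"]),
        sex=str(row["sex"]),
        cd4=float(row["cd4"]),
        suppressed=bool(row["suppressed"]),
        oi_history=bool(row["oi_history"]),
        log10_vl=float(row["log10_vl"]),
        months_since_last_oi=None,
    )
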