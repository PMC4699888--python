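import pytest

from hivsim import default_parameters, load_parameters
from hivsim.strata import OI_TYPES, ROUTINE_STRATA


@pytest.fixture(scope="session")
def params():
    """Bundled base-case parameter set (treated as read-only)."""
    return default_parameters()


def quiet_overrides() -> dict:
    """Overrides that switch off every stochastic event: suppression is
    certain, and late failure, AE discontinuation, OIs and death never
    occur. Used for closed-form degenerate runs."""
    eff = {
        key: {
            "suppression_rate_y1": 1.0,
            "suppression_ci": [0.0, 1.0],
            "late_failure_monthly_48_96": 0.0,
            "late_failure_monthly_after96": 0.0,
        }
        for key in ("line1_dtg", "line1_ral", "line2_no_resistance",
                    "line2_ini_resistance", "salvage1", "salvage2")
    }
    zeros = {s: 0.0 for s in ROUTINE_STRATA}
    return {
        "efficacy": eff,
        "oi": {"hazards_monthly": {t: dict(zeros) for t in OI_TYPES}},
        "mortality": {"background": [[15, 0.0, 0.0]], "hiv_excess_annual": dict(zeros)},
        "ae": {"discontinuation_monthly": 0.0},
    }


@pytest.fixture(scope="session")
def quiet_params():
    """Event-free parameter set: every patient stays suppressed on line 1."""
    return load_parameters(quiet_overrides())


def identical_arm_overrides(base) -> dict:
    """Overrides making the RAL arm an exact copy of the DTG arm, so that
    paired runs on common random numbers must produce zero increments."""
    d = base.to_dict()
    return {
        "algorithm": {"RAL": d["algorithm"]["DTG"]},
        "resistance": {"prob_on_failure": {"RAL": d["resistance"]["prob_on_failure"]["DTG"]}},
    }
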