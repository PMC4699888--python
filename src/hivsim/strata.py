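"""CD4 stratification and opportunistic-infection type registries.

Two stratifications coexist in the model: a six-level grid driving routine
care costs, OI hazards, excess mortality and terminal decline, and a
four-level grid driving utilities. Both are closed on the left at 50, 100,
200 (and 350/500 for the six-level grid), i.e. a count of exactly 50 falls
in the <=50 stratum.
"""

from __future__ import annotations

import numpy as np

#: Six-level CD4 strata (cells/uL), lowest first: <=50, 51-100, 101-200,
#: 201-350, 351-500, >500.
ROUTINE_STRATA = ("le50", "s51_100", "s101_200", "s201_350", "s351_500", "gt500")
_EDGES6 = np.array([50.0, 100.0, 200.0, 350.0, 500.0])

#: Four-level CD4 strata for utilities: <=50, 51-100, 101-200, >200.
UTILITY_STRATA = ("le50", "s51_100", "s101_200", "gt200")
_EDGES4 = np.array([50.0, 100.0, 200.0])

#: Opportunistic-infection types in the fixed draw-allocation order.
OI_TYPES = ("bacterial", "fungal", "protozoal", "viral", "other")


def routine_stratum_index(cd4) -> np.ndarray:
    """Index into ROUTINE_STRATA for CD4 count(s)."""
    return np.searchsorted(_EDGES6, np.asarray(cd4, dtype=float), side="left")

def utility_stratum_index(cd4) -> np.ndarray:
    """Index into UTILITY_STRATA for CD4 count(s)."""
    return np.searchsorted(_EDGES4, np.asarray(cd4, dtype=float), side="left")
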