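"""Counter-based random draw streams for reproducible paired simulation.

Every uniform variate consumed anywhere in the simulation is a pure function
of ``(seed, patient id, month, slot)``: there is no mutable generator state.
This gives three guarantees the model design relies on:

* **Determinism** — identical inputs reproduce identical event streams,
  bit for bit, independent of execution order or worker count.
* **Common random numbers** — the treatment arm never enters the key, so for
  a given patient the baseline attributes and every event draw coincide
  across arms wherever the arms' parameters coincide.  Incremental outcomes
  between paired runs then reflect parameter differences, not sampling noise.
* **Fixed draw budget** — each patient-month owns one counter per event slot
  whether or not the event is reachable on the branch taken, so perturbing
  one parameter (a sensitivity analysis) cannot desynchronise later draws.

The mixing function is the SplitMix64 finalizer applied to each key word in
turn; its output passes standard empirical uniformity batteries and is more
than adequate for Monte Carlo event draws.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = ["Slot", "BaselineSlot", "BASELINE_MONTH", "CounterRng", "ScriptedDraws"]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_U64 = np.uint64


class Slot(IntEnum):
    """Per patient-month draw slots, one per potential event."""

    DEATH_HIV = 0
    DEATH_BACKGROUND = 1
    OI_ONSET = 2
    LATE_FAILURE = 3
    AE_DISCONTINUATION = 4
    RESISTANCE = 5
    YEAR1_SUPPRESSION = 6


#: Sentinel "month" under which baseline-attribute draws live, far above any
#: simulated calendar month so the streams never collide.
BASELINE_MONTH = 0x00FF_FFFF


class BaselineSlot(IntEnum):
    """Draw slots for baseline patient attributes (keyed under BASELINE_MONTH)."""

    AGE = 0
    SEX = 1
    CD4 = 2
    OI_HISTORY = 3
    VIRAL_LOAD = 4
    SUPPRESSED = 5


def _mix(z: np.ndarray) -> np.ndarray:
    # SplitMix64 output finalizer (Steele, Lea & Flood 2014); uint64
    # arithmetic wraps modulo 2^64 by design.
    with np.errstate(over="ignore"):
        z = z + _GOLDEN
        z = z ^ (z >> _U64(30))
        z = z * _MIX1
        z = z ^ (z >> _U64(27))
        z = z * _MIX2
        z = z ^ (z >> _U64(31))
    return z


class CounterRng:
    """Stateless uniform source keyed by ``(seed, patient, month, slot)``."""

    def __init__(self, seed: int):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = int(seed)
        self._h0 = _mix(np.asarray(self.seed, dtype=np.uint64))

    def uniform(self, patient_ids: np.ndarray, month: int, slot: int) -> np.ndarray:
        """Uniform(0, 1) variates for each patient id at (month, slot)."""
        pids = np.asarray(patient_ids, dtype=np.uint64)
        h = _mix(self._h0 ^ pids)
        h = _mix(h ^ _U64(int(month)))
        h = _mix(h ^ _U64(int(slot)))
        return (h >> _U64(11)).astype(np.float64) * (2.0**-53)

    def baseline(self, patient_ids: np.ndarray, slot: int) -> np.ndarray:
        """Uniforms for baseline attributes (arm-invariant by construction)."""
        return self.uniform(patient_ids, BASELINE_MONTH, slot)


class ScriptedDraws:
    """Deterministic draw source that replays a scripted event path.

    ``script`` maps ``(month, slot)`` to the uniform returned for every
    patient at that point; unscripted keys fall back to ``default``, which is
    just below 1 so events with probability < 1 never fire spontaneously.
    Intended for single-patient oracle tests and worked examples where the
    exact event path must be forced.
    """

    def __init__(self, script: dict[tuple[int, int], float], default: float = 1.0 - 2.0**-30):
        self.script = {(int(m), int(s)): float(v) for (m, s), v in script.items()}
        self.default = float(default)

    def uniform(self, patient_ids: np.ndarray, month: int, slot: int) -> np.ndarray:
        value = self.script.get((int(month), int(slot)), self.default)
        return np.full(np.asarray(patient_ids).shape, value, dtype=np.float64)

    def baseline(self, patient_ids: np.ndarray, slot: int) -> np.ndarray:
        return self.uniform(patient_ids, BASELINE_MONTH, slot)
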