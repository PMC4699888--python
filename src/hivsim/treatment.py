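"""Treatment-line state machine and per-line virologic efficacy.

Patients start on the study regimen plus optimized background therapy
(line 1). Exits are caused by first-year virologic failure (evaluated at the
week-48 endpoint, i.e. after 12 model months on the line), late failure
(monthly rebound risk once suppressed beyond week 48), or adverse-event
discontinuation. INI resistance can be acquired only at a first-line
virologic failure and selects the successor branch: without resistance the
path runs through a second optimized line and two salvage lines (four lines
in all); with resistance it runs through the salvage-composition second line
and one further salvage line (three lines). After the final line fails the
patient remains on that regimen, flagged as failing the last line.
"""

from __future__ import annotations

from .parameters import EfficacyBlock, ModelParameters, RegimenLine

__all__ = [
    "initial_line",
    "line_sequence",
    "next_line",
    "line_art_cost",
    "year1_outcome",
    "monthly_late_failure_prob",
    "resistance_on_failure",
    "ae_discontinuation",
]

#: Month (0-based, counted from line start) at which the week-48 virologic
#: endpoint is evaluated; non-responders switch at the end of this month,
#: having accrued 12 months of the line's cost.
YEAR1_EVAL_MONTH = 11

#: First 0-based month-on-line of the "beyond week 96" late-failure regime.
LATE_SECOND_REGIME_MONTH = 24


def _algorithm(arm: str, params: ModelParameters):
    try:
        return params.algorithm[arm]
    except KeyError:
        raise KeyError(f"unknown arm '{arm}'; configured arms: {sorted(params.algorithm)}")


def initial_line(arm: str, params: ModelParameters) -> RegimenLine:
    """Line 1 of the given arm."""
    return _algorithm(arm, params).line1


def line_sequence(arm: str, ini_resistant: bool, params: ModelParameters) -> tuple[RegimenLine, ...]:
    """The full ordered line path for an arm and resistance status."""
    return _algorithm(arm, params).sequence(ini_resistant)


def next_line(arm: str, current_line_index: int, ini_resistant: bool,
              params: ModelParameters) -> RegimenLine | None:
    """Successor of the line at ``current_line_index`` (0-based position on
    the patient's realized path), or ``None`` once the path is exhausted:
    the patient then stays on the final regimen, failing the last line."""
    seq = line_sequence(arm, ini_resistant, params)
    if not 0 <= current_line_index < len(seq):
        raise IndexError(f"line index {current_line_index} outside path of length {len(seq)}")
    nxt = current_line_index + 1
    return seq[nxt] if nxt < len(seq) else None


def line_art_cost(line: RegimenLine, params: ModelParameters) -> float:
    """Monthly ART cost of a line: the sum of its priced components."""
    return float(sum(params.costs.art_monthly[c] for c in line.cost_components))


def efficacy_of(line: RegimenLine, params: ModelParameters) -> EfficacyBlock:
    return params.efficacy[line.efficacy]


def year1_outcome(line: RegimenLine, rng_draw: float, params: ModelParameters) -> bool:
    """Bernoulli week-48 suppression outcome for a patient starting the line."""
    return float(rng_draw) < efficacy_of(line, params).suppression_rate_y1


def monthly_late_failure_prob(line: RegimenLine, months_since_line_start: int,
                              params: ModelParameters) -> float:
    """Monthly probability of virologic rebound for a suppressed patient.

    Constant between weeks 48 and 96, then a single higher constant
    thereafter (the beyond-week-240 rate is extended unchanged).
    ``months_since_line_start`` counts elapsed months on the line (>= 12;
    the first year is governed by :func:`year1_outcome`).
    """
    m = int(months_since_line_start)
    if m < 12:
        raise ValueError(
            f"late failure applies from month 12 on a line; got month {m} "
            "(the first year is governed by the week-48 suppression outcome)"
        )
    eff = efficacy_of(line, params)
    if m < LATE_SECOND_REGIME_MONTH:
        return eff.late_failure_monthly_48_96
    return eff.late_failure_monthly_after96


def resistance_on_failure(arm: str, params: ModelParameters, rng_draw: float) -> bool:
    """Whether INI resistance is acquired at a first-line virologic failure.

    The flag persists for life and selects the successor branch.
    """
    return float(rng_draw) < params.resistance_prob_on_failure[arm]


def ae_discontinuation(params: ModelParameters, rng_draw: float) -> bool:
    """Monthly Bernoulli adverse-event discontinuation. Triggers the same
    successor logic as a failure but never confers resistance."""
    return float(rng_draw) < params.ae_discontinuation_monthly
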