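"""Cohort-scale reference constants.

The printed per-rat session and lap counts of the study cohort that the
synthetic defaults emulate (7 rats, 48-53 sessions each, ~74 laps per
session), plus the tracking-lag exclusion counts at the two choice points.
These are inputs to desk-checkable arithmetic (cohort totals, exclusion
fractions), not fitted quantities.
"""

from __future__ import annotations

SESSIONS_PER_RAT = {1: 48, 2: 50, 3: 50, 4: 50, 5: 53, 6: 53, 7: 53}
LAPS_PER_RAT = {1: 3313, 2: 3602, 3: 4079, 4: 3610, 5: 3594, 6: 3805, 7: 4478}

#: choice-point passes lost to momentary tracking lag
EXCLUDED_PASSES_CP1 = 13
EXCLUDED_PASSES_CP2 = 10

N_RATS = len(SESSIONS_PER_RAT)


def total_sessions() -> int:
    return sum(SESSIONS_PER_RAT.values())


def total_laps() -> int:
    return sum(LAPS_PER_RAT.values())


def mean_laps_per_session() -> float:
    return total_laps() / total_sessions()


def exclusion_percent(choice_point: int) -> float:
    """Percentage of laps excluded at a choice point (1 or 2)."""
    n = {1: EXCLUDED_PASSES_CP1, 2: EXCLUDED_PASSES_CP2}[choice_point]
    return 100.0 * n / total_laps()
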