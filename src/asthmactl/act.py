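"""Asthma Control Test (ACT) scoring and control-status classification.

The ACT is a five-item patient questionnaire with a 4-week recall period.
Each item is answered on a 1-5 scale (1 worst, 5 best); the total score is
the plain sum, ranging 5 (poor control) to 25 (complete control).  Scores
<= 19 indicate not-well-controlled asthma; scores > 19 well-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ControlStatus",
    "score_act",
    "classify_control",
    "NOT_WELL_CONTROLLED",
    "WELL_CONTROLLED",
    "CONTROL_CUTOFF",
]

NOT_WELL_CONTROLLED = "not_well_controlled"
WELL_CONTROLLED = "well_controlled"
#: highest total score still classified as not well-controlled
CONTROL_CUTOFF = 19

MIN_SCORE = 5
MAX_SCORE = 25


@dataclass(frozen=True)
class ControlStatus:
    score: int
    status: str


def score_act(items) -> int:
    """Sum the five item responses.

    Raises ``ValueError`` if any item is missing or out of the 1-5 range;
    incomplete questionnaires cannot be scored and must be screened out
    beforehand (see :func:`asthmactl.cohort.is_valid_act`).
    """
    items = tuple(items)
    if len(items) != 5:
        raise ValueError(f"expected exactly 5 items, got {len(items)}")
    for i, v in enumerate(items):
        if v is None:
            raise ValueError(f"item {i + 1} is missing; score cannot be calculated")
        if not isinstance(v, int) or not 1 <= v <= 5:
            raise ValueError(f"item {i + 1} out of range [1,5]: {v!r}")
    return sum(items)


def classify_control(score: int) -> ControlStatus:
    """Classify a total ACT score; <= 19 is not well-controlled."""
    if not MIN_SCORE <= score <= MAX_SCORE:
        raise ValueError(f"ACT score out of range [{MIN_SCORE},{MAX_SCORE}]: {score}")
    status = NOT_WELL_CONTROLLED if score <= CONTROL_CUTOFF else WELL_CONTROLLED
    return ControlStatus(score=score, status=status)
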