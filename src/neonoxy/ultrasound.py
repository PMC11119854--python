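"""Lung-ultrasound aeration scoring.

Each lung is scored in three anterior zones (upper, middle, lower) plus a
single posterolateral zone, on a 0-3 aeration scale: 0 = only horizontal
A-lines, 1 = at least three well-spaced B-lines, 2 = crowded B-lines
and/or subpleural consolidation, 3 = extended consolidation. The composite
score sums the eight zones, giving a 0-24 injury index per animal. Image
interpretation itself is out of scope; zone scores are inputs.
"""
from __future__ import annotations

from typing import Dict, Mapping

from pydantic import BaseModel, field_validator

from .errors import DomainError

__all__ = ["ZONES", "LungUSExam", "composite_score", "MAX_SCORE"]

ZONES = (
    "left_ant_upper",
    "left_ant_middle",
    "left_ant_lower",
    "left_posterolateral",
    "right_ant_upper",
    "right_ant_middle",
    "right_ant_lower",
    "right_posterolateral",
)

MAX_SCORE = 3 * len(ZONES)  # 24


class LungUSExam(BaseModel):
    """Per-zone scores for one animal at one period."""

    animal_id: str = ""
    period: str = ""
    scores: Dict[str, int]

    @field_validator("scores")
    @classmethod
    def _validate_scores(cls, scores: Dict[str, int]) -> Dict[str, int]:
        missing = set(ZONES) - set(scores)
        if missing:
            raise ValueError(f"missing zone(s): {sorted(missing)}")
        extra = set(scores) - set(ZONES)
        if extra:
            raise ValueError(f"unknown zone(s): {sorted(extra)}")
        for zone in ZONES:
            if scores[zone] not in (0, 1, 2, 3):
                raise ValueError(
                    f"zone {zone!r} has score {scores[zone]!r}; "
                    "must be an integer in 0..3"
                )
        return scores


def composite_score(exam: "LungUSExam | Mapping[str, int]") -> int:
    """Composite lung-ultrasound score: sum of the 8 zone scores, 0-24."""
    if not isinstance(exam, LungUSExam):
        try:
            exam = LungUSExam(scores=dict(exam))
        except (TypeError, ValueError) as err:
            raise DomainError(str(err)) from err
    return sum(exam.scores[z] for z in ZONES)
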