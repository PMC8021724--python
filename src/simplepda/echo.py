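"""Echocardiographic hsPDA criterion at the 24/48/72 h screening hours.

A duct is hemodynamically significant when its inner diameter indexed to
body weight exceeds 1.5 mm/kg and/or the left-atrium-to-aortic-root ratio
exceeds 1.5 (both strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ECHO_HOURS",
    "DUCT_WEIGHT_THRESHOLD",
    "LA_AO_THRESHOLD",
    "EchoAssessment",
    "classify_hspda",
    "label_infant",
]

ECHO_HOURS = (24, 48, 72)
DUCT_WEIGHT_THRESHOLD = 1.5  # mm/kg
LA_AO_THRESHOLD = 1.5


class EchoInputError(ValueError):
    pass


@dataclass(frozen=True)
class EchoAssessment:
    """One echo screen: LA/Ao ratio, duct inner diameter (mm), weight (kg)."""

    infant_id: str
    hour: int
    la_ao: float
    duct_diameter: float
    weight: float

    def __post_init__(self) -> None:
        if self.hour not in ECHO_HOURS:
            raise EchoInputError(f"echo hour must be one of {ECHO_HOURS}, got {self.hour}")
        for name in ("la_ao", "duct_diameter", "weight"):
            v = getattr(self, name)
            if not v > 0:
                raise EchoInputError(f"{name} must be positive, got {v}")

    @property
    def duct_per_kg(self) -> float:
        """Duct inner diameter indexed to current weight, mm/kg."""
        return self.duct_diameter / self.weight


def classify_hspda(assessment: EchoAssessment) -> bool:
    """True iff duct diameter/weight > 1.5 mm/kg or LA/Ao > 1.5 (strict)."""
    return (
        assessment.duct_per_kg > DUCT_WEIGHT_THRESHOLD
        or assessment.la_ao > LA_AO_THRESHOLD
    )


def label_infant(assessments: Sequence[EchoAssessment]) -> tuple[bool, int | None]:
    """Infant-level echo label over the 24–72 h window (any-hour rule).

    Returns ``(label, deciding_hour)`` where ``deciding_hour`` is the first
    hour at which the criterion is met, or ``None`` if it never is.
    """
    if len(assessments) == 0:
        raise EchoInputError("at least one echo assessment is required")
    ids = {a.infant_id for a in assessments}
    if len(ids) != 1:
        raise EchoInputError(f"assessments span multiple infants: {sorted(ids)}")
    for a in sorted(assessments, key=lambda a: a.hour):
        if classify_hspda(a):
            return True, a.hour
    return False, None
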