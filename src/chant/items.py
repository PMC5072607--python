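"""The four screening items, their scales, orientations, and decision thresholds.

The instrument scores four bilateral items on the feet: pain (numeric rating
scale 0-10), numbness (0-10), timed great-toe vibration sense (seconds; shorter
perception times are abnormal), and the ankle reflex (ordinal grade: 0 normal,
1 hypoactive, 2 absent).  Each item has a fixed *orientation* -- which side of
its cutoff counts as abnormal -- that is stored alongside the cutoff rather
than hard-coded in the scoring logic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .exceptions import ConfigurationError

#: canonical item order used throughout the package
ITEMS = ("pain", "numb", "vib", "reflex")

#: human-readable labels for reports
ITEM_LABELS = {
    "pain": "Bilateral feet pain",
    "numb": "Bilateral feet numbness",
    "vib": "Bilateral great-toe vibration",
    "reflex": "Bilateral ankle reflex",
}


class Orientation(enum.Enum):
    """Which side of a cutoff is abnormal.  Comparison is inclusive on the
    abnormal side (``>= cut`` for HIGHER_ABNORMAL, ``<= cut`` for
    LOWER_ABNORMAL)."""

    HIGHER_ABNORMAL = "higher_abnormal"
    LOWER_ABNORMAL = "lower_abnormal"


#: fixed per-item orientation: high pain/numbness scores and high reflex grades
#: are abnormal; *short* vibration perception times are abnormal
ITEM_ORIENTATION = {
    "pain": Orientation.HIGHER_ABNORMAL,
    "numb": Orientation.HIGHER_ABNORMAL,
    "vib": Orientation.LOWER_ABNORMAL,
    "reflex": Orientation.HIGHER_ABNORMAL,
}

#: reflex grades
REFLEX_NORMAL, REFLEX_HYPOACTIVE, REFLEX_ABSENT = 0, 1, 2


@dataclass(frozen=True)
class MeasurandThresholds:
    """Per-item decision thresholds.

    Defaults are the consensus cutoffs derived in the development phase:
    pain >= 5.5 on the 0-10 scale, numbness >= 2.55, vibration perception
    <= 13.2 seconds, and an ankle reflex graded hypoactive or absent.
    """

    pain_cut: float = 5.5
    numb_cut: float = 2.55
    vib_cut: float = 13.2
    reflex_abnormal_grades: frozenset[int] = field(
        default_factory=lambda: frozenset({REFLEX_HYPOACTIVE, REFLEX_ABSENT})
    )

    def __post_init__(self) -> None:
        if not 0 <= self.pain_cut <= 10:
            raise ConfigurationError(f"pain_cut outside 0-10: {self.pain_cut}")
        if not 0 <= self.numb_cut <= 10:
            raise ConfigurationError(f"numb_cut outside 0-10: {self.numb_cut}")
        if self.vib_cut < 0:
            raise ConfigurationError(f"vib_cut must be >= 0: {self.vib_cut}")
        grades = frozenset(self.reflex_abnormal_grades)
        if not grades or not grades <= {0, 1, 2}:
            raise ConfigurationError(
                f"reflex_abnormal_grades must be a non-empty subset of "
                f"{{0,1,2}}: {set(self.reflex_abnormal_grades)}"
            )
        object.__setattr__(self, "reflex_abnormal_grades", grades)

    def side_abnormal(self, item: str, value: float) -> bool:
        """Whether a single-side measurement is abnormal for ``item``."""
        if item == "pain":
            return value >= self.pain_cut
        if item == "numb":
            return value >= self.numb_cut
        if item == "vib":
            return value <= self.vib_cut
        if item == "reflex":
            return int(value) in self.reflex_abnormal_grades
        raise ConfigurationError(f"unknown item {item!r}")
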