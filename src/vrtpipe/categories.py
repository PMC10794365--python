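"""Stimulus categories of the viewing-reaction-time paradigm.

The paradigm shows nude computer-generated figures of males and females in
the five Tanner stages of pubertal development.  Each (sex, Tanner stage)
pair is one stimulus category; there are exactly ten.  Categories with
Tanner stage 1-3 depict pre- or peripubertal bodies ("child" categories),
stages 4-5 depict late-/postpubertal bodies ("adult" categories).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"


@dataclass(frozen=True, order=True)
class StimulusCategory:
    """One of the ten (sex, Tanner stage) stimulus categories."""

    sex: Sex
    tanner: int

    def __post_init__(self) -> None:
        if self.tanner not in range(1, 6):
            raise ValueError(f"Tanner stage must be 1-5, got {self.tanner}")

    @property
    def label(self) -> str:
        """Short label, e.g. 'FT3' for female Tanner stage 3."""
        return f"{self.sex.value}T{self.tanner}"

    @property
    def is_child(self) -> bool:
        """Pre-/peripubertal (Tanner 1-3)."""
        return self.tanner <= 3

    @classmethod
    def from_label(cls, label: str) -> "StimulusCategory":
        label = label.strip().upper()
        if len(label) != 3 or label[1] != "T":
            raise ValueError(f"bad category label {label!r}; expected e.g. 'MT1'")
        try:
            sex = Sex(label[0])
        except ValueError:
            raise ValueError(f"bad sex code {label[0]!r} in category {label!r}") from None
        try:
            tanner = int(label[2])
        except ValueError:
            raise ValueError(f"bad Tanner code in category {label!r}") from None
        return cls(sex, tanner)


# Fixed deterministic ordering: male before female, ascending Tanner stage.
# This order is the documented tie-break for the max-based index.
CATEGORIES: tuple[StimulusCategory, ...] = tuple(
    StimulusCategory(sex, t) for sex in (Sex.MALE, Sex.FEMALE) for t in range(1, 6)
)
CATEGORY_LABELS: tuple[str, ...] = tuple(c.label for c in CATEGORIES)

CHILD_CATEGORIES: tuple[StimulusCategory, ...] = tuple(c for c in CATEGORIES if c.is_child)
ADULT_CATEGORIES: tuple[StimulusCategory, ...] = tuple(c for c in CATEGORIES if not c.is_child)
CHILD_LABELS: tuple[str, ...] = tuple(c.label for c in CHILD_CATEGORIES)
ADULT_LABELS: tuple[str, ...] = tuple(c.label for c in ADULT_CATEGORIES)

# Display order used by the descriptive tables (mirrors the convention of
# listing male Tanner 5 first down to female Tanner 5 last).
TABLE_ORDER: tuple[str, ...] = ("MT5", "MT4", "MT3", "MT2", "MT1", "FT1", "FT2", "FT3", "FT4", "FT5")
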