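"""Quality grade labels.

Apples are sorted into three visually ordered quality grades. Integer codes
are fixed: 0 = premium, 1 = middle, 2 = poor. The ordering matters — a higher
code means more/larger/darker surface defects.
"""

from __future__ import annotations

from dataclasses import dataclass

GRADE_NAMES = ("premium", "middle", "poor")
N_CLASSES = 3


@dataclass(frozen=True)
class GradeLabel:
    """One of the three quality grades, identified by code and name."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in (0, 1, 2):
            raise ValueError(f"grade code must be 0, 1 or 2, got {self.code}")

    @property
    def name(self) -> str:
        return GRADE_NAMES[self.code]

    @classmethod
    def from_name(cls, name: str) -> "GradeLabel":
        try:
            return cls(GRADE_NAMES.index(name))
        except ValueError:
            raise ValueError(f"unknown grade name {name!r}") from None

    def __int__(self) -> int:
        return self.code


PREMIUM = GradeLabel(0)
MIDDLE = GradeLabel(1)
POOR = GradeLabel(2)
ALL_GRADES = (PREMIUM, MIDDLE, POOR)
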