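"""The fixed eight-class tissue label schema and its display colors.

The segmentation task distinguishes six "main" tissue classes — tumor (TUM),
mouse stroma / connective tissue (MST), necrosis (NEC), blood cells / vessels /
inbleeding (BLC), vacuoles (VAC) and muscle (MUS) — plus technical artifacts
(TAR) and slide background (BGR).  Rendered tissue maps use the conventional
color coding red TUM, blue MST, yellow NEC, green BLC, cyan VAC, magenta MUS,
black TAR and white BGR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassEntry",
    "ClassPalette",
    "make_palette",
    "TUM",
    "MST",
    "NEC",
    "BLC",
    "VAC",
    "MUS",
    "TAR",
    "BGR",
    "CLASS_NAMES",
    "MAIN_CLASSES",
    "N_CLASSES",
]

TUM, MST, NEC, BLC, VAC, MUS, TAR, BGR = range(8)
N_CLASSES = 8

CLASS_NAMES = ("TUM", "MST", "NEC", "BLC", "VAC", "MUS", "TAR", "BGR")
#: The six tissue classes that count towards the tissue area A.
MAIN_CLASSES = (TUM, MST, NEC, BLC, VAC, MUS)

_COLORS = (
    (1.0, 0.0, 0.0),  # TUM red
    (0.0, 0.0, 1.0),  # MST blue
    (1.0, 1.0, 0.0),  # NEC yellow
    (0.0, 1.0, 0.0),  # BLC green
    (0.0, 1.0, 1.0),  # VAC cyan
    (1.0, 0.0, 1.0),  # MUS magenta
    (0.0, 0.0, 0.0),  # TAR black
    (1.0, 1.0, 1.0),  # BGR white
)


@dataclass(frozen=True)
class ClassEntry:
    id: int
    name: str
    color: tuple[float, float, float]


@dataclass(frozen=True)
class ClassPalette:
    """Ordered, immutable mapping of class ids to names and display colors."""

    entries: tuple[ClassEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if ids != list(range(len(self.entries))):
            raise ValueError("palette ids must be exactly 0..n-1 in order")
        if len({e.name for e in self.entries}) != len(self.entries):
            raise ValueError("palette names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def colors(self) -> np.ndarray:
        """(n_classes, 3) float array of display colors in [0, 1]."""
        return np.asarray([e.color for e in self.entries], dtype=np.float64)

    def id_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.id
        raise KeyError(name)


def make_palette() -> ClassPalette:
    """Return the fixed eight-class palette (ids 0..7, standard colors)."""
    return ClassPalette(
        tuple(
            ClassEntry(i, CLASS_NAMES[i], _COLORS[i]) for i in range(N_CLASSES)
        )
    )
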