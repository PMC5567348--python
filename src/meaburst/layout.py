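"""Planar micro-electrode array geometry.

The standard culture dish used throughout this package is an 8x8 grid of
60 electrodes on a 200 um pitch (the four corners of the grid are empty).
Electrodes are named by a two-digit column-row code ("12" = column 1,
row 2), following the Multi Channel Systems convention, so the physical
position of an electrode is recoverable from its label alone.  One
electrode serves as internal reference and records no activity, leaving
59 recording sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


CORNER_LABELS = frozenset({"11", "18", "81", "88"})
#: MCS 60MEA convention: electrode 15 is the internal reference.
DEFAULT_REFERENCE = "15"


@dataclass(frozen=True)
class MEALayout:
    """Electrode labels, coordinates (um) and excluded (reference) sites."""

    electrodes: tuple[str, ...]
    coordinates: dict[str, tuple[float, float]]
    excluded: frozenset[str] = field(default_factory=frozenset)
    pitch_um: float = 200.0

    @property
    def recording_electrodes(self) -> tuple[str, ...]:
        return tuple(e for e in self.electrodes if e not in self.excluded)

    def __contains__(self, label: str) -> bool:
        return label in self.coordinates

    def distance_um(self, a: str, b: str) -> float:
        """Euclidean distance between two electrode centres in micrometres."""
        xa, ya = self.coordinates[a]
        xb, yb = self.coordinates[b]
        return math.hypot(xa - xb, ya - yb)

    def neighbors(self, label: str, radius_um: float | None = None) -> list[str]:
        """Recording electrodes within ``radius_um`` of ``label`` (excluded: itself).

        Default radius covers the 8-neighborhood on the grid (diagonal
        pitch is ``pitch * sqrt(2)``).
        """
        if radius_um is None:
            radius_um = self.pitch_um * math.sqrt(2.0) * 1.01
        return [
            e
            for e in self.recording_electrodes
            if e != label and self.distance_um(label, e) <= radius_um
        ]


def mcs_8x8(reference: str | None = DEFAULT_REFERENCE, pitch_um: float = 200.0) -> MEALayout:
    """Build the standard 8x8, 60-electrode layout.

    Parameters
    ----------
    reference : str or None
        Label of the internal reference electrode (excluded from
        recording).  ``None`` marks no electrode as reference.
    pitch_um : float
        Centre-to-centre electrode spacing in micrometres.
    """
    labels = []
    coords = {}
    for col in range(1, 9):
        for row in range(1, 9):
            label = f"{col}{row}"
            if label in CORNER_LABELS:
                continue
            labels.append(label)
            coords[label] = ((col - 1) * pitch_um, (row - 1) * pitch_um)
    excluded = frozenset() if reference is None else frozenset({reference})
    if reference is not None and reference not in coords:
        raise ValueError(f"reference electrode {reference!r} not on the grid")
    return MEALayout(
        electrodes=tuple(sorted(labels)),
        coordinates=coords,
        excluded=excluded,
        pitch_um=pitch_um,
    )
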