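"""Cell agents and small deterministic cell configurations.

A :class:`CellRecord` is one off-lattice agent: a circle of fixed radius
with a phenotype, a growth clock, a division budget and per-partner
contact clocks (used by the T-cell engulfment rules).  The module also
provides the deterministic configurations used throughout the tests and
examples: a two-cell pair, a seven-cell hexagon and a hexagonally packed
islet monolayer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Phenotype",
    "CellRecord",
    "positions_array",
    "two_cell_pair",
    "hexagon_with_center",
    "hex_lattice_disk",
]


class Phenotype(str, Enum):
    EPITHELIAL = "epithelial"
    CANCER = "cancer"
    TCELL = "tcell"


@dataclass
class CellRecord:
    """One agent of the off-lattice model."""

    id: int
    position: np.ndarray                    # 2-vector, um
    phenotype: Phenotype = Phenotype.EPITHELIAL
    radius: float = 2.5                     # um (R or R_t by phenotype)
    alive: bool = True
    growth_clock: float = 0.0               # min since birth / last division
    divisions_done: int = 0
    contact_clocks: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)
        if self.radius <= 0:
            raise ValueError(f"cell {self.id}: radius must be positive")
        if self.growth_clock < 0:
            raise ValueError(f"cell {self.id}: growth clock must be non-negative")


def positions_array(cells: list[CellRecord]) -> np.ndarray:
    """Stack live-cell positions into an (n, 2) array (order preserved)."""
    if not cells:
        return np.empty((0, 2), dtype=float)
    return np.array([c.position for c in cells], dtype=float)


def _make(positions: np.ndarray, radius: float, phenotype: Phenotype) -> list[CellRecord]:
    return [
        CellRecord(id=i, position=p, phenotype=phenotype, radius=radius)
        for i, p in enumerate(positions)
    ]


def two_cell_pair(separation: float, radius: float = 2.5,
                  phenotype: Phenotype = Phenotype.EPITHELIAL) -> list[CellRecord]:
    """Two identical cells on the x-axis, centred on the origin."""
    half = separation / 2.0
    pos = np.array([[-half, 0.0], [half, 0.0]])
    return _make(pos, radius, phenotype)


def hexagon_with_center(spacing: float, radius: float = 2.5,
                        phenotype: Phenotype = Phenotype.EPITHELIAL) -> list[CellRecord]:
    """Seven cells: one at the origin, six at the vertices of a regular hexagon.

    ``spacing`` is the centre-to-vertex distance, so every vertex cell is a
    nearest neighbour of the central cell (id 0).
    """
    pts = [np.zeros(2)]
    for j in range(6):
        theta = j * math.pi / 3.0
        pts.append(spacing * np.array([math.cos(theta), math.sin(theta)]))
    return _make(np.array(pts), radius, phenotype)


def hex_lattice_points(disk_radius: float, spacing: float) -> np.ndarray:
    """Points of a hexagonal lattice inside a disk centred on the origin.

    The lattice always contains the origin; a point is kept when its norm
    is at most ``disk_radius``.  Deterministic (no randomness).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    row_height = spacing * math.sqrt(3.0) / 2.0
    n_rows = int(math.ceil(disk_radius / row_height)) + 1
    n_cols = int(math.ceil(disk_radius / spacing)) + 1
    pts = []
    for row in range(-n_rows, n_rows + 1):
        y = row * row_height
        x_offset = 0.0 if row % 2 == 0 else spacing / 2.0
        for col in range(-n_cols, n_cols + 1):
            x = col * spacing + x_offset
            if math.hypot(x, y) <= disk_radius:
                pts.append((x, y))
    return np.array(sorted(pts), dtype=float)


def hex_lattice_disk(disk_radius: float, spacing: float, radius: float = 2.5,
                     phenotype: Phenotype = Phenotype.EPITHELIAL) -> list[CellRecord]:
    """Hexagonally packed monolayer of cells filling a disk."""
    pts = hex_lattice_points(disk_radius, spacing)
    if pts.size == 0:
        raise ValueError("packing produced zero cells")
    return _make(pts, radius, phenotype)
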