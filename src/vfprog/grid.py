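"""Geometry and topology of the 24-2 perimetric test pattern.

The 24-2 pattern places 54 stimuli on a 6-degree lattice offset 3 degrees
from both meridians (rows at y = +-3, +-9, +-15, +-21), with the row at
y = +-3 extended one extra column into the nasal field.  The two locations
falling on the physiologic blind spot (15 degrees temporal, y = +-3) are
excluded from analysis, leaving the 52 locations that carry sensitivity
data.  This module fixes the coordinate convention, the location ordering,
the adjacency relation used by cluster criteria, and the edge (rim)
definition used by baseline screening.

Conventions
-----------
* y > 0 is superior; no location lies on the horizontal meridian.
* x is signed with **nasal positive for OD**; the OS grid is the OD grid
  mirrored in x (so a given index refers to the anatomically mirrored
  location in either eye, and per-index arrays are comparable across eyes).
* Locations are indexed 0..51 in row-major order: rows from superior to
  inferior, x ascending within a row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridLocation",
    "Grid24_2",
    "build_grid",
    "are_adjacent",
    "edge_locations",
]

# x-columns per row of the OD 24-2 pattern (nasal = positive x), before
# blind-spot removal.  The +-3 rows carry the extra nasal column at x = 27.
_ROW_X: dict[int, tuple[int, ...]] = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    3: (-21, -15, -9, -3, 3, 9, 15, 21, 27),
}

#: blind-spot column: 15 degrees temporal (x = -15 for OD under the
#: nasal-positive convention), straddling the horizontal meridian.
BLIND_SPOT_OD = ((-15, 3), (-15, -3))


@dataclass(frozen=True)
class GridLocation:
    """One 24-2 test location."""

    index: int
    x: int  # degrees; nasal positive for OD, mirrored for OS
    y: int  # degrees; superior positive
    is_edge: bool
    hemifield: str  # "superior" | "inferior"


@dataclass(frozen=True, eq=False)
class Grid24_2:
    """The 52-location 24-2 grid for one eye side.

    ``adjacency`` is a symmetric irreflexive boolean matrix; cluster search
    additionally restricts it to pairs in the same hemifield (see
    :meth:`hemifield_adjacency`).
    """

    eye_side: str  # "OD" | "OS"
    locations: tuple[GridLocation, ...]
    adjacency: np.ndarray = field(repr=False)
    connectivity: int = 8

    def __post_init__(self) -> None:
        if len(self.locations) != 52:
            raise ValueError("24-2 grid must hold 52 locations")

    @property
    def n(self) -> int:
        return len(self.locations)

    def coords(self) -> np.ndarray:
        """(52, 2) array of (x, y) in degrees."""
        return np.array([(p.x, p.y) for p in self.locations])

    def hemifield_mask(self, hemifield: str) -> np.ndarray:
        return np.array([p.hemifield == hemifield for p in self.locations])

    def hemifield_adjacency(self) -> np.ndarray:
        """Adjacency restricted to same-hemifield pairs (never crosses the
        horizontal midline), as used by cluster criteria."""
        sup = self.hemifield_mask("superior")
        same = np.equal.outer(sup, sup)
        return self.adjacency & same

    def to_frame(self) -> pd.DataFrame:
        """Audit table: index, x_deg, y_deg, hemifield, is_edge."""
        return pd.DataFrame(
            {
                "index": [p.index for p in self.locations],
                "x_deg": [p.x for p in self.locations],
                "y_deg": [p.y for p in self.locations],
                "hemifield": [p.hemifield for p in self.locations],
                "is_edge": [p.is_edge for p in self.locations],
            }
        )


def _lattice_points_od() -> list[tuple[int, int]]:
    pts = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        for x in _ROW_X[abs(y)]:
            if (x, y) in BLIND_SPOT_OD:
                continue
            pts.append((x, y))
    return pts


def _is_edge(x: int, y: int, edge_rows: int = 21, nasal_col: int = 27) -> bool:
    return abs(y) >= edge_rows or abs(x) >= nasal_col


def build_grid(eye_side: str, connectivity: int = 8) -> Grid24_2:
    """Construct the 52-location 24-2 grid for one eye.

    Parameters
    ----------
    eye_side:
        ``"OD"`` or ``"OS"``.  The OS grid mirrors the OD grid in x; index
        order is preserved so per-index arrays correspond anatomically.
    connectivity:
        8 (default; diagonals on the 6-degree lattice count as adjacent) or
        4 (rook moves only).
    """
    if eye_side not in ("OD", "OS"):
        raise ValueError(f"eye_side must be 'OD' or 'OS', got {eye_side!r}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mirror = -1 if eye_side == "OS" else 1
    pts = [(mirror * x, y) for x, y in _lattice_points_od()]
    locs = tuple(
        GridLocation(
            index=i,
            x=x,
            y=y,
            is_edge=_is_edge(x, y),
            hemifield="superior" if y > 0 else "inferior",
        )
        for i, (x, y) in enumerate(pts)
    )
    adj = np.zeros((52, 52), dtype=bool)
    for a, b in itertools.combinations(range(52), 2):
        dx = abs(locs[a].x - locs[b].x)
        dy = abs(locs[a].y - locs[b].y)
        if connectivity == 8:
            near = dx <= 6 and dy <= 6
        else:
            near = (dx == 6 and dy == 0) or (dx == 0 and dy == 6)
        if near:
            adj[a, b] = adj[b, a] = True
    return Grid24_2(eye_side=eye_side, locations=locs, adjacency=adj,
                    connectivity=connectivity)


def are_adjacent(grid: Grid24_2, a: int, b: int) -> bool:
    """True iff locations ``a`` and ``b`` are neighbours under the grid's
    connectivity (irreflexive)."""
    n = grid.n
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"location index out of range: {a}, {b}")
    if a == b:
        raise ValueError("adjacency is irreflexive; a and b must differ")
    return bool(grid.adjacency[a, b])


def edge_locations(grid: Grid24_2) -> frozenset[int]:
    """Indices of rim locations (default: |y| = 21 rows plus the extreme
    nasal column |x| = 27), excluded from the baseline cluster criterion."""
    return frozenset(p.index for p in grid.locations if p.is_edge)
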