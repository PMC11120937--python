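"""Deterministic per-atom grids and cell-list neighbor search.

Two discretizations drive every measurement in the geometry engine:

* a spherical Fibonacci (golden-angle) point set on each atom's sphere
  surface, each point representing an equal area element
  ``delta_s = 4 * pi * r**2 / n``;
* an axis-aligned cubic lattice anchored at the atom's own center, each
  point representing a volume element ``delta_v = spacing**3``.

Default precision uses 5000 surface points and a 0.2 A lattice; enhanced
precision uses 15092 points and 0.1 A.  There is no randomness anywhere:
identical arguments always give bit-identical point sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "GridSpec",
    "CellIndex",
    "surface_points",
    "lattice_points",
    "neighbors_within",
    "DEFAULT_SOLVENT_RADIUS",
]

DEFAULT_SOLVENT_RADIUS = 1.4
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class GridSpec:
    """Grid resolution settings for the contact engine."""

    precision: str = "default"
    n_surface_points: int = 5000
    lattice_spacing: float = 0.2
    solvent_radius: float = DEFAULT_SOLVENT_RADIUS

    @property
    def delta_v(self) -> float:
        return self.lattice_spacing ** 3

    def delta_s(self, radius: float) -> float:
        """Area element for one surface point on a sphere of *radius*."""
        return 4.0 * math.pi * radius * radius / self.n_surface_points

    @classmethod
    def from_precision(cls, precision: str = "default",
                       solvent_radius: float = DEFAULT_SOLVENT_RADIUS) -> "GridSpec":
        if precision == "default":
            return cls("default", 5000, 0.2, solvent_radius)
        if precision == "enhanced":
            return cls("enhanced", 15092, 0.1, solvent_radius)
        raise ValueError(f"unknown precision {precision!r}")


@lru_cache(maxsize=64)
def _unit_fibonacci(n: int) -> np.ndarray:
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = _GOLDEN_ANGLE * i
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    pts.setflags(write=False)
    return pts


def surface_points(center, radius: float, n: int) -> np.ndarray:
    """*n* near-uniform points on the sphere of *radius* around *center*."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if n < 4:
        raise ValueError(f"need at least 4 surface points, got {n}")
    return np.asarray(center, dtype=np.float64) + radius * _unit_fibonacci(n)


@lru_cache(maxsize=512)
def _lattice_offsets(radius: float, spacing: float) -> np.ndarray:
    k = int(math.floor(radius / spacing))
    ax = spacing * np.arange(-k, k + 1, dtype=np.float64)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = (pts * pts).sum(axis=1) <= radius * radius
    pts = pts[keep]
    pts.setflags(write=False)
    return pts


def lattice_points(center, radius: float, spacing: float) -> np.ndarray:
    """Cubic-lattice points within *radius* of *center*, lattice anchored there.

    The center itself is always a lattice point, so the set is never empty.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if spacing >= radius:
        raise ValueError(
            f"degenerate lattice: spacing {spacing} too coarse for radius {radius}"
        )
    return np.asarray(center, dtype=np.float64) + _lattice_offsets(float(radius), float(spacing))


class CellIndex:
    """Uniform-grid spatial index over a list of atoms.

    ``cell_size`` defaults to the largest expanded diameter in the model so
    that a one-shell scan can never miss an overlapping sphere pair.
    """

    def __init__(self, atoms, cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.cell_size = cell_size
        self.atoms = list(atoms)
        self._coords = np.array([a.position for a in self.atoms], dtype=np.float64) \
            if self.atoms else np.zeros((0, 3))
        self._cells: dict[tuple[int, int, int], list[int]] = {}
        keys = np.floor(self._coords / cell_size).astype(np.int64)
        for idx, key in enumerate(map(tuple, keys)):
            self._cells.setdefault(key, []).append(idx)
        self._ids = {id(a): i for i, a in enumerate(self.atoms)}

    def _candidates(self, position, cutoff: float) -> np.ndarray:
        reach = int(math.ceil(cutoff / self.cell_size))
        cx, cy, cz = (int(math.floor(c / self.cell_size)) for c in position)
        out: list[int] = []
        for dx in range(-reach, reach + 1):
            for dy in range(-reach, reach + 1):
                for dz in range(-reach, reach + 1):
                    out.extend(self._cells.get((cx + dx, cy + dy, cz + dz), ()))
        return np.array(out, dtype=np.intp)

    def neighbors_within(self, atom, cutoff: float) -> list:
        """Atoms (excluding *atom*) with center distance <= cutoff."""
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        me = self._ids.get(id(atom))
        if me is None:
            raise KeyError(f"atom {getattr(atom, 'serial', atom)} not in index")
        cand = self._candidates(atom.position, cutoff)
        if cand.size == 0:
            return []
        d2 = ((self._coords[cand] - atom.position) ** 2).sum(axis=1)
        keep = cand[(d2 <= cutoff * cutoff) & (cand != me)]
        return [self.atoms[i] for i in keep]


def neighbors_within(index: CellIndex, atom, cutoff: float) -> list:
    return index.neighbors_within(atom, cutoff)
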