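"""Nearest-water hydration profiling for structures with ordered waters.

For every solute heavy atom the *spherical distance* to its nearest
crystallographic water oxygen is

    d_sph = |center_a - center_w| - r_vdw(a) - r_vdw(water O)

Negative values mean the two vdW spheres interpenetrate (a "mosaic"
overlap).  Records are grouped by residue type and atom category -- the
peptide-plane atoms N, C, O versus the starred side-chain categories
C*, N*, O* -- and binned at 0.1 A over [-2.0, 2.8] A.

A record is labelled *interference* when some other solute atom sits
closer (by spherical distance) to that water than the focal atom does;
only waters without interference probe the atom's intrinsic hydration.
Only water oxygens are considered; water hydrogens are too small to
matter and are rarely resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HydrationRecord",
    "HydrationProfile",
    "nearest_water",
    "interference_label",
    "hydration_records",
    "bin_profile",
    "BIN_WIDTH",
    "PROFILE_RANGE",
]

BIN_WIDTH = 0.1
PROFILE_RANGE = (-2.0, 2.8)
_BACKBONE = {"N", "C", "O"}


@dataclass
class HydrationRecord:
    """One solute atom's nearest-water measurement."""

    atom: object
    water: object
    spherical_distance: float
    interference: str = ""       # "no_interference" | "interference"

    @property
    def category(self) -> str:
        el = self.atom.element
        if self.atom.name in _BACKBONE and self.atom.name == el:
            return el
        return el + "*" if el in ("C", "N", "O") else el


@dataclass
class HydrationProfile:
    """Binned spherical-distance histogram per (residue type, category)."""

    bin_edges: np.ndarray
    counts: pd.DataFrame          # index (AA, Category), one column per bin
    ratios: pd.DataFrame          # counts normalized per row
    n_records: int
    n_in_range: int


def _spherical_distances(atom, waters):
    wpos = np.array([w.position for w in waters], float).reshape(-1, 3)
    wrad = np.array([w.vdw_radius for w in waters], float)
    d = np.linalg.norm(wpos - np.asarray(atom.position, float), axis=1)
    return d - atom.vdw_radius - wrad


def nearest_water(atom, waters):
    """(water, spherical distance) minimizing the spherical distance.

    Ties are broken by the lowest water serial, so the result is
    deterministic for symmetric configurations.
    """
    waters = list(waters)
    if not waters:
        raise ValueError("no waters present")
    ds = _spherical_distances(atom, waters)
    best = min(range(len(waters)), key=lambda i: (ds[i], waters[i].serial))
    return waters[best], float(ds[best])


def interference_label(atom, water, solute_atoms) -> str:
    """Is some other solute atom closer (spherically) to *water* than *atom*?"""
    ds = _spherical_distances(water, solute_atoms)
    focal = None
    best = None
    for i, a in enumerate(solute_atoms):
        key = (float(ds[i]), a.serial)
        if a is atom:
            focal = key
        elif best is None or key < best:
            best = key
    if focal is None:
        raise ValueError("focal atom not among the solute atoms")
    if best is None or focal <= best:
        return "no_interference"
    return "interference"


def hydration_records(solute_atoms, waters) -> list[HydrationRecord]:
    """Nearest-water record for every solute atom, interference labelled."""
    solute_atoms = list(solute_atoms)
    waters = list(waters)
    out = []
    for atom in solute_atoms:
        w, d = nearest_water(atom, waters)
        out.append(HydrationRecord(
            atom=atom, water=w, spherical_distance=d,
            interference=interference_label(atom, w, solute_atoms)))
    return out


def bin_profile(records, bin_width: float = BIN_WIDTH,
                profile_range: tuple[float, float] = PROFILE_RANGE) -> HydrationProfile:
    """Histogram records per (residue type, atom category).

    Left-closed bins of *bin_width* over *profile_range*; ratios are
    normalized within each (AA, Category) row over the in-range records
    (rows with no in-range records keep all-zero ratios).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    records = list(records)
    if not records:
        raise ValueError("no records to bin")
    lo, hi = profile_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges = np.round(edges, 9) + 0.0   # exact decimals, no negative zero

    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        key = (r.atom.residue_name, r.category)
        groups.setdefault(key, []).append(r.spherical_distance)

    index = sorted(groups)
    counts = np.zeros((len(index), n_bins), dtype=int)
    for row, key in enumerate(index):
        vals = np.asarray(groups[key])
        in_range = vals[(vals >= lo) & (vals < hi)]
        if in_range.size:
            bins = np.minimum(((in_range - lo) / bin_width).astype(int), n_bins - 1)
            np.add.at(counts[row], bins, 1)

    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    labels = [f"[{edges[i]:.1f},{edges[i+1]:.1f})" for i in range(n_bins)]
    midx = pd.MultiIndex.from_tuples(index, names=["AA", "Category"])
    return HydrationProfile(
        bin_edges=edges,
        counts=pd.DataFrame(counts, index=midx, columns=labels),
        ratios=pd.DataFrame(ratios, index=midx, columns=labels),
        n_records=len(records),
        n_in_range=int(counts.sum()),
    )
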