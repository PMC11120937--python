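"""Water-mediated hydrophilic contacts (the ``-p`` analysis mode).

Instead of inflating every atom by a uniform 1.4 A solvent shell, this mode
scores an atom pair through a virtual bridging water: a 1.4 A-radius sphere
placed on the segment between the two atom centers.  How deeply the water
may interpenetrate a protein atom's vdW sphere is element specific -- the
"mosaic distance" maxima calibrated from hydration shells in crystal
structures:

====  =================
atom  max mosaic (A)
====  =================
N     0.1
O     0.2
P     0.3
S     0.5
====  =================

A pair is eligible when at least one atom is hydrophilic (N, O, P or S)
and the gap between the two vdW spheres is smaller than one water diameter
(2.8 A).  Hydrophobic atoms get no solvent expansion and permit no mosaic
overlap.  The reported contact is the grid contact between the hydrophilic
atom's vdW sphere and its bridge water; when both atoms are hydrophilic,
each gets its own water and the two contacts are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_core import ContactRecord, _one_sided_area, _one_sided_volume, _pair_distance
from .grids import GridSpec

__all__ = [
    "MOSAIC_MAXIMA",
    "WATER_RADIUS",
    "WATER_DIAMETER",
    "BridgeWater",
    "mosaic_threshold",
    "bridge_eligible",
    "place_bridge_water",
    "water_mediated_pair",
    "water_mediated_contacts",
]

MOSAIC_MAXIMA = {"N": 0.1, "O": 0.2, "P": 0.3, "S": 0.5}
WATER_RADIUS = 1.4
WATER_DIAMETER = 2.8


@dataclass
class BridgeWater:
    """A virtual bridging water sphere anchored to one or two atoms."""

    center: np.ndarray
    radius: float
    anchored_serials: tuple[int, ...]
    achieved_mosaic: tuple[float, ...]


@dataclass
class _WaterSphere:
    """Minimal sphere object understood by the contact grid routines."""

    position: np.ndarray
    vdw_radius: float = WATER_RADIUS
    serial: int = -1
    residue_id: tuple = ("", 0, "")

    def label(self) -> str:
        return "bridge-water"


def mosaic_threshold(element: str, table: dict | None = None) -> float:
    table = table or MOSAIC_MAXIMA
    try:
        return table[element.upper()]
    except KeyError:
        raise ValueError(
            f"element {element!r} is not hydrophilic; no mosaic distance defined"
        ) from None


def _gap(a, b) -> float:
    return _pair_distance(a, b) - a.vdw_radius - b.vdw_radius


def bridge_eligible(a, b, max_gap: float = WATER_DIAMETER) -> bool:
    """Pair can host a bridging water: >= 1 hydrophilic atom, vdW gap < max_gap."""
    if not (a.hydrophilic or b.hydrophilic):
        return False
    return _gap(a, b) < max_gap


def _axis(from_atom, to_atom) -> np.ndarray:
    v = np.asarray(to_atom.position, float) - np.asarray(from_atom.position, float)
    return v / np.linalg.norm(v)


def _single_overlap(h, partner, table) -> float:
    """Achieved mosaic overlap for the water anchored at hydrophilic *h*.

    The target overlap is the element maximum; when the partner is so far
    that a fully-overlapping water would have to penetrate the partner's
    sphere, the overlap is reduced (clamped) to keep the water clear of it.
    The overlap therefore decays continuously to zero as the gap approaches
    one water diameter.
    """
    m = mosaic_threshold(h.element, table)
    return min(m, WATER_DIAMETER - _gap(h, partner))


def place_single_water(h, partner, table=None) -> BridgeWater:
    """Bridge water for hydrophilic *h*, on the axis toward *partner*."""
    table = table or MOSAIC_MAXIMA
    o = _single_overlap(h, partner, table)
    d_h = h.vdw_radius + WATER_RADIUS - o
    center = np.asarray(h.position, float) + d_h * _axis(h, partner)
    return BridgeWater(center=center, radius=WATER_RADIUS,
                       anchored_serials=(h.serial,), achieved_mosaic=(o,))


def place_bridge_water(a, b, table=None) -> BridgeWater:
    """Deterministic on-axis placement of the bridging water for (a, b).

    Single hydrophilic atom: anchored at that atom with its element's
    mosaic overlap, clamped away from the partner's sphere.  Two
    hydrophilic atoms: the on-segment point whose two overlap deviations
    from the element targets are equal, so neither target is missed (or
    exceeded) by more than the other; both targets are met exactly when
    the gap equals ``2.8 - m_a - m_b``.
    """
    table = table or MOSAIC_MAXIMA
    if not bridge_eligible(a, b):
        raise ValueError(
            f"pair {getattr(a, 'serial', a)}-{getattr(b, 'serial', b)} "
            "is not eligible for a bridging water")
    if a.hydrophilic and b.hydrophilic:
        m_a = mosaic_threshold(a.element, table)
        m_b = mosaic_threshold(b.element, table)
        total = WATER_DIAMETER - _gap(a, b)   # o_a + o_b for an on-segment water
        o_a = (total + m_a - m_b) / 2.0
        o_b = total - o_a
        d_a = a.vdw_radius + WATER_RADIUS - o_a
        center = np.asarray(a.position, float) + d_a * _axis(a, b)
        return BridgeWater(center=center, radius=WATER_RADIUS,
                           anchored_serials=(a.serial, b.serial),
                           achieved_mosaic=(o_a, o_b))
    h, partner = (a, b) if a.hydrophilic else (b, a)
    return place_single_water(h, partner, table)


def _single_water_contact(h, partner, table, spec: GridSpec) -> tuple[float, float]:
    """(area, volume) of *h*'s vdW sphere against its own bridge water."""
    water = _WaterSphere(position=place_single_water(h, partner, table).center)
    bare = GridSpec(spec.precision, spec.n_surface_points, spec.lattice_spacing,
                    solvent_radius=0.0)
    ctx = [h, water]
    area = 0.5 * (_one_sided_area(h, water, ctx, bare)
                  + _one_sided_area(water, h, ctx, bare))
    v_h, _ = _one_sided_volume(h, water, ctx, bare)
    v_w, _ = _one_sided_volume(water, h, ctx, bare)
    return area, 0.5 * (v_h + v_w)


def water_mediated_pair(a, b, table=None, spec: GridSpec | None = None,
                        max_gap: float = WATER_DIAMETER) -> tuple[float, float]:
    """(area, volume) of the water-mediated contact between *a* and *b*.

    One hydrophilic atom: its contact with a single bridging water.  Both
    hydrophilic: the average of each atom's contact with its own water.
    No direct atom-atom sphere overlap enters the result.
    """
    table = table or MOSAIC_MAXIMA
    spec = spec or GridSpec()
    if not bridge_eligible(a, b, max_gap):
        raise ValueError(
            f"pair {getattr(a, 'serial', a)}-{getattr(b, 'serial', b)} "
            "is not eligible for water mediation")
    parts = [atom for atom in (a, b) if atom.hydrophilic]
    results = [_single_water_contact(h, b if h is a else a, table, spec)
               for h in parts]
    area = sum(r[0] for r in results) / len(results)
    volume = sum(r[1] for r in results) / len(results)
    return area, volume


def water_mediated_contacts(atoms, spec: GridSpec | None = None,
                            max_gap: float = WATER_DIAMETER,
                            include_aowv: bool = False):
    """All eligible inter-residue water-mediated contacts in one model.

    Mirrors :func:`contact_core.model_contacts` but in ``-p`` mode.  The
    AOWV of a water-bridged pair is reported as twice its volume (a single
    atom-water lens has unit occupancy everywhere).
    """
    spec = spec or GridSpec()
    atoms = list(atoms)
    records = []
    coords = np.array([at.position for at in atoms], float).reshape(-1, 3)
    radii = np.array([at.vdw_radius for at in atoms], float)
    for i, a in enumerate(atoms[:-1]):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        gaps = d - radii[i] - radii[i + 1:]
        for off in np.nonzero(gaps < max_gap)[0]:
            b = atoms[i + 1 + off]
            if b.residue_id == a.residue_id:
                continue
            if not (a.hydrophilic or b.hydrophilic):
                continue
            area, volume = water_mediated_pair(a, b, spec=spec, max_gap=max_gap)
            if area <= 0.0 and volume <= 0.0:
                continue
            records.append(ContactRecord(
                atom_a=a, atom_b=b,
                center_distance=float(d[off]),
                S=area, V=volume,
                V0=2.0 * volume if include_aowv else None,
            ))
    return records
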