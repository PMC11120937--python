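"""Grid-based interatomic contact area, contact volume, AOWV and SASA.

Every atom is a hard sphere of radius ``vdw + solvent_radius`` (the
"expanded" sphere; the solvent expansion is 1.4 A by default).  Contact
quantities are obtained by counting grid elements:

* contact area ``S``: surface points of one atom lying inside the partner's
  sphere, each contributing ``delta_s / ci``, where ``ci`` is the number of
  *other* atoms whose sphere contains the point.  The shared-occupancy
  division prevents a surface element in contact with several atoms from
  being counted more than once.
* contact volume ``V``: cubic-lattice points of one atom's sphere lying
  inside the partner, each contributing ``delta_v / ci`` (no double
  counting of shared overlap volume).
* atomic-overlap-weighted volume ``V0``: the same lattice traversal, but
  each point contributes ``delta_v * (1 + ci)`` -- overlap elements covered
  by many atoms are up-weighted instead of shared.
* SASA: surface points inside no other atom's sphere, times ``delta_s``.

Both one-sided estimates of a pair quantity (host a / host b) approximate
the same lens; the reported value is their mean, which makes ``S``, ``V``
and ``V0`` exactly symmetric in the two atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CellIndex, GridSpec, lattice_points, surface_points

__all__ = [
    "ContactRecord",
    "DegenerateGeometryError",
    "contact_area",
    "contact_volume",
    "aowv",
    "sasa",
    "model_sasa",
    "model_contacts",
    "expanded_radius",
]

COINCIDENT_TOLERANCE = 0.01  # A; closer centers indicate a corrupt file


class DegenerateGeometryError(ValueError):
    """Two atoms with (near-)coincident centers."""


@dataclass
class ContactRecord:
    """One atom pair's contact measurements and labels."""

    atom_a: object
    atom_b: object
    center_distance: float
    S: float                      # contact area, A^2
    V: float | None = None        # contact volume, A^3
    V0: float | None = None       # atomic-overlap-weighted volume, A^3
    covalent: bool = False
    contact_types: frozenset = field(default_factory=frozenset)
    separation_class: str = ""
    attribution: str = "NC"       # Cova | NC | UNDEF (ambiguous hetero links)


def expanded_radius(atom, spec: GridSpec) -> float:
    return atom.vdw_radius + spec.solvent_radius


def _pair_distance(a, b) -> float:
    d = float(np.linalg.norm(np.asarray(a.position, float) - np.asarray(b.position, float)))
    if d < COINCIDENT_TOLERANCE:
        raise DegenerateGeometryError(
            f"coincident atom centers ({d:.4f} A apart): "
            f"{getattr(a, 'serial', a)} and {getattr(b, 'serial', b)}"
        )
    return d


def _context_arrays(host, context, partner=None):
    """Coordinates/radii of context atoms excluding *host*; partner appended
    if missing.  Returns (coords, radii, partner_column_index)."""
    others = [c for c in context if c is not host]
    p_idx = None
    if partner is not None:
        for i, c in enumerate(others):
            if c is partner:
                p_idx = i
                break
        if p_idx is None:
            others.append(partner)
            p_idx = len(others) - 1
    coords = np.array([c.position for c in others], dtype=np.float64).reshape(-1, 3)
    return coords, np.array([c.vdw_radius for c in others], dtype=np.float64), p_idx


def _inside(points: np.ndarray, coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean (n_points, n_spheres): point strictly inside each sphere."""
    if coords.shape[0] == 0:
        return np.zeros((points.shape[0], 0), dtype=bool)
    d2 = ((points[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return d2 < (radii * radii)[None, :]


def _one_sided_area(host, partner, context, spec: GridSpec) -> float:
    r_h = expanded_radius(host, spec)
    pts = surface_points(host.position, r_h, spec.n_surface_points)
    coords, radii, p_idx = _context_arrays(host, context, partner)
    inside = _inside(pts, coords, radii + spec.solvent_radius)
    ci = inside.sum(axis=1)
    mask = inside[:, p_idx]
    if not mask.any():
        return 0.0
    return spec.delta_s(r_h) * float((1.0 / ci[mask]).sum())


def _one_sided_volume(host, partner, context, spec: GridSpec) -> tuple[float, float]:
    r_h = expanded_radius(host, spec)
    pts = lattice_points(host.position, r_h, spec.lattice_spacing)
    coords, radii, p_idx = _context_arrays(host, context, partner)
    inside = _inside(pts, coords, radii + spec.solvent_radius)
    ci = inside.sum(axis=1)
    mask = inside[:, p_idx]
    if not mask.any():
        return 0.0, 0.0
    dv = spec.delta_v
    v = dv * float((1.0 / ci[mask]).sum())
    v0 = dv * float((1.0 + ci[mask]).sum())
    return v, v0


def contact_area(a, b, context=(), spec: GridSpec | None = None) -> float:
    """Mean of the two one-sided grid contact areas between *a* and *b*."""
    spec = spec or GridSpec()
    _pair_distance(a, b)
    return 0.5 * (_one_sided_area(a, b, context, spec)
                  + _one_sided_area(b, a, context, spec))


def contact_volume(a, b, context=(), spec: GridSpec | None = None) -> float:
    """Mean of the two one-sided grid contact volumes (shared via 1/ci)."""
    spec = spec or GridSpec()
    _pair_distance(a, b)
    va, _ = _one_sided_volume(a, b, context, spec)
    vb, _ = _one_sided_volume(b, a, context, spec)
    return 0.5 * (va + vb)


def aowv(a, b, context=(), spec: GridSpec | None = None) -> float:
    """Atomic-overlap-weighted volume: lattice elements weighted by 1 + ci."""
    spec = spec or GridSpec()
    _pair_distance(a, b)
    _, wa = _one_sided_volume(a, b, context, spec)
    _, wb = _one_sided_volume(b, a, context, spec)
    return 0.5 * (wa + wb)


def sasa(a, context=(), spec: GridSpec | None = None) -> float:
    """Solvent-accessible surface area of *a* within *context*."""
    spec = spec or GridSpec()
    r_a = expanded_radius(a, spec)
    pts = surface_points(a.position, r_a, spec.n_surface_points)
    coords, radii, _ = _context_arrays(a, context)
    inside = _inside(pts, coords, radii + spec.solvent_radius)
    exposed = int((inside.sum(axis=1) == 0).sum())
    return spec.delta_s(r_a) * exposed


def model_sasa(atoms, spec: GridSpec | None = None) -> dict[int, float]:
    """SASA per atom serial for one model (expanded-sphere occupancy)."""
    spec = spec or GridSpec()
    atoms = list(atoms)
    out: dict[int, float] = {}
    if not atoms:
        return out
    exp_r = np.array([expanded_radius(a, spec) for a in atoms])
    cell = CellIndex(atoms, cell_size=2.0 * exp_r.max())
    for i, a in enumerate(atoms):
        neighbors = cell.neighbors_within(a, exp_r[i] + exp_r.max())
        out[a.serial] = sasa(a, neighbors, spec)
    return out


def model_contacts(
    atoms,
    spec: GridSpec | None = None,
    include_volume: bool = True,
    include_aowv: bool = False,
    include_sasa: bool = False,
    max_gap: float | None = None,
):
    """All inter-residue pair contacts in one model, plus optional SASA.

    Candidate pairs are found with a cell list; a pair is scored when the
    gap between vdW spheres is below *max_gap* (default: twice the solvent
    radius, i.e. exactly when the expanded spheres overlap).  Atom pairs
    within the same residue are never emitted, but every atom -- bonded or
    not -- participates in the occupancy counts ``ci``.

    Returns ``(records, sasa_by_serial)`` where the second item is ``{}``
    unless *include_sasa*.
    """
    spec = spec or GridSpec()
    atoms = list(atoms)
    if max_gap is None:
        max_gap = 2.0 * spec.solvent_radius
    records: dict[tuple[int, int], dict] = {}
    sasa_out: dict[int, float] = {}
    if not atoms:
        return [], sasa_out

    exp_r = np.array([expanded_radius(a, spec) for a in atoms])
    cell = CellIndex(atoms, cell_size=max(2.0 * exp_r.max(),
                                          max_gap + 2.0 * exp_r.max()))
    index_of = {id(a): i for i, a in enumerate(atoms)}
    reach = float(exp_r.max() + max(2.0 * spec.solvent_radius, max_gap))

    for i, a in enumerate(atoms):
        neighbors = cell.neighbors_within(a, a.vdw_radius + reach)
        if not neighbors and not include_sasa:
            continue
        coords = np.array([nb.position for nb in neighbors], float).reshape(-1, 3)
        radii = np.array([nb.vdw_radius for nb in neighbors], float)
        dists = (np.linalg.norm(coords - np.asarray(a.position, float), axis=1)
                 if neighbors else np.zeros(0))
        for d, nb in zip(dists, neighbors):
            if d < COINCIDENT_TOLERANCE:
                raise DegenerateGeometryError(
                    f"coincident atom centers: {a.label()} and {nb.label()}")

        r_a = exp_r[i]
        spts = surface_points(a.position, r_a, spec.n_surface_points)
        s_inside = _inside(spts, coords, radii + spec.solvent_radius)
        s_ci = s_inside.sum(axis=1)
        if include_sasa:
            sasa_out[a.serial] = spec.delta_s(r_a) * int((s_ci == 0).sum())

        if include_volume or include_aowv:
            vpts = lattice_points(a.position, r_a, spec.lattice_spacing)
            v_inside = _inside(vpts, coords, radii + spec.solvent_radius)
            v_ci = v_inside.sum(axis=1)
        else:
            v_inside = v_ci = None

        for j_local, nb in enumerate(neighbors):
            j = index_of[id(nb)]
            if nb.residue_id == a.residue_id:
                continue
            gap = dists[j_local] - a.vdw_radius - nb.vdw_radius
            if gap >= max_gap:
                continue
            key = (min(i, j), max(i, j))
            rec = records.setdefault(
                key, {"S": 0.0, "V": 0.0, "V0": 0.0, "d": float(dists[j_local])})
            mask = s_inside[:, j_local]
            if mask.any():
                rec["S"] += 0.5 * spec.delta_s(r_a) * float((1.0 / s_ci[mask]).sum())
            if v_inside is not None:
                vmask = v_inside[:, j_local]
                if vmask.any():
                    rec["V"] += 0.5 * spec.delta_v * float((1.0 / v_ci[vmask]).sum())
                    rec["V0"] += 0.5 * spec.delta_v * float((1.0 + v_ci[vmask]).sum())

    out = []
    for (i, j), rec in sorted(records.items()):
        if rec["S"] <= 0.0 and rec["V"] <= 0.0:
            continue
        out.append(ContactRecord(
            atom_a=atoms[i], atom_b=atoms[j],
            center_distance=rec["d"],
            S=rec["S"],
            V=rec["V"] if include_volume else None,
            V0=rec["V0"] if include_aowv else None,
        ))
    return out, sasa_out
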