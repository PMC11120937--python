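"""Synthetic PDB inputs and closed-form geometric reference values.

Everything the test suite and examples need can be generated here: toy
structures with exact decimal coordinates (isolated atom pairs, short
peptides, multi-model ensembles, crystallographic-style waters) plus the
analytic sphere-intersection formulas that the grid engine is checked
against.  No real PDB accessions are required anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ToyAtom",
    "make_pdb_text",
    "make_two_atom_pdb",
    "make_ensemble_pdb",
    "make_tripeptide_pdb",
    "cap_area_oracle",
    "lens_volume_oracle",
    "sphere_area",
    "sphere_volume",
]

# residue names used for single-atom "residues" in toy structures
_RESIDUE_FOR_ELEMENT = {"C": "ALA", "N": "ALA", "O": "ALA", "S": "CYS", "P": "UNL"}
_ATOM_FOR_ELEMENT = {"C": "CB", "N": "N", "O": "O", "S": "SG", "P": "P"}


@dataclass
class ToyAtom:
    """One atom descriptor for synthetic PDB text."""

    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str = "A"
    position: tuple = (0.0, 0.0, 0.0)
    hetatm: bool = False


def _record(serial: int, atom: ToyAtom, position=None) -> str:
    x, y, z = position if position is not None else atom.position
    rec = "HETATM" if atom.hetatm else "ATOM  "
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (f"{rec}{serial:5d} {name} {atom.residue_name:>3s} "
            f"{atom.chain_id:1s}{atom.residue_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {atom.element:>2s}")


def make_pdb_text(atoms: list[ToyAtom], n_models: int = 1,
                  displacements=None) -> str:
    """Standard-conformant PDB text from atom descriptors.

    With ``n_models > 1``, model *m* shifts every atom by
    ``displacements[m-1]`` (a 3-vector; defaults to zero shifts).
    """
    lines = []
    if n_models == 1 and displacements is None:
        lines += [_record(i + 1, a) for i, a in enumerate(atoms)]
    else:
        if displacements is None:
            displacements = [(0.0, 0.0, 0.0)] * n_models
        if len(displacements) != n_models:
            raise ValueError("need one displacement per model")
        for m in range(1, n_models + 1):
            lines.append(f"MODEL     {m:4d}")
            shift = np.asarray(displacements[m - 1], float)
            for i, a in enumerate(atoms):
                lines.append(_record(i + 1, a, np.asarray(a.position, float) + shift))
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_two_atom_pdb(elements: tuple[str, str], distance: float,
                      waters=()) -> str:
    """Two single-atom residues on one chain, *distance* apart along x.

    *waters* is an optional list of (x, y, z) positions for HOH oxygens.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    el_a, el_b = (e.upper() for e in elements)
    atoms = [
        ToyAtom(_ATOM_FOR_ELEMENT[el_a], el_a, _RESIDUE_FOR_ELEMENT[el_a], 1,
                position=(0.0, 0.0, 0.0)),
        ToyAtom(_ATOM_FOR_ELEMENT[el_b], el_b, _RESIDUE_FOR_ELEMENT[el_b], 2,
                position=(float(distance), 0.0, 0.0)),
    ]
    for i, w in enumerate(waters):
        atoms.append(ToyAtom("O", "O", "HOH", 100 + i,
                             position=tuple(float(c) for c in w), hetatm=True))
    return make_pdb_text(atoms)


def make_ensemble_pdb(atoms: list[ToyAtom], displacements) -> str:
    """MODEL/ENDMDL ensemble: one displaced copy of *atoms* per model."""
    return make_pdb_text(atoms, n_models=len(displacements),
                         displacements=displacements)


# idealized backbone for a three-residue peptide (ALA-GLY-ALA); planar
# trans peptide bonds with canonical 1.33 A C-N lengths, coordinates exact
# to 3 decimals so expected distances are reproducible
_TRIPEPTIDE = [
    ("N",  "N", "ALA", 1, (0.000, 0.000, 0.000)),
    ("CA", "C", "ALA", 1, (1.458, 0.000, 0.000)),
    ("C",  "C", "ALA", 1, (2.009, 1.420, 0.000)),
    ("O",  "O", "ALA", 1, (1.251, 2.390, 0.000)),
    ("CB", "C", "ALA", 1, (1.988, -0.773, -1.199)),
    ("N",  "N", "GLY", 2, (3.332, 1.536, 0.000)),
    ("CA", "C", "GLY", 2, (3.988, 2.836, 0.000)),
    ("C",  "C", "GLY", 2, (5.504, 2.703, 0.000)),
    ("O",  "O", "GLY", 2, (6.099, 1.626, 0.000)),
    ("N",  "N", "ALA", 3, (6.155, 3.860, 0.000)),
    ("CA", "C", "ALA", 3, (7.610, 3.904, 0.000)),
    ("C",  "C", "ALA", 3, (8.156, 5.323, 0.000)),
    ("O",  "O", "ALA", 3, (7.399, 6.293, 0.000)),
    ("CB", "C", "ALA", 3, (8.140, 3.131, 1.199)),
]


def make_tripeptide_pdb(chain_id: str = "A", waters=()) -> str:
    """A planar ALA-GLY-ALA tripeptide with canonical peptide-bond lengths."""
    atoms = [ToyAtom(n, el, res, seq, chain_id, pos)
             for n, el, res, seq, pos in _TRIPEPTIDE]
    for i, w in enumerate(waters):
        atoms.append(ToyAtom("O", "O", "HOH", 100 + i, chain_id,
                             tuple(float(c) for c in w), hetatm=True))
    return make_pdb_text(atoms)


# ---------------------------------------------------------------------------
# analytic reference formulas


def sphere_area(r: float) -> float:
    return 4.0 * math.pi * r * r


def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r ** 3


def cap_area_oracle(r_host: float, r_other: float, d: float) -> float:
    """Area of the host sphere's surface lying inside the other sphere.

    Spherical-cap formula ``2 pi R h`` with cap height
    ``h = R - (d^2 + R^2 - r^2) / (2 d)``.  Returns 0 for disjoint spheres
    and the full host area when the host is nested inside the other.
    """
    if d <= 0:
        raise ValueError("center distance must be positive")
    if d >= r_host + r_other:
        return 0.0
    if d + r_host <= r_other:          # host fully inside other
        return sphere_area(r_host)
    if d + r_other <= r_host:          # other fully inside host: no host surface
        return 0.0
    h = r_host - (d * d + r_host * r_host - r_other * r_other) / (2.0 * d)
    return 2.0 * math.pi * r_host * h


def lens_volume_oracle(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres a distance *d* apart.

    Standard sphere-sphere lens closed form; nested configurations return
    the volume of the smaller sphere, disjoint ones return 0.
    """
    if d <= 0:
        raise ValueError("center distance must be positive")
    if d >= r1 + r2:
        return 0.0
    if d + min(r1, r2) <= max(r1, r2):
        return sphere_volume(min(r1, r2))
    return (math.pi * (r1 + r2 - d) ** 2
            * (d * d + 2.0 * d * r2 - 3.0 * r2 * r2
               + 2.0 * d * r1 + 6.0 * r1 * r2 - 3.0 * r1 * r1)
            / (12.0 * d))
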