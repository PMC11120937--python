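"""Contact classification: covalent bonds, non-covalent types, sequence
separation classes and backbone dihedral angles.

Non-covalent atom-pair types follow the classical donor/acceptor/aromatic/
hydrophobic taxonomy used by residue-contact tools:

* ``HB``    -- donor/acceptor pair at 1.5-3.5 A;
* ``AROM``  -- both atoms on an aromatic ring (for histidine only the
  imidazole carbons CG, CD2, CE1 count as aromatic);
* ``PHOB``  -- both atoms hydrophobic (carbon);
* ``DC``    -- destabilizing contact, hydrophobic vs hydrophilic;
* ``OTHER`` -- none of the above.

Labels may co-occur (aromatic carbons are also hydrophobic); a fixed
priority Cova > HB > AROM > PHOB > DC > OTHER collapses the set to one
label for single-column output.

Sequence separation partitions same-chain residue pairs by |i - j|:
S 1-2, M 3-4, L1 5-10, L2 11-20, L3 21-30, L4 31-40, L5 41-50, L6 >50;
pairs on different chains are class I.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .pdb_io import STANDARD_AMINO_ACIDS, AtomSphere

__all__ = [
    "AtomClassTable",
    "default_class_table",
    "detect_disulfide",
    "detect_peptide_bond",
    "contact_type",
    "primary_label",
    "separation_class",
    "torsion_angle",
    "backbone_dihedrals",
    "SEPARATION_CLASSES",
    "LABEL_PRIORITY",
]

DISULFIDE_RANGE = (1.95, 2.1)     # S-S center distance window, CYS SG only
PEPTIDE_BOND_MAX = 1.6            # C(i)-N(i+1) center distance, A
HB_RANGE = (1.5, 3.5)             # donor-acceptor center distance window, A
LABEL_PRIORITY = ("Cova", "HB", "AROM", "PHOB", "DC", "OTHER")
SEPARATION_CLASSES = ("S", "M", "L1", "L2", "L3", "L4", "L5", "L6", "I")


class AtomClassTable:
    """(residue, atom-name) -> donor/acceptor/aromatic flags."""

    def __init__(self, flags: dict[tuple[str, str], tuple[bool, bool, bool]]):
        self._flags = flags

    @classmethod
    def from_csv(cls, path) -> "AtomClassTable":
        flags = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                flags[(row["residue"], row["atom"])] = (
                    row["donor"] == "1", row["acceptor"] == "1", row["aromatic"] == "1")
        return cls(flags)

    def _get(self, atom: AtomSphere) -> tuple[bool, bool, bool]:
        return self._flags.get((atom.residue_name, atom.name), (False, False, False))

    def is_donor(self, atom: AtomSphere) -> bool:
        return self._get(atom)[0]

    def is_acceptor(self, atom: AtomSphere) -> bool:
        return self._get(atom)[1]

    def is_aromatic(self, atom: AtomSphere) -> bool:
        return self._get(atom)[2]

    def atom_type_label(self, atom: AtomSphere) -> str:
        """Human-readable atom chemistry label for output columns."""
        donor, acceptor, aromatic = self._get(atom)
        if donor and acceptor:
            return "donor/acceptor"
        if donor:
            return "donor"
        if acceptor:
            return "acceptor"
        if aromatic:
            return "aromatic"
        return "hydrophilic" if atom.hydrophilic else "hydrophobic"


_DEFAULT_CLASSES: AtomClassTable | None = None


def default_class_table() -> AtomClassTable:
    global _DEFAULT_CLASSES
    if _DEFAULT_CLASSES is None:
        with resources.as_file(resources.files("contactgrid.data") / "atom_classes.csv") as p:
            _DEFAULT_CLASSES = AtomClassTable.from_csv(p)
    return _DEFAULT_CLASSES


def _distance(a: AtomSphere, b: AtomSphere) -> float:
    return float(np.linalg.norm(np.asarray(a.position, float)
                                - np.asarray(b.position, float)))


def detect_disulfide(a: AtomSphere, b: AtomSphere) -> bool:
    """CYS SG - CYS SG pair with center distance in [1.95, 2.1] A."""
    if not (a.residue_name == "CYS" and a.name == "SG"
            and b.residue_name == "CYS" and b.name == "SG"):
        return False
    lo, hi = DISULFIDE_RANGE
    return lo <= _distance(a, b) <= hi


def detect_peptide_bond(c: AtomSphere, n: AtomSphere) -> bool:
    """Backbone C(i) to backbone N(i+1) on one chain, within bonding range."""
    if c.name != "C" or n.name != "N":
        return False
    if c.chain_id != n.chain_id:
        return False
    if n.residue_seq - c.residue_seq != 1:
        return False
    return _distance(c, n) <= PEPTIDE_BOND_MAX


def is_covalent(a: AtomSphere, b: AtomSphere) -> bool:
    return (detect_disulfide(a, b)
            or detect_peptide_bond(a, b) or detect_peptide_bond(b, a))


def contact_type(a: AtomSphere, b: AtomSphere, distance: float | None = None,
                 table: AtomClassTable | None = None) -> frozenset:
    """Set of non-covalent contact-type labels for an atom pair."""
    table = table or default_class_table()
    if distance is None:
        distance = _distance(a, b)
    labels = set()
    donors = (table.is_donor(a), table.is_donor(b))
    acceptors = (table.is_acceptor(a), table.is_acceptor(b))
    if ((donors[0] and acceptors[1]) or (donors[1] and acceptors[0])) \
            and HB_RANGE[0] <= distance <= HB_RANGE[1]:
        labels.add("HB")
    if table.is_aromatic(a) and table.is_aromatic(b):
        labels.add("AROM")
    if a.hydrophobic and b.hydrophobic:
        labels.add("PHOB")
    if (a.hydrophobic and b.hydrophilic) or (a.hydrophilic and b.hydrophobic):
        labels.add("DC")
    if not labels:
        labels.add("OTHER")
    return frozenset(labels)


def primary_label(labels, covalent: bool = False) -> str:
    """Collapse a label set to one label by fixed priority."""
    if covalent:
        return "Cova"
    for lab in LABEL_PRIORITY:
        if lab in labels:
            return lab
    return "OTHER"


def separation_class(res_a, res_b) -> str:
    """Class label for a residue pair.

    Arguments are (chain_id, residue_seq[, insertion_code]) tuples or
    AtomSphere objects.
    """
    def unpack(r):
        if isinstance(r, AtomSphere):
            return r.chain_id, r.residue_seq, r.insertion_code
        return r[0], r[1], (r[2] if len(r) > 2 else "")

    chain_a, seq_a, ic_a = unpack(res_a)
    chain_b, seq_b, ic_b = unpack(res_b)
    if (chain_a, seq_a, ic_a) == (chain_b, seq_b, ic_b):
        raise ValueError("separation class is undefined for a residue and itself")
    if chain_a != chain_b:
        return "I"
    delta = abs(seq_a - seq_b)
    if delta <= 2:
        return "S"
    if delta <= 4:
        return "M"
    if delta <= 10:
        return "L1"
    if delta <= 20:
        return "L2"
    if delta <= 30:
        return "L3"
    if delta <= 40:
        return "L4"
    if delta <= 50:
        return "L5"
    return "L6"


def torsion_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm_b1 = np.linalg.norm(b1)
    if norm_b1 < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return math.nan
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1) / norm_b1)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def backbone_dihedrals(atoms) -> dict[tuple[str, int, str], tuple[float, float]]:
    """Phi/psi per residue for one model; NaN where undefined.

    Phi(i) = torsion(C_{i-1}, N_i, CA_i, C_i); psi(i) = torsion(N_i, CA_i,
    C_i, N_{i+1}).  Angles are computed only for standard amino acids whose
    neighbor in the torsion is a directly bonded (peptide-linked) residue.
    """
    by_res: dict[tuple[str, int, str], dict[str, AtomSphere]] = {}
    order: list[tuple[str, int, str]] = []
    standard: dict[tuple[str, int, str], bool] = {}
    for a in atoms:
        rid = a.residue_id
        if rid not in by_res:
            by_res[rid] = {}
            order.append(rid)
            standard[rid] = a.is_standard_residue
        if a.name in ("N", "CA", "C"):
            by_res[rid].setdefault(a.name, a)

    out: dict[tuple[str, int, str], tuple[float, float]] = {}
    for rid in order:
        if not standard[rid]:
            out[rid] = (math.nan, math.nan)
            continue
        bb = by_res[rid]
        phi = psi = math.nan
        prev_rid = (rid[0], rid[1] - 1, "")
        next_rid = (rid[0], rid[1] + 1, "")
        prev_bb = by_res.get(prev_rid)
        next_bb = by_res.get(next_rid)
        if {"N", "CA", "C"} <= bb.keys():
            if prev_bb and "C" in prev_bb and standard.get(prev_rid, False) \
                    and detect_peptide_bond(prev_bb["C"], bb["N"]):
                phi = torsion_angle(prev_bb["C"].position, bb["N"].position,
                                    bb["CA"].position, bb["C"].position)
            if next_bb and "N" in next_bb and standard.get(next_rid, False) \
                    and detect_peptide_bond(bb["C"], next_bb["N"]):
                psi = torsion_angle(bb["N"].position, bb["CA"].position,
                                    bb["C"].position, next_bb["N"].position)
        out[rid] = (phi, psi)
    return out
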