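"""PDB input: parsing, van der Waals radius assignment and atom classification.

Structures are read with :mod:`gemmi` and converted into flat lists of
:class:`AtomSphere` records, one list per model.  Each atom carries its
hard-sphere (van der Waals) radius, its chemical class flags and a water
flag, so downstream geometry code never needs to look back at the file.

Conventions adopted here:

* hydrogens (and deuteriums) are dropped from the solute -- the analysis is
  heavy-atom only;
* for alternate locations, the first altLoc seen for a given atom name
  within a residue is kept;
* waters (HOH/WAT) are parsed but kept separate from the solute;
* radii come from the bundled Bondi heavy-atom table
  (``data/vdw_radii.csv``), with per-element fallbacks for atoms that have
  no (residue, atom-name) entry; such atoms are flagged ``radius_guessed``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomSphere",
    "Structure",
    "RadiiTable",
    "PDBError",
    "ParseError",
    "EmptyStructureError",
    "UnknownElementError",
    "STANDARD_AMINO_ACIDS",
    "HYDROPHILIC_ELEMENTS",
    "parse_structure",
    "assign_radii",
    "discover_inputs",
    "default_radii_table",
    "model_to_pdb_text",
    "residue_id",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
WATER_NAMES = frozenset({"HOH", "WAT"})
HYDROPHILIC_ELEMENTS = frozenset({"N", "O", "P", "S"})


class PDBError(Exception):
    """Base class for PDB reading problems."""


class ParseError(PDBError):
    """A record could not be interpreted; the message names the line."""


class EmptyStructureError(PDBError):
    """The file contains no ATOM/HETATM records (or no solute atoms)."""


class UnknownElementError(PDBError):
    """An atom's element could not be resolved from the record."""


@dataclass
class AtomSphere:
    """One heavy atom treated as a hard sphere."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    model_index: int
    position: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float = 0.0
    radius_guessed: bool = False
    is_water: bool = False
    is_standard_residue: bool = False

    @property
    def hydrophilic(self) -> bool:
        return self.element in HYDROPHILIC_ELEMENTS

    @property
    def hydrophobic(self) -> bool:
        return self.element == "C"

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, seq, insertion code) -- identity of the parent residue."""
        return (self.chain_id, self.residue_seq, self.insertion_code)

    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}:{self.residue_name}{self.residue_seq}{icode}:{self.name}"


def residue_id(atom: AtomSphere) -> tuple[str, int, str]:
    return atom.residue_id


@dataclass
class Structure:
    """All models of one coordinate file, solute and waters separated."""

    models: list[list[AtomSphere]]          # solute (heavy, non-water) atoms
    waters: list[list[AtomSphere]]          # water oxygens, per model
    source_path: str = ""
    title: str = ""

    @property
    def n_models(self) -> int:
        return len(self.models)


class RadiiTable:
    """Per-(residue, atom-name) vdW radii with per-element fallbacks."""

    def __init__(self, entries: dict[tuple[str, str], float], fallbacks: dict[str, float]):
        self.entries = entries
        self.fallbacks = fallbacks

    @classmethod
    def from_csv(cls, path) -> "RadiiTable":
        entries: dict[tuple[str, str], float] = {}
        fallbacks: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                r = float(row["radius"])
                if row["residue"] == "*":
                    fallbacks[row["atom"].upper()] = r
                else:
                    entries[(row["residue"], row["atom"])] = r
        return cls(entries, fallbacks)

    def lookup(self, residue_name: str, atom_name: str, element: str) -> tuple[float, bool]:
        """Return (radius, guessed)."""
        key = (residue_name, atom_name)
        if key in self.entries:
            return self.entries[key], False
        el = element.upper()
        if el in self.fallbacks:
            return self.fallbacks[el], True
        raise UnknownElementError(
            f"no radius for atom {atom_name!r} (element {element!r}) in residue {residue_name!r}"
        )


_DEFAULT_TABLE: RadiiTable | None = None


def default_radii_table() -> RadiiTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(resources.files("contactgrid.data") / "vdw_radii.csv") as p:
            _DEFAULT_TABLE = RadiiTable.from_csv(p)
    return _DEFAULT_TABLE


def _validate_records(path) -> None:
    # gemmi silently truncates malformed numeric fields, so coordinate
    # columns are checked up front and errors name the offending line.
    with open(path) as fh:
        n_atoms = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n_atoms += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: malformed coordinate field {fieldtxt!r}"
                        ) from None
    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: no ATOM or HETATM records")


def parse_structure(path, radii: RadiiTable | None = None) -> Structure:
    """Parse a (possibly multi-model) PDB file into a :class:`Structure`.

    Hydrogens are excluded, waters are separated from the solute, the first
    alternate location per atom is kept, and every atom receives a vdW
    radius from *radii* (default: the bundled table).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_records(path)
    st = gemmi.read_structure(path)
    if radii is None:
        radii = default_radii_table()

    models: list[list[AtomSphere]] = []
    waters: list[list[AtomSphere]] = []
    for model_pos, model in enumerate(st, start=1):
        solute: list[AtomSphere] = []
        wats: list[AtomSphere] = []
        for chain in model:
            for res in chain:
                is_water = res.name in WATER_NAMES
                seen_names: dict[str, str] = {}
                for atom in res:
                    el = atom.element.name.upper()
                    if el in ("H", "D"):
                        continue
                    if not el or el == "X":
                        raise UnknownElementError(
                            f"{path}: cannot resolve element for atom "
                            f"{atom.name!r} in {res.name} {res.seqid.num}"
                        )
                    # first altLoc wins, per atom name
                    alt = atom.altloc if atom.altloc != "\x00" else ""
                    if atom.name in seen_names and seen_names[atom.name] != alt:
                        continue
                    seen_names[atom.name] = alt
                    r, guessed = radii.lookup(res.name, atom.name, el)
                    sphere = AtomSphere(
                        serial=atom.serial,
                        name=atom.name,
                        element=el,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        insertion_code=res.seqid.icode.strip(),
                        chain_id=chain.name,
                        model_index=model_pos,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        vdw_radius=r,
                        radius_guessed=guessed,
                        is_water=is_water,
                        is_standard_residue=res.name in STANDARD_AMINO_ACIDS,
                    )
                    (wats if is_water else solute).append(sphere)
        if solute or wats:
            models.append(solute)
            waters.append(wats)
    if not models or all(len(m) == 0 for m in models):
        raise EmptyStructureError(f"{path}: no solute atoms after filtering")
    return Structure(models=models, waters=waters, source_path=path,
                     title=st.name or "")


def assign_radii(structure: Structure, table: RadiiTable) -> Structure:
    """Re-assign radii from *table*; returns a new Structure."""
    def redo(atoms):
        out = []
        for a in atoms:
            r, guessed = table.lookup(a.residue_name, a.name, a.element)
            out.append(replace(a, vdw_radius=r, radius_guessed=guessed))
        return out

    return Structure(
        models=[redo(m) for m in structure.models],
        waters=[redo(w) for w in structure.waters],
        source_path=structure.source_path,
        title=structure.title,
    )


def discover_inputs(path) -> list[Path]:
    """Resolve a file or directory argument into a sorted list of PDB files."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.is_file():
        return [p]
    files = sorted(p.glob("*.pdb"))
    if not files:
        raise EmptyStructureError(f"{p}: directory contains no .pdb files")
    return files


def format_atom_line(a: AtomSphere) -> str:
    """One fixed-column ATOM/HETATM record for *a*."""
    record = "HETATM" if (a.is_water or not a.is_standard_residue) else "ATOM  "
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.position
    return (
        f"{record}{a.serial:5d} {name}{'':1s}{a.residue_name:>3s} "
        f"{a.chain_id:1s}{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def model_to_pdb_text(atoms: list[AtomSphere]) -> str:
    """Serialize one model's atoms back to PDB text (round-trip safe)."""
    lines = [format_atom_line(a) for a in atoms]
    lines.append("END")
    return "\n".join(lines) + "\n"
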