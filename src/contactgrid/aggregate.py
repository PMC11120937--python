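"""Residue-level aggregation, cutoff filtering and CSV output.

Three CSV products are written per model, mirroring the atom / residue /
residue-pair levels of detail:

* ``*_ALL.csv``  -- one row per surviving atom pair, with distances,
  area/volume/AOWV, atom chemistry types, the collapsed contact label and
  the sequence-separation class;
* ``*_SUM.csv``  -- one row per residue: phi/psi dihedrals, covalent vs
  non-covalent area (and volume) totals, optional SASA and AOWV columns;
* ``*_RES.csv``  -- one row per residue pair with cumulative totals
  ``Sr = sum(Sa)`` and ``Vr = sum(Va)`` over its atom contacts.

Column presence depends on the analysis switches: ``-s`` drops all volume
columns, ``-w`` adds AOWV columns, ``-a`` adds SASA.  Numeric fields are
serialized with 4 decimals; undefined dihedrals are left empty.
Sums run over a canonically ordered contact list, so results are
bit-identical regardless of input order or thread count.
"""

from __future__ import annotations

import gzip
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify
from .contact_core import ContactRecord, GridSpec, model_contacts, model_sasa
from .pdb_io import AtomSphere, Structure, parse_structure
from .solvation import WATER_DIAMETER, water_mediated_contacts

__all__ = [
    "AnalysisOptions",
    "ResiduePairSummary",
    "classify_records",
    "sort_records",
    "apply_cutoff",
    "residue_pair_totals",
    "residue_summaries",
    "analyze_model",
    "write_all_csv",
    "write_sum_csv",
    "write_res_csv",
    "write_residue_csvs",
    "process_structure",
    "residue_label",
]

# center distance below which a link to a non-standard residue is treated
# as a potential covalent bond of unknown type
AMBIGUOUS_LINK_MAX = 2.0


@dataclass
class AnalysisOptions:
    """Switches controlling one analysis run (CLI flags map 1:1)."""

    precision: str = "default"           # -e selects "enhanced"
    water_mediated: bool = False         # -p
    custom_distance: float | None = None  # -d, A
    sasa: bool = False                   # -a
    aowv: bool = False                   # -w
    surface_only: bool = False           # -s
    min_area: float = 0.0                # -c
    min_volume: float = 0.0              # -c
    compress: bool = False               # -z
    per_residue: bool = False            # -r
    threads: int = 1                     # -t

    def grid_spec(self) -> GridSpec:
        return GridSpec.from_precision(self.precision)

    @property
    def include_volume(self) -> bool:
        return not self.surface_only


@dataclass
class ResiduePairSummary:
    """Aggregated contact totals for one unordered residue pair."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    name_a: str
    name_b: str
    Sr: float
    Vr: float | None
    AOWVr: float | None
    separation_class: str
    n_atom_pairs: int


def residue_label(name: str, rid: tuple[str, int, str]) -> str:
    """Display label; non-standard residue names get a trailing underscore."""
    shown = name if name in classify.STANDARD_AMINO_ACIDS else name + "_"
    chain, seq, icode = rid
    return f"{chain}:{shown}{seq}{icode}"


def _atom_sort_key(a: AtomSphere):
    return (a.chain_id, a.residue_seq, a.insertion_code, a.serial)


def _orient(rec: ContactRecord) -> ContactRecord:
    if _atom_sort_key(rec.atom_b) < _atom_sort_key(rec.atom_a):
        rec.atom_a, rec.atom_b = rec.atom_b, rec.atom_a
    return rec


def sort_records(records) -> list[ContactRecord]:
    """Canonical (chain, seq, serial) ordering; makes all sums reproducible."""
    return sorted((_orient(r) for r in records),
                  key=lambda r: (_atom_sort_key(r.atom_a), _atom_sort_key(r.atom_b)))


def classify_records(records, table=None) -> list[ContactRecord]:
    """Fill covalent/type/separation labels in place; returns sorted records."""
    table = table or classify.default_class_table()
    for rec in records:
        a, b = rec.atom_a, rec.atom_b
        rec.covalent = classify.is_covalent(a, b)
        rec.separation_class = classify.separation_class(a, b)
        if rec.covalent:
            rec.attribution = "Cova"
            rec.contact_types = frozenset()
        else:
            rec.contact_types = classify.contact_type(a, b, rec.center_distance, table)
            ambiguous = (not a.is_standard_residue or not b.is_standard_residue) \
                and rec.center_distance < AMBIGUOUS_LINK_MAX
            rec.attribution = "UNDEF" if ambiguous else "NC"
    return sort_records(records)


def apply_cutoff(records, min_area: float = 0.0, min_volume: float = 0.0):
    """Keep records with S >= min_area and (when present) V >= min_volume."""
    if min_area < 0 or min_volume < 0:
        raise ValueError("cutoff thresholds must be non-negative")
    out = []
    for r in records:
        if r.S < min_area:
            continue
        if r.V is not None and r.V < min_volume:
            continue
        out.append(r)
    return out


def residue_pair_totals(records) -> list[ResiduePairSummary]:
    """Cumulative Sr/Vr/AOWVr per unordered residue pair."""
    groups: dict[tuple, dict] = {}
    for rec in sort_records(records):
        a, b = rec.atom_a, rec.atom_b
        key = (a.residue_id, b.residue_id)
        g = groups.setdefault(key, {
            "names": (a.residue_name, b.residue_name),
            "S": 0.0, "V": 0.0, "V0": 0.0, "n": 0,
            "has_v": rec.V is not None, "has_w": rec.V0 is not None,
            "class": rec.separation_class,
        })
        g["S"] += rec.S
        g["V"] += rec.V or 0.0
        g["V0"] += rec.V0 or 0.0
        g["n"] += 1
    out = []
    for (rid_a, rid_b), g in sorted(groups.items()):
        out.append(ResiduePairSummary(
            residue_a=rid_a, residue_b=rid_b,
            name_a=g["names"][0], name_b=g["names"][1],
            Sr=g["S"],
            Vr=g["V"] if g["has_v"] else None,
            AOWVr=g["V0"] if g["has_w"] else None,
            separation_class=g["class"],
            n_atom_pairs=g["n"],
        ))
    return out


def residue_summaries(atoms, records, sasa_by_serial=None,
                      options: AnalysisOptions | None = None) -> pd.DataFrame:
    """Per-residue table: dihedrals plus covalent/NC/UNDEF contact totals."""
    options = options or AnalysisOptions()
    dihedrals = classify.backbone_dihedrals(atoms)

    order: list[tuple] = []
    names: dict[tuple, str] = {}
    for a in atoms:
        if a.residue_id not in names:
            names[a.residue_id] = a.residue_name
            order.append(a.residue_id)

    zero = {"Cova_Area": 0.0, "NC_Area": 0.0, "UNDEF_Area": 0.0,
            "Cova_Volu": 0.0, "NC_Volu": 0.0, "UNDEF_Volu": 0.0,
            "Cova_AOWV": 0.0, "NC_AOWV": 0.0, "UNDEF_AOWV": 0.0,
            "SASA": 0.0}
    acc = {rid: dict(zero) for rid in order}
    for rec in sort_records(records):
        kind = rec.attribution
        for atom in (rec.atom_a, rec.atom_b):
            row = acc[atom.residue_id]
            row[f"{kind}_Area"] += rec.S
            if rec.V is not None:
                row[f"{kind}_Volu"] += rec.V
            if rec.V0 is not None:
                row[f"{kind}_AOWV"] += rec.V0
    if sasa_by_serial:
        for a in atoms:
            acc[a.residue_id]["SASA"] += sasa_by_serial.get(a.serial, 0.0)

    rows = []
    for rid in order:
        phi, psi = dihedrals.get(rid, (math.nan, math.nan))
        row = {"Residue": residue_label(names[rid], rid), "Phi": phi, "Psi": psi}
        row.update(acc[rid])
        rows.append(row)

    cols = ["Residue", "Phi", "Psi", "Cova_Area", "NC_Area"]
    if options.include_volume:
        cols += ["Cova_Volu", "NC_Volu"]
    if options.sasa:
        cols.append("SASA")
    if options.aowv:
        cols += ["Cova_AOWV", "NC_AOWV"]
    cols.append("UNDEF_Area")
    if options.include_volume:
        cols.append("UNDEF_Volu")
    return pd.DataFrame(rows, columns=cols)


def analyze_model(atoms, options: AnalysisOptions | None = None):
    """Run the full per-model pipeline.

    Returns ``(records, pair_summaries, residue_table)`` with records
    classified, filtered and canonically ordered.
    """
    options = options or AnalysisOptions()
    spec = options.grid_spec()
    if options.water_mediated:
        records = water_mediated_contacts(
            atoms, spec,
            max_gap=options.custom_distance or WATER_DIAMETER,
            include_aowv=options.aowv)
        if not options.include_volume:
            for r in records:
                r.V = None
        sasa_by_serial = model_sasa(atoms, spec) if options.sasa else {}
    else:
        records, sasa_by_serial = model_contacts(
            atoms, spec,
            include_volume=options.include_volume or options.aowv,
            include_aowv=options.aowv,
            include_sasa=options.sasa,
            max_gap=options.custom_distance)
        if not options.include_volume:
            for r in records:
                r.V = None
    records = classify_records(records)
    records = apply_cutoff(records, options.min_area, options.min_volume)
    pairs = residue_pair_totals(records)
    table = residue_summaries(atoms, records, sasa_by_serial, options)
    return records, pairs, table


# ---------------------------------------------------------------------------
# CSV serialization


def _write_csv(df: pd.DataFrame, path, compress: bool) -> Path:
    path = Path(path)
    if compress:
        path = path.with_suffix(path.suffix + ".gz")
    df.to_csv(path, index=False, float_format="%.4f",
              compression="gzip" if compress else None)
    return path


def _all_columns(options: AnalysisOptions) -> list[str]:
    cols = ["Residue1", "Atom1", "Type1", "Residue2", "Atom2", "Type2",
            "Distance", "Area"]
    if options.include_volume:
        cols.append("Volume")
    if options.aowv:
        cols.append("AOWV")
    return cols + ["Contact", "Class"]


def records_frame(records, options: AnalysisOptions | None = None,
                  table=None) -> pd.DataFrame:
    options = options or AnalysisOptions()
    table = table or classify.default_class_table()
    rows = []
    for r in records:
        a, b = r.atom_a, r.atom_b
        row = {
            "Residue1": residue_label(a.residue_name, a.residue_id),
            "Atom1": a.name,
            "Type1": table.atom_type_label(a),
            "Residue2": residue_label(b.residue_name, b.residue_id),
            "Atom2": b.name,
            "Type2": table.atom_type_label(b),
            "Distance": r.center_distance,
            "Area": r.S,
            "Contact": classify.primary_label(r.contact_types, r.covalent),
            "Class": r.separation_class,
        }
        if options.include_volume:
            row["Volume"] = r.V
        if options.aowv:
            row["AOWV"] = r.V0
        rows.append(row)
    return pd.DataFrame(rows, columns=_all_columns(options))


def write_all_csv(records, path, options: AnalysisOptions | None = None) -> Path:
    options = options or AnalysisOptions()
    return _write_csv(records_frame(records, options), path, options.compress)


def write_sum_csv(residue_table: pd.DataFrame, path,
                  options: AnalysisOptions | None = None) -> Path:
    options = options or AnalysisOptions()
    return _write_csv(residue_table, path, options.compress)


def pairs_frame(pairs, options: AnalysisOptions | None = None) -> pd.DataFrame:
    options = options or AnalysisOptions()
    cols = ["Residue1", "Residue2", "Class", "Area"]
    if options.include_volume:
        cols.append("Volume")
    if options.aowv:
        cols.append("AOWV")
    rows = []
    for p in pairs:
        row = {"Residue1": residue_label(p.name_a, p.residue_a),
               "Residue2": residue_label(p.name_b, p.residue_b),
               "Class": p.separation_class, "Area": p.Sr}
        if options.include_volume:
            row["Volume"] = p.Vr
        if options.aowv:
            row["AOWV"] = p.AOWVr
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def write_res_csv(pairs, path, options: AnalysisOptions | None = None) -> Path:
    options = options or AnalysisOptions()
    return _write_csv(pairs_frame(pairs, options), path, options.compress)


def write_residue_csvs(records, directory, options: AnalysisOptions | None = None):
    """One CSV per residue holding the atom-pair rows it participates in."""
    options = options or AnalysisOptions()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame = records_frame(records, options)
    by_res: dict[str, list[int]] = {}
    for idx, r in enumerate(records):
        for atom in (r.atom_a, r.atom_b):
            key = residue_label(atom.residue_name, atom.residue_id)
            by_res.setdefault(key, []).append(idx)
    written = []
    for key in sorted(by_res):
        safe = key.replace(":", "_")
        sub = frame.iloc[sorted(set(by_res[key]))]
        written.append(_write_csv(sub, directory / f"{safe}.csv", options.compress))
    return written


def _model_output_files(atoms, stem: str, out_dir: Path,
                        options: AnalysisOptions):
    records, pairs, table = analyze_model(atoms, options)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_all_csv(records, out_dir / f"{stem}_ALL.csv", options)
    write_sum_csv(table, out_dir / f"{stem}_SUM.csv", options)
    write_res_csv(pairs, out_dir / f"{stem}_RES.csv", options)
    if options.per_residue:
        write_residue_csvs(records, out_dir / "residues", options)


def process_structure(path, output_root,
                      options: AnalysisOptions | None = None) -> Path:
    """Analyze one PDB file; returns the per-structure output folder.

    Single-model files write directly into ``<output_root>/<stem>/``;
    multi-model files get one ``model_<k>`` subfolder per model.
    """
    options = options or AnalysisOptions()
    path = Path(path)
    structure = parse_structure(path)
    stem = path.stem
    folder = Path(output_root) / stem
    if structure.n_models == 1:
        _model_output_files(structure.models[0], stem, folder, options)
    else:
        for k, atoms in enumerate(structure.models, start=1):
            _model_output_files(atoms, stem, folder / f"model_{k}", options)
    return folder
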