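# Methods

## Model

Every heavy atom is a hard sphere. Two radii matter:

* the van der Waals radius `r_vdW`, taken from the bundled table
  (`src/contactgrid/data/vdw_radii.csv`): Bondi element radii (C 1.70,
  N 1.55, O 1.52, S 1.80, P 1.80 Å, …) expanded into per-(residue,
  atom-name) entries for the 20 standard amino acids. Atoms without a
  table entry fall back to their element radius and carry a
  `radius_guessed` flag; an atom whose element cannot be resolved is an
  error. Radius assignment is a pure function of
  (residue name, atom name, element).
* the expanded (solvated) radius `r_vdW + r_solvent`, with
  `r_solvent = 1.4 Å` by default — the oxygen-sized water probe. All
  default-mode geometry (contact area, contact volume, AOWV, SASA) is
  computed on expanded spheres.

Hydrogens are excluded throughout (X-ray and NMR depositions are
inconsistent about them); waters (HOH/WAT) are parsed but kept out of the
solute; the first altLoc per atom is kept; coordinates and residue
numbering are used exactly as printed.

### Grids

Deterministic, per atom:

* surface: a spherical Fibonacci (golden-angle) lattice of `n` points,
  each representing `Δs = 4πr²/n`. `n` = 5000 (default) or 15092
  (enhanced). The construction is exactly reproducible at any `n` and
  near-uniform (nearest-neighbor spacing ratio ≤ 2).
* volume: an axis-aligned cubic lattice anchored at the atom's own
  center, spacing `h` = 0.2 Å (default) or 0.1 Å (enhanced), each point
  representing `Δv = h³`. Anchoring at the atom center makes per-atom
  results translation invariant; the center is always a lattice point.

Candidate pairs come from a cell list with cell size ≥ the largest
expanded diameter, so a one-shell scan cannot miss an overlap.

### Contact measures and occupancy sharing

For a grid point of host atom `a`, the occupancy `ci` is the number of
atoms **other than `a`** whose (expanded) sphere contains the point
(strict inequality; tangent spheres share nothing). Then

* contact area `S(a,b)`: surface points of `a` inside `b` contribute
  `Δs_a / ci`; the reported pair value is the **mean of the two one-sided
  estimates**, which makes `S` exactly symmetric. The same averaging is
  used for `V` and `V0`: both one-sided lattices approximate the same
  lens, and the mean halves the discretization bias.
* contact volume `V(a,b)`: lattice points of `a` inside `b` contribute
  `Δv / ci`. Because each point with `ci = k` contributes `Δv/k` to each
  of the `k` host–partner pairs covering it, summing over pairs
  reconstructs every overlapped grid element exactly once — no double
  counting (this identity is asserted to 1e-12 in the tests).
* AOWV `V0(a,b)`: the same traversal contributes `Δv·(1+ci)`; an
  isolated pair satisfies `V0 = 2V` exactly, and `V0 ≥ 2V` always.
* SASA: `Δs_a` times the number of surface points covered by no other
  atom.

Atom pairs within one residue are never reported, but every solute atom
participates in the occupancy counts. A pair is scored when the gap
between vdW spheres is below twice the solvent radius (exactly when the
expanded spheres overlap); the `-d` switch replaces that gap threshold.
Coincident centers (< 0.01 Å apart) are rejected as corrupt input.

### Water-mediated mode (`-p`)

Uniform 1.4 Å expansion lets any two atoms "contact" through solvent even
when neither could actually bind a water. The `-p` mode instead requires
at least one hydrophilic atom (N, O, P, S) and a vdW gap < 2.8 Å (one
water diameter), and scores the pair through a virtual bridging water of
radius 1.4 Å placed on the inter-center segment. How deeply a water may
interpenetrate a protein atom is element specific — the mosaic maxima
N 0.1, O 0.2, P 0.3, S 0.5 Å. The achieved overlap for a single anchored
water is `min(m_element, 2.8 − gap)`: capped at the element maximum,
decaying continuously to zero at the eligibility limit, so the
water-mediated volume is monotone non-increasing in the gap. The reported
contact is the grid atom–water lens of the hydrophilic atom's **vdW**
sphere (no extra expansion); when both atoms are hydrophilic each gets
its own water and the two contacts are averaged. No direct atom–atom
overlap is added. For the joint two-anchor diagnostic placement the
on-segment point equalizing the two overlap deviations is used; both
targets are met exactly when `gap = 2.8 − m_a − m_b`, and for much
smaller gaps an on-segment water necessarily exceeds the maxima (the
contact computation is unaffected, since it uses per-atom waters).

Note a resolution effect: mosaic lenses are thin. The N–water lens
(overlap 0.1 Å) is a sliver thinner than the default 0.2 Å lattice and
can contain zero lattice points, i.e. volume 0 at default precision;
enhanced precision (0.1 Å) resolves it to within ~2% of the closed form.
Water-mediated volume work should use `-e`.

### Classification

Covalent: peptide bonds (backbone C(i)–N(i+1), same chain, ≤ 1.6 Å — the
1.6 Å tolerance separates bonded from chain-break cases) and disulfides
(CYS SG–SG within [1.95, 2.1] Å). Non-covalent labels from the bundled
donor/acceptor/aromatic table (`data/atom_classes.csv`): HB
(donor↔acceptor, 1.5–3.5 Å), AROM (both aromatic; histidine's aromatic
set is the imidazole carbons CG, CD2, CE1 only), PHOB (both carbons), DC
(carbon vs N/O/P/S), OTHER. Labels can co-occur (aromatic carbons are
hydrophobic); single-label columns collapse by priority
Cova > HB > AROM > PHOB > DC > OTHER. Sequence separation partitions
same-chain pairs by |Δresidue|: S 1–2, M 3–4, L1 5–10, L2 11–20, L3
21–30, L4 31–40, L5 41–50, L6 > 50; different chains are class I.
Backbone φ/ψ are computed for standard residues whose torsion neighbors
are genuinely peptide-bonded; terminal, incomplete, non-standard or
collinear cases give an undefined marker (empty CSV field).

Contacts touching a non-standard residue at center distance < 2.0 Å are
potential covalent links of unknown type and are reported under the
UNDEF columns rather than guessed either way.

### Aggregation and output

`Sr = Σ Sa`, `Vr = Σ Va`, `AOWVr = Σ V0` over the atom pairs of each
residue pair, summed over a canonically ordered record list so results
are bit-identical under input permutation and any thread count. Optional
cutoffs keep records with `S ≥ min_area` **and** `V ≥ min_volume`
(boundary inclusive; defaults 0). Suggested working cutoffs for noisy
ensembles are 0.5 Å² / 0.25 Å³. Numbers are serialized with 4 decimals;
CSV columns follow the flag contract (`-s` drops volume columns, `-w`
adds AOWV, `-a` adds SASA) documented in the README.

### Ensembles

Per-pair mean and range (max − min) over models, with a pair absent from
a model counted as 0 for that model — this choice (not the only possible
one) makes intermittent contacts show their full amplitude in the range
matrix. Flexible contacts default to mean ≥ 30 Å³ and range ≥ 100 Å³,
configurable. Over N copies of one model the range is identically zero
and the mean equals the single-model matrix.

### Hydration profiling

For each solute atom, the spherical distance to its nearest water oxygen
(`center distance − r_vdW,atom − r_vdW,waterO`; negative = mosaic
overlap), ties broken by lowest serial. A record is *interference* when
another solute atom is spherically closer to that water. Histograms use
left-closed 0.1 Å bins over [−2.0, 2.8] Å, grouped by residue type and
atom category — peptide-plane N/C/O by exact atom name versus the starred
side-chain categories C*/N*/O* (all remaining atoms of that element).
Ratios normalize within each group over in-range records.

## Numerical accuracy

A convergence study (12 seeds × 50 random two-sphere configurations,
radii 1.5–3.5 Å, overlap 0.2–2.0 Å) against the closed-form
spherical-cap and lens formulas fixed the guarantees asserted in
`tests/test_acceptance.py`:

* contact area: max relative error 2.0% at 5000 points, 0.9% at 15092;
  asserted at 3% / 1.5%.
* contact volume: the error is a boundary-layer effect, bounded by
  `0.03·V + 1.0·h` (worst observed excess 0.51·h default, 0.15·h
  enhanced). A pure relative bound is impossible for thin lenses — an
  0.2 Å-overlap lens spans ~10 lattice cells, so its relative error is
  intrinsically tens of percent at default spacing.
* refinement: enhanced precision reduces the suite-level maximum and
  mean error of both quantities. It does **not** reduce every
  individual configuration's error (a config can be luckily accurate at
  the coarse grid); the same holds for isolated-sphere volume estimates
  across spacings, which is why convergence is asserted on the mean over
  a radius grid.

## Synthetic data

All tests and examples run on structures generated by
`contactgrid.fixtures`: isolated atom pairs at exact decimal separations,
a planar ALA–GLY–ALA tripeptide with canonical bond lengths (1.33 Å
peptide bonds), multi-model ensembles with prescribed displacements, and
optional toy waters. These exercise the full parsing → geometry →
classification → aggregation → ensemble path, but they are not proteins:
they contain no realistic packing density, no side-chain rotamer
diversity, no crystallographic disorder, and only a handful of atoms, so
passing tests demonstrate correctness of the algorithms, not performance
or robustness claims on real PDB depositions. Real files exercise the
same code path (the parser handles multi-model files, alternate
locations, insertion codes, waters and unknown residues), and the radii
and donor/acceptor tables are deliberately pinned, versioned data files
so absolute values are reproducible — but they will differ by a
radius-dependent offset from tools built on other radius sets.

## Known limitations

* Heavy atoms only; no hydrogen placement, no angular hydrogen-bond
  criteria, no π-stacking geometry.
* Single conformer per atom (first altLoc); no symmetry expansion, no
  mmCIF.
* Default-precision volumes of very thin overlaps (including N-mediated
  water bridges) can quantize to zero; use enhanced precision there.
* The grid engine is pure NumPy; a 200-atom model takes seconds, large
  complexes minutes. Problem sizes in the test-suite and acceptance runs
  (2–14 atoms, 50-pair oracle suites, 2–40 model ensembles) were chosen
  to exercise every code path with closed-form cross-checks.
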