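# Methods

## Empirical error model

The central quantity is the expected coordinate error of a homology
model with no experimental structure. For a family of related
receptors, models built from one template against sequences of *known*
structure give direct (similarity, RMSD) measurements; the error model
is the ordinary-least-squares line

RMSD(s) = a + b·s,

with *s* the percent sequence similarity of the modelled sequence to
the template. The packaged estrogen-receptor LBD series fixes
(100, 0), (94, 0.71), (72, 1.45); the fit gives b ≈ −0.0469 Å per
percentage point and a ≈ 4.877 Å, and the prediction at the rotifer's
68 % similarity is 1.69 Å.

Design choices, all configurable:

- **Template anchor.** The template self-comparison (100 %, 0 Å) is a
  legitimate calibration row (a model built from an identical sequence
  has zero error by construction) and is included by default;
  `--exclude-anchor` drops it for sensitivity analysis.
- **Two R² conventions.** `calibration_only` computes 1 − SS_res/SS_tot
  over the measured points (0.909 for the packaged series) and is the
  default headline number. `with_predictions` appends each
  prediction-only point *at its predicted value* before computing R²
  (0.945 for the packaged series). Because appended points have zero
  residual but widen the spread of y, they can only raise R² — a
  property the test suite asserts. Both are always reported side by
  side; the second exists to replicate plots that draw the extrapolated
  point with the calibration series.
- **Flooring.** The linear form can go negative at high similarity;
  predictions are floored at 0 Å and the raw value is kept in the
  report.
- **Extrapolation flag.** 68 % lies below the calibrated range
  (72–100 %), so the packaged prediction is itself an extrapolation;
  the report flags any query outside the range rather than refusing it.
- **No weighting, no robust loss** — the calibration is a plain trend
  line, and with three points anything richer is theater.
  Leave-one-out validation (`loo_validate`) is provided as the honest
  small-sample diagnostic.

## Superposition and RMSD

Rotations come from the Kabsch/SVD construction with the determinant
forced to +1 (reflections excluded); translation aligns centroids.
Fewer than 3 pairs or a collinear point set raises an error rather than
returning an ill-conditioned fit. RMSD is the root mean square of
paired Euclidean distances after the fit.

Correspondence between model and reference atoms is **alignment
driven**: residues are matched through the gap-free columns of a global
sequence alignment, never through residue numbering, which is not
comparable across species. Within a matched residue pair, the selected
atom names present in both residues are paired. The default selection
for the calibration pipeline is CA-only — the robust convention for
cross-species model/structure comparison; `backbone` and `all-heavy`
are provided for sensitivity checks.

## Alignment

Needleman–Wunsch with affine gaps (Gotoh three-state recursion);
defaults BLOSUM62, gap open 10, gap extend 0.5, with a gap of length L
costing open + (L−1)·extend. Percent identity is the fraction of
identical columns; percent similarity additionally counts columns whose
residue pair co-occurs in one of the strong conservation groups
{STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW}. The default
denominator is the number of columns where neither sequence is gapped;
full-alignment-length is available because published percentages rarely
state their convention, and the two can differ materially for
length-mismatched pairs. Ties among co-optimal alignments are broken
deterministically (substitution preferred over a gap in the second
sequence over a gap in the first, resolved from the alignment end
backwards), so co-optimal terminal gaps land at the alignment start.
The DP score is verified in the test suite against exhaustive
enumeration of all global alignments for short pairs and against an
independent aligner for long ones.

## Pocket geometry

All structures are assumed hydrogen-free (homology models usually are),
so contact criteria are heavy-atom criteria:

- **Pocket residues**: ≥ 1 heavy atom within 4.5 Å of any ligand heavy
  atom.
- **Hydrogen bonds**: N/O–N/O pairs with distance in [2.4, 3.5] Å. The
  lower bound excludes steric clashes. Without hydrogens the
  donor–H–acceptor angle is unavailable, so an antecedent proxy is
  used: for each polar partner whose covalently bonded neighbour
  (nearest heavy atom ≤ 1.8 Å in the same residue) is identifiable, the
  neighbour–atom–partner angle must be ≥ 120°; isolated atoms (e.g.
  water oxygen) fall back to distance-only. Donor/acceptor roles are
  not assigned.
- **van der Waals contacts**: heavy-atom pairs within r_i + r_j +
  0.5 Å using bundled Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80 …;
  unknown elements fall back to 1.70 with a logged warning). Pairs
  already classified as hydrogen bonds are excluded, so the two classes
  partition the contact set.
- **Occlusion**: from the ligand heavy-atom centroid (or averaged per
  ligand atom), cast one ray per direction of a Fibonacci-sphere set
  (default 512 directions; the whole set is rotated by a seed-derived
  random rotation so scores are reproducible but not axis-aligned). A
  ray is blocked when it passes within r_atom + probe (probe 1.4 Å, a
  water radius) of a receptor heavy atom no farther than 15 Å from the
  origin. The score is the blocked fraction: 0 = fully open site,
  1 = fully enclosed. The 15 Å horizon keeps distant lobes of a large
  receptor from counting as pocket walls.

## Synthetic data

The generators produce everything the tests and example workflows
consume; all are pure functions of their parameters and a seed, and all
emit standard formats (PDB/FASTA/CSV plus a ground-truth JSON sidecar
from the CLI).

- `make_helix`: ideal α-helix backbone (rise 1.5 Å, 100° twist, CA
  radius 2.3 Å; N/CA/C/O per residue, poly-alanine). CA–CA spacing
  comes out at ≈ 3.83 Å, matching real chains; peptide-bond geometry
  between residues is only approximate, which is irrelevant to the
  rigid-body and selection logic it exercises.
- `perturb`: rigid motion (seed-derived or explicit) plus i.i.d.
  per-coordinate Gaussian noise. Per-coordinate noise makes the
  post-superposition expectation exact: E[RMSD] ≈ σ√3 (up to the
  1 − 2/n fitting deflation, ≈ 0.4 % at 500 atoms), which the suite
  checks at σ ∈ {0.2, 0.5, 1.0} Å averaged over 50 seeds.
- `make_sequence_pair`: mutates exactly round(L·(1 − target/100))
  positions, never to the original residue, giving a designed gapless
  identity. At length 100 and target 68 % this mirrors the scale of the
  rotifer-vs-human comparison.
- `make_calibration_table`: points on a known line plus N(0, σ) noise,
  floored at 0; defaults reproduce the packaged ER line. Used for the
  unbiasedness check (1,000 replicates at σ = 0.1 Å, 3-SE band).
- `make_pocket_scene`: a point ligand inside a carbon shell (default
  radius 8 Å, 600 atoms) covering a spherical cap. A probe-inflated
  shell atom at radius R blocks a cone of half-angle
  α = asin((r_C + probe)/R), so a cap of atom *centers* blocks more
  solid angle than it subtends; the generator shrinks the center cap by
  α so that the *designed occlusion equals the requested coverage*
  under the default probing parameters (probe 1.4 Å, carbon shell).
  The recorded ground truth therefore assumes those defaults; probing a
  scene with a different probe radius shifts the score by the change in
  α. The test suite also checks the uncompensated case: a literal z>0
  hemisphere blocks (1 + sin α)/2, and the measured score matches that
  analytic value.
- `make_contact_scene`: four receptor atoms and a two-atom ligand laid
  out so that exactly one pair satisfies the hydrogen-bond criteria and
  exactly one the van der Waals criteria, with margins of ≥ 0.15 Å to
  every threshold.

What the generators do **not** emulate: side chains and their packing,
real secondary-structure diversity, correlated (domain-level) model
error, alignment errors between model and reference sequences, and
chemically realistic ligands. Passing tests therefore demonstrate that
the operators compute their definitions correctly and recover designed
ground truth — not that a 1.69 Å prediction is accurate for any
particular real receptor; that depends on the calibration points
supplied.

## Numerical and procedural choices

- Problem sizes in the test suite (500-atom structures, 50 seeds per
  noise level, 1,000 alignment pairs, 1,000 regression replicates,
  512 ray directions) are chosen so the whole suite runs in about a
  minute on one CPU while keeping Monte-Carlo standard errors an order
  of magnitude below the asserted tolerances.
- PDB parsing keeps the first model only, resolves altlocs to the
  highest-occupancy (first-listed on ties) conformer, excludes waters
  by default, and preserves author residue numbering and insertion
  codes verbatim. Malformed coordinate fields fail with the line
  number; coordinates round-trip through the fixed-column writer to
  3 decimals.
- Reports are serialized with sorted keys and no timestamps, and embed
  the package version and a hash of the resolved configuration, so
  identical runs are byte-identical.
- Degenerate inputs fail loudly and specifically: < 3 superposition
  pairs, collinear point sets, < 2 calibration points, equal
  similarities, zero total sum of squares, empty selections and empty
  structures each raise a typed error mapped to a distinct CLI exit
  code (2 configuration, 3 data, 4 degeneracy).

## Known limitations

- The error model is linear in similarity and calibrated on three
  points; it is a family-specific trend line, not a general accuracy
  predictor, and extrapolation below the calibrated range (as in the
  packaged 68 % query) inherits all the usual risks of extrapolation.
- Percent similarity depends on the alignment parameters and group
  definitions; published values computed with other tools can differ by
  several points for the same pair of sequences.
- Hydrogen-bond detection without hydrogens is necessarily
  approximate; the antecedent-angle proxy rejects grossly bent
  geometries but cannot distinguish donor from acceptor or detect
  bifurcated bonds.
- The occlusion score is a visibility measure from the ligand centroid;
  it does not measure cavity volume or channel width, and a score near
  0.5 says only that about half the directions are walled.
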