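# Methods

## Contact definition

A receptor residue k and a ligand residue l are in contact in a model when
the minimum distance over all atom pairs (a ∈ k, b ∈ l) is strictly below
the cutoff (default 5.0 Å, the distance used in blind docking assessment to
define native residue-residue contacts). "Closer than" is implemented as a
strict `<` with no epsilon: a pair at exactly the cutoff is not a contact.
Distances are plain Euclidean distances on the stored coordinates — no
periodic images, no symmetry expansion.

Detection runs through a k-d tree (`scipy.spatial.cKDTree`), which is an
indexing accelerator only; the test suite always re-derives contact sets
with an exhaustive all-atom-pairs oracle (`naive_contacts`) and requires
exact set equality at 3, 5 and 8 Å.

Atom filtering before detection:

* hydrogens (and deuterium) are **excluded by default** — docking models
  carry them inconsistently, and including them for some models would bias
  per-model contact counts; `--include-hydrogens` restores the literal
  any-atom reading;
* waters (HOH/WAT/DOD) are always excluded;
* other HETATM groups (ions, cofactors) are **included by default** since
  they can mediate interface contacts; `--exclude-hetero` drops them;
* for alternate locations, the highest-occupancy conformer is kept,
  first-in-file winning ties — deterministic and conventional.

## Residue identity across models

Residues are equated across models by (chain id, residue number, insertion
code); the residue name is carried for reporting only. This assumes the
shared numbering that blind-assessment model sets guarantee. **Limitation:**
there is no sequence-alignment fallback, so ensembles with renumbered or
differently-chained models must be harmonised upstream. `read_ensemble`
warns (never errors) about residues not present in every model, because a
truncated decoy should not abort an ensemble analysis; such residues simply
contribute contacts to fewer models.

## Conservation scores

With nc_i the contact count of model i, nc_ij the shared contacts of models
i and j, N models:

* Cpair_ij = nc_ij / ((nc_i + nc_j)/2). Both models empty → the score is
  undefined and raises; one empty model → 0. In ensemble averages,
  undefined pairs are skipped with a warning that reports how many, so one
  crashed model cannot abort the run.
* Cpair_av is the mean over the N(N−1)/2 unordered pairs (equivalently the
  upper matrix triangle).
* C_P = nc_P / (Nt/N), where nc_P counts distinct contacts whose occurrence
  is at least ⌈P·N/100⌉ models. The threshold is a **model count** with
  ceiling, so "conserved in 70%" always means at least that share; a 1e-9
  slack absorbs binary-float noise in P·N/100 before the ceiling. C_P is
  non-increasing in P and may exceed 1 at small P (many weakly-shared
  contacts against a modest mean count).
* CR_kl = nc_kl / N per contact; contacts absent from every model are
  implicit zeros and are not stored.
* Ranking of most-conserved contacts sorts by CR descending with ties
  broken lexicographically by (receptor key, ligand key) — an arbitrary but
  fixed rule that makes reports reproducible.
* Q-score maps incorrect/acceptable/medium/high to 0/1/2/3 and sums.

## Consensus maps

Receptor residues on the x-axis, ligand on the y-axis (fixed convention,
recorded in the sidecar), axes ordered by (chain, number, insertion code)
over the union of residues in the ensemble. Cell (k, l) holds CR_kl.

Grey level = 255·(1 − CR/vmax). Two scalings are offered because "darkest =
most conserved" is ambiguous across ensembles: `relative` (default) sets
vmax to the grid's own maximum, so the best-conserved contact of *this* map
is black and weak consensus remains visible; `absolute` sets vmax = 1, so
black always means full conservation and maps of different ensembles are
directly comparable. `render_map` writes the raster with one integer pixel
block per residue pair (no interpolation, so tests read grey values back
exactly) plus a sidecar stating scale, vmax, the grey↔CR formula and the
axis labels; `render_figure` writes a matplotlib figure with labelled
residue axes for human inspection. The numeric grid TSV uses 17-significant-
digit floats and round-trips bit-exactly.

## Superposition and ligand RMSD

The rotation minimising backbone RMSD is the Kabsch solution, computed via
`scipy.spatial.transform.Rotation.align_vectors` on centred point sets;
reflections are excluded and collinear point sets (rank < 2 after
centring) are rejected as degenerate. An independent nested rotation-grid
search serves as the oracle in tests.

L_rmsd between two models: least-squares fit on the backbone atoms
(N, CA, C, O; OXT excluded) of the receptor residues present in **both**
models ("invariant residues" of the pair; an optional argument restricts to
an ensemble-wide set for matrix consistency), then RMSD over ligand heavy
atoms (element ≠ H/D) matched by residue key and atom name, unmatched atoms
dropped with a warning. Per residue, the fit uses whichever of the four
backbone atoms both models carry; a residue drops out (with a warning) only
when none match. Requiring the full quartet instead would discard every
residue in models that omit carbonyl oxygens — common in docking output and
true of this package's own three-atom pseudo-residues.

## Synthetic fixtures

Real decoy sets are bulky and not redistributable, so fixtures are
generated:

* **Toy complexes** (`make_toy_complex`): two random residue blobs (three
  atoms per pseudo-residue, named N/CA/C) facing each other across an
  adjustable gap; the exact contact set is emitted alongside, computed by
  the naive oracle. Pseudo-residues rather than real amino-acid geometry:
  contact logic needs only coordinates and names, and three-atom residues
  keep files tiny and oracle checks fast.
* **Planted-overlap ensembles** (`make_ensemble`): the receptor is a hub
  residue on an axis plus an annular rim lattice (arc pitch 9 Å, ring gap
  9 Å); the ligand is a compact core cluster above the hub plus a radial
  arm above the rim. Each model is a genuine rigid-body rotation of the
  ligand about the interface normal onto a distinct lattice slot. Distances
  from core atoms to the on-axis hub are rotation-invariant, so the
  round(f·n) core contacts survive in every model; arm contacts land on a
  model-specific rim column shared with no other model. Every model has
  exactly n contacts and **every pair** of models shares exactly the core,
  so the pairwise conservation of each pair equals round(f·n)/n by
  construction. This is why the generator controls overlap by splitting the
  contact budget rather than by calibrating a displacement magnitude: a
  single displacement size tuned against the reference model fixes only the
  reference-to-model overlap, while pairwise overlap depends on each pair's
  relative displacement and cannot be held at f for all N(N−1)/2 pairs
  simultaneously. The full PDB → parse → contact pipeline is still
  exercised, since models differ by real rigid motions written to PDB.
  Default conditions: N = 20 models and 40 contacts per model, matching the
  recovery checks (Cpair_av within ±0.05 of the planted level).
* **Displacement ladders**: with `displacement_ladder`, each model
  translates the ligand rigidly along +x from a reference pose with a small
  positive interface gap, so every atom-pair distance grows monotonically
  with the offset: contact sets shrink monotonically and the planted offset
  equals L_rmsd exactly (fit on an identical receptor is the identity).

What the fixtures do **not** emulate: real amino-acid geometry and packing,
conformational (non-rigid) variation between decoys, clashes, missing
atoms, and heterogeneous residue numbering. Passing the recovery tests
therefore demonstrates the correctness of the scoring pipeline, not the
behaviour of real docking decoys.

All generator randomness flows from a single integer seed through
`numpy.random.default_rng`; coordinates are written at PDB precision
(0.001 Å), and a fixed spec reproduces byte-identical files. Geometry
margins (≥1.5 Å between the worst-case atom distance and the 5 Å cutoff)
make the planted contact sets immune to that coordinate rounding.

## Numerical and interface choices

* Scores involving an empty denominator raise a dedicated
  `ScoreUndefinedError` rather than returning NaN.
* Matrix cells for undefined pairs are NaN in the in-memory report and the
  TSV prints `nan`.
* TSV (not CSV) outputs with decimal points throughout; six decimals in
  reports, full precision in grid exports.
* Multi-MODEL PDB files require an explicit 0-based `--model-index`;
  reading silently from such a file would risk scoring the wrong pose.
* Exit codes: 0 success, 1 usage error, 2 data error.
* mmCIF input is out of scope; fixed-column PDB only.

## Problem sizes in checks

The bundled verification suite uses toy complexes of 5–50 residues per side
(seeds 0–199) for oracle equivalence, 30–50 random abstract ensembles for
the score identities, and 20-model ensembles at five planted conservation
levels for recovery — sizes chosen so the full suite re-derives every
guarantee in well under a minute on one CPU while covering the regimes
(sparse/dense interfaces, empty models, boundary distances) where the
implementation could plausibly diverge from the definitions.
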