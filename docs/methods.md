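# Methods

`e2dyn` re-implements, as a tested pipeline over synthetic ensembles, the
conformational analysis used to study how the acidic β4α2 loop of
Cdc34-like E2 ubiquitin-conjugating enzymes gates solvent access to the
catalytic cysteine, and how CK2 phospho-sites (S130/S167 in yeast Cdc34
numbering) co-occur with that loop across E2 families.  This note records
the models, the defaults that matter, and the choices made where the
design was genuinely open.

## The ensemble container and superposition

All stages operate on a `ConformerSet`: an ordered block of F frames over
a fixed atom table (Å units, author residue numbering from the input
file).  It stands in equally for an MD trajectory slice, an NMR model
set, or a synthetic ensemble.  Multi-model PDB I/O goes through biotite;
atom matching across models is positional.  Only single-chain inputs are
supported; multi-chain files are reduced to their first chain with a
warning.

Least-squares superposition is the Kabsch algorithm (SVD of the 3×3
cross-covariance; the smallest singular direction is sign-flipped when
the unconstrained optimum would be a reflection, so rotations are always
proper).  A batched implementation aligns whole frame blocks in one
vectorised call; tests assert it is identical to the per-frame closed
form, and the closed form itself is checked against a brute-force
quaternion-grid search.

## The synthetic-ensemble generator

The original study rests on ~2.5 µs of MD that is not publicly
deposited, so every downstream stage is driven by a generator that
emulates the *statistical* structure of such data, not its physics:

* **Scaffold** — an ideal helix-like Cα curve with ~3.8 Å spacing, one
  CA per residue (7–170 by default, 164 residues) plus a single pseudo
  side-chain atom ("SG") on the catalytic cysteine C95, placed 2 Å
  radially outward so that a displaced loop can occlude it.
* **Loop basins** — metastable conformations of the acidic loop
  (103–114) are rigid centroid offsets of the loop atoms.  The
  wild-type-like preset has five basins whose loop-COM-to-C95-COM
  distances are 5.0, 9.0, 11.9, 15.3 and 17.8 Å — one closed state
  (centroid within ~6 Å of the SG), two intermediates, two open states
  (≥ 14 Å) — with occupancies (0.28, 0.22, 0.19, 0.16, 0.15).  States
  follow a slow first-order Markov chain: with probability p = 0.02 per
  frame the state is redrawn from the occupancy distribution (making the
  occupancies the exact stationary law); an iid mode exists for tests.
* **Collective modes** — Gaussian amplitudes along fixed displacement
  fields (a loop-opening mode, stdev 1.0 Å for the wild-type-like
  system, and a global breathing mode, 0.5 Å).  Every mode field is
  projected onto the orthogonal complement of the six rigid-body degrees
  of freedom (translations and infinitesimal rotations, QR-orthonormalised)
  before normalisation: a mode with net translation or torque would be
  partially absorbed by superposition and its designed variance would not
  be recoverable.
* **Baseline flexibility** — per-residue isotropic jitter, a smooth
  0.25–0.45 Å profile with mobile termini.
* **Equilibration transient** — the first 200 of 2000 frames start from
  a 3 Å-RMS internally deformed copy (a sinusoidal, rigid-body-free
  field, so the transient survives superposition) and relax linearly to
  zero.  2000 frames at 10 ps/frame correspond to a 20 ns replica, the
  per-replica length of the wild-type system in the study design this
  emulates.
* **Variants** — `phospho_like` and `s130e_like` keep the basin geometry
  but shift occupancy toward the open states (0.80 and 0.60 open vs.
  0.31) and stiffen the loop mode (0.4/0.6 Å), encoding "the loop locked
  open, reduced fluctuation"; `delta12_like` deletes residues 103–114
  outright (152 residues, no basins); `ubc1_like` is an insertion-free
  homolog with a slightly more mobile baseline.

Replica r of a system uses seed `base_seed + r`; identical spec + seed
is bit-identical.  What the generator does **not** emulate: force-field
energetics, solvent, side chains beyond the single pseudo-SG, realistic
secondary structure, or anharmonic couplings between modes.  Passing
tests therefore demonstrate that the *analysis operators* recover known
ground truth under realistic statistical structure — not that they would
reach the study's absolute numbers on real trajectories.

## Stage 1 — convergence

RMSD series are computed after superposition on the common E2 fold (all
residues minus the acidic loop), against the initial frame, matching the
convention of measuring convergence on the conserved fold so that loop
state-switching does not mask equilibration.  The equilibration cut is
the smallest index i at which (a) the least-squares slope of the RMSD
over a window (default 10 % of the series) is below 1e-3 Å/frame in
magnitude and (b) the window mean lies within 0.5 Å of the remaining-series
mean; a series that never satisfies both is flagged unconverged.  The
rule is deliberately simple and oracle-checkable (exhaustive scan over
cut points); statistical-inefficiency methods are out of scope.

Equilibrated replica portions are joined into a macro-trajectory with
per-frame provenance.  RMSF is computed on Cα atoms about the two-pass
average structure.  The two-pass iteration starts from the plain
coordinate mean rather than frame 0: a frame-0 start would make
macro-trajectory RMSF depend on the order in which replicas were
concatenated, which exchangeable post-equilibration frames must not.
Further iterations change RMSF by <1e-3 Å on test ensembles.  Replica
consistency is the pairwise Pearson matrix of RMSF profiles, passing
when every coefficient exceeds 0.6 (the conventional criterion).

## Stage 2 — essential dynamics

PCA eigendecomposes C = ⟨Δx Δxᵀ⟩ of the Cα positional deviations.  For
the alignment before covariance we iterate align-to-mean to a fixed
point (tolerance 1e-10, ≤ 20 iterations; the first two iterations are
exactly the two-pass rule, and convergence typically takes 3–5): at the
fixed point the alignment target *is* the aligned-frame average, which
makes the identity "variance of projection i = eigenvalue i" hold to
machine precision for the fitting ensemble instead of only
approximately.  Mass weighting (√m-scaled deviations) is implemented but
defaults off: for an all-Cα selection it is a uniform scalar that
rescales eigenvalues and leaves eigenvectors and explained fractions
unchanged (unit-tested).  Eigenvector signs follow the
largest-component-positive convention.

Cosine content of a projection series uses the plain discrete estimator
c = (2/T)(Σ_t p(t) cos(πt/T))² / Σ_t p(t)² on the mean-centred series
(no windowing); near-1 values indicate diffusion-like, unconverged
sampling, and an all-zero series returns 0 by convention.

The free-energy landscape over (PC1, PC2) is ΔG = −kT ln(n_bin/n_max) on
a 32×32 grid spanning the data range padded 5 %, kT = 2.494 kJ/mol
(300 K); empty bins are masked and the modal bin sits at ΔG = 0.  The
grid resolution and colour scale of the original figures are not stated
anywhere; these defaults are declared, not inferred.

## Stage 3 — ensembles

Clustering is the iterative neighbor-count (GROMOS-style) algorithm over
the all-pairs superposed Cα RMSD matrix, cutoff 1.0 Å by default, ties
broken toward the lower frame index; it is asserted equal to a
brute-force oracle on small ensembles.  Because the matrix is quadratic
in frames, the pipeline clusters a stride-subsampled macro-trajectory
(default ≤ 300 frames), standard practice for cutoff clustering.

Basins are extracted from the (3×3 box-smoothed) landscape: local minima
within a depth cut of the global minimum seed an ascending 8-neighbour
watershed; saddle-sharing bins go to the lower minimum, ties to the
earlier (row-major) one, and a flat plateau yields a single basin.  The
`find_basins` default depth cut is 1 kT; the *pipeline* default is 2 kT,
fixed from preset arithmetic before any run: with occupancies 0.28 vs.
0.15 the modal-bin gap is ln(0.28/0.15) ≈ 0.6 kT and bin-edge splitting
can add up to ln 2 ≈ 0.7 kT, so 1 kT leaves no margin, while raising the
cut cannot merge basins whose separating bins are empty (masked).

A cluster is linked to a basin when >50 % of its frames project into the
basin's bins (the exact congruence rule of the original protocol is not
published; this threshold is a declared decision).  Linked pairs become
ensembles A, B, … by descending cluster population; the congruence score
is the fraction of all frames lying in a matched cluster *and* its
linked basin.  On the five-basin preset this integration recovers
exactly five labeled ensembles in ≥ 95 % of seeded runs.

## Stage 4 — cleft geometry

Solvent-accessible surface area is Shrake–Rupley: 960 deterministic
golden-spiral points per expanded sphere (r + 1.4 Å probe), a point is
buried only if *strictly* inside a neighbouring expanded sphere
(boundary contacts count as exposed, for determinism at exact-contact
geometries).  Radii: C 1.70, N 1.55, O 1.52, S 1.80 Å.  Doubling the
point count changes any atom's exposed fraction by <1 % of its full
sphere on the package's structures; accuracy is checked against a dense
latitude–longitude integration oracle and cross-checked against an
independent library implementation.

Relative side-chain SASA divides the in-context side-chain area by the
same atoms computed *in isolation* with the same engine and parameters —
a self-consistent reference that avoids an external Gly-X-Gly table and
may differ by a few points from other normalisations.  The side chain of
a residue is everything outside the N/CA/C/O backbone, hydrogens
ignored.

The loop state of a frame is classified from the distance between the
centers of mass of the catalytic residue and the acidic loop: closed if
d ≤ 8 Å (inclusive), open if d ≥ 12 Å, else intermediate; thresholds are
configuration (the original definitions are qualitative).  SASA is
carried alongside but does not enter the label.  The joint profile
reports avSAS (mean relative SASA over frames), state fractions, and the
d–SAS Pearson correlation (undefined, with a note, for zero-variance
input).  The study's absolute avSAS values (30 %/34 %) derive from µs MD
and are out of scope as numeric targets; the package reports avSAS for
whatever ensemble it is given and tests only structure-based bounds and
synthetic orderings (phospho-like more open and more exposed than
wild-type-like, accessibility increasing with loop distance).

## Conservation scan

The package consumes externally built alignments (FASTA/Clustal); it
does not rebuild the 250-sequence E2 alignment.  Reference residue
numbers map to alignment columns by counting non-gap reference
characters (1-based columns).  Conservation degree is the percentage of
sequences carrying the residue class at the column, among non-gap rows
(gap-only columns report 0 with a flag).  The acidic-insertion scan
takes the longest run of reference-residue/comparator-gap columns in a
window, present at ≥ 8 columns (below the canonical 12/13).  The CK2
context rule — acidic at +3, or ≥ 2 acidic among +1..+3 — encodes the
canonical S/T-x-x-D/E motif with an acidic-context relaxation; the
original work never writes its pattern, so the rule is configurable.
DE1/DE2 positions are configuration inputs, not hard-coded.  Pairwise
identity uses Needleman–Wunsch (BLOSUM62, gap open 10 / extend 0.5,
terminal gaps free, identity over non-terminal columns); the input pair
is canonicalised by lexicographic order so tie-breaking among co-optimal
alignments cannot break symmetry.

## Problem sizes and numerical conventions

The standard study condition is 4 replicas × 2000 frames (≙ 20 ns each);
clustering runs on ≤ 300 subsampled frames; SASA profiles stride the
macro-trajectory (default every 20th frame).  These sizes recover all
designed quantities comfortably (first 3 PCs ≈ 84 % of variance vs. the
60 % bound; RMSF consistency ≈ 1.0 vs. 0.6).  Degenerate inputs have
defined behaviour throughout: empty selections warn, single frames
reject RMSF/PCA, zero-variance series report undefined correlations with
reasons, loop operations on Δ-loop systems raise a "not applicable"
error that the pipeline records as a skip.

## Known limitations

Synthetic ensembles only (no trajectory formats beyond multi-model PDB
in v1); no mmCIF/XTC/DCD; no hydrogens, altlocs or occupancies; no
autocorrelation-based equilibration detection or block averaging; no
kinetic (time-lagged) component analysis or RMSIP subspace overlap; no
phylogenetic reconstruction (family labels are inputs).  External
real-structure checks (the Ube2g2 NMR entry 2KLY, real UBC-domain
sequences) require user-supplied files under `data/external/`.
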