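# Methods notes

This note records the models implemented, the conventions and defaults
chosen where the methods themselves leave room, what the synthetic
generators do and do not emulate, and the numerical choices that affect
results.  No empirical number appears here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Residue equivalences and filtering

Chains are put in register by global sequence alignment (BLOSUM62, gap
open −10, extend −0.5) of their Cα-bearing residues.  The first chain
anchors the column set: every reference residue is one column; residues of
other chains inserted relative to the reference get private trailing
columns, which can never be occupied in all chains and therefore never
enter the common analysis subset.  This reference-anchored construction is
deterministic and exact for the chain sets the package targets (one fold
family); it does not attempt progressive-alignment refinement of
insertions shared by several non-reference chains — those columns remain
per-chain.  Chains under 30% identity to the reference are flagged for
manual curation, not dropped.

The completeness filter retains a chain iff every column of every required
region (by default the nucleotide-site regions named in the shipped
recipe: P-loop, switch I, switch II) is occupied, and reports each
exclusion with the missing region.  Author residue numbering is preserved
for reporting only; all computation uses 0-based alignment columns, since
subfamilies number the same fold differently.

## Superposition and the invariant core

Rigid-body fits use the Kabsch algorithm (SVD of the cross-covariance with
a determinant guard that flips the smallest singular direction for the
reflection case).  Fits determined on a Cα subset are applied to all atom
layers, so side-chain pseudo-atoms stay consistent.

The invariant core is found by iterated superposition: fit all frames onto
their mean over the current candidate set (two mean-refinement passes per
round), measure each candidate's variance-ellipsoid volume — (4π/3) times
the product of the standard deviations along the three principal axes of
that position's scatter — and drop the worst batch.  The batch is the top
10% of candidates among those above threshold (at least one), a
coarse-to-fine schedule that removes clearly mobile regions quickly and
refines near the boundary.  Iteration stops when every remaining volume is
below `stop_volume` (default 0.5 Å³) or at a requested target size; it is
an error to reach fewer than 3 positions.  The per-round history (excluded
columns, worst remaining volume) is returned for audit.  The volume
threshold and batch fraction are tunables: the procedure's fixed point,
not the exact path, is the contract.

## PCA conventions

* Covariance uses the **population convention** (divide by F).  Variance
  *fractions* — the quantities usually reported — are convention-invariant;
  absolute eigenvalues (Å²) are not, so this choice is stated prominently.
  The two-frame example (single coordinate differing by d → single entry
  d²/4) pins the convention in the tests.
* Eigenvalues are clipped at zero; eigenvector sign is fixed by making the
  largest-magnitude component positive, so projections are deterministic.
* Conformer clustering is complete-linkage on Euclidean distance over the
  scores on the first five PCs, with the number of groups K supplied by
  the user (default 3 in the shipped recipe); no automatic K selection is
  attempted.
* Per-residue contribution to a PC is the squared norm of that position's
  three eigenvector components (sums to 1 over positions).
* The B-factor comparison is made on the linear B vs RMSF² scale, since
  B = (8π²/3)·RMSF² under the isotropic harmonic model; a constant profile
  has no defined correlation and is reported as NaN with a warning.
* Subspace similarity is the average cumulative squared inner product:
  the mean over one model's first two PCs of their cumulative squared
  projections onto the other model's first K eigenvectors; monotone
  non-decreasing in K, equal to 1 at K = 3N.

## Correlation networks

The DCCM is the normalized covariance of Cα displacements about the mean.
Zero-variance positions get NaN rows/columns and contribute no edges.

Contact edges require the minimum heavy-atom distance (over all available
atom layers) to be below 4.5 Å in at least 75% of frames, boundary
inclusive.  Sequence neighbours i, i±1 are excluded by default (i±2
optionally) — backbone adjacency would otherwise dominate every path; how
far to extend this exclusion is a genuine free choice and is exposed as a
parameter.

Edge length is w_ij = −log|C_ij|: the product of |C| along a path becomes
an additive path length, so the shortest path is the most correlated
chain of contacts.  |C| is floored at 1e-6 (w_max ≈ 13.8) and capped edges
carry a flag.  Communities come from Girvan–Newman removal ordered by
weighted edge betweenness, with ties broken toward the lowest node pair
for determinism; among the nested partitions the one maximising modularity
is returned, with **|C| as edge strength** for modularity and **w as
length** for paths.  The signed DCCM is retained for reporting (±0.5
thresholding in the matrix plot convention).

Critical nodes are residues incident to inter-community edges whose
betweenness exceeds a configurable quantile (default the median) among
such boundary nodes — the "carries a majority of the community-bridging
shortest paths" reading, which the source method leaves quantitatively
open.  Suboptimal paths are enumerated by depth-first search pruned with
the exact Dijkstra distance-to-sink bound, so enumeration is exhaustive
within the tolerance yet touches only viable prefixes.

## Contact events and segmentation

Pair distance is the minimum side-chain heavy-atom distance, with Cα as
the glycine fallback.  The dual-cutoff reading of "in contact between
6.5 and 7.5 Å" is implemented as hysteresis (form below 6.5 Å, break above
7.5 Å, state persists inside the band; the initial state is taken against
the band midpoint), matching the cited event-detection tool's design; the
literal distance-band reading is available behind `mode="band"`.

Each pair's boolean series is median-filtered with half-width expressed in
frames (14 ns at 20 ps sampling = 700 frames in the shipped recipe; both
are config-visible).  Transitions of the *filtered* series are the events;
the total per frame, smoothed by a Gaussian kernel whose bandwidth
defaults to half the median half-width (unstated in the source method),
is the activity curve.  Segment boundaries are activity peaks whose
prominence exceeds a fraction (default 0.3) of the curve's maximum —
a relative criterion, so genuine transitions stand out against the
noise-floor event rate at any trajectory length; a flat curve yields one
segment.  Segments tile the trajectory without overlap.

## Order parameters

Distance/angle protrusion: distance between uniform-mass Cα centres of
mass of two selections; angle between the dominant principal axes of the
two selections' within-frame Cα scatter, folded below 90° (a COM pair does
not define an angle by itself, so the axis convention is declared here).
Both are rigid-motion invariant.  The default selections in the shipped
recipe are the α4 helix window and the β3 strand window, both
config-visible since exact windows are a curation choice.

Docking calls monitor named-atom (default Cβ, Cα for glycine) pair
distances; a frame is docked iff all pairs are below the cutoff (default
8.0 Å — the dashed-line value in the source figure is not printed, so this
is calibration-grade).  Raising the cutoff can only turn undocked frames
docked (monotonicity, tested).

Secondary structure defaults to a φ/ψ-region heuristic (helix
φ ∈ (−120°, −30°), ψ ∈ (−77°, −7°); strand φ ∈ (−180°, −45°),
ψ > 90° or ψ < −150°) refined by the i→i+4 O···N hydrogen-bond geometry
where carbonyl oxygens exist; chain termini inherit their neighbour's
class.  Any external assigner can be plugged in as a callable receiving
the backbone layers; the tests use DSSP (via mdtraj) as the independent
reference and require ≥85% per-residue agreement on an ideal
helix–coil–helix construct.

## Synthetic generators: what they emulate, and what they do not

The generators provide the three statistical structures the analyses
assume, with ground truth emitted machine-readably:

* `gaussian_ensemble` — conformers around a mean with a prescribed
  low-rank covariance (orthonormalized modes, default variances 9:3:1,
  optional isotropic noise): the analogue of a crystal-structure
  distribution dominated by a few collective motions.
* `switching_trajectory` — piecewise-constant hopping between reference
  conformations on a known dwell schedule plus isotropic noise
  (default σ = 0.3 Å): the analogue of a trajectory with discrete
  conformational transitions.  Transition frames and per-state contact
  maps are the ground truth.
* `block_correlated_trajectory` — per-block shared latent displacements
  calibrated so the expected Cα cross-correlation equals the intra-block
  target (default 0.8; inter-block coupling up to the feasible bound
  intra): the analogue of correlated community motion.  The default mean
  structure stacks one β-hairpin per block (2.6 Å rise, 3.3 Å cross-strand
  separation) so each block is a connected component of the 4.5 Å contact
  graph with ≥0.3 Å margin between contact and non-contact distances
  against the displacement noise (amplitude 0.3 Å); blocks are 20 Å apart,
  giving zero inter-block contacts by construction.

The toy structures are idealized helix/strand/linker constructs (72
residues) with labeled regions named after the motor-domain elements
(α4, β3, loop8, neck, P-loop, SI, SII) and one Cβ-like pseudo-atom per
residue, so the shipped recipe configurations run unchanged on synthetic
data.  They carry **no physical realism**: no force field, no
excluded-volume, no realistic side chains, no solvent.  Passing tests
demonstrate that the estimators recover known statistical structure and
that the orchestration is correct — they do not demonstrate anything about
real kinesin trajectories, whose correlations are neither block-constant
nor stationary.  The separate full-backbone builder (natural-extension
construction with standard bond lengths/angles from a φ/ψ list) exists for
secondary-structure tests only.

## Problem sizes and reproducibility

The tests and the acceptance script use deliberately small problems chosen
so each estimator's sampling error is well inside its tolerance: F = 2000
frames for variance-fraction recovery (3-standard-error bands), F = 5000
for DCCM block means (±0.05), 600-frame switching trajectories for
segmentation (boundary within one 25-frame filter half-width), toy graphs
of ≤12 nodes wherever an exhaustive oracle (all partitions, all simple
paths) is the reference.  All randomness flows from a single seed;
end-to-end runs with the same config and seed are byte-identical, which
the suite asserts on the summary JSON.

## Known limitations

* The reference-anchored alignment does not merge insertions shared by
  non-reference chains; for deeply divergent sets a full progressive MSA
  would be preferable.
* Girvan–Newman scales as O(E²·V); it is intended for single-domain
  networks (hundreds of nodes), not large complexes.
* DCD trajectories are read through MDAnalysis when importable (declared
  capability); multi-model PDB is the always-available interchange format.
* The contact-activity implementation follows the described behaviour
  (median-filtered dual-cutoff events, kernel-smoothed activity); bitwise
  fidelity to any particular external tool is not claimed.
* mmCIF input is not implemented; inputs are PDB-format files.
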