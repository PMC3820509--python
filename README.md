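# ensdyn

Analysis of protein conformational ensembles and molecular-dynamics
trajectories, built around the workflow used to characterise kinesin
motor-domain mechanochemistry: interconformer principal component analysis
of crystal-structure sets, projection of trajectory snapshots onto the
crystallographic principal components, dynamical cross-correlation and
weighted-network community analysis of coupled motions, contact-event
activity segmentation, and geometric order parameters (α4–β3 protrusion,
neck-linker docking, latch interactions).

It is aimed at structural bioinformaticians who have a set of related PDB
structures and/or trajectories of one fold and want a reproducible,
scriptable route from raw coordinates to conformational states, correlated
communities and order-parameter traces.  Every stage also runs on built-in
synthetic generators with analytically known structure, so the whole stack
is testable without downloading anything.

## The methods

**Interconformer PCA.**  After residues are put in equivalence by sequence
alignment and chains are filtered for completeness in required regions, an
iterated superposition procedure finds the *invariant core*: before each
round, the positions with the largest interconformer scatter — measured as
the volume (4π/3)·σ₁σ₂σ₃ of the ellipsoid spanned by the standard
deviations along the principal axes of each position's coordinate scatter —
are excluded, until every remaining position's ellipsoid is below a volume
threshold.  With all frames superposed on the core, the 3N×3N Cartesian
covariance

  C_ij = ⟨(r_i − ⟨r_i⟩)(r_j − ⟨r_j⟩)⟩

is diagonalized; eigenvectors are the principal components, eigenvalues the
variance along each.  Structures and trajectory snapshots are projected
onto the leading PCs ("conformer plots"), and complete-linkage hierarchical
clustering of Euclidean distances in PC1–PC5 groups conformers into states.

**Correlation networks.**  The dynamical cross-correlation matrix (DCCM)

  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)

is computed from Cα displacements about the mean.  A weighted graph has one
node per residue and an edge wherever the closest heavy atoms of two
residues are within 4.5 Å in at least 75% of frames; edge lengths are
w_ij = −log|C_ij|.  Girvan–Newman edge-betweenness removal partitions the
graph into communities at maximum modularity, and weighted betweenness
ranks the residues mediating inter-community coupling; optimal and
suboptimal paths are enumerated within a weight tolerance.

**Contact events.**  Per residue pair, a side-chain distance series is
converted to a hysteretic contact state (forms below 6.5 Å, breaks above
7.5 Å), median-filtered, and the filtered transitions counted per frame;
a Gaussian kernel yields a smooth activity curve whose peaks segment the
trajectory into regions of similar contact structure.

**Order parameters.**  The protrusion of a helical subdomain (α4) from the
core is the distance between the centres of mass of two residue selections
together with the angle between their principal axes; neck-linker docking
is called from monitored Cβ–Cβ pair distances against a cutoff; secondary
structure comes from a φ/ψ + O···H-N heuristic or any external assigner
plugged in as a callback.

## Worked example

```python
import numpy as np
import ensdyn

# two reference conformations of the toy motor domain: alpha4 "up" with a
# docked neck-linker, alpha4 "down" with the neck-linker released
up, down = ensdyn.toy_two_state()

# 600-frame switching trajectory, one transition at frame 300
spec = ensdyn.GeneratorSpec(seed=42, states=[up, down], noise=0.3,
                            schedule=[(0, 300), (1, 300)])
traj, truth = ensdyn.switching_trajectory(spec, 600)

cfg = ensdyn.AnalysisConfig(outdir="demo", half_width=25)
result = ensdyn.run_trajectory_analysis(cfg, ensemble=traj)

s = result["summary"]
print("segments:", s["segments"])
print("events:", s["n_events"])
print("mean alpha4-beta3 distance: %.1f A"
      % s["geometry"]["protrusion_distance_mean"])
print("docked fraction: %.2f" % s["geometry"]["docked_fraction"])
pc1 = result["projections"].scores[:, 0]
print("PC1 cloud separation: %.1f A"
      % abs(np.median(pc1[:300]) - np.median(pc1[300:])))
```

prints

```
segments: [[0, 299], [300, 599]]
events: 205
mean alpha4-beta3 distance: 14.5 A
docked fraction: 0.49
PC1 cloud separation: 61.8 A
```

The contact-event segmentation recovers the constructed transition at
frame 300 exactly; the mean protrusion distance (14.5 Å) sits between the
16 Å "up" and 13 Å "down" states because the trajectory spends half its
time in each, and the docked fraction ≈ 0.5 for the same reason; the two
conformational states separate into two well-resolved clouds along PC1.

The same recipes run from the shell:

```
ensdyn simulate --kind switching -n 600 --out sim --seed 42
ensdyn trajectory -t sim/trajectory.pdb --out run --seed 42
ensdyn conformers -s a.pdb -s b.pdb -s c.pdb --out conf
```

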