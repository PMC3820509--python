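"""Principal component analysis of superposed coordinate ensembles.

The covariance matrix C has elements C_ij = ⟨(r_i − ⟨r_i⟩)(r_j − ⟨r_j⟩)⟩
over the F frames, for all pairs of the 3N Cartesian coordinates of the
superposed structures.  The population convention (divide by F) is used
throughout; variance *fractions* are convention-invariant, absolute
eigenvalues (Å²) are not.

Eigenvectors of C are the principal components (PCs); eigenvalues give the
variance of the distribution along each PC.  Projection of structures onto
the leading PCs yields the low-dimensional conformer plot; complete-linkage
hierarchical clustering of Euclidean distances in the first five PCs groups
conformers into conformational states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .core_fit import SuperposedEnsemble
from .ensemble_io import CoordinateEnsemble

__all__ = [
    "CovarianceMatrix",
    "PCAModel",
    "ProjectionSet",
    "ClusterAssignment",
    "covariance",
    "pca",
    "project",
    "residue_contributions",
    "cluster_conformers",
    "rmsf",
    "bfactor_correlation",
    "subspace_overlap",
]

Ensemble = CoordinateEnsemble | SuperposedEnsemble


def _frames_of(ensemble: Ensemble | np.ndarray) -> np.ndarray:
    if isinstance(ensemble, np.ndarray):
        return ensemble
    return ensemble.frames


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CovarianceMatrix:
    matrix: np.ndarray        # (3N, 3N), Å²
    mean: np.ndarray          # (3N,)
    n_positions: int
    n_frames: int

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


@dataclass
class PCAModel:
    """Mean conformation plus the eigendecomposition of the covariance."""

    eigenvectors: np.ndarray     # (3N, K), orthonormal columns
    eigenvalues: np.ndarray      # (K,), Å², descending
    fractions: np.ndarray        # eigenvalue / total variance
    cumulative: np.ndarray
    mean: np.ndarray             # (3N,)
    n_positions: int

    @property
    def rank(self) -> int:
        return int(np.sum(self.eigenvalues > 1e-10 * self.eigenvalues[0]))


@dataclass
class ProjectionSet:
    scores: np.ndarray   # (F, K), Å
    labels: list

    def to_tsv(self, path) -> None:
        header = "label\t" + "\t".join(
            f"PC{k + 1}" for k in range(self.scores.shape[1]))
        lines = [header]
        for lab, row in zip(self.labels, self.scores):
            lines.append(str(lab) + "\t" +
                         "\t".join(f"{v:.6f}" for v in row))
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # (F,), values in 1..K
    linkage_tree: np.ndarray    # scipy linkage matrix
    K: int
    distance: str = "euclidean-PC"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def covariance(ensemble: Ensemble | np.ndarray) -> CovarianceMatrix:
    """Cartesian covariance matrix of a superposed ensemble.

    Population convention: ``C = X_cᵀ X_c / F`` where ``X_c`` are the
    mean-centred frames flattened to (F, 3N).  Two frames differing in one
    coordinate by d therefore give a single nonzero entry d²/4.
    """
    frames = _frames_of(ensemble)
    F, N = frames.shape[0], frames.shape[1]
    if F < 2:
        raise ValueError("need at least 2 frames to estimate a covariance")
    X = frames.reshape(F, 3 * N)
    mean = X.mean(axis=0)
    Xc = X - mean
    C = (Xc.T @ Xc) / F
    return CovarianceMatrix(matrix=C, mean=mean, n_positions=N, n_frames=F)


def pca(cov: CovarianceMatrix) -> PCAModel:
    """Descending eigendecomposition of a covariance matrix.

    Eigenvalues are clipped at zero (values below −1e-8 × trace are a
    symmetry error and rejected by :class:`CovarianceMatrix`); each
    eigenvector's sign is fixed by making its largest-magnitude component
    positive so projections are deterministic.
    """
    vals, vecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    total = vals.sum()
    fractions = vals / total if total > 0 else np.zeros_like(vals)
    return PCAModel(
        eigenvectors=vecs,
        eigenvalues=vals,
        fractions=fractions,
        cumulative=np.cumsum(fractions),
        mean=cov.mean,
        n_positions=cov.n_positions,
    )


def project(frames: Ensemble | np.ndarray, model: PCAModel,
            K: int | None = None) -> ProjectionSet:
    """Project frames onto the first K principal components.

    Frames must be superposed on the same core/reference as the model's
    training ensemble; scores are ``(frame − mean) · eigenvector``.
    """
    arr = _frames_of(frames)
    labels = (list(frames.labels)
              if not isinstance(frames, np.ndarray) else
              list(range(arr.shape[0])))
    X = arr.reshape(arr.shape[0], -1)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: frames have {X.shape[1]} coordinates, "
            f"model has {model.mean.shape[0]}")
    if K is None:
        K = model.eigenvectors.shape[1]
    scores = (X - model.mean) @ model.eigenvectors[:, :K]
    return ProjectionSet(scores=scores, labels=labels)


def reconstruct(scores: np.ndarray, model: PCAModel) -> np.ndarray:
    """Inverse of :func:`project` for a full set of 3N scores."""
    X = scores @ model.eigenvectors[:, :scores.shape[1]].T + model.mean
    return X.reshape(scores.shape[0], model.n_positions, 3)


def residue_contributions(model: PCAModel, pc: int = 0) -> np.ndarray:
    """Per-position contribution to one PC (squared eigenvector norm).

    Sums to 1 over positions; peaks mark the regions carrying the motion.
    """
    if pc >= model.eigenvectors.shape[1]:
        raise ValueError("pc index exceeds rank")
    v = model.eigenvectors[:, pc].reshape(model.n_positions, 3)
    return np.sum(v ** 2, axis=1)


def cluster_conformers(projections: ProjectionSet, K: int,
                       n_pcs: int = 5) -> ClusterAssignment:
    """Complete-linkage clustering of conformers in PC space.

    The Euclidean distance matrix over the scores on the first ``n_pcs``
    PCs is clustered by complete linkage and the tree cut into K groups.
    """
    scores = projections.scores[:, :n_pcs]
    F = scores.shape[0]
    if K > F:
        raise ValueError(f"cannot form {K} clusters from {F} frames")
    tree = linkage(pdist(scores), method="complete")
    labels = fcluster(tree, t=K, criterion="maxclust")
    return ClusterAssignment(labels=labels, linkage_tree=tree, K=K)


def rmsf(ensemble: Ensemble | np.ndarray) -> np.ndarray:
    """Per-position root-mean-square fluctuation about the mean (Å)."""
    frames = _frames_of(ensemble)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames for fluctuations")
    dev = frames - frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


def bfactor_correlation(profile: np.ndarray,
                        bfactors: np.ndarray) -> float:
    """Squared Pearson correlation of B-factors with RMSF².

    Compared on the linear B-vs-RMSF² scale (B = 8π²/3 · RMSF² for an
    isotropic harmonic model).  Returns NaN with a warning when either
    profile is constant.
    """
    x = np.asarray(profile, dtype=float) ** 2
    y = np.asarray(bfactors, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant profile: B-factor correlation undefined")
        return float("nan")
    r, _ = pearsonr(x, y)
    return float(r ** 2)


def porcupine_pdb(model: PCAModel, pc: int, path,
                  n_steps: int = 11, amplitude: float = 2.0) -> None:
    """Write a multi-model PDB interpolating along one PC.

    Frames sweep the mean conformation from −amplitude to +amplitude
    standard deviations along the chosen component, for visualizing the
    collective motion in a molecular viewer.
    """
    from .ensemble_io import CoordinateEnsemble, write_ensemble_pdb
    sd = float(np.sqrt(model.eigenvalues[pc]))
    steps = np.linspace(-amplitude, amplitude, n_steps)
    X = model.mean + np.outer(steps * sd, model.eigenvectors[:, pc])
    ens = CoordinateEnsemble(
        frames=X.reshape(n_steps, model.n_positions, 3),
        labels=[float(s) for s in steps])
    write_ensemble_pdb(ens, path)


def subspace_overlap(model_a: PCAModel, model_b: PCAModel,
                     K: int, n_ref: int = 2) -> float:
    """Average cumulative squared inner product between PC subspaces.

    Mean, over model_a's first ``n_ref`` PCs, of the cumulative squared
    projections onto model_b's first K eigenvectors.  Monotone
    non-decreasing in K and equal to 1 at K = 3N.
    """
    if model_a.eigenvectors.shape[0] != model_b.eigenvectors.shape[0]:
        raise ValueError("models live in different coordinate dimensions")
    A = model_a.eigenvectors[:, :n_ref]
    B = model_b.eigenvectors[:, :K]
    return float(np.mean(np.sum((A.T @ B) ** 2, axis=1)))
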