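"""Rigid-body superposition and invariant-core identification.

Least-squares superposition uses the Kabsch algorithm (SVD with a
reflection guard).  The structurally invariant core is found by iterated
rounds of superposition, excluding before each round the positions with the
largest interconformer positional variance, measured as the volume of the
ellipsoid spanned by the standard deviations of each position's coordinate
scatter along its three principal axes, until every remaining position's
ellipsoid is smaller than a volume threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble_io import CoordinateEnsemble

__all__ = [
    "CoreSelection",
    "SuperposedEnsemble",
    "kabsch",
    "superpose",
    "rmsd",
    "fit_ensemble",
    "find_invariant_core",
]


@dataclass
class CoreSelection:
    """Invariant-core column indices with the per-iteration history."""

    columns: np.ndarray
    history: list[dict] = field(default_factory=list)
    # each history entry: {"excluded": [...], "max_volume": float,
    #                      "n_remaining": int}

    def __len__(self) -> int:
        return len(self.columns)

    def to_tsv(self, path: str | Path,
               residue_numbers: np.ndarray | None = None) -> None:
        lines = ["column\tresidue"]
        for c in self.columns:
            res = "" if residue_numbers is None else str(residue_numbers[c])
            lines.append(f"{c}\t{res}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SuperposedEnsemble:
    """A coordinate ensemble after least-squares fitting onto a reference."""

    ensemble: CoordinateEnsemble
    reference: int
    subset: np.ndarray

    @property
    def frames(self) -> np.ndarray:
        return self.ensemble.frames

    @property
    def atom_frames(self) -> dict[str, np.ndarray]:
        return self.ensemble.atom_frames

    @property
    def labels(self) -> list:
        return self.ensemble.labels

    @property
    def n_frames(self) -> int:
        return self.ensemble.n_frames

    @property
    def n_positions(self) -> int:
        return self.ensemble.n_positions

    @property
    def dt(self) -> float | None:
        return self.ensemble.dt


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids aligning mobile onto reference.

    Returns ``(R, mobile_centroid, reference_centroid)`` such that
    ``(x - mobile_centroid) @ R.T + reference_centroid`` is the fitted
    position of any point ``x``.  Handles the improper-rotation case by
    flipping the singular direction with the smallest singular value.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for a determined rotation")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("points are collinear: rotation underdetermined")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cp, cq


def rmsd(a: np.ndarray, b: np.ndarray,
         subset: np.ndarray | None = None) -> float:
    """Root-mean-square deviation between two frames over a subset."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if subset is not None:
        a, b = a[subset], b[subset]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset: np.ndarray | None = None,
    report_subset: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares fit of a mobile frame onto a reference over a subset.

    The rigid transformation is determined on ``subset`` (all positions by
    default) and applied to the whole frame; the returned RMSD is computed
    over ``report_subset`` if given, else over the fitting subset.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if subset is None:
        subset = np.arange(len(mobile))
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("fitting subset is empty")
    R, cp, cq = kabsch(mobile[subset], reference[subset])
    fitted = (mobile - cp) @ R.T + cq
    rs = subset if report_subset is None else np.asarray(report_subset)
    return fitted, rmsd(fitted, reference, rs)


def fit_ensemble(
    ensemble: CoordinateEnsemble,
    selection: np.ndarray | None = None,
    reference: int = 0,
) -> SuperposedEnsemble:
    """Superpose every frame of an ensemble onto a reference frame.

    The transformation determined on the Cα ``selection`` is applied to all
    atom layers so side-chain pseudo-atoms stay consistent.  Idempotent:
    refitting a fitted ensemble moves no coordinate by more than 1e-6 Å.
    """
    if selection is None:
        selection = np.arange(ensemble.n_positions)
    selection = np.asarray(selection, dtype=int)
    ref = ensemble.frames[reference]
    new_atoms = {k: v.copy() for k, v in ensemble.atom_frames.items()}
    new_frames = new_atoms["CA"]
    for f in range(ensemble.n_frames):
        R, cp, cq = kabsch(ensemble.frames[f][selection], ref[selection])
        for arr in new_atoms.values():
            arr[f] = (arr[f] - cp) @ R.T + cq
    fitted = CoordinateEnsemble(
        frames=new_frames,
        labels=list(ensemble.labels),
        residue_numbers=ensemble.residue_numbers,
        residue_names=ensemble.residue_names,
        atom_frames=new_atoms,
        regions=dict(ensemble.regions),
        bfactors=ensemble.bfactors,
        dt=ensemble.dt,
    )
    return SuperposedEnsemble(ensemble=fitted, reference=reference,
                              subset=selection)


def _ellipsoid_volumes(frames: np.ndarray) -> np.ndarray:
    """Per-position variance-ellipsoid volume (Å³).

    For each position, the 3×3 covariance of its coordinate scatter across
    frames is diagonalized; the volume is 4π/3 times the product of the
    standard deviations along the three principal axes.
    """
    mean = frames.mean(axis=0)
    dev = frames - mean
    # per-position covariance: (N, 3, 3)
    cov = np.einsum("fni,fnj->nij", dev, dev) / frames.shape[0]
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    return (4.0 * np.pi / 3.0) * np.prod(np.sqrt(eig), axis=1)


def find_invariant_core(
    ensemble: CoordinateEnsemble,
    stop_volume: float = 0.5,
    target_size: int | None = None,
    drop_fraction: float = 0.1,
) -> CoreSelection:
    """Iterated-superposition identification of the invariant core.

    Each round fits all frames onto their mean over the current candidate
    set, measures every candidate position's variance-ellipsoid volume, and
    drops the worst batch (the top ``drop_fraction`` of candidates above
    threshold, at least one).  Iteration stops when every remaining volume
    is below ``stop_volume`` Å³, or when the candidate set has shrunk to
    ``target_size`` if one is given.  Raises if the criterion cannot be met
    before fewer than 3 positions remain, attaching the history.
    """
    if ensemble.n_frames < 3:
        raise ValueError("need at least 3 frames to define a core")
    candidates = np.arange(ensemble.n_positions)
    history: list[dict] = []

    while True:
        fitted = _mean_fit(ensemble.frames, candidates)
        volumes = _ellipsoid_volumes(fitted[:, candidates])
        max_vol = float(volumes.max())
        if target_size is not None:
            done = len(candidates) <= target_size
        else:
            done = max_vol <= stop_volume
        if done:
            history.append({"excluded": [], "max_volume": max_vol,
                            "n_remaining": len(candidates)})
            return CoreSelection(columns=candidates, history=history)
        n_above = int(np.sum(volumes > stop_volume)) or 1
        n_drop = max(1, min(n_above,
                            int(np.ceil(drop_fraction * len(candidates)))))
        if target_size is not None:
            n_drop = min(n_drop, len(candidates) - target_size)
            n_drop = max(n_drop, 1)
        order = np.argsort(volumes)[::-1]
        dropped = candidates[order[:n_drop]]
        history.append({
            "excluded": sorted(int(c) for c in dropped),
            "max_volume": max_vol,
            "n_remaining": len(candidates) - n_drop,
        })
        keep = np.ones(len(candidates), dtype=bool)
        keep[order[:n_drop]] = False
        candidates = candidates[keep]
        if len(candidates) < 3:
            err = ValueError(
                "stop criterion unreachable: fewer than 3 candidate "
                "positions remain")
            err.history = history  # type: ignore[attr-defined]
            raise err


def _mean_fit(frames: np.ndarray, subset: np.ndarray,
              n_iter: int = 2) -> np.ndarray:
    """Fit all frames onto the (iteratively refined) mean over a subset."""
    ref = frames[0]
    fitted = frames
    for _ in range(n_iter):
        out = np.empty_like(frames)
        for f in range(frames.shape[0]):
            R, cp, cq = kabsch(fitted[f][subset], ref[subset])
            out[f] = (fitted[f] - cp) @ R.T + cq
        fitted = out
        ref = fitted.mean(axis=0)
    return fitted
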