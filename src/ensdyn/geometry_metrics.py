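"""Geometric order parameters for motor-domain conformational states.

Implements the order parameters used to characterise the α4 subdomain and
neck-linker: the protrusion of a helical subdomain from the core measured
as the distance between the centres of mass of two residue selections and
the angle between their dominant principal axes; neck-linker docking calls
from a set of monitored Cβ–Cβ pair distances against a cutoff; generic
minimum heavy-atom interaction traces (latch residues, salt bridges); and
a per-residue secondary-structure trace with a pluggable backend (built-in
φ/ψ heuristic by default, any external assigner via callback).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .core_fit import SuperposedEnsemble
from .ensemble_io import CoordinateEnsemble

__all__ = [
    "ProtrusionTrace",
    "DockingTrace",
    "protrusion",
    "docking_state",
    "interaction_trace",
    "secondary_structure_trace",
]

Ensemble = CoordinateEnsemble | SuperposedEnsemble


@dataclass
class ProtrusionTrace:
    distance: np.ndarray     # (F,) Å between selection centres of mass
    angle: np.ndarray        # (F,) degrees, folded to [0, 90]
    sel_a: np.ndarray
    sel_b: np.ndarray


@dataclass
class DockingTrace:
    distances: np.ndarray                 # (F, n_pairs) Å
    docked: np.ndarray                    # (F,) bool
    pairs: list[tuple[int, int, str]]
    cutoff: float
    first_undocked: int | None = None


def _frames(x: Ensemble | np.ndarray) -> np.ndarray:
    return x if isinstance(x, np.ndarray) else x.frames


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant principal axis of a point cloud (unit vector)."""
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[0]


def protrusion(ensemble: Ensemble | np.ndarray,
               sel_a: Sequence[int], sel_b: Sequence[int]) -> ProtrusionTrace:
    """Distance and angle between two residue selections per frame.

    Distance is between the uniform-mass Cα centres of mass; the angle is
    between the dominant principal axes of the two selections' Cα scatter
    in each frame, folded below 90° (axis sign is arbitrary).  Both are
    invariant under global rigid motion of the frame.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) < 3 or len(sel_b) < 3:
        raise ValueError("selections need at least 3 residues to define an axis")
    frames = _frames(ensemble)
    F = frames.shape[0]
    dist = np.empty(F)
    angle = np.empty(F)
    for f in range(F):
        a, b = frames[f, sel_a], frames[f, sel_b]
        dist[f] = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        cosang = abs(float(_principal_axis(a) @ _principal_axis(b)))
        angle[f] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ProtrusionTrace(distance=dist, angle=angle,
                           sel_a=sel_a, sel_b=sel_b)


def docking_state(ensemble: Ensemble,
                  pairs: list[tuple[int, int, str]],
                  cutoff: float = 8.0) -> DockingTrace:
    """Docked/undocked call from monitored atom-pair distances.

    Each pair is (position i, position j, atom name); the named atom
    defaults to Cβ with a Cα fallback where the side-chain atom is absent
    (glycine).  A frame is docked iff every monitored distance is below
    the cutoff; the first undocked frame is reported (None when always
    docked).  Raising the cutoff can only turn undocked calls docked.
    """
    atom_frames = ensemble.atom_frames
    ca = atom_frames["CA"]
    F = ca.shape[0]
    dists = np.empty((F, len(pairs)))
    for p, (i, j, atom) in enumerate(pairs):
        for idx in (i, j):
            if idx >= ca.shape[1]:
                raise ValueError(f"residue index {idx} out of range")
        A = atom_frames.get(atom, ca)[:, i]
        B = atom_frames.get(atom, ca)[:, j]
        A = np.where(np.isfinite(A), A, ca[:, i])
        B = np.where(np.isfinite(B), B, ca[:, j])
        dists[:, p] = np.linalg.norm(A - B, axis=1)
    docked = (dists < cutoff).all(axis=1)
    undocked_frames = np.flatnonzero(~docked)
    first = int(undocked_frames[0]) if undocked_frames.size else None
    return DockingTrace(distances=dists, docked=docked, pairs=list(pairs),
                        cutoff=cutoff, first_undocked=first)


def interaction_trace(
    ensemble: Ensemble,
    groups: list[Sequence[int]],
    cutoff: float = 4.5,
) -> dict[tuple[int, int], dict]:
    """Minimum heavy-atom distance traces between residue groups.

    For every pair of groups, the per-frame minimum distance over all
    heavy-atom layers and group members, plus the fraction of frames in
    which the interaction is formed at the given cutoff.
    """
    atom_frames = ensemble.atom_frames
    layers = [atom_frames[k] for k in sorted(atom_frames)]
    F = layers[0].shape[0]
    out: dict[tuple[int, int], dict] = {}
    for ga, gb in combinations(range(len(groups)), 2):
        mind = np.full(F, np.inf)
        for A in layers:
            for B in layers:
                for i in groups[ga]:
                    for j in groups[gb]:
                        d = np.linalg.norm(A[:, i] - B[:, j], axis=1)
                        np.fmin(mind, d, out=mind)
        out[(ga, gb)] = {
            "distance": mind,
            "formed_fraction": float(np.mean(mind < cutoff)),
        }
    return out


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3):
    """Signed dihedral in degrees, IUPAC convention."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    c1 = np.cross(b2, b3)
    c2 = np.cross(b1, b2)
    p = np.sum(b1 * c1, axis=-1) * np.linalg.norm(b2, axis=-1)
    q = np.sum(c1 * c2, axis=-1)
    return np.degrees(np.arctan2(p, q))


def _phi_psi(atom_frames: dict[str, np.ndarray]
             ) -> tuple[np.ndarray, np.ndarray]:
    """Backbone φ/ψ per frame per residue (NaN at chain termini)."""
    for name in ("N", "CA", "C"):
        if name not in atom_frames:
            raise ValueError(f"backbone atom {name} missing")
    N, CA, C = atom_frames["N"], atom_frames["CA"], atom_frames["C"]
    F, n = CA.shape[:2]
    phi = np.full((F, n), np.nan)
    psi = np.full((F, n), np.nan)
    phi[:, 1:] = _dihedral(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
    psi[:, :-1] = _dihedral(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    return phi, psi


def _builtin_assign(atom_frames: dict[str, np.ndarray]) -> np.ndarray:
    """φ/ψ-region secondary-structure heuristic, refined by O···N contacts.

    Helix: φ ∈ (−120°, −30°) and ψ ∈ (−77°, −7°), widened to the i→i+4
    O···N hydrogen-bond geometry where carbonyl oxygens are available;
    strand: φ ∈ (−180°, −45°) and ψ ∈ (90°, 180°] or ψ < −150°.
    Residues lacking backbone atoms are left unassigned ('C').
    """
    phi, psi = _phi_psi(atom_frames)
    F, n = phi.shape
    ss = np.full((F, n), "C", dtype="<U1")
    helix = (phi > -120) & (phi < -30) & (psi > -77) & (psi < -7)
    strand = (phi > -180) & (phi < -45) & ((psi > 90) | (psi < -150))
    ss[np.where(strand)] = "E"
    ss[np.where(helix)] = "H"
    if "O" in atom_frames and "N" in atom_frames and n > 4:
        O, Nn = atom_frames["O"], atom_frames["N"]
        hb = np.linalg.norm(O[:, :-4] - Nn[:, 4:], axis=2) < 3.5
        for off in range(1, 4):  # residues spanned by an i→i+4 H-bond
            seg = np.zeros((F, n), dtype=bool)
            seg[:, off:n - 4 + off] = hb
            ss[seg & (ss == "C") & (phi < 0)] = "H"
    # terminal residues inherit their neighbour's class when undefined
    ss[:, 0] = ss[:, 1]
    ss[:, -1] = ss[:, -2]
    return ss


def secondary_structure_trace(
    ensemble: Ensemble,
    backend: str | Callable[[dict[str, np.ndarray]], np.ndarray] = "builtin",
    regions: dict[str, Sequence[int]] | None = None,
) -> dict:
    """Per-frame per-residue secondary-structure classes (H/E/C).

    ``backend`` may be "builtin" (φ/ψ + O···N heuristic) or a callable
    receiving the backbone atom layers and returning an (F, N) class
    array — the hook for an external assigner.  When ``regions`` are
    given, per-region content fractions over time are summarised.
    """
    atom_frames = (ensemble.atom_frames
                   if not isinstance(ensemble, np.ndarray) else
                   {"CA": ensemble})
    if callable(backend):
        classes = np.asarray(backend(atom_frames))
    elif backend == "builtin":
        classes = _builtin_assign(atom_frames)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    result: dict = {"classes": classes}
    if regions:
        content: dict[str, dict[str, np.ndarray]] = {}
        for name, cols in regions.items():
            cols = np.asarray(cols, dtype=int)
            sub = classes[:, cols]
            content[name] = {
                kind: (sub == kind).mean(axis=1)
                for kind in ("H", "E", "C")
            }
        result["region_content"] = content
    return result
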