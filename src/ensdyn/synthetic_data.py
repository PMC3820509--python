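"""Synthetic ensembles and trajectories with known statistical structure.

Every analysis stage is exercisable without downloads through three
generators: Gaussian conformer ensembles drawn around a mean structure
with a prescribed low-rank covariance; two-state switching trajectories
with known transition times between reference conformations plus isotropic
noise; and trajectories with block-structured residue-residue correlation
(known community partition).  All generators are seed-deterministic and
emit their ground truth machine-readably next to the data.

The toy structures are small idealized helix/strand/linker constructs with
labeled subsets named after the motor-domain elements (α4, β3, loop8,
neck-linker, ...) so the kinesin-recipe configurations run unchanged on
synthetic data.  One Cβ-like pseudo-atom per residue at fixed local
geometry supports the contact and docking operators; no physical force
field or thermodynamic realism is claimed — statistical structure only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble_io import CoordinateEnsemble

__all__ = [
    "GeneratorSpec",
    "toy_structure",
    "toy_two_state",
    "build_backbone",
    "gaussian_ensemble",
    "switching_trajectory",
    "block_correlated_trajectory",
]


@dataclass
class GeneratorSpec:
    """Bundle of generator parameters; same seed ⇒ identical output."""

    seed: int = 0
    mean: np.ndarray | None = None                 # (N, 3)
    modes: np.ndarray | None = None                # (K, 3N)
    variances: np.ndarray | None = None            # (K,), Å²
    noise: float = 0.0                             # isotropic σ, Å
    states: list | None = None                     # CoordinateEnsembles
    schedule: list[tuple[int, int]] | None = None  # (state, n_frames)
    blocks: list[np.ndarray] | None = None         # partition of positions
    intra: float = 0.8
    inter: float = 0.0
    dt: float | None = None                        # ns per frame

    def __post_init__(self) -> None:
        if self.variances is not None:
            self.variances = np.asarray(self.variances, dtype=float)
            if (self.variances <= 0).any():
                raise ValueError("mode variances must be positive")
        for name, val in (("intra", self.intra), ("inter", self.inter)):
            if not -1.0 <= val <= 1.0:
                raise ValueError(f"{name} correlation target outside [-1, 1]")
        if self.schedule is not None:
            if any(n < 1 for _, n in self.schedule):
                raise ValueError("dwell times must be at least 1 frame")


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_SEGMENTS = [
    # (name, kind, length)
    ("beta1", "strand", 6),
    ("loop1", "coil", 3),
    ("P-loop", "coil", 6),
    ("SI", "coil", 6),
    ("SII", "coil", 6),
    ("beta3", "strand", 8),
    ("loop8", "coil", 5),
    ("alpha4", "helix", 12),
    ("loop13", "coil", 4),
    ("alpha6", "helix", 8),
    ("neck", "coil", 8),
]

_REF = np.array([0.30, 0.60, 0.74])  # fixed side-chain offset reference


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _segment_coords(kind: str, n: int, com: np.ndarray,
                    direction: np.ndarray) -> np.ndarray:
    """Cα trace of one idealized segment, recentred on the requested COM."""
    d = _unit(np.asarray(direction, dtype=float))
    perp1 = _unit(np.cross(d, _REF))
    perp2 = np.cross(d, perp1)
    t = np.arange(n, dtype=float)
    if kind == "helix":  # 1.5 Å rise, 100° twist, 2.3 Å radius
        ang = np.radians(100.0) * t
        xyz = (np.outer(1.5 * t, d)
               + 2.3 * np.outer(np.cos(ang), perp1)
               + 2.3 * np.outer(np.sin(ang), perp2))
    elif kind == "strand":  # 3.3 Å rise with alternating 0.5 Å pleat
        xyz = np.outer(3.3 * t, d) + np.outer(0.5 * (-1.0) ** t, perp2)
    else:  # coil: 3.6 Å spacing with a gentle sinusoidal wiggle
        xyz = (np.outer(3.6 * t, d)
               + 0.8 * np.outer(np.sin(0.9 * t), perp1)
               + 0.8 * np.outer(np.cos(0.9 * t), perp2))
    return xyz - xyz.mean(axis=0) + np.asarray(com, dtype=float)


def toy_structure(
    alpha4_distance: float = 16.0,
    alpha4_angle: float = 65.0,
    neck_docked: bool = True,
) -> CoordinateEnsemble:
    """Idealized 72-residue motor-domain-like construct (one frame).

    ``alpha4_distance`` and ``alpha4_angle`` place the α4 helix relative to
    the β3 strand (COM separation in Å, angle between segment axes in
    degrees); ``neck_docked`` lays the neck-linker alongside α4 or swings
    it 25 Å away.  Regions are labeled; one glycine (no Cβ) sits at the
    start of loop1 to exercise side-chain fallbacks.
    """
    th = np.radians(alpha4_angle)
    a4_dir = np.array([np.cos(th), 0.0, np.sin(th)])
    a4_com = np.array([0.0, alpha4_distance, 0.0])  # beta3 COM is origin
    neck_com = a4_com + np.array([2.0, 5.0, 0.0])
    if not neck_docked:
        neck_com = neck_com + np.array([0.0, 25.0, 0.0])
    placements = {
        "beta1": (np.array([0.0, -4.3, 0.0]), np.array([1.0, 0.0, 0.0])),
        "loop1": (np.array([14.0, -4.3, 1.0]), np.array([1.0, 0.2, 0.0])),
        "P-loop": (np.array([20.0, -2.0, 1.0]), np.array([1.0, 0.5, 0.0])),
        "SI": (np.array([24.0, 3.0, 2.0]), np.array([0.2, 1.0, 0.0])),
        "SII": (np.array([20.0, 8.0, -2.0]), np.array([-1.0, 0.3, 0.0])),
        "beta3": (np.zeros(3), np.array([1.0, 0.0, 0.0])),
        "loop8": (np.array([16.0, 3.0, 0.0]), np.array([1.0, 1.0, 0.0])),
        "alpha4": (a4_com, a4_dir),
        # loop13 sits beside the docked neck-linker groove next to α4
        "loop13": (a4_com + np.array([2.0, 5.0, 2.0]),
                   np.array([1.0, -0.3, 0.0])),
        "alpha6": (np.array([6.0, 8.0, -7.0]), np.array([1.0, 0.0, 0.0])),
        "neck": (neck_com, a4_dir),
    }
    coords, names, regions = [], [], {}
    idx = 0
    for name, kind, n in _SEGMENTS:
        com, direction = placements[name]
        coords.append(_segment_coords(kind, n, com, direction))
        regions[name] = np.arange(idx, idx + n)
        names.extend(["ALA"] * n)
        idx += n
    ca = np.concatenate(coords)
    names[regions["loop1"][0]] = "GLY"

    # Cβ pseudo-atom: 1.5 Å off the local chain direction; NaN for glycine
    cb = np.full_like(ca, np.nan)
    for i in range(len(ca)):
        if names[i] == "GLY":
            continue
        lo, hi = max(i - 1, 0), min(i + 1, len(ca) - 1)
        d = _unit(ca[hi] - ca[lo])
        cb[i] = ca[i] + 1.5 * _unit(np.cross(d, _REF))

    return CoordinateEnsemble(
        frames=ca[None],
        labels=["toy"],
        residue_numbers=np.arange(1, len(ca) + 1),
        residue_names=names,
        atom_frames={"CA": ca[None], "CB": cb[None]},
        regions=regions,
    )


def toy_two_state() -> tuple[CoordinateEnsemble, CoordinateEnsemble]:
    """α4-"up" (docked neck) and α4-"down" (undocked) toy conformations."""
    up = toy_structure(alpha4_distance=16.0, alpha4_angle=65.0,
                       neck_docked=True)
    down = toy_structure(alpha4_distance=13.0, alpha4_angle=50.0,
                         neck_docked=False)
    return up, down


# ---------------------------------------------------------------------------
# Backbone builder (for secondary-structure tests)
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _place(a, b, c, bond, angle, torsion):
    angle, torsion = np.radians(angle), np.radians(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(torsions: list[tuple[float, float]],
                   omega: float = 180.0) -> dict[str, np.ndarray]:
    """Ideal-geometry backbone (N, CA, C, O) from a φ/ψ list.

    Sequential natural-extension construction with standard bond lengths
    and angles; returns atom layers of shape (1, n, 3).  The first φ and
    last ψ are consumed only through the carbonyl placement.
    """
    n = len(torsions)
    if n < 2:
        raise ValueError("need at least two residues")
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND["N-CA"], 0.0, 0.0)
    ang = np.radians(_ANGLE["N-CA-C"])
    C[0] = CA[0] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n - 1):
        psi = torsions[i][1]
        N[i + 1] = _place(N[i], CA[i], C[i], _BOND["C-N"],
                          _ANGLE["CA-C-N"], psi)
        CA[i + 1] = _place(CA[i], C[i], N[i + 1], _BOND["N-CA"],
                           _ANGLE["C-N-CA"], omega)
        C[i + 1] = _place(C[i], N[i + 1], CA[i + 1], _BOND["CA-C"],
                          _ANGLE["N-CA-C"], torsions[i + 1][0])
        O[i] = _place(N[i], CA[i], C[i], _BOND["C-O"],
                      _ANGLE["CA-C-O"], psi + 180.0)
    O[-1] = _place(N[-1], CA[-1], C[-1], _BOND["C-O"],
                   _ANGLE["CA-C-O"], torsions[-1][1] + 180.0)
    return {"N": N[None], "CA": CA[None], "C": C[None], "O": O[None]}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _orthonormalize(modes: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(modes.T)
    return q.T[:modes.shape[0]]


def gaussian_ensemble(spec: GeneratorSpec, F: int) -> CoordinateEnsemble:
    """Conformers drawn around a mean with a prescribed low-rank covariance.

    frames = mean + Σ_k z_k · mode_k + ε with z_k ~ N(0, var_k) and ε an
    isotropic N(0, noise²) perturbation; modes are orthonormalized, so the
    population covariance is Σ_k var_k m_k m_kᵀ + noise² I analytically.
    """
    if F < 2:
        raise ValueError("need F >= 2 frames")
    if spec.mean is None or spec.modes is None or spec.variances is None:
        raise ValueError("gaussian_ensemble needs mean, modes and variances")
    mean = np.asarray(spec.mean, dtype=float)
    N = mean.shape[0]
    modes = _orthonormalize(np.asarray(spec.modes, dtype=float))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((F, len(modes))) * np.sqrt(spec.variances)
    X = mean.reshape(-1) + z @ modes
    if spec.noise > 0:
        X = X + spec.noise * rng.standard_normal(X.shape)
    frames = X.reshape(F, N, 3)
    return CoordinateEnsemble(
        frames=frames,
        labels=list(range(F)),
        residue_numbers=np.arange(1, N + 1),
        dt=spec.dt,
    )


def switching_trajectory(spec: GeneratorSpec, F: int
                         ) -> tuple[CoordinateEnsemble, dict]:
    """Piecewise-constant switching between reference conformations.

    The state follows the dwell ``schedule`` (list of (state index,
    n_frames) covering at least F frames); coordinates are the state
    conformation plus isotropic Gaussian noise, for the Cα layer and every
    side-chain pseudo-atom layer alike.  Ground truth — transition frames,
    the per-frame state, and each state's Cα/Cβ contact map at 4.5 Å — is
    returned alongside the data.
    """
    if spec.states is None or len(spec.states) < 2:
        raise ValueError("need at least 2 state conformations")
    if spec.schedule is None:
        raise ValueError("a dwell schedule is required")
    total = sum(n for _, n in spec.schedule)
    if total < F:
        raise ValueError(f"schedule covers {total} frames < F = {F}")
    state_of_frame = np.concatenate([
        np.full(n, s, dtype=int) for s, n in spec.schedule])[:F]
    transitions = (np.flatnonzero(np.diff(state_of_frame) != 0) + 1).tolist()

    ref = spec.states[0]
    layers = {k: [] for k in ref.atom_frames}
    rng = np.random.default_rng(spec.seed)
    for k in sorted(layers):
        stacked = np.stack([s.atom_frames[k][0] for s in spec.states])
        per_frame = stacked[state_of_frame]
        noise = spec.noise * rng.standard_normal(per_frame.shape)
        layer = per_frame + np.where(np.isfinite(per_frame), noise, 0.0)
        layers[k] = layer

    truth = {
        "transitions": transitions,
        "state_of_frame": state_of_frame.tolist(),
        "contact_maps": [
            _contact_map(s).tolist() for s in spec.states],
    }
    ens = CoordinateEnsemble(
        frames=layers["CA"],
        labels=list(range(F)),
        residue_numbers=ref.residue_numbers,
        residue_names=ref.residue_names,
        atom_frames=layers,
        regions=dict(ref.regions),
        dt=spec.dt,
    )
    return ens, truth


def _contact_map(structure: CoordinateEnsemble, cutoff: float = 4.5,
                 exclude_neighbors: int = 1) -> np.ndarray:
    layers = [structure.atom_frames[k][0] for k in
              sorted(structure.atom_frames)]
    N = layers[0].shape[0]
    mind = np.full((N, N), np.inf)
    for A in layers:
        for B in layers:
            d = np.sqrt(((A[:, None] - B[None]) ** 2).sum(axis=2))
            np.fmin(mind, d, out=mind)
    adj = mind < cutoff
    idx = np.arange(N)
    adj &= np.abs(idx[:, None] - idx[None]) > exclude_neighbors
    return adj


def block_correlated_trajectory(spec: GeneratorSpec, F: int,
                                amplitude: float = 0.3
                                ) -> tuple[CoordinateEnsemble, dict]:
    """Trajectory whose DCCM has a prescribed block structure.

    Position i of block b is displaced by
    ``amplitude · (√ρ_b L_b + √(1−ρ_b) ε_i)`` per frame, with block latent
    3-vectors L_b and independent ε_i all standard normal, so the expected
    Cα cross-correlation is ``intra`` within blocks; with ``inter`` > 0 the
    block latents share a global latent giving inter-block correlation
    ``inter`` exactly.  Infeasible targets (inter > intra, |intra| > 1)
    raise with the feasible bound.  The mean structure defaults to stacked
    β-hairpin blocks whose cross-strand contacts make each block a
    connected component of the 4.5 Å contact graph — the ground-truth
    partition, returned alongside.
    """
    if spec.blocks is None:
        raise ValueError("block partition required")
    blocks = [np.asarray(b, dtype=int) for b in spec.blocks]
    intra, inter = spec.intra, spec.inter
    if not 0.0 <= intra <= 1.0:
        raise ValueError("feasible intra-block target is [0, 1]")
    if inter > intra:
        raise ValueError(
            f"inter-block target {inter} exceeds the feasible bound "
            f"intra = {intra}")
    if spec.mean is not None:
        mean_ca = np.asarray(spec.mean, dtype=float)
        mean_cb = None
    else:
        mean_ca, mean_cb = _hairpin_blocks(blocks)
    N = mean_ca.shape[0]
    covered = np.sort(np.concatenate(blocks))
    if not np.array_equal(covered, np.arange(N)):
        raise ValueError("blocks must partition all positions")

    rng = np.random.default_rng(spec.seed)
    share = 0.0 if intra == 0 else inter / intra
    g = rng.standard_normal((F, 1, 3))
    disp = np.empty((F, N, 3))
    for b, members in enumerate(blocks):
        hb = rng.standard_normal((F, 1, 3))
        latent = np.sqrt(share) * g + np.sqrt(1.0 - share) * hb
        eps = rng.standard_normal((F, len(members), 3))
        disp[:, members] = (np.sqrt(intra) * latent
                            + np.sqrt(1.0 - intra) * eps)
    frames = mean_ca + amplitude * disp
    atom_frames = {"CA": frames}
    if mean_cb is not None:
        atom_frames["CB"] = mean_cb + amplitude * disp
    truth = {
        "blocks": [b.tolist() for b in blocks],
        "intra": intra,
        "inter": inter,
        "adjacency": _mean_adjacency(mean_ca, mean_cb).tolist(),
    }
    ens = CoordinateEnsemble(
        frames=frames,
        labels=list(range(F)),
        residue_numbers=np.arange(1, N + 1),
        atom_frames=atom_frames,
        dt=spec.dt,
    )
    return ens, truth


def _hairpin_blocks(blocks: list[np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Stacked β-hairpin mean structure: one hairpin per block.

    Within a block, the first half runs +x and the second half returns −x
    at 3.3 Å cross-strand separation with a 2.6 Å rise, so both direct
    and diagonal cross-strand pairs sit inside the 4.5 Å contact cutoff
    with ≥ 0.3 Å margin — each block is a connected component of the
    contact graph.  Blocks are stacked 20 Å apart in z, giving zero
    inter-block contacts.
    """
    N = sum(len(b) for b in blocks)
    ca = np.zeros((N, 3))
    for b, members in enumerate(blocks):
        n = len(members)
        half = (n + 1) // 2
        for k, pos in enumerate(members):
            if k < half:
                ca[pos] = (2.6 * k, 0.0, 20.0 * b)
            else:
                ca[pos] = (2.6 * (n - 1 - k), 3.3, 20.0 * b)
    cb = ca + np.array([0.0, 0.0, 1.5])
    return ca, cb


def _mean_adjacency(mean_ca, mean_cb, cutoff: float = 4.5,
                    exclude_neighbors: int = 1) -> np.ndarray:
    layers = [mean_ca] if mean_cb is None else [mean_ca, mean_cb]
    N = mean_ca.shape[0]
    mind = np.full((N, N), np.inf)
    for A in layers:
        for B in layers:
            d = np.sqrt(((A[:, None] - B[None]) ** 2).sum(axis=2))
            np.fmin(mind, d, out=mind)
    adj = mind < cutoff
    idx = np.arange(N)
    adj &= np.abs(idx[:, None] - idx[None]) > exclude_neighbors
    return adj


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Write generator ground truth as JSON next to the data."""
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))
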