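"""Dynamical cross-correlation matrices and weighted residue networks.

The cross-correlation coefficient for Cα atoms i and j is

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)

with Δr_i the displacement from the mean position over the trajectory
segment analysed.  A weighted graph is built with one node per residue and
an edge wherever two residues' closest heavy atoms are within 4.5 Å for at
least 75% of frames; edge lengths are w_ij = −log|C_ij| so strongly
correlated contacts are short.  Communities are found by Girvan–Newman
edge-betweenness removal at maximum modularity; node betweenness over the
weighted shortest paths ranks residues mediating inter-community coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .core_fit import SuperposedEnsemble
from .ensemble_io import CoordinateEnsemble

__all__ = [
    "DCCM",
    "ContactAdjacency",
    "DynamicNetwork",
    "PathSet",
    "dccm",
    "contact_adjacency",
    "build_network",
    "detect_communities",
    "betweenness_and_critical_nodes",
    "paths",
]

Ensemble = CoordinateEnsemble | SuperposedEnsemble

#: |C| floor below which edge weights are capped (w_max = −log(floor) ≈ 13.8)
CORRELATION_FLOOR = 1e-6


def _frames_of(x):
    return x if isinstance(x, np.ndarray) else x.frames


@dataclass
class DCCM:
    """Symmetric residue-residue correlation matrix in [−1, 1]."""

    matrix: np.ndarray
    segment: str = "full"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("DCCM must be square")
        finite = np.isfinite(m)
        if not np.allclose(m[finite & finite.T],
                           m.T[finite & finite.T], atol=1e-8):
            raise ValueError("DCCM must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, delimiter="\t", fmt="%.6f")


@dataclass
class ContactAdjacency:
    matrix: np.ndarray          # (N, N) bool
    cutoff: float = 4.5
    occupancy: float = 0.75

    def __post_init__(self) -> None:
        m = self.matrix
        if not (m == m.T).all() or m.diagonal().any():
            raise ValueError("adjacency must be symmetric with zero diagonal")


@dataclass
class DynamicNetwork:
    """Contact-filtered weighted residue graph with analysis annotations."""

    graph: nx.Graph
    partition: list[set[int]] | None = None
    betweenness: dict[int, float] | None = None
    critical_nodes: list[int] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def community_of(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for k, comm in enumerate(self.partition or []):
            for node in comm:
                out[node] = k
        return out

    def to_edge_tsv(self, path: str | Path) -> None:
        comm = self.community_of()
        eb = self.betweenness or {}
        lines = ["node_i\tnode_j\tcorr\tweight\tcommunity_i\tcommunity_j"]
        for u, v, d in sorted(self.graph.edges(data=True)):
            lines.append(
                f"{u}\t{v}\t{d['corr']:.6f}\t{d['weight']:.6f}"
                f"\t{comm.get(u, -1)}\t{comm.get(v, -1)}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PathSet:
    """Optimal path plus all suboptimal paths within a weight tolerance."""

    source: int
    sink: int
    optimal: list[int] | None
    optimal_weight: float | None
    suboptimal: list[tuple[list[int], float]] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return self.optimal is not None


# ---------------------------------------------------------------------------
# Cross-correlation
# ---------------------------------------------------------------------------

def dccm(ensemble: Ensemble | np.ndarray, segment: str = "full") -> DCCM:
    """Dynamical cross-correlation matrix of a superposed ensemble.

    Zero-variance positions get NaN rows/columns (excluded downstream)
    with a warning; mobile positions have C_ii = 1.
    """
    frames = _frames_of(ensemble)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    dev = frames - frames.mean(axis=0)
    G = np.einsum("fia,fja->ij", dev, dev) / frames.shape[0]
    d = np.diag(G).copy()
    static = d <= 0
    if static.any():
        warnings.warn(f"{static.sum()} zero-variance positions marked NaN")
        d[static] = np.nan
    C = G / np.sqrt(np.outer(d, d))
    C = np.clip(C, -1.0, 1.0, out=C, where=np.isfinite(C))
    np.fill_diagonal(C, np.where(static, np.nan, 1.0))
    return DCCM(matrix=C, segment=segment)


def contact_adjacency(
    ensemble: Ensemble,
    cutoff: float = 4.5,
    occupancy: float = 0.75,
    exclude_neighbors: int = 1,
    chunk: int = 200,
) -> ContactAdjacency:
    """Contact map: closest heavy atoms within ``cutoff`` Å in at least
    ``occupancy`` of frames (boundary inclusive).

    The minimum is taken over all available heavy-atom layers of the
    ensemble (Cα plus side-chain atoms where present).  Sequence neighbours
    within ``exclude_neighbors`` positions are excluded — backbone contacts
    would otherwise dominate every path.
    """
    atom_frames = (ensemble.atom_frames
                   if not isinstance(ensemble, np.ndarray)
                   else {"CA": ensemble})
    layers = [atom_frames[k] for k in sorted(atom_frames)]
    F, N = layers[0].shape[0], layers[0].shape[1]
    counts = np.zeros((N, N), dtype=np.int64)
    for start in range(0, F, chunk):
        sl = slice(start, min(start + chunk, F))
        nf = sl.stop - sl.start
        mind = np.full((nf, N, N), np.inf)
        for A in layers:
            for B in layers:
                diff = A[sl][:, :, None, :] - B[sl][:, None, :, :]
                d = np.sqrt(np.sum(diff ** 2, axis=3))
                np.fmin(mind, d, out=mind)  # fmin ignores NaN layers
        counts += (mind < cutoff).sum(axis=0)
    frac = counts / F
    adj = frac + 1e-12 >= occupancy
    idx = np.arange(N)
    band = np.abs(idx[:, None] - idx[None, :]) <= exclude_neighbors
    adj &= ~band
    return ContactAdjacency(matrix=adj, cutoff=cutoff, occupancy=occupancy)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(corr: DCCM, adjacency: ContactAdjacency,
                  floor: float = CORRELATION_FLOOR) -> DynamicNetwork:
    """Weighted residue graph over the contact edges.

    Edge length w_ij = −log|C_ij|, capped at −log(floor) for vanishing
    correlations (capped edges carry a ``capped`` flag).  NaN-correlation
    nodes contribute no edges.
    """
    if corr.n != adjacency.matrix.shape[0]:
        raise ValueError("DCCM and adjacency sizes differ")
    G = nx.Graph()
    G.add_nodes_from(range(corr.n))
    w_max = -np.log(floor)
    for i, j in zip(*np.nonzero(np.triu(adjacency.matrix, k=1))):
        c = corr.matrix[i, j]
        if not np.isfinite(c):
            continue
        a = abs(c)
        capped = a < floor
        w = w_max if capped else -np.log(a)
        G.add_edge(int(i), int(j), corr=a, signed_corr=float(c),
                   weight=float(w), capped=bool(capped))
    return DynamicNetwork(graph=G)


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def _modularity(G: nx.Graph, partition: list[set[int]]) -> float:
    return nx.community.modularity(G, partition, weight="corr")


def detect_communities(network: DynamicNetwork) -> list[set[int]]:
    """Girvan–Newman community detection at maximum modularity.

    Edges are removed in order of weighted edge betweenness (path lengths
    use the −log|C| weights); among the nested partitions produced, the one
    maximising modularity with |C| edge strengths is returned.  Ties in the
    most-valuable edge are broken toward the lowest node pair for
    determinism.  The partition is stored on the network in place and also
    returned; connected components are handled independently by
    construction (betweenness never joins components).
    """
    G = network.graph
    if G.number_of_edges() == 0:
        partition = [{n} for n in sorted(G.nodes)]
        network.partition = partition
        return partition
    H = G.copy()
    best = [set(c) for c in nx.connected_components(G)]
    best_q = _modularity(G, best)
    n_comp = len(best)
    while H.number_of_edges():
        eb = nx.edge_betweenness_centrality(H, weight="weight")
        edge = min(eb, key=lambda e: (-eb[e], tuple(sorted(e))))
        H.remove_edge(*edge)
        comps = [set(c) for c in nx.connected_components(H)]
        if len(comps) != n_comp:
            n_comp = len(comps)
            q = _modularity(G, comps)
            if q > best_q + 1e-12:
                best_q, best = q, comps
    order = sorted(best, key=lambda c: min(c))
    network.partition = order
    return order


def betweenness_and_critical_nodes(
    network: DynamicNetwork,
    partition: list[set[int]] | None = None,
    quantile: float = 0.5,
) -> tuple[dict[int, float], list[int]]:
    """Weighted shortest-path betweenness and inter-community critical nodes.

    A critical node is incident to at least one inter-community edge and
    has betweenness above the given quantile among such boundary nodes
    (default: the median, i.e. carrying a majority share of the
    community-bridging shortest paths).  Disconnected source/sink pairs
    simply contribute no paths.
    """
    if partition is None:
        partition = network.partition or detect_communities(network)
    G = network.graph
    bc = nx.betweenness_centrality(G, weight="weight", normalized=False)
    comm = {n: k for k, c in enumerate(partition) for n in c}
    boundary = sorted({
        n for u, v in G.edges if comm.get(u) != comm.get(v)
        for n in (u, v)})
    critical: list[int] = []
    if boundary:
        thresh = float(np.quantile([bc[n] for n in boundary], quantile))
        critical = [n for n in boundary if bc[n] > thresh]
        if not critical:  # all-equal betweenness at the boundary
            critical = boundary
    network.betweenness = bc
    network.critical_nodes = critical
    return bc, critical


# ---------------------------------------------------------------------------
# Optimal and suboptimal paths
# ---------------------------------------------------------------------------

def paths(network: DynamicNetwork, source: int, sink: int,
          tolerance: float = 0.0) -> PathSet:
    """Dijkstra optimal path plus all simple paths within ``tolerance``.

    Suboptimal paths are enumerated by depth-first search pruned with the
    exact distance-to-sink lower bound, so the enumeration touches only
    prefixes that can still finish within budget.  Returns an explicit
    no-path result when source and sink are disconnected.
    """
    G = network.graph
    try:
        dist_to_sink = nx.single_source_dijkstra_path_length(
            G, sink, weight="weight")
    except nx.NodeNotFound:
        raise ValueError("source or sink not in network")
    if source not in dist_to_sink:
        return PathSet(source=source, sink=sink,
                       optimal=None, optimal_weight=None)
    opt_w = dist_to_sink[source]
    budget = opt_w + tolerance + 1e-9

    results: list[tuple[float, list[int]]] = []
    stack: list[tuple[int, float, list[int]]] = [(source, 0.0, [source])]
    while stack:
        node, cost, path = stack.pop()
        if node == sink:
            results.append((cost, path))
            continue
        for nbr in sorted(G[node], reverse=True):
            if nbr in path:
                continue
            c = cost + G[node][nbr]["weight"]
            if nbr in dist_to_sink and c + dist_to_sink[nbr] <= budget:
                stack.append((nbr, c, path + [nbr]))
    results.sort(key=lambda t: (t[0], t[1]))
    optimal = results[0]
    return PathSet(
        source=source, sink=sink,
        optimal=optimal[1], optimal_weight=optimal[0],
        suboptimal=[(p, w) for w, p in results],
    )
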