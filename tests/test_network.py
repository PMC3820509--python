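"""DCCM, contact filtering, network weights, communities, paths."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

import ensdyn
from ensdyn.dccm_network import DCCM, ContactAdjacency, DynamicNetwork


def make_network(edges):
    """DynamicNetwork from (u, v, corr) triples."""
    G = nx.Graph()
    for u, v, c in edges:
        G.add_edge(u, v, corr=c, signed_corr=c, weight=float(-np.log(c)),
                   capped=False)
    return DynamicNetwork(graph=G)


class TestDCCM:
    def test_diagonal_and_perfect_correlations(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(50, 1, 3))
        frames = np.concatenate(
            [base, base, -base, rng.normal(size=(50, 1, 3))], axis=1)
        frames += rng.normal(size=(50, 4, 3)) * 0  # keep exact
        C = ensdyn.dccm(frames).matrix
        assert np.allclose(np.diag(C), 1.0)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)
        assert abs(C[0, 3]) < 0.5

    def test_time_reversal_invariance(self, block_traj):
        ens, _, _ = block_traj
        C1 = ensdyn.dccm(ens.frames[:500]).matrix
        C2 = ensdyn.dccm(ens.frames[:500][::-1]).matrix
        np.testing.assert_allclose(C1, C2, atol=1e-12)

    def test_block_targets_recovered(self, block_traj):
        ens, truth, blocks = block_traj
        C = ensdyn.dccm(ens).matrix
        intra = [C[i, j] for b in blocks
                 for i, j in combinations(b.tolist(), 2)]
        inter = [C[i, j] for a, b in combinations(range(3), 2)
                 for i in blocks[a] for j in blocks[b]]
        assert abs(np.mean(intra) - truth["intra"]) < 0.05
        assert abs(np.mean(inter) - truth["inter"]) < 0.05

    def test_zero_variance_position_flagged(self):
        frames = np.zeros((10, 3, 3))
        frames[:, 0, 0] = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            C = ensdyn.dccm(frames).matrix
        assert np.isnan(C[1]).all() and np.isnan(C[:, 2]).all()
        assert C[0, 0] == 1.0


class TestContactAdjacency:
    def test_static_contact_present(self):
        frames = np.zeros((4, 3, 3))
        frames[:, 1] = [4.0, 0.0, 0.0]
        frames[:, 2] = [20.0, 0.0, 0.0]
        adj = ensdyn.contact_adjacency(frames, exclude_neighbors=0)
        assert adj.matrix[0, 1] and not adj.matrix[0, 2]

    def test_occupancy_boundary_inclusive(self):
        """74% occupancy gives no edge; exactly 75% gives an edge."""
        F = 100
        frames = np.zeros((F, 3, 3))
        frames[:, 2] = [50.0, 0.0, 0.0]
        d = np.full(F, 10.0)
        d[:74] = 4.0
        frames[:, 1, 0] = d
        adj74 = ensdyn.contact_adjacency(frames, exclude_neighbors=0)
        d[74] = 4.0
        frames[:, 1, 0] = d
        adj75 = ensdyn.contact_adjacency(frames, exclude_neighbors=0)
        assert not adj74.matrix[0, 1]
        assert adj75.matrix[0, 1]

    def test_scripted_occupancy_matches_truth(self, block_traj):
        ens, truth, _ = block_traj
        adj = ensdyn.contact_adjacency(ens)
        np.testing.assert_array_equal(adj.matrix,
                                      np.array(truth["adjacency"]))

    def test_sequence_neighbors_excluded(self):
        frames = np.zeros((2, 4, 3))
        frames[:, 1] = [3.0, 0.0, 0.0]
        frames[:, 2] = [6.0, 0.0, 0.0]
        frames[:, 3] = [3.0, 3.0, 0.0]
        adj = ensdyn.contact_adjacency(frames, exclude_neighbors=1)
        assert not adj.matrix[0, 1]      # |i-j| = 1 excluded
        assert adj.matrix[0, 3]          # |i-j| = 3 kept


class TestNetworkWeights:
    def test_weight_closed_forms(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 1.0
        C[1, 2] = C[2, 1] = np.exp(-1.0)
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        net = ensdyn.build_network(
            DCCM(matrix=C), ContactAdjacency(matrix=adj))
        assert net.graph[0][1]["weight"] == pytest.approx(0.0)
        assert net.graph[1][2]["weight"] == pytest.approx(1.0)

    def test_vanishing_correlation_capped_and_flagged(self):
        C = np.eye(2)
        C[0, 1] = C[1, 0] = 1e-12
        adj = np.array([[0, 1], [1, 0]], dtype=bool)
        net = ensdyn.build_network(DCCM(matrix=C),
                                   ContactAdjacency(matrix=adj))
        e = net.graph[0][1]
        assert e["capped"]
        assert e["weight"] == pytest.approx(-np.log(1e-6))

    def test_weight_monotone_in_correlation(self):
        cs = np.linspace(0.1, 1.0, 10)
        ws = [-np.log(c) for c in cs]
        N = len(cs) + 1
        C = np.eye(N)
        adj = np.zeros((N, N), dtype=bool)
        for k, c in enumerate(cs):
            C[k, N - 1] = C[N - 1, k] = c
            adj[k, N - 1] = adj[N - 1, k] = True
        net = ensdyn.build_network(DCCM(matrix=C),
                                   ContactAdjacency(matrix=adj))
        got = [net.graph[k][N - 1]["weight"] for k in range(len(cs))]
        np.testing.assert_allclose(got, ws)
        assert all(b < a for a, b in zip(got, got[1:]))


def exhaustive_best_modularity(G, max_groups=3):
    """Exhaustive modularity maximum over all partitions into at most
    max_groups groups (oracle; feasible for <= 12 nodes)."""
    from itertools import product
    nodes = sorted(G.nodes)
    best_q, best_part = -np.inf, None
    for assignment in product(range(max_groups), repeat=len(nodes)):
        groups = {}
        for node, g in zip(nodes, assignment):
            groups.setdefault(g, set()).add(node)
        part = list(groups.values())
        q = nx.community.modularity(G, part, weight="corr")
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    return best_q, best_part


class TestCommunities:
    def two_clique_bridge(self):
        edges = []
        for u, v in combinations(range(5), 2):
            edges.append((u, v, 0.9))
        for u, v in combinations(range(5, 10), 2):
            edges.append((u, v, 0.9))
        edges.append((4, 5, 0.2))
        return make_network(edges)

    def test_two_cliques_split_at_bridge(self):
        net = self.two_clique_bridge()
        part = ensdyn.detect_communities(net)
        assert sorted(sorted(c) for c in part) == [
            [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]
        # matches the exhaustive-modularity oracle
        q_oracle, part_oracle = exhaustive_best_modularity(net.graph, 2)
        q_ours = nx.community.modularity(net.graph, part, weight="corr")
        assert q_ours == pytest.approx(q_oracle, abs=1e-12)

    def test_complete_graph_single_community(self):
        edges = [(u, v, 0.8) for u, v in combinations(range(6), 2)]
        net = make_network(edges)
        part = ensdyn.detect_communities(net)
        # uniform complete graph: no split improves modularity over the
        # single community (closed form: Q <= 0 for any split)
        assert len(part) == 1

    def test_partition_beats_trivial_partitions(self):
        net = self.two_clique_bridge()
        part = ensdyn.detect_communities(net)
        G = net.graph
        q = nx.community.modularity(G, part, weight="corr")
        q_single = nx.community.modularity(G, [set(G.nodes)], weight="corr")
        q_singletons = nx.community.modularity(
            G, [{n} for n in G.nodes], weight="corr")
        assert q >= q_single and q >= q_singletons

    def test_block_trajectory_partition_recovered(self, block_traj):
        ens, _, blocks = block_traj
        C = ensdyn.dccm(ens)
        adj = ensdyn.contact_adjacency(ens)
        net = ensdyn.build_network(C, adj)
        part = ensdyn.detect_communities(net)
        assert sorted(sorted(c) for c in part) == [
            b.tolist() for b in blocks]

    def test_partition_invariant_under_relabeling(self):
        net = self.two_clique_bridge()
        mapping = {n: 9 - n for n in net.graph.nodes}
        relabeled = DynamicNetwork(
            graph=nx.relabel_nodes(net.graph, mapping))
        p1 = ensdyn.detect_communities(net)
        p2 = ensdyn.detect_communities(relabeled)
        mapped = sorted(sorted(mapping[n] for n in c) for c in p1)
        assert mapped == sorted(sorted(c) for c in p2)


def enumerate_betweenness(G):
    """Node betweenness by explicit enumeration of all weighted shortest
    paths between every node pair (oracle for small graphs)."""
    bc = {n: 0.0 for n in G.nodes}
    nodes = sorted(G.nodes)
    for s, t in combinations(nodes, 2):
        try:
            opt = nx.dijkstra_path_length(G, s, t)
        except nx.NetworkXNoPath:
            continue
        shortest = [p for p in nx.all_simple_paths(G, s, t)
                    if np.isclose(nx.path_weight(G, p, "weight"), opt)]
        for p in shortest:
            for n in p[1:-1]:
                bc[n] += 1.0 / len(shortest)
    return bc


class TestBetweenness:
    def test_path_graph_center_highest(self):
        edges = [(i, i + 1, 0.8) for i in range(4)]
        net = make_network(edges)
        bc, _ = ensdyn.betweenness_and_critical_nodes(
            net, partition=[{0, 1, 2}, {3, 4}])
        oracle = enumerate_betweenness(net.graph)
        for n in net.graph.nodes:
            assert bc[n] == pytest.approx(oracle[n])
        assert max(bc, key=bc.get) == 2

    def test_star_graph_hub_carries_all(self):
        edges = [(0, k, 0.8) for k in range(1, 6)]
        net = make_network(edges)
        bc, _ = ensdyn.betweenness_and_critical_nodes(
            net, partition=[{0, 1, 2}, {3, 4, 5}])
        assert bc[0] == pytest.approx(10.0)  # C(5,2) through-paths
        for leaf in range(1, 6):
            assert bc[leaf] == 0.0

    def test_bridge_endpoints_are_critical(self):
        edges = []
        for u, v in combinations(range(4), 2):
            edges.append((u, v, 0.9))
        for u, v in combinations(range(4, 8), 2):
            edges.append((u, v, 0.9))
        edges.append((3, 4, 0.5))
        net = make_network(edges)
        part = ensdyn.detect_communities(net)
        bc, critical = ensdyn.betweenness_and_critical_nodes(net, part)
        assert set(critical) == {3, 4}
        oracle = enumerate_betweenness(net.graph)
        for n in net.graph.nodes:
            assert bc[n] == pytest.approx(oracle[n])


class TestPaths:
    def test_chain_unique_path(self):
        edges = [(i, i + 1, 0.8) for i in range(4)]
        net = make_network(edges)
        out = ensdyn.paths(net, 0, 4, tolerance=0.0)
        assert out.optimal == [0, 1, 2, 3, 4]
        assert len(out.suboptimal) == 1

    def test_diamond_tie_both_branches(self):
        edges = [(0, 1, 0.8), (1, 3, 0.8), (0, 2, 0.8), (2, 3, 0.8)]
        net = make_network(edges)
        out = ensdyn.paths(net, 0, 3, tolerance=0.0)
        got = sorted(p for p, _ in out.suboptimal)
        assert got == [[0, 1, 3], [0, 2, 3]]

    def test_no_path_result(self):
        net = make_network([(0, 1, 0.8), (2, 3, 0.8)])
        out = ensdyn.paths(net, 0, 3)
        assert not out.found and out.optimal is None

    def test_random_graph_matches_brute_force(self):
        """Suboptimal path set equals exhaustive enumeration of all
        simple paths on a random 12-node graph."""
        rng = np.random.default_rng(21)
        G = nx.gnp_random_graph(12, 0.35, seed=5)
        edges = [(u, v, float(rng.uniform(0.2, 0.95)))
                 for u, v in G.edges]
        net = make_network(edges)
        src, dst = 0, 11
        assert nx.has_path(net.graph, src, dst)  # stable: fixed seed
        tol = 1.5
        out = ensdyn.paths(net, src, dst, tolerance=tol)
        opt = nx.dijkstra_path_length(net.graph, src, dst)
        brute = sorted(
            p for p in nx.all_simple_paths(net.graph, src, dst)
            if nx.path_weight(net.graph, p, "weight") <= opt + tol + 1e-9)
        assert sorted(p for p, _ in out.suboptimal) == brute
        assert out.optimal_weight == pytest.approx(opt)
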