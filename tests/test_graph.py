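"""Graph construction and network metrics against analytic and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from restgraph import graph as gr
from restgraph.synthetic import planted_partition_graph


# --------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive)

def brute_clustering(A):
    n = len(A)
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        d = len(nbrs)
        if d < 2:
            continue
        links = sum(A[u, v] for u, v in itertools.combinations(nbrs, 2))
        C[i] = 2.0 * links / (d * (d - 1))
    return C


def floyd_warshall_L(A):
    n = len(A)
    dist = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    off = dist[~np.eye(n, dtype=bool)]
    return off.mean()


def brute_participation(A, assignment):
    n = len(A)
    P = np.zeros(n)
    for i in range(n):
        d = A[i].sum()
        if d == 0:
            continue
        acc = 0.0
        for m in np.unique(assignment):
            k_im = sum(A[i, j] for j in range(n) if assignment[j] == m)
            acc += (k_im / d) ** 2
        P[i] = 1.0 - acc
    return P


def brute_modularity(A, assignment):
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    n = len(A)
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                q += A[i, j] - A[i].sum() * A[j].sum() / two_m
    return q / two_m


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, 1)
    edges = rng.random(len(iu[0])) < p
    A[iu[0][edges], iu[1][edges]] = 1
    return A + A.T


def ring_lattice(n, k):
    A = np.zeros((n, n), dtype=np.int8)
    for d in range(1, k // 2 + 1):
        idx = np.arange(n)
        A[idx, (idx + d) % n] = 1
        A[(idx + d) % n, idx] = 1
    return A


def watts_strogatz(n, k, p, seed):
    rng = np.random.default_rng(seed)
    A = ring_lattice(n, k).copy()
    g = gr.BinaryGraph(adjacency=A)
    A = g.adjacency.copy()
    for u, v in g.edge_array():
        if rng.random() < p:
            w = int(rng.integers(n))
            if w != u and not A[u, w]:
                A[u, v] = A[v, u] = 0
                A[u, w] = A[w, u] = 1
    return gr.BinaryGraph(adjacency=A)


# --------------------------------------------------------------------------

class TestConstruction:
    def test_fisher_z_matches_atanh(self):
        assert gr.fisher_z(0.5) == pytest.approx(np.arctanh(0.5), rel=1e-12)
        assert np.isfinite(gr.fisher_z(1.0))

    def test_connectivity_matrix_values(self, rng):
        # plant an exact correlation of 0.5 via a rotation-free mix
        n = 100000
        a = rng.standard_normal(n)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        m = gr.connectivity_matrix(np.vstack([a, b]))
        assert m.z[0, 1] == pytest.approx(np.arctanh(0.5), abs=0.02)
        assert m.z[0, 0] == 0

    def test_duplicated_row_hits_cap(self, rng):
        x = rng.standard_normal(50)
        m = gr.connectivity_matrix(np.vstack([x, x]))
        assert m.z[0, 1] == pytest.approx(gr.Z_CAP)

    def test_null_series_mean_z_near_zero(self, rng):
        ts = rng.standard_normal((30, 168))
        m = gr.connectivity_matrix(ts)
        iu = np.triu_indices(30, 1)
        se = 1.0 / np.sqrt(168 - 3)
        assert abs(m.z[iu].mean()) < 3 * se / np.sqrt(len(iu[0]))

    def test_zero_variance_row_rejected(self, rng):
        ts = np.vstack([rng.standard_normal(30), np.ones(30)])
        with pytest.raises(ValueError, match="zero-variance"):
            gr.connectivity_matrix(ts)


class TestThresholding:
    def test_edge_count_follows_sparsity(self, rng):
        w = rng.standard_normal((5, 5))
        w = (w + w.T) / 2
        g = gr.threshold_proportional(w, 0.2)
        assert g.n_edges == 2  # round(0.2 * 10)

    def test_full_sparsity_complete_graph(self, rng):
        w = rng.standard_normal((6, 6))
        w = (w + w.T) / 2
        assert gr.threshold_proportional(w, 1.0).n_edges == 15

    def test_tie_break_deterministic(self):
        w = np.ones((6, 6))
        g1 = gr.threshold_proportional(w, 0.5)
        g2 = gr.threshold_proportional(w, 0.5)
        assert g1.n_edges == round(0.5 * 15)
        np.testing.assert_array_equal(g1.adjacency, g2.adjacency)

    def test_monotone_nesting_in_sparsity(self, rng):
        w = rng.standard_normal((20, 20))
        w = (w + w.T) / 2
        prev = None
        for S in (0.1, 0.2, 0.3, 0.5, 0.8, 1.0):
            g = gr.threshold_proportional(w, S)
            if prev is not None:
                assert np.all(prev.adjacency <= g.adjacency)
            prev = g

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ValueError):
            gr.threshold_proportional(np.zeros((4, 4)), 0.0)


class TestAnalyticIdentities:
    def test_triangle_clustering_one(self):
        g = gr.BinaryGraph(adjacency=np.ones((3, 3)) - np.eye(3))
        C_i, C = gr.clustering_coefficients(g)
        assert np.all(C_i == 1) and C == 1

    def test_star_clustering_zero(self):
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 1
        C_i, C = gr.clustering_coefficients(gr.BinaryGraph(adjacency=A))
        assert np.all(C_i == 0)

    def test_complete_graph_unit_path_length(self):
        g = gr.BinaryGraph(adjacency=np.ones((5, 5)) - np.eye(5))
        assert gr.characteristic_path_length(g) == pytest.approx(1.0)

    def test_path_of_three_nodes(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert gr.characteristic_path_length(gr.BinaryGraph(adjacency=A)) == pytest.approx(4 / 3)

    def test_disconnected_graph_is_an_error(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1
        with pytest.raises(ValueError, match="disconnected"):
            gr.characteristic_path_length(gr.BinaryGraph(adjacency=A))

    def test_star_degrees(self):
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 1
        D, _ = gr.degree_and_z(gr.BinaryGraph(adjacency=A))
        np.testing.assert_array_equal(D, [3, 1, 1, 1])

    def test_z_degree_hand_example(self):
        # graph with degree profile 1,2,2,3; z uses the population SD
        A = np.array([[0, 0, 0, 1],
                      [0, 0, 1, 1],
                      [0, 1, 0, 1],
                      [1, 1, 1, 0]])
        D, z = gr.degree_and_z(gr.BinaryGraph(adjacency=A))
        np.testing.assert_array_equal(D, [1, 2, 2, 3])
        np.testing.assert_allclose(z, (D - 2.0) / np.sqrt(0.5), atol=1e-12)
        # the degree profile 1,2,3 standardises to -1.2247, 0, +1.2247
        vals = np.array([1.0, 2.0, 3.0])
        zref = (vals - vals.mean()) / vals.std()
        np.testing.assert_allclose(zref, [-1.22474487, 0, 1.22474487], atol=1e-8)

    def test_regular_graph_z_undefined(self):
        g = gr.BinaryGraph(adjacency=ring_lattice(6, 2))
        with pytest.raises(ValueError, match="zero spread"):
            gr.degree_and_z(g)

    def test_two_cliques_modularity_half(self):
        A = np.zeros((8, 8))
        A[:4, :4] = 1
        A[4:, 4:] = 1
        np.fill_diagonal(A, 0)
        part = gr.detect_communities(gr.BinaryGraph(adjacency=A))
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5, abs=1e-12)
        assert len(set(part.assignment[:4])) == 1
        assert part.assignment[0] != part.assignment[4]

    def test_single_clique_single_module(self):
        g = gr.BinaryGraph(adjacency=np.ones((6, 6)) - np.eye(6))
        assert gr.detect_communities(g).n_modules == 1

    @pytest.mark.parametrize("edges,expected_p", [
        # degree-2 node with one edge into each of two modules -> P = 0.5
        ([(0, 1), (0, 2), (1, 3), (2, 4), (3, 4)], None),
    ])
    def test_participation_hand_values(self, edges, expected_p):
        A = np.zeros((5, 5))
        for u, v in edges:
            A[u, v] = A[v, u] = 1
        g = gr.BinaryGraph(adjacency=A)
        part = gr.Partition(assignment=np.array([1, 1, 2, 1, 2]), q=0.0)
        P = gr.participation_coefficients(g, part)
        # node 0: edges to 1 (module 1) and 2 (module 2) -> 1 - (1/4 + 1/4)
        assert P[0] == pytest.approx(0.5)

    def test_participation_even_spread_four_modules(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1
        part = gr.Partition(assignment=np.array([1, 1, 2, 3, 4]), q=0.0)
        P = gr.participation_coefficients(gr.BinaryGraph(adjacency=A), part)
        assert P[0] == pytest.approx(0.75)  # 1 - 4 * (1/16)

    def test_participation_zero_within_own_module(self):
        A = np.ones((4, 4)) - np.eye(4)
        part = gr.Partition(assignment=np.ones(4, int), q=0.0)
        P = gr.participation_coefficients(gr.BinaryGraph(adjacency=A), part)
        np.testing.assert_allclose(P, 0)


class TestOracleEquivalence:
    """Exact agreement with naive implementations on enumerated and random graphs."""

    def all_graphs_n5(self):
        iu = np.triu_indices(5, 1)
        for bits in range(1024):
            A = np.zeros((5, 5), dtype=np.int8)
            mask = [(bits >> k) & 1 for k in range(10)]
            A[iu[0], iu[1]] = mask
            yield A + A.T

    def test_exhaustive_five_node_graphs(self):
        rng = np.random.default_rng(0)
        for A in self.all_graphs_n5():
            g = gr.BinaryGraph(adjacency=A)
            C_i, _ = gr.clustering_coefficients(g)
            np.testing.assert_allclose(C_i, brute_clustering(A), atol=1e-12)
            assignment = rng.integers(1, 3, size=5)
            part = gr.Partition(assignment=assignment, q=0.0)
            np.testing.assert_allclose(
                gr.participation_coefficients(g, part),
                brute_participation(A, assignment), atol=1e-12)
            assert gr.modularity(g, assignment) == pytest.approx(
                brute_modularity(A.astype(float), assignment), abs=1e-12)
            if g.is_connected() and g.n_nodes > 1:
                assert gr.characteristic_path_length(g) == pytest.approx(
                    floyd_warshall_L(A), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_graphs_up_to_30_nodes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        A = random_graph(n, 0.3, seed=seed + 1000)
        g = gr.BinaryGraph(adjacency=A)
        np.testing.assert_allclose(
            gr.clustering_coefficients(g)[0], brute_clustering(A), atol=1e-12)
        if g.is_connected():
            assert gr.characteristic_path_length(g) == pytest.approx(
                floyd_warshall_L(A), abs=1e-10)
        assignment = rng.integers(1, 5, size=n)
        np.testing.assert_allclose(
            gr.participation_coefficients(g, gr.Partition(assignment=assignment, q=0)),
            brute_participation(A, assignment), atol=1e-12)

    def test_clustering_matches_networkx(self):
        A = random_graph(25, 0.25, seed=3)
        g = gr.BinaryGraph(adjacency=A)
        G = nx.from_numpy_array(A)
        ours, _ = gr.clustering_coefficients(g)
        theirs = np.array([nx.clustering(G, i) for i in range(25)])
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_modularity_matches_networkx(self):
        g, labels = planted_partition_graph(3, 8, 0.7, 0.1, seed=5)
        comms = [set(np.flatnonzero(labels == m)) for m in np.unique(labels)]
        theirs = nx.algorithms.community.modularity(
            nx.from_numpy_array(g.adjacency), comms)
        assert gr.modularity(g, labels) == pytest.approx(theirs, abs=1e-12)

    def test_best_two_partition_not_better_than_detected(self):
        """On small graphs, exhaustive 2-way search never beats detection."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            A = random_graph(8, 0.4, seed=int(rng.integers(1e6)))
            g = gr.BinaryGraph(adjacency=A)
            detected = gr.detect_communities(g)
            best2 = max(
                gr.modularity(g, np.array([1 if (bits >> i) & 1 else 2
                                           for i in range(8)]))
                for bits in range(256)
            )
            assert detected.q >= best2 - 1e-9 or detected.n_modules > 2


class TestRewiring:
    def test_degree_sequence_and_edge_count_conserved(self):
        g, _ = planted_partition_graph(4, 10, 0.6, 0.1, seed=0)
        ref = gr.random_reference(g, n_swaps_per_edge=10, seed=1)
        np.testing.assert_array_equal(np.sort(ref.degrees()), np.sort(g.degrees()))
        np.testing.assert_array_equal(ref.degrees(), g.degrees())
        assert ref.n_edges == g.n_edges

    def test_triangle_has_no_valid_swap(self):
        A = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(UserWarning, match="no valid"):
            ref = gr.random_reference(gr.BinaryGraph(adjacency=A), seed=0)
        np.testing.assert_array_equal(ref.adjacency, A.astype(np.int8))

    def test_rewiring_destroys_lattice_clustering(self):
        g = gr.BinaryGraph(adjacency=ring_lattice(100, 6))
        _, C0 = gr.clustering_coefficients(g)
        ref = gr.random_reference(g, n_swaps_per_edge=10, seed=2)
        _, C1 = gr.clustering_coefficients(ref)
        density = g.n_edges / (100 * 99 / 2)
        assert C0 == pytest.approx(0.6, abs=0.01)  # lattice value
        assert C1 < 0.2  # toward the density ~ 0.06
        assert C1 > 0

    def test_seeded_rewiring_reproducible(self):
        g, _ = planted_partition_graph(3, 10, 0.5, 0.1, seed=4)
        a = gr.random_reference(g, seed=77)
        b = gr.random_reference(g, seed=77)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestSmallWorldMetrics:
    def test_dense_random_graph_is_its_own_null(self):
        A = random_graph(50, 0.3, seed=6)
        g = gr.BinaryGraph(adjacency=A)
        gm = gr.normalized_global_metrics(g, n_random=10, seed=3)
        assert gm.gamma == pytest.approx(1.0, abs=0.15)
        assert gm.lam == pytest.approx(1.0, abs=0.1)

    def test_small_world_regime_detected(self):
        g = watts_strogatz(100, 6, 0.2, seed=8)
        assert g.is_connected()
        gm = gr.normalized_global_metrics(g, n_random=10, seed=4)
        assert gm.gamma > 1.5
        assert gm.lam < 1.2
        assert gm.sigma > 1

    def test_zero_references_rejected(self):
        g = gr.BinaryGraph(adjacency=ring_lattice(10, 4))
        with pytest.raises(ValueError):
            gr.normalized_global_metrics(g, n_random=0)


class TestCommunityRecovery:
    def test_planted_partition_recovered(self):
        from sklearn.metrics import normalized_mutual_info_score
        hits = 0
        for seed in range(20):
            g, labels = planted_partition_graph(4, 20, 0.8, 0.05, seed=seed)
            part = gr.detect_communities(g)
            hits += normalized_mutual_info_score(labels, part.assignment) == 1.0
        assert hits >= 19

    def test_q_at_least_planted_partition_q(self):
        for seed in range(5):
            g, labels = planted_partition_graph(4, 15, 0.8, 0.05, seed=seed)
            part = gr.detect_communities(g)
            assert part.q >= gr.modularity(g, labels) - 1e-9
            assert part.q >= 0.0


class TestModuleSummaries:
    def test_uniform_metrics_give_zero_means(self):
        import pandas as pd
        df = pd.DataFrame({"subject_id": ["s1"] * 4, "sparsity": [0.2] * 4,
                           "node": range(4), "z_degree": [0.0] * 4})
        part = gr.Partition(assignment=np.array([1, 1, 2, 2]), q=0)
        out = gr.module_summaries(df, part)
        np.testing.assert_allclose(out["z_degree"], 0)
        assert set(out["module"]) == {1, 2}
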