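"""Weighted graph metrics against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pytest

import spikefbn as sf
from spikefbn.errors import DisconnectedNetworkError
from spikefbn.graphs import modularity_value, shortest_path_lengths


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation paths)
# ---------------------------------------------------------------------------

def strength_oracle(w, i):
    return sum(w[i, j] for j in range(w.shape[0]) if j != i)


def clustering_oracle(w):
    """Triangle-intensity clustering, neighbor pairs enumerated directly."""
    n = w.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        s = sum((w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
                for j, h in itertools.combinations(nbrs, 2))
        cs.append(2 * s / (k * (k - 1)))
    return float(np.mean(cs))


def shortest_paths_oracle(w):
    """Exhaustive simple-path enumeration (feasible for <= 7 nodes)."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nodes = range(n)
    for i, j in itertools.permutations(nodes, 2):
        best = np.inf
        others = [k for k in nodes if k not in (i, j)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (i, *mid, j)
                length = 0.0
                for a, b in zip(path, path[1:]):
                    if w[a, b] <= 0:
                        length = np.inf
                        break
                    length += 1.0 / w[a, b]
                best = min(best, length)
        dist[i, j] = best
    return dist


def modularity_oracle(w, partition):
    """Eq-style double loop: e_uv = inter-module weight / total weight."""
    total = sum(w[i, j] for i in range(w.shape[0])
                for j in range(i + 1, w.shape[0]))
    if total == 0:
        return 0.0
    module_of = {}
    for u, mem in enumerate(partition):
        for i in mem:
            module_of[i] = u
    m = len(partition)
    e = np.zeros((m, m))
    for i in range(w.shape[0]):
        for j in range(i + 1, w.shape[0]):
            if w[i, j] > 0:
                u, v = module_of[i], module_of[j]
                e[u, v] += w[i, j] / total
                if u != v:
                    e[v, u] += w[i, j] / total
    return float(sum(e[u, u] - e[u].sum() ** 2 for u in range(m)))


def _complete(n, weight=1.0):
    w = np.full((n, n), weight, dtype=float)
    np.fill_diagonal(w, 0.0)
    return w


def _path3():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    return w


def _random_graph(rng, n=6, density=1.0):
    w = rng.uniform(0.1, 1.0, size=(n, n))
    w = (w + w.T) / 2
    if density < 1.0:
        mask = rng.random((n, n)) < density
        mask = mask & mask.T
        w = w * mask
    np.fill_diagonal(w, 0.0)
    return w


class TestClosedForms:
    def test_complete_graph_k4(self):
        w = _complete(4)
        assert sf.node_strength(w, 0) == pytest.approx(3.0)
        assert sf.average_degree(w) == pytest.approx(3.0)
        assert sf.characteristic_path_length(w) == pytest.approx(1.0)
        assert sf.characteristic_path_length(w, "as_printed") == \
            pytest.approx(12 / 20)
        assert sf.global_efficiency(w) == pytest.approx(1.0)

    def test_k4_uniform_weight_clustering(self):
        for weight in (0.3, 0.7, 1.0):
            assert sf.average_clustering(_complete(4, weight)) == \
                pytest.approx(weight)

    def test_binary_triangle_and_path(self):
        assert sf.average_clustering(_complete(3), mode="binarized") == \
            pytest.approx(1.0)
        assert sf.average_clustering(_path3(), mode="binarized") == \
            pytest.approx(0.0)

    def test_path_graph_p3(self):
        w = _path3()
        # ordered-pair distances (1, 1, 2, 2, 1, 1)
        assert sf.characteristic_path_length(w) == pytest.approx(4 / 3)
        assert sf.global_efficiency(w) == pytest.approx(5 / 6)

    def test_node_strength_partial_weights(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.25
        assert sf.node_strength(w, 0) == pytest.approx(0.75)

    def test_twin_triangles_modularity(self):
        w = np.zeros((6, 6))
        for tri in ((0, 1, 2), (3, 4, 5)):
            for i, j in itertools.combinations(tri, 2):
                w[i, j] = w[j, i] = 1.0
        partition = [{0, 1, 2}, {3, 4, 5}]
        assert modularity_value(w, partition) == pytest.approx(0.5)
        md, found = sf.modularity(w)
        assert md == pytest.approx(0.5)
        assert sorted(map(sorted, found)) == [[0, 1, 2], [3, 4, 5]]

    def test_one_module_partition_scores_zero(self):
        rng = np.random.default_rng(0)
        w = _random_graph(rng)
        assert modularity_value(w, [set(range(6))]) == pytest.approx(0.0)

    def test_edgeless_network(self):
        w = np.zeros((4, 4))
        assert sf.average_degree(w) == 0.0
        md, partition = sf.modularity(w)
        assert md == 0.0
        assert len(partition) == 4
        assert sf.global_efficiency(w) == 0.0

    def test_all_ones_fbn_feature_vector(self):
        feats = sf.network_feature_vector(_complete(16))
        np.testing.assert_allclose(feats.to_array(),
                                   [15.0, 1.0, 1.0, 1.0, 0.0], atol=1e-9)


class TestOracleAgreement:
    def test_metrics_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            w = _random_graph(rng, density=1.0 if trial % 2 else 0.8)
            for i in range(6):
                assert sf.node_strength(w, i) == \
                    pytest.approx(strength_oracle(w, i), abs=1e-9)
            assert sf.average_clustering(w) == \
                pytest.approx(clustering_oracle(w), abs=1e-9)
            dist = shortest_paths_oracle(w)
            np.testing.assert_allclose(shortest_path_lengths(w), dist,
                                       atol=1e-9)
            off = ~np.eye(6, dtype=bool)
            if np.isfinite(dist[off]).all():
                assert sf.characteristic_path_length(w) == \
                    pytest.approx(dist[off].mean(), abs=1e-9)
            inv = np.where(np.isinf(dist[off]), 0.0, 1.0 / dist[off])
            assert sf.global_efficiency(w) == \
                pytest.approx(inv.mean(), abs=1e-9)

    def test_modularity_equals_oracle_on_greedy_partition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            w = _random_graph(rng, density=0.6)
            md, partition = sf.modularity(w)
            assert md == pytest.approx(modularity_oracle(w, partition),
                                       abs=1e-12)


class TestProperties:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        w = _random_graph(rng)
        perm = rng.permutation(6)
        wp = w[np.ix_(perm, perm)]
        a = sf.network_feature_vector(w).to_array()
        b = sf.network_feature_vector(wp).to_array()
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_convention_ratio(self):
        rng = np.random.default_rng(2)
        for n in (4, 6, 16):
            w = _random_graph(rng, n=n)
            ratio = (n - 1) / (n + 1)
            assert sf.characteristic_path_length(w, "as_printed") == \
                pytest.approx(ratio * sf.characteristic_path_length(w))
            assert sf.global_efficiency(w, "as_printed") == \
                pytest.approx(ratio * sf.global_efficiency(w))

    def test_adding_an_edge_increases_average_degree(self):
        rng = np.random.default_rng(3)
        w = _random_graph(rng, density=0.5)
        zeros = np.argwhere((w == 0) & ~np.eye(6, dtype=bool))
        i, j = zeros[0]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 0.5
        assert sf.average_degree(w2) > sf.average_degree(w)

    def test_disconnected_network_has_no_cpl(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(DisconnectedNetworkError):
            sf.characteristic_path_length(w)
        assert sf.global_efficiency(w) > 0.0  # GE handles disconnection
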