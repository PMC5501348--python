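import networkx as nx
import numpy as np
import pytest

from eegfc.connectivity import DependenceMatrix
from eegfc.graphs import (
    BinaryGraph,
    binarize_sparsity,
    binarize_statistical,
    compute_metrics,
    eco_threshold,
    flip_hemispheres,
    global_efficiency,
    interdensity,
    intradensity,
    local_efficiency,
)
from eegfc.montage import CHANNELS_58, default_hemisphere_map


def _graph(adj, labels=None):
    adj = np.asarray(adj)
    labels = labels or tuple(f"n{i}" for i in range(adj.shape[0]))
    return BinaryGraph(adjacency=adj, labels=labels, threshold_kind="sparsity",
                       threshold_value=0.0)


def _dep_matrix(values, labels=None, subject="s", session="pre", band="b"):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"n{i}" for i in range(values.shape[0]))
    return DependenceMatrix(subject_id=subject, session=session, band=band,
                            values=values, labels=labels, n_trials_averaged=1)


def _random_symmetric(rng, n):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v


def floyd_warshall_efficiency(adj):
    """Brute-force shortest-path oracle for global efficiency."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    tot = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
              if i != j and np.isfinite(d[i, j]))
    return tot / (n * (n - 1))


class TestEcoThreshold:
    @pytest.mark.parametrize("n,expected", [(58, 3 / 57), (4, 1.0), (301, 0.01)])
    def test_formula(self, n, expected):
        assert eco_threshold(n) == pytest.approx(expected)

    def test_58_nodes_rounds_to_0053(self):
        assert round(eco_threshold(58), 3) == 0.053


class TestBinarizeSparsity:
    def test_exact_edge_count_58_nodes(self, rng):
        m = _dep_matrix(_random_symmetric(rng, 58), labels=CHANNELS_58)
        g = binarize_sparsity(m, 0.05)
        assert g.n_edges == 83 == round(0.05 * 1653)

    def test_half_sparsity_small_graph(self, rng):
        m = _dep_matrix(_random_symmetric(rng, 4))
        g = binarize_sparsity(m, 0.5)
        assert g.n_edges == 3

    def test_idempotent_and_keeps_strongest(self, rng):
        m = _dep_matrix(_random_symmetric(rng, 10))
        g1 = binarize_sparsity(m, 0.5)
        g2 = binarize_sparsity(m, 0.5)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        kept = m.values[g1.adjacency.astype(bool)]
        dropped = m.values[(g1.adjacency == 0) & ~np.eye(10, dtype=bool)]
        assert kept.min() >= dropped.max()

    def test_tied_values_broken_by_index_order(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0.0)
        g = binarize_sparsity(_dep_matrix(v), 1 / 3)  # keep 2 of 6
        assert g.n_edges == 2
        assert g.adjacency[0, 1] == 1 and g.adjacency[0, 2] == 1

    def test_density_matches_t(self, rng):
        m = _dep_matrix(_random_symmetric(rng, 58), labels=CHANNELS_58)
        for t in (0.05, 0.2, 0.5):
            g = binarize_sparsity(m, t)
            assert abs(g.n_edges / 1653 - t) <= 1 / 1653

    def test_out_of_range_rejected(self, rng):
        m = _dep_matrix(_random_symmetric(rng, 4))
        for t in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError, match="0, 0.5"):
                binarize_sparsity(m, t)


class TestBinarizeStatistical:
    def test_constant_entries_give_empty_graphs(self):
        v = np.full((6, 6), 0.4)
        np.fill_diagonal(v, 0.0)
        with pytest.warns(UserWarning, match="constant"):
            g1, g2 = binarize_statistical(_dep_matrix(v), _dep_matrix(v, session="post"))
        assert g1.n_edges == 0 and g2.n_edges == 0

    def test_outlier_cells_survive(self):
        # pooled entries: mostly 0 with a few 1s; median+SD < 1 keeps only 1s
        rng = np.random.default_rng(0)
        v = np.zeros((16, 16))
        ones = [(0, 1), (2, 3), (4, 5)]
        for i, j in ones:
            v[i, j] = v[j, i] = 1.0
        m_pre = _dep_matrix(v)
        m_post = _dep_matrix(np.zeros((16, 16)), session="post")
        pooled = np.concatenate([m_pre.offdiag_upper(), m_post.offdiag_upper()])
        thr = np.median(pooled) + pooled.std(ddof=1)
        assert 0 < thr < 1
        g1, g2 = binarize_statistical(m_pre, m_post)
        assert g1.n_edges == 3 and g2.n_edges == 0

    def test_identical_sessions_give_identical_graphs(self, rng):
        v = _random_symmetric(rng, 10)
        g1, g2 = binarize_statistical(_dep_matrix(v), _dep_matrix(v, session="post"))
        assert np.array_equal(g1.adjacency, g2.adjacency)


class TestEfficiency:
    def test_analytic_cases(self):
        complete = 1 - np.eye(4, dtype=int)
        assert global_efficiency(_graph(complete)) == 1.0
        assert local_efficiency(_graph(complete))[0] == 1.0
        empty = np.zeros((5, 5), dtype=int)
        assert global_efficiency(_graph(empty)) == 0.0
        path3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert global_efficiency(_graph(path3)) == pytest.approx(5 / 6)
        star = np.zeros((5, 5), dtype=int)
        star[0, 1:] = star[1:, 0] = 1
        assert local_efficiency(_graph(star))[0] == 0.0

    def test_triangle_with_pendant_per_node_values(self):
        adj = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (0, 2), (1, 2), (2, 3)]:
            adj[i, j] = adj[j, i] = 1
        net, per_node = local_efficiency(_graph(adj))
        # nodes 0,1 have fully connected neighbor pairs; node 2's neighbors
        # {0,1,3} have one of three possible edges; node 3 has one neighbor
        assert per_node == pytest.approx([1.0, 1.0, 1 / 3, 0.0])
        assert net == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)

    def test_matches_oracles_on_random_graphs(self, rng):
        """Global/local efficiency equal a Floyd-Warshall oracle and the
        networkx reference on 500 random graphs with up to 12 nodes."""
        for _ in range(500):
            n = int(rng.integers(3, 13))
            p = rng.uniform(0.1, 0.9)
            adj = (rng.random((n, n)) < p).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            g = _graph(adj)
            assert global_efficiency(g) == pytest.approx(
                floyd_warshall_efficiency(adj), abs=1e-12)
            gx = nx.from_numpy_array(adj)
            assert global_efficiency(g) == pytest.approx(
                nx.global_efficiency(gx), abs=1e-12)
            assert local_efficiency(g)[0] == pytest.approx(
                nx.local_efficiency(gx), abs=1e-12)

    def test_monotone_under_edge_addition(self, rng):
        n = 10
        adj = np.zeros((n, n), dtype=int)
        prev_glo, prev_loc = 0.0, None
        order = [(i, j) for i in range(n) for j in range(i + 1, n)]
        rng.shuffle(order)
        for i, j in order[:25]:
            adj[i, j] = adj[j, i] = 1
            glo = global_efficiency(_graph(adj))
            assert glo >= prev_glo - 1e-12
            prev_glo = glo


class TestDensities:
    def test_interdensity_extremes_and_count(self, rng):
        hmap = default_hemisphere_map()
        n = 58
        adj = np.zeros((n, n), dtype=int)
        ia = [CHANNELS_58.index(l) for l in hmap.affected_set]
        ib = [CHANNELS_58.index(l) for l in hmap.unaffected_set]
        g = BinaryGraph(adj.copy(), CHANNELS_58, "sparsity", 0.0)
        assert interdensity(g, hmap) == 0.0
        for i in ia:
            for j in ib:
                adj[i, j] = adj[j, i] = 1
        assert interdensity(BinaryGraph(adj, CHANNELS_58, "sparsity", 0.0),
                            hmap) == 1.0
        adj2 = np.zeros((n, n), dtype=int)
        pairs = [(i, j) for i in ia for j in ib]
        for i, j in pairs[:45]:
            adj2[i, j] = adj2[j, i] = 1
        assert interdensity(BinaryGraph(adj2, CHANNELS_58, "sparsity", 0.0),
                            hmap) == pytest.approx(45 / 225)

    def test_intradensity_cases(self):
        labels = ("a", "b", "c")
        full = 1 - np.eye(3, dtype=int)
        assert intradensity(_graph(full, labels), labels) == 1.0
        one = np.zeros((3, 3), dtype=int)
        one[0, 1] = one[1, 0] = 1
        assert intradensity(_graph(one, labels), labels) == pytest.approx(1 / 3)
        assert intradensity(_graph(np.zeros((3, 3), dtype=int), labels),
                            labels) == 0.0
        with pytest.raises(ValueError, match="at least 2"):
            intradensity(_graph(full, labels), ("a",))

    def test_densities_match_edge_enumeration_oracle(self, rng):
        hmap = default_hemisphere_map()
        ia = [CHANNELS_58.index(l) for l in hmap.affected_set]
        ib = [CHANNELS_58.index(l) for l in hmap.unaffected_set]
        for _ in range(100):
            adj = (rng.random((58, 58)) < 0.1).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            g = BinaryGraph(adj, CHANNELS_58, "sparsity", 0.0)
            cross = sum(adj[i, j] for i in ia for j in ib)
            within = sum(adj[i, j] for ki, i in enumerate(ib)
                         for j in ib[ki + 1:])
            assert interdensity(g, hmap) == pytest.approx(cross / 225)
            assert intradensity(g, hmap.unaffected_set) == pytest.approx(
                within / 105)


class TestFlip:
    def _matrix(self, rng):
        v = _random_symmetric(rng, 58)
        return _dep_matrix(v, labels=CHANNELS_58)

    def test_right_lesion_identity(self, rng):
        m = self._matrix(rng)
        assert flip_hemispheres(m, "right") is m

    def test_involution(self, rng):
        m = self._matrix(rng)
        f2 = flip_hemispheres(flip_hemispheres(m, "left"), "left")
        assert np.array_equal(f2.values, m.values)

    def test_flip_moves_intradensity_between_hemisphere_sets(self, rng):
        """Measuring the affected (left) set after flipping equals measuring
        the flip image of that set before flipping."""
        hmap = default_hemisphere_map(symmetric=True)
        m = self._matrix(rng)
        g_flip = binarize_sparsity(flip_hemispheres(m, "left", hmap), 0.05)
        g_orig = binarize_sparsity(m, 0.05)
        flipped_set = tuple(hmap.flip_map[l] for l in hmap.affected_set)
        assert intradensity(g_flip, hmap.affected_set) == pytest.approx(
            intradensity(g_orig, flipped_set))

    def test_unmapped_label_rejected(self, rng):
        m = _dep_matrix(_random_symmetric(rng, 4))
        with pytest.raises(KeyError, match="flip mapping"):
            flip_hemispheres(m, "left")


def test_compute_metrics_panel_in_unit_interval(rng):
    v = _random_symmetric(rng, 58)
    g = binarize_sparsity(_dep_matrix(v, labels=CHANNELS_58), 0.05)
    rec = compute_metrics(g)
    for name, value in rec.as_dict().items():
        assert 0.0 <= value <= 1.0, name
    assert rec.E_loc_node.shape == (58,)
    assert np.all((rec.E_loc_node >= 0) & (rec.E_loc_node <= 1))
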