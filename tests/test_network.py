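import numpy as np
import pandas as pd
import networkx as nx
import pytest
from scipy import stats

from oracles import bh_stepup, graph_modularity, max_modularity_exhaustive, spearman_permutation_p
from sphingonet import (
    bh_adjust,
    build_distance_network,
    fast_greedy_partition,
    interclass_distance,
    modularity,
    permutation_interclass_test,
    sample_lipid_matrix,
    spearman_matrix,
    steiger_compare,
    stratum_network,
)
from sphingonet.network import CorrelationResult, distance_matrix_fast


def corr_from_rho(rho, p_adj, names=None):
    names = names or [f"s{i}" for i in range(len(rho))]
    mk = lambda a: pd.DataFrame(np.asarray(a, float), index=names, columns=names)
    return CorrelationResult(mk(rho), mk(p_adj), mk(p_adj), n=100)


def graph_from_weights(w):
    g = nx.Graph()
    n = w.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, weight=float(w[i, j]))
    return g


def two_triangles():
    w = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        w[i, j] = w[j, i] = 1.0
    return w


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, toy_matrix_factory):
        x = np.linspace(1, 5, 20)
        mat = toy_matrix_factory(np.c_[x, x**3], ["a", "b"], ["CER", "LCER"])
        res = spearman_matrix(mat)
        assert res.rho.loc["a", "b"] == pytest.approx(1.0)
        assert res.p_raw.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_midrank_example(self, toy_matrix_factory):
        mat = toy_matrix_factory(np.c_[[1, 2, 3, 4, 5], [5, 6, 7, 8, 7]], ["a", "b"], ["CER", "CER"])
        res = spearman_matrix(mat)
        # ranks of b with the midrank tie: (1, 2, 3.5, 5, 3.5); Pearson of
        # ranks = 8/sqrt(10*9.5)
        assert res.rho.loc["a", "b"] == pytest.approx(8.0 / np.sqrt(95.0), abs=1e-12)

    def test_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        rho, p_analytic = stats.spearmanr(x, y)
        assert p_analytic == pytest.approx(spearman_permutation_p(x, y, seed=1), abs=0.02)

    def test_invariants_and_pairwise_missing(self, toy_matrix_factory):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(size=(40, 4))
        vals[rng.random((40, 4)) < 0.1] = np.nan
        mat = toy_matrix_factory(vals, list("abcd"), ["CER"] * 4)
        res = spearman_matrix(mat)
        np.testing.assert_allclose(res.rho, res.rho.T)
        np.testing.assert_allclose(np.diag(res.rho), 1.0)
        off = ~np.eye(4, dtype=bool)
        assert (res.p_adj.to_numpy()[off] >= res.p_raw.to_numpy()[off] - 1e-15).all()
        assert res.p_adj.to_numpy().max() <= 1.0
        # pairwise-complete agreement with scipy on one NaN-bearing pair
        ok = ~(np.isnan(vals[:, 0]) | np.isnan(vals[:, 1]))
        ref, _ = stats.spearmanr(vals[ok, 0], vals[ok, 1])
        assert res.rho.loc["a", "b"] == pytest.approx(ref, abs=1e-12)

    def test_constant_species_named(self, toy_matrix_factory):
        vals = np.c_[np.ones(10), np.arange(10.0) + 1]
        mat = toy_matrix_factory(vals, ["flat", "x"], ["CER", "CER"])
        with pytest.raises(ValueError, match="flat"):
            spearman_matrix(mat)

    def test_too_few_subjects(self, toy_matrix_factory):
        mat = toy_matrix_factory(np.random.default_rng(0).lognormal(size=(3, 2)), ["a", "b"], ["CER", "CER"])
        with pytest.raises(ValueError, match="4 subjects"):
            spearman_matrix(mat)


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 50))
        np.testing.assert_allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_dominates_raw_p(self):
        rng = np.random.default_rng(99)
        p = rng.random(30)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDistanceNetwork:
    def test_significant_edge_formula(self):
        corr = corr_from_rho([[1, 0.8], [0.8, 1]], [[0, 0.001], [0.001, 0]])
        net = build_distance_network(corr)
        assert net.d.iloc[0, 1] == pytest.approx(0.2)
        assert net.graph.edges[("s0", "s1")]["weight"] == pytest.approx(0.8)

    def test_nonsignificant_pair_zeroed(self):
        corr = corr_from_rho([[1, 0.5], [0.5, 1]], [[0, 0.20], [0.20, 0]])
        net = build_distance_network(corr)
        assert net.d.iloc[0, 1] == 1.0
        assert net.graph.number_of_edges() == 0

    def test_negative_rho_uses_magnitude(self):
        corr = corr_from_rho([[1, -0.9], [-0.9, 1]], [[0, 0.001], [0.001, 0]])
        net = build_distance_network(corr)
        assert net.d.iloc[0, 1] == pytest.approx(0.1)

    def test_distance_respects_correlation_ordering(self, mini_panel):
        mat = sample_lipid_matrix(mini_panel, 0.6, 0.3, n=300, seed=2)
        corr, net, _ = stratum_network(mat, mat.subjects)
        rho = np.abs(corr.rho.to_numpy())
        d = net.d.to_numpy()
        iu = np.triu_indices_from(d, 1)
        sig = d[iu] < 1.0
        pairs = sorted(zip(rho[iu][sig], d[iu][sig]))
        ds = np.array([p[1] for p in pairs])
        assert (np.diff(ds) <= 1e-12).all()  # larger |rho| => strictly shorter d

    def test_fast_path_matches_object_path(self, mini_panel):
        mat = sample_lipid_matrix(mini_panel, 0.5, 0.2, n=150, seed=5)
        corr = spearman_matrix(mat)
        d_obj = build_distance_network(corr).d.to_numpy()
        d_fast = distance_matrix_fast(mat.abundances.to_numpy())
        np.testing.assert_allclose(d_obj, d_fast, atol=1e-12)


class TestModularity:
    def test_closed_forms(self):
        w = two_triangles()
        g = graph_from_weights(w)
        split = {i: 0 if i < 3 else 1 for i in range(6)}
        assert modularity(g, split) == pytest.approx(0.5)
        assert modularity(g, {i: 0 for i in range(6)}) == pytest.approx(0.0)
        tri = graph_from_weights(two_triangles()[:3, :3])
        assert modularity(tri, {0: 0, 1: 1, 2: 2}) == pytest.approx(-1.0 / 3.0)

    def test_matches_networkx_on_random_graph(self):
        rng = np.random.default_rng(31)
        w = np.triu(rng.random((7, 7)) * (rng.random((7, 7)) < 0.5), 1)
        w = w + w.T
        g = graph_from_weights(w)
        part = {i: i % 3 for i in range(7)}
        communities = [{n for n in g if part[n] == c} for c in range(3)]
        ref = nx.algorithms.community.modularity(g, communities, weight="weight")
        assert modularity(g, part) == pytest.approx(ref, abs=1e-12)

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.raises(ValueError):
            modularity(g, {i: 0 for i in range(3)})


class TestFastGreedy:
    def test_two_disjoint_triangles(self):
        part = fast_greedy_partition(graph_from_weights(two_triangles()))
        assert part.q == pytest.approx(0.5)
        clusters = sorted(sorted(c) for c in part.clusters)
        assert clusters == [[0, 1, 2], [3, 4, 5]]

    def test_complete_graph_single_cluster(self):
        w = np.ones((5, 5)) - np.eye(5)
        part = fast_greedy_partition(graph_from_weights(w))
        assert len(part.clusters) == 1

    def test_isolated_nodes_stay_singletons(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        part = fast_greedy_partition(graph_from_weights(w))
        labels = part.labels
        assert labels[0] == labels[1]
        assert labels[2] != labels[3] != labels[0]

    def test_edgeless_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.raises(ValueError):
            fast_greedy_partition(g)

    @pytest.mark.parametrize("seed", range(15))
    def test_never_beats_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.6), 1)
        w = w + w.T
        if w.sum() == 0:
            w[0, 1] = w[1, 0] = 1.0
        part = fast_greedy_partition(graph_from_weights(w))
        q_opt, _ = max_modularity_exhaustive(w)
        assert part.q <= q_opt + 1e-10
        # reported Q matches the direct formula on its own partition
        blocks = [sorted(c) for c in part.clusters]
        assert part.q == pytest.approx(graph_modularity(w, blocks), abs=1e-12)

    def test_planted_two_blocks_recovered_exactly(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i < j:
                        w[i, j] = w[j, i] = 1.0
        w[0, 4] = w[4, 0] = w[1, 5] = w[5, 1] = 0.05
        part = fast_greedy_partition(graph_from_weights(w))
        q_opt, _ = max_modularity_exhaustive(w)
        assert part.q == pytest.approx(q_opt, abs=1e-12)
        assert sorted(sorted(c) for c in part.clusters) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_deterministic(self, mini_panel):
        mat = sample_lipid_matrix(mini_panel, 0.6, 0.2, n=200, seed=9)
        p1 = fast_greedy_partition(stratum_network(mat, mat.subjects)[1])
        p2 = fast_greedy_partition(stratum_network(mat, mat.subjects)[1])
        assert p1.labels == p2.labels and p1.q == p2.q


class TestInterclassDistance:
    def make_net(self, d):
        names = ["a1", "a2", "b1"]
        corr = corr_from_rho(np.eye(3), np.ones((3, 3)), names)
        net = build_distance_network(corr)
        net.d.iloc[:, :] = d
        return net

    def test_arithmetic_mean_of_cross_pairs(self):
        d = np.array([[0.0, 0.9, 0.2], [0.9, 0.0, 0.4], [0.2, 0.4, 0.0]])
        net = self.make_net(d)
        cm = {"a1": "CER", "a2": "CER", "b1": "LCER"}
        assert interclass_distance(net, cm, "CER", "LCER") == pytest.approx(0.3)
        assert interclass_distance(net, cm, "LCER", "CER") == pytest.approx(0.3)

    def test_all_nonsignificant_gives_one(self):
        net = self.make_net(np.ones((3, 3)) - np.eye(3))
        cm = {"a1": "CER", "a2": "CER", "b1": "LCER"}
        assert interclass_distance(net, cm, "CER", "LCER") == 1.0

    def test_empty_class_rejected(self):
        net = self.make_net(np.ones((3, 3)))
        with pytest.raises(ValueError):
            interclass_distance(net, {"a1": "CER", "a2": "CER", "b1": "CER"}, "CER", "LCER")


class TestPermutationTest:
    def test_identical_strata_null(self, mini_panel):
        mat = sample_lipid_matrix(mini_panel, 0.5, 0.2, n=80, seed=41)
        res = permutation_interclass_test(mat, mat.subjects, mat.subjects,
                                          ("CER", "LCER"), n_perm=50, seed=1)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_pvalue_bounds_and_seed_determinism(self, mini_panel):
        rng = np.random.default_rng(42)
        a = sample_lipid_matrix(mini_panel, 0.6, 0.5, n=120, seed=1)
        b = sample_lipid_matrix(mini_panel, 0.6, 0.1, n=120, seed=2)
        pooled = pd.concat([a.abundances, b.abundances], ignore_index=True)
        pooled.index.name = "subject_id"
        from sphingonet import LipidMatrix

        mat = LipidMatrix(pooled, a.class_map)
        kw = dict(class_pair=("CER", "LCER"), n_perm=99, seed=7)
        r1 = permutation_interclass_test(mat, range(120), range(120, 240), **kw)
        r2 = permutation_interclass_test(mat, range(120), range(120, 240), **kw)
        assert r1.p_value == r2.p_value and r1.delta == r2.delta
        assert 0.0 < r1.p_value <= 1.0
        assert r1.p_value == pytest.approx(0.01, abs=0.011)  # strong planted difference

    def test_invalid_inputs(self, mini_panel):
        mat = sample_lipid_matrix(mini_panel, 0.5, 0.2, n=40, seed=3)
        with pytest.raises(ValueError):
            permutation_interclass_test(mat, mat.subjects, mat.subjects, ("CER", "LCER"), n_perm=0)
        with pytest.raises(ValueError):
            permutation_interclass_test(mat, mat.subjects[:2], mat.subjects, ("CER", "LCER"), n_perm=10)


class TestSteiger:
    def test_identical_matrices(self, mini_panel):
        mat = sample_lipid_matrix(mini_panel, 0.5, 0.2, n=100, seed=6)
        corr = spearman_matrix(mat)
        res = steiger_compare(corr, corr)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 8 * 7 // 2

    def test_single_pair_hand_computation(self):
        c1 = corr_from_rho([[1, 0.5], [0.5, 1]], np.zeros((2, 2)))
        c2 = corr_from_rho([[1, 0.3], [0.3, 1]], np.zeros((2, 2)))
        c1.n = c2.n = 103
        res = steiger_compare(c1, c2)
        z1, z2 = np.arctanh(0.5), np.arctanh(0.3)
        assert z1 == pytest.approx(0.5493, abs=1e-4)
        assert z2 == pytest.approx(0.3095, abs=1e-4)
        assert res.chi_square == pytest.approx((z1 - z2) ** 2 / 0.02, rel=1e-12)
        assert res.df == 1
        # equivalent two-sample correlation z-test
        z_stat = (z1 - z2) / np.sqrt(1 / 100 + 1 / 100)
        p_z = 2 * stats.norm.sf(abs(z_stat))
        assert res.p_value == pytest.approx(p_z, rel=1e-10)

    def test_perfect_correlation_rejected(self):
        c1 = corr_from_rho([[1, 1.0], [1.0, 1]], np.zeros((2, 2)))
        c2 = corr_from_rho([[1, 0.3], [0.3, 1]], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            steiger_compare(c1, c2)

    def test_mismatched_species_rejected(self, mini_panel):
        mat = sample_lipid_matrix(mini_panel, 0.5, 0.2, n=50, seed=8)
        corr = spearman_matrix(mat)
        other = spearman_matrix(mat.select_species(mat.species[:4]))
        with pytest.raises(ValueError):
            steiger_compare(corr, other)


def test_pipeline_monotone_invariance(mini_panel):
    """Cubing abundances changes no correlation, distance, cluster, or test output."""
    from sphingonet import LipidMatrix

    mat = sample_lipid_matrix(mini_panel, 0.6, 0.25, n=150, seed=77)
    cubed = LipidMatrix(mat.abundances**3, mat.class_map)
    c1, n1, p1 = stratum_network(mat, mat.subjects)
    c2, n2, p2 = stratum_network(cubed, cubed.subjects)
    pd.testing.assert_frame_equal(c1.rho, c2.rho)
    pd.testing.assert_frame_equal(n1.d, n2.d)
    assert p1.labels == p2.labels
    half_a, half_b = mat.subjects[:75], mat.subjects[75:]
    r1 = permutation_interclass_test(mat, half_a, half_b, ("CER", "LCER"), n_perm=30, seed=5)
    r2 = permutation_interclass_test(cubed, half_a, half_b, ("CER", "LCER"), n_perm=30, seed=5)
    assert r1.delta == r2.delta and r1.p_value == r2.p_value
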