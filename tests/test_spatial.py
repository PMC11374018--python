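"""Moran's I, permutation inference, BH, neighborhood enrichment."""

import numpy as np
import pytest

import spotfuse as sf
from spotfuse.errors import ParameterError, ValidationError, ZeroVarianceError
from spotfuse.spatial import morans_i_table, normalize_log1p, screen_genes

from conftest import morans_i_bruteforce


def _random_graph(rng, n, p=0.2):
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p]
    if not pairs:
        pairs = [(0, 1)]
    return sf.WeightsGraph([f"n{i}" for i in range(n)], np.array(pairs))


class TestMoransI:
    def test_two_node_antithetic_is_minus_one(self):
        g = sf.WeightsGraph(["a", "b"], [[0, 1]])
        assert sf.morans_i([1.0, -1.0], g) == pytest.approx(-1.0)

    def test_constant_values_zero_variance_error(self):
        g = sf.WeightsGraph(["a", "b"], [[0, 1]])
        with pytest.raises(ZeroVarianceError):
            sf.morans_i([3.0, 3.0], g)

    @pytest.mark.parametrize("row_standardize", [False, True])
    def test_matches_bruteforce_double_loop(self, row_standardize):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            g = _random_graph(rng, n)
            x = rng.normal(size=n)
            if row_standardize:
                # brute force with row-standardized dense weights
                w = np.zeros((n, n))
                for (i, j), wt in zip(g.edges, g.weights):
                    w[i, j] = w[j, i] = wt
                rs = w.sum(axis=1, keepdims=True)
                w = np.divide(w, rs, out=np.zeros_like(w), where=rs > 0)
                z = x - x.mean()
                expect = (n / w.sum()) * (z @ w @ z) / (z @ z)
                got = sf.morans_i(x, g, row_standardize=True)
            else:
                expect = morans_i_bruteforce(x, g)
                got = sf.morans_i(x, g)
            assert got == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_node_reordering(self):
        rng = np.random.default_rng(3)
        g = _random_graph(rng, 15)
        x = rng.normal(size=15)
        perm = rng.permutation(15)
        inv = np.argsort(perm)
        g2 = sf.WeightsGraph(
            [g.node_ids[i] for i in perm],
            np.array([[inv[i], inv[j]] for i, j in g.edges]),
        )
        assert sf.morans_i(x[perm], g2) == pytest.approx(sf.morans_i(x, g), abs=1e-12)

    def test_row_standardized_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = _random_graph(rng, 12, p=0.4)
            x = rng.normal(size=12)
            assert abs(sf.morans_i(x, g, row_standardize=True)) <= 1.0 + 1e-9


class TestMoranPermutation:
    def test_identity_permutation_gives_p_one(self):
        g = sf.WeightsGraph(["a", "b", "c"], [[0, 1], [1, 2]])
        res = sf.morans_i_test([1.0, 5.0, 2.0], g, n_perm=1, seed=0)
        assert res.p_perm <= 1.0
        assert res.p_perm >= 1.0 / 2.0  # (1 + c)/(1+1) with c ∈ {0, 1}

    def test_type_i_error_near_nominal(self):
        grid = sf.generate_visium_grid(10, 10)
        g = sf.build_spot_graph(grid)
        rng = np.random.default_rng(123)
        n_vars = 200
        vals = rng.normal(size=(100, n_vars))
        df = morans_i_table(vals, [f"v{i}" for i in range(n_vars)], g, n_perm=199, seed=5)
        frac = (df["p_perm"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_vars)
        assert abs(frac - 0.05) < 3 * se

    def test_smooth_gradient_strongly_significant(self):
        grid = sf.generate_visium_grid(10, 10)
        g = sf.build_spot_graph(grid)
        vals = grid.x_um + grid.y_um
        res = sf.morans_i_test(vals, g, n_perm=999, seed=0)
        assert res.I > 0.5
        assert res.p_perm <= 0.01

    def test_deterministic_given_seed(self):
        g = sf.WeightsGraph([f"n{i}" for i in range(10)], [[i, i + 1] for i in range(9)])
        x = np.arange(10.0) ** 2
        a = sf.morans_i_test(x, g, n_perm=99, seed=42)
        b = sf.morans_i_test(x, g, n_perm=99, seed=42)
        assert a.p_perm == b.p_perm


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sf.bh_fdr([0.03]), [0.03])

    def test_stepup_arithmetic(self):
        np.testing.assert_allclose(
            sf.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(sf.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sf.bh_fdr([0.5, 0.0])

    def test_monotone_and_dominates_input(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=50)
        q = sf.bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestEnrichment:
    def test_single_type_z_zero(self):
        g = sf.WeightsGraph(["a", "b", "c"], [[0, 1], [1, 2]])
        labels = np.array(["T", "T", "T"], dtype=object)
        enr = sf.neighborhood_enrichment(labels, g, n_perm=99, seed=0)
        assert enr.z.shape == (1, 1)
        assert enr.z[0, 0] == 0.0

    def test_two_cliques_positive_diagonal(self):
        # two same-type cliques, no cross edges
        n = 10
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, j) for i in range(5, n) for j in range(i + 1, n)]
        g = sf.WeightsGraph([f"n{i}" for i in range(n)], np.array(edges))
        labels = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
        enr = sf.neighborhood_enrichment(labels, g, n_perm=999, seed=0)
        assert enr.z[0, 0] > 0 and enr.z[1, 1] > 0
        assert enr.z[0, 1] < 0
        np.testing.assert_allclose(enr.z, enr.z.T)

    def test_edge_count_conservation_and_symmetry(self, fused):
        grid, truth, _, _, labelled, _ = fused
        g = sf.build_cell_graph(labelled, k=6)
        labels = labelled.type_label
        enr = sf.neighborhood_enrichment(labels, g, n_perm=99, seed=1)
        o = enr.observed
        np.testing.assert_array_equal(o, o.T)
        n_labelled_edges = sum(
            1 for i, j in g.edges
            if labels[i] is not None and labels[j] is not None
        )
        assert np.triu(o).sum() == n_labelled_edges

    def test_iid_null_rarely_exceeds_3(self):
        grid = sf.generate_visium_grid(8, 8)
        g = sf.build_spot_graph(grid)
        rng = np.random.default_rng(17)
        exceed = total = 0
        for rep in range(20):
            labels = np.array(rng.choice(["A", "B", "C"], size=g.n_nodes), dtype=object)
            enr = sf.neighborhood_enrichment(labels, g, n_perm=199, seed=rep)
            iu = np.triu_indices(3)
            exceed += (np.abs(enr.z[iu]) > 3).sum()
            total += len(iu[0])
        assert exceed / total <= 0.01

    def test_all_unlabelled_rejected(self):
        g = sf.WeightsGraph(["a", "b"], [[0, 1]])
        with pytest.raises(ValidationError):
            sf.neighborhood_enrichment(np.array([None, None], dtype=object), g)


class TestGeneScreen:
    def test_normalization_keeps_zero_spots_zero(self, small_experiment):
        _, _, _, counts = small_experiment
        norm = normalize_log1p(counts)
        zero_rows = counts.counts.sum(axis=1) == 0
        assert (norm[zero_rows] == 0).all()

    def test_screen_returns_q_and_respects_top_n(self, small_experiment):
        grid, _, _, counts = small_experiment
        g = sf.build_spot_graph(grid)
        df = screen_genes(counts, g, top_n=10, n_perm=49, seed=0)
        assert len(df) == 10
        ok = df["p_perm"].notna()
        assert (df.loc[ok, "q"] >= df.loc[ok, "p_perm"] - 1e-12).all()
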