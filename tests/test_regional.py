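"""Infiltration profiles, two-proportion Z-tests, and regional DE."""

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import box

import spotfuse as sf
from spotfuse.errors import ParameterError, ValidationError
from spotfuse.regional import DEFAULT_BIN_EDGES


class TestTwoPropZ:
    def test_equal_proportions_z_zero(self):
        r = sf.two_prop_ztest(5, 10, 50, 100)
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_verified_example(self):
        # pooled p̂ = 0.5, SE = √(0.25·0.2) = 0.223607, z = 0.8/0.223607
        r = sf.two_prop_ztest(9, 10, 1, 10)
        assert r.z == pytest.approx(3.5777, abs=5e-4)
        assert r.p == pytest.approx(3.47e-4, rel=0.02)

    def test_degenerate_pool_convention(self):
        r = sf.two_prop_ztest(0, 10, 0, 10)
        assert r.z == 0.0 and r.p == 1.0
        r = sf.two_prop_ztest(10, 10, 10, 10)
        assert r.z == 0.0 and r.p == 1.0

    def test_antisymmetric_under_group_swap(self):
        a = sf.two_prop_ztest(7, 20, 3, 15)
        b = sf.two_prop_ztest(3, 15, 7, 20)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ParameterError):
            sf.two_prop_ztest(0, 0, 1, 5)


def _mixed_tissue(seed, n_rows=14, n_cols=14, n_types=2):
    grid = sf.generate_visium_grid(n_rows, n_cols)
    params = sf.SimulationParams(
        n_types=n_types, seed=seed, frac_outside_spots=0.0, cells_per_spot_mean=6.0
    )
    truth = sf.simulate_tissue(grid, params)
    return grid, truth


class TestInfiltration:
    def test_null_calibration_uniform_mixture(self):
        grid, truth = _mixed_tissue(seed=3)
        region = box(300, 300, 1000, 900)
        prof = sf.infiltration_profile(truth.cells, region, "roi")
        tests = prof.table.dropna(subset=["p"])
        frac = (tests["p"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(tests))
        assert abs(frac - 0.05) <= 3 * se + 1e-12

    def test_positive_control_enriched_region(self):
        grid = sf.generate_visium_grid(20, 20)
        region = box(400, 300, 1500, 1400)
        params = sf.SimulationParams(
            n_types=2, seed=4, frac_outside_spots=0.0, cells_per_spot_mean=6.0,
            region_specs=[(region, "type_A", 5.0)],
        )
        truth = sf.simulate_tissue(grid, params)
        prof = sf.infiltration_profile(truth.cells, region, "roi")
        inner = prof.table[
            (prof.table["bin_lo_um"] == -200.0) & (prof.table["cell_type"] == "type_A")
        ].iloc[0]
        assert inner["z"] > 0
        assert inner["q"] <= 0.05

    def test_counts_conserved_across_bins(self):
        grid, truth = _mixed_tissue(seed=5)
        region = box(300, 300, 1000, 900)
        prof = sf.infiltration_profile(truth.cells, region, "roi")
        from spotfuse.geometry import distance_to_boundary

        d = distance_to_boundary(truth.cells.coords(), region)
        in_range = ((d >= DEFAULT_BIN_EDGES[0]) & (d < DEFAULT_BIN_EDGES[-1])).sum()
        assert prof.table["count"].sum() == in_range

    def test_single_cell_bin_proportion_one(self):
        cells = sf.CellTable(
            cell_ids=["a", "b", "c"],
            x_um=[-225.0, 25.0, 1000.0],
            y_um=[50.0, 50.0, 50.0],
            morphology=np.ones((3, 1)),
            feature_names=["f"],
            type_label=np.array(["A", "B", "B"], dtype=object),
        )
        region = box(0, 0, 100, 100)
        # cell a sits 225 µm left of the region: outside every bin → reference
        prof = sf.infiltration_profile(cells, region, "roi")
        row = prof.table[
            (prof.table["cell_type"] == "B") & (prof.table["count"] > 0)
        ].iloc[0]
        assert row["bin_total"] == 1
        assert row["proportion"] == 1.0
        assert np.isfinite(row["z"])

    def test_all_bins_empty_rejected(self):
        cells = sf.CellTable(
            cell_ids=["a"], x_um=[5000.0], y_um=[5000.0],
            morphology=[[1.0]], feature_names=["f"],
            type_label=np.array(["A"], dtype=object),
        )
        with pytest.raises(ValidationError):
            sf.infiltration_profile(cells, box(0, 0, 10, 10), "roi")

    def test_empty_bins_reported_with_null_stats(self):
        cells = sf.CellTable(
            cell_ids=["a", "b"], x_um=[25.0, 600.0], y_um=[50.0, 50.0],
            morphology=np.ones((2, 1)), feature_names=["f"],
            type_label=np.array(["A", "A"], dtype=object),
        )
        prof = sf.infiltration_profile(cells, box(0, 0, 100, 100), "roi")
        empty = prof.table[prof.table["bin_total"] == 0]
        assert len(empty) > 0
        assert empty["p"].isna().all()


class TestCompareRegionsDE:
    def test_null_pvalues_uniform(self):
        grid = sf.generate_visium_grid(16, 16)
        params = sf.SimulationParams(n_types=3, seed=6, cells_per_spot_mean=8.0)
        _, truth, _, counts = sf.simulate_experiment(grid, params)
        rng = np.random.default_rng(0)
        perm = rng.permutation(grid.n_spots)
        a = [grid.barcodes[i] for i in perm[:128]]
        b = [grid.barcodes[i] for i in perm[128:]]
        de = sf.compare_regions_de(counts, a, b)
        ks = stats.kstest(de["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_spikein_gene_ranks_first(self):
        grid = sf.generate_visium_grid(12, 12)
        params = sf.SimulationParams(n_types=2, seed=7, cells_per_spot_mean=6.0)
        _, truth, _, counts = sf.simulate_experiment(grid, params)
        half = grid.n_spots // 2
        a, b = grid.barcodes[:half], grid.barcodes[half:]
        boosted = counts.counts.copy()
        ia = [i for i, bc in enumerate(counts.spot_barcodes) if bc in set(a)]
        boosted[np.ix_(ia, [0])] *= 2
        boosted[ia, 0] += 2  # double-ish the first gene's rate in group A
        cm = sf.CountMatrix(counts.spot_barcodes, counts.gene_ids, boosted)
        de = sf.compare_regions_de(cm, a, b)
        assert de["gene_id"].iloc[0] == counts.gene_ids[0]
        assert de["q"].iloc[0] == de["q"].min()

    def test_swap_groups_flips_log2fc(self, small_experiment):
        grid, _, _, counts = small_experiment
        a, b = grid.barcodes[:50], grid.barcodes[50:]
        d1 = sf.compare_regions_de(counts, a, b).set_index("gene_id")
        d2 = sf.compare_regions_de(counts, b, a).set_index("gene_id")
        np.testing.assert_allclose(
            d1["log2fc"], -d2.loc[d1.index, "log2fc"], atol=1e-12
        )
        np.testing.assert_allclose(d1["p"], d2.loc[d1.index, "p"], atol=1e-12)

    def test_degenerate_sizes_flagged_low_power(self, small_experiment):
        grid, _, _, counts = small_experiment
        de = sf.compare_regions_de(counts, [grid.barcodes[0]], [grid.barcodes[1]])
        assert de["low_power"].all()

    def test_empty_group_rejected(self, small_experiment):
        grid, _, _, counts = small_experiment
        with pytest.raises(ValidationError):
            sf.compare_regions_de(counts, [], grid.barcodes[:5])
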