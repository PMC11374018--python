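"""Fusion: apportionment, exact constrained assignment, and the full loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spotfuse as sf
from spotfuse.errors import ValidationError
from spotfuse.fusion import _standardize

from conftest import distinct_labelings


class TestApportionment:
    @pytest.mark.parametrize(
        "n,p,expect",
        [
            (3, [0.5, 0.5], [2, 1]),  # symmetric tie → lower index
            (0, [0.2, 0.8], [0, 0]),
            (7, [0.45, 0.35, 0.20], [3, 3, 1]),  # quotas 3.15, 2.45, 1.40
            (4, [0.25, 0.75], [1, 3]),  # exact quotas
            (10, [1.0], [10]),
        ],
    )
    def test_examples(self, n, p, expect):
        np.testing.assert_array_equal(sf.apportion_counts(n, np.array(p)), expect)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValidationError):
            sf.apportion_counts(5, np.array([0.7, 0.7]))

    @given(
        n=st.integers(0, 200),
        raw=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_conserves_and_stays_within_one_of_quota(self, n, raw):
        p = np.array(raw) / np.sum(raw)
        c = sf.apportion_counts(n, p)
        assert c.sum() == n
        assert (c >= 0).all()
        # Hamilton quota property: each count is ⌊q⌋ or ⌈q⌉
        q = n * p
        assert ((c == np.floor(q)) | (c == np.ceil(q))).all()


class TestEstimateTypeCounts:
    def test_exact_quota_spot(self):
        cells = sf.CellTable(
            cell_ids=[f"c{i}" for i in range(4)],
            x_um=np.zeros(4), y_um=np.zeros(4),
            morphology=np.ones((4, 1)), feature_names=["f"],
            spot_barcode=np.array(["s1"] * 4, dtype=object),
        )
        deconv = sf.DeconvMatrix(["s1"], ["A", "B"], [[0.25, 0.75]])
        tc = sf.estimate_type_counts(cells, deconv)
        np.testing.assert_array_equal(tc.counts, [[1, 3]])

    def test_zero_cell_spot_all_zero(self):
        cells = sf.CellTable(
            cell_ids=["c0"], x_um=[0.0], y_um=[0.0],
            morphology=[[1.0]], feature_names=["f"],
        )
        deconv = sf.DeconvMatrix(["s1", "s2"], ["A", "B"], [[0.5, 0.5], [0.1, 0.9]])
        tc = sf.estimate_type_counts(cells, deconv)
        assert tc.counts.sum() == 0

    def test_missing_barcode_listed(self):
        cells = sf.CellTable(
            cell_ids=["c0"], x_um=[0.0], y_um=[0.0], morphology=[[1.0]],
            feature_names=["f"], spot_barcode=np.array(["ghost"], dtype=object),
        )
        deconv = sf.DeconvMatrix(["s1"], ["A"], [[1.0]])
        with pytest.raises(ValidationError, match="ghost"):
            sf.estimate_type_counts(cells, deconv)

    def test_conservation_on_simulated_spots(self, fused):
        _, _, _, _, _, tc = fused
        assert np.array_equal(tc.counts.sum(axis=1), tc.n_cells)


class TestConstrainedAssignment:
    def test_single_cell_forced(self):
        lab = sf.constrained_label_assignment([[99.0]], [1], [[0.0]])
        np.testing.assert_array_equal(lab, [0])

    def test_separable_optimum(self):
        feats = [[0.0], [0.1], [5.0]]
        lab = sf.constrained_label_assignment(feats, [2, 1], [[0.0], [5.0]])
        np.testing.assert_array_equal(lab, [0, 0, 1])

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            sf.constrained_label_assignment([[0.0]], [2], [[0.0], [1.0]])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            k = int(rng.integers(1, 4))
            counts = rng.multinomial(n, np.ones(k) / k)
            feats = rng.normal(size=(n, 2))
            cents = rng.normal(size=(k, 2))
            lab = sf.constrained_label_assignment(feats, counts, cents)
            obj = ((feats - cents[lab]) ** 2).sum()
            best = min(
                ((feats - cents[list(assign)]) ** 2).sum()
                for assign in distinct_labelings(counts)
            )
            assert obj == pytest.approx(best, abs=1e-9)
            assert np.array_equal(np.bincount(lab, minlength=k), counts)


def _recovery(labelled, truth, mask):
    hits = [
        a == b for a, b, m in zip(labelled.type_label, truth.cells.type_label, mask) if m
    ]
    return float(np.mean(hits))


class TestFuse:
    def test_single_type_labels_everything(self, small_grid):
        truth = sf.simulate_tissue(
            small_grid, sf.SimulationParams(n_types=1, seed=0)
        )
        deconv = sf.simulate_deconvolution(truth, 100.0, seed=0)
        cells = sf.assign_cells_to_spots(truth.cells, small_grid)
        labelled, _ = sf.fuse(cells, deconv)
        for b, t in zip(labelled.spot_barcode, labelled.type_label):
            assert (t is None) == (b is None)
            if t is not None:
                assert t == "type_A"

    def test_counts_respected_with_identical_morphology(self, small_grid):
        p = sf.SimulationParams(
            seed=9, morphology_means=np.zeros((3, 2)), morphology_sds=np.ones((3, 2))
        )
        truth = sf.simulate_tissue(small_grid, p)
        deconv = sf.simulate_deconvolution(truth, 50.0, seed=9)
        cells = sf.assign_cells_to_spots(truth.cells, small_grid)
        labelled, tc = sf.fuse(cells, deconv)
        idx = {b: i for i, b in enumerate(tc.spot_barcodes)}
        got = np.zeros_like(tc.counts)
        tmap = {t: j for j, t in enumerate(tc.cell_types)}
        for b, t in zip(labelled.spot_barcode, labelled.type_label):
            if b is not None:
                got[idx[b], tmap[t]] += 1
        np.testing.assert_array_equal(got, tc.counts)

    def test_objective_non_increasing_over_iterations(self, small_experiment):
        grid, truth, deconv, _ = small_experiment
        cells = sf.assign_cells_to_spots(truth.cells, grid)
        feats = _standardize(cells.morphology)
        tmap = {t: j for j, t in enumerate(deconv.cell_types)}
        objs = []
        for m in (1, 2, 3, 5, 50):
            labelled, _ = sf.fuse(cells, deconv, sf.FusionConfig(max_iter=m))
            lab = np.array([tmap[t] if t is not None else -1 for t in labelled.type_label])
            cents = np.zeros((len(tmap), feats.shape[1]))
            for j in range(len(tmap)):
                if (lab == j).any():
                    cents[j] = feats[lab == j].mean(axis=0)
            mask = lab >= 0
            objs.append(((feats[mask] - cents[lab[mask]]) ** 2).sum())
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_determinism(self, small_experiment):
        grid, truth, deconv, _ = small_experiment
        cells = sf.assign_cells_to_spots(truth.cells, grid)
        l1, _ = sf.fuse(cells, deconv, sf.FusionConfig(seed=1))
        l2, _ = sf.fuse(cells, deconv, sf.FusionConfig(seed=1))
        assert list(l1.type_label) == list(l2.type_label)

    def test_recovery_with_separated_morphology(self):
        grid = sf.generate_visium_grid(10, 20)
        params = sf.default_params(seed=1, deconv_noise=1e6)
        grid, truth, deconv, _ = sf.simulate_experiment(grid, params)
        cells = sf.assign_cells_to_spots(truth.cells, grid)
        labelled, _ = sf.fuse(cells, deconv, sf.FusionConfig(seed=1))
        assert _recovery(labelled, truth, cells.assigned_mask()) >= 0.95

    def test_unassigned_cells_keep_null_label(self, fused):
        _, _, _, _, labelled, _ = fused
        for b, t in zip(labelled.spot_barcode, labelled.type_label):
            if b is None:
                assert t is None
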