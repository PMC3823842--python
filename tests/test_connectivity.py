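"""Region averaging, nuisance regression, Pearson matrices, thresholding."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import brainnet as bn


class TestSparsityGrid:
    def test_default_grid_has_40_points(self):
        g = bn.SparsityGrid()
        assert g.n_points == 40
        assert g.points[0] == pytest.approx(0.10)
        assert g.points[-1] == pytest.approx(0.49)

    @pytest.mark.parametrize("kwargs", [
        {"start": 0.5, "stop": 0.2}, {"start": 0.0, "stop": 0.4}, {"step": -0.01},
    ])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            bn.SparsityGrid(**kwargs)


class TestAverageByRegion:
    def test_identity_when_one_voxel_per_region(self):
        atlas = bn.generic_atlas(3)
        V = np.arange(12.0).reshape(4, 3)
        out = bn.average_by_region(V, np.array([1, 2, 3]), atlas)
        assert np.array_equal(out.data, V)

    def test_two_voxel_average(self):
        atlas = bn.generic_atlas(2)
        V = np.array([[1.0, 3.0, 7.0], [3.0, 5.0, 9.0]])
        out = bn.average_by_region(V, np.array([1, 1, 2]), atlas)
        assert np.array_equal(out.data[:, 0], [2.0, 4.0])

    def test_unassigned_voxels_ignored_and_empty_region_named(self, aal):
        T, V = 5, 91
        ts = np.random.default_rng(0).standard_normal((T, V))
        labels = np.concatenate([np.arange(1, 91), [0]])
        out = bn.average_by_region(ts, labels, aal)
        assert out.data.shape == (T, 90)
        labels[1] = 0  # empty region index 2 -> PreCG.R
        with pytest.raises(ValueError, match="empty region PreCG.R"):
            bn.average_by_region(ts, labels, aal)


class TestRegressNuisance:
    def test_perfectly_explained_series_leaves_zero_residuals(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((50, 1))
        ts = bn.RegionalTimeSeries(3.0 * z + 2.0, ["R001"])
        res = bn.regress_nuisance(ts, z)
        assert np.allclose(res.data, 0, atol=1e-10)

    def test_residuals_orthogonal_to_all_regressors(self):
        rng = np.random.default_rng(2)
        ts = bn.RegionalTimeSeries(rng.standard_normal((80, 5)), [f"R{i}" for i in range(5)])
        Z = rng.standard_normal((80, 4))
        res = bn.regress_nuisance(ts, Z)
        X = np.column_stack([np.ones(80), Z])
        dots = np.abs(X.T @ res.data)
        norms = np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(res.data, axis=0)
        assert np.all(dots <= 1e-8 * np.maximum(norms, 1e-30))

    def test_rank_deficiency_reports_columns(self):
        rng = np.random.default_rng(3)
        ts = bn.RegionalTimeSeries(rng.standard_normal((30, 2)), ["a", "b"])
        Z = np.zeros((30, 2))
        with pytest.raises(ValueError, match=r"collinear columns \[0, 1\]"):
            bn.regress_nuisance(ts, Z)

    def test_synthetic_contamination_fully_removed(self, small_cohort):
        """Residuals decorrelate from the planted global/motion components."""
        _, cohort = small_cohort
        d = cohort[0]
        atlas = bn.generic_atlas(d.timeseries.shape[1])
        res = bn.regress_nuisance(
            bn.RegionalTimeSeries(d.timeseries, atlas.labels), d.nuisance
        )
        corr = res.data.T @ d.nuisance
        scale = np.linalg.norm(res.data, axis=0)[:, None] * np.linalg.norm(d.nuisance, axis=0)
        assert np.abs(corr / scale).max() < 1e-8


class TestPearsonMatrix:
    def test_identical_and_negated_columns(self):
        x = np.random.default_rng(0).standard_normal(40)
        ts = bn.RegionalTimeSeries(np.column_stack([x, x, -x]), ["a", "b", "c"])
        C = bn.pearson_matrix(ts)
        assert C.values[0, 1] == pytest.approx(1.0)
        assert C.values[0, 2] == pytest.approx(-1.0)
        assert np.array_equal(np.diag(C.values), np.ones(3))

    def test_hand_computed_value_matches_scipy(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        C = bn.pearson_matrix(bn.RegionalTimeSeries(np.column_stack([x, y]), ["x", "y"]))
        expected = scipy.stats.pearsonr(x, y).statistic
        assert expected == pytest.approx(0.8)  # sum xy dev = 4, each SS = 5
        assert C.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_region_is_named(self):
        ts = bn.RegionalTimeSeries(
            np.column_stack([np.ones(10), np.arange(10.0)]), ["flat", "ok"]
        )
        with pytest.raises(ValueError, match="zero-variance region flat"):
            bn.pearson_matrix(ts)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_invariant_under_affine_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 4))
        a = rng.uniform(0.1, 5.0, 4)
        b = rng.uniform(-3, 3, 4)
        labels = [f"R{i}" for i in range(4)]
        C1 = bn.pearson_matrix(bn.RegionalTimeSeries(X, labels))
        C2 = bn.pearson_matrix(bn.RegionalTimeSeries(X * a + b, labels))
        assert np.allclose(C1.values, C2.values, atol=1e-10)


class TestThresholdBySparsity:
    def _corr(self, n, seed=0):
        rng = np.random.default_rng(seed)
        M = rng.uniform(-1, 1, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        return bn.LabeledMatrix(M, [f"R{i}" for i in range(n)])

    def test_full_sparsity_gives_complete_graph(self):
        net = bn.threshold_by_sparsity(self._corr(6), 1.0)
        assert net.n_edges == 15

    def test_keeps_exactly_the_strongest_pairs(self):
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1}
        M = np.eye(4)
        for (i, j), v in vals.items():
            M[i, j] = M[j, i] = v
        net = bn.threshold_by_sparsity(bn.LabeledMatrix(M, list("abcd")), 0.5)
        got = set(zip(*np.nonzero(np.triu(net.adjacency, 1))))
        assert got == {(0, 1), (0, 2), (0, 3)}

    def test_edge_count_at_aal_scale(self):
        # 90 nodes at sparsity 0.10: round(0.10 * 4005) = 401 edges
        net = bn.threshold_by_sparsity(self._corr(90), 0.10)
        assert net.n_edges == 401

    def test_absolute_versus_positive_ranking(self):
        M = np.eye(3)
        M[0, 1] = M[1, 0] = -0.9
        M[0, 2] = M[2, 0] = 0.5
        M[1, 2] = M[2, 1] = 0.1
        lm = bn.LabeledMatrix(M, list("abc"))
        got_abs = bn.threshold_by_sparsity(lm, 1 / 3, rank_by="absolute")
        got_pos = bn.threshold_by_sparsity(lm, 1 / 3, rank_by="positive")
        assert got_abs.adjacency[0, 1] and not got_abs.adjacency[0, 2]
        assert got_pos.adjacency[0, 2] and not got_pos.adjacency[0, 1]

    def test_sparsity_too_low_raises(self):
        with pytest.raises(ValueError, match="too low"):
            bn.threshold_by_sparsity(self._corr(4), 0.01)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_exact_edge_count_across_default_grid(self, seed):
        n = 15
        C = self._corr(n, seed)
        m_max = n * (n - 1) // 2
        for s in bn.SparsityGrid().points:
            net = bn.threshold_by_sparsity(C, float(s))
            assert net.n_edges == int(np.floor(s * m_max + 0.5))

    def test_nested_edge_sets_when_no_ties(self):
        C = self._corr(12, seed=5)
        prev = None
        for s in (0.1, 0.2, 0.3, 0.4):
            edges = set(zip(*np.nonzero(np.triu(bn.threshold_by_sparsity(C, s).adjacency, 1))))
            if prev is not None:
                assert prev <= edges
            prev = edges
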