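"""Synthetic cohort generator: topology, covariance, determinism, recovery."""

import numpy as np
import pytest

import brainnet as bn
from brainnet.synth import covariance_from_graph, module_assignment


def spec(**kw):
    base = dict(
        n_regions=10, n_timepoints=100, backbone="ring_lattice", base_degree=2,
        hub_regions=(), hub_extra_degree=0, n_modules=2, seed=0,
    )
    base.update(kw)
    return bn.GroundTruthSpec(**base)


class TestGroundTruthGraph:
    def test_ring_lattice_is_a_cycle(self):
        A = bn.build_ground_truth_graph(spec())
        assert np.all(A.sum(0) == 2)
        # a single 10-cycle: connected with 10 edges
        assert A.sum() // 2 == 10
        assert not bn.characteristic_path_length(A).disconnected

    def test_zero_rewiring_equals_lattice_for_any_seed(self):
        a = bn.build_ground_truth_graph(spec(backbone="small_world", rewiring_prob=0.0, seed=1))
        b = bn.build_ground_truth_graph(spec(backbone="small_world", rewiring_prob=0.0, seed=99))
        assert np.array_equal(a, b)

    def test_hub_gains_requested_degree(self):
        A = bn.build_ground_truth_graph(spec(hub_regions=(0,), hub_extra_degree=5))
        assert A.sum(0)[0] == 7  # cycle degree 2 + 5 extra

    def test_infeasible_hub_degree_raises(self):
        with pytest.raises(ValueError, match="simple graph"):
            bn.build_ground_truth_graph(spec(hub_regions=(0,), hub_extra_degree=9))

    def test_planted_hubs_top_betweenness_at_study_scale(self):
        s = bn.GroundTruthSpec(seed=3)
        A = bn.build_ground_truth_graph(s)
        bc = bn.betweenness(A)
        top = set(np.argsort(bc)[::-1][: len(s.hub_regions)])
        assert top == set(s.hub_regions)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="even"):
            spec(base_degree=3)
        with pytest.raises(ValueError, match="inter_module"):
            spec(intra_module_coupling=0.2, inter_module_coupling=0.4)


class TestCovariance:
    def test_empty_graph_gives_identity(self):
        A = np.zeros((6, 6), bool)
        C = covariance_from_graph(A, spec(n_regions=6))
        assert np.array_equal(C, np.eye(6))

    def test_single_edge_carries_coupling(self):
        A = np.zeros((2, 2), bool)
        A[0, 1] = A[1, 0] = True
        s = bn.GroundTruthSpec(
            n_regions=2, base_degree=0, intra_module_coupling=0.5,
            inter_module_coupling=0.0, n_modules=1, hub_regions=(),
        )
        C = covariance_from_graph(A, s)
        assert C[0, 1] == pytest.approx(0.5)

    def test_output_is_positive_definite_correlation(self):
        s = spec(intra_module_coupling=0.6, inter_module_coupling=0.2)
        A = bn.build_ground_truth_graph(s)
        C = covariance_from_graph(A, s)
        assert np.linalg.eigvalsh(C).min() > 0
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)

    def test_condition_effect_raises_inter_module_targets_only(self):
        s = bn.GroundTruthSpec(seed=0)
        A = bn.build_ground_truth_graph(s)
        mod = module_assignment(s.n_regions, s.n_modules)
        cross = A & (mod[:, None] != mod[None, :])
        ci = covariance_from_graph(A, s, "implicit")
        ce = covariance_from_graph(A, s, "explicit")
        assert ce[cross].mean() > ci[cross].mean()

    def test_module_assignment_contiguous_blocks(self):
        m = module_assignment(10, 2)
        assert list(m) == [0] * 5 + [1] * 5


class TestCohort:
    def test_shapes_and_count(self):
        cohort = bn.simulate_cohort(spec(), 3)
        assert len(cohort) == 6
        d = cohort[0]
        assert d.timeseries.shape == (100, 10)
        assert d.nuisance.shape == (100, 9)
        assert {c.condition for c in cohort} == {"implicit", "explicit"}

    def test_bit_identical_given_seed(self):
        a = bn.simulate_cohort(spec(seed=5), 2)
        b = bn.simulate_cohort(spec(seed=5), 2)
        assert all(np.array_equal(x.timeseries, y.timeseries) for x, y in zip(a, b))
        c = bn.simulate_cohort(spec(seed=6), 2)
        assert not np.array_equal(a[0].timeseries, c[0].timeseries)

    def test_zero_condition_effect_gives_equal_targets(self):
        s = spec(condition_effect=0.0)
        A = bn.build_ground_truth_graph(s)
        assert np.array_equal(
            covariance_from_graph(A, s, "implicit"), covariance_from_graph(A, s, "explicit")
        )

    def test_planted_edge_correlations_near_generator_target(self):
        """Observed edge correlations concentrate around the generator's own
        target: the projected coupling attenuated by the white-noise
        variance, C_ij / (1 + noise_sd^2)."""
        hits = total = 0
        for seed in range(6):
            s = bn.GroundTruthSpec(n_regions=30, base_degree=4, hub_regions=(),
                                   n_modules=3, seed=seed)
            A = bn.build_ground_truth_graph(s)
            target = covariance_from_graph(A, s, "implicit") / (1 + s.noise_sd**2)
            d = bn.simulate_cohort(s, 2)[0]
            atlas = bn.generic_atlas(30)
            res = bn.regress_nuisance(
                bn.RegionalTimeSeries(d.timeseries, atlas.labels), d.nuisance
            )
            C = bn.pearson_matrix(res).values
            iu = np.triu_indices(30, 1)
            e = A[iu]
            hits += int(np.sum(np.abs(C[iu][e] - target[iu][e]) < 0.1))
            total += int(e.sum())
        assert hits / total >= 0.95

    def test_write_read_round_trip(self, small_cohort, tmp_path):
        _, cohort = small_cohort
        manifest = bn.write_cohort(cohort, tmp_path)
        back = bn.read_cohort(manifest)
        assert len(back) == len(cohort)
        for x, y in zip(cohort, back):
            assert (x.subject_id, x.condition) == (y.subject_id, y.condition)
            assert np.array_equal(x.timeseries, y.timeseries)
            assert np.array_equal(x.ground_truth_adjacency, y.ground_truth_adjacency)


class TestRecovery:
    def test_thresholding_recovers_planted_edges(self, aal):
        """At the ground-truth density, >=80% of planted edges survive the
        pipeline (nuisance regression -> Pearson -> sparsity threshold),
        averaged over 10 seeds at the study conditions."""
        recalls = []
        for seed in range(10):
            s = bn.GroundTruthSpec(seed=seed)
            d = bn.simulate_cohort(s, 2)[0]
            A = d.ground_truth_adjacency
            res = bn.regress_nuisance(
                bn.RegionalTimeSeries(d.timeseries, aal.labels), d.nuisance
            )
            C = bn.pearson_matrix(res)
            density = A.sum() / (90 * 89)
            net = bn.threshold_by_sparsity(C, density)
            gt = np.triu(A, 1)
            recalls.append((gt & np.triu(net.adjacency, 1)).sum() / gt.sum())
        assert np.mean(recalls) >= 0.80
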