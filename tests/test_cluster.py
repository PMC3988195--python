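import itertools

import numpy as np
import pytest

from rvcluster import (
    GenotypePanel,
    PhenotypeVector,
    SimulationConfig,
    default_thresholds,
    identity_kernel,
    maf_filter,
    run_ada_test,
    run_cluster_test,
    signal_vectors,
    simulate_dataset,
    threshold_statistic,
)
from rvcluster.cluster import _minp_adjust, _stats_for_labels
from rvcluster.kernel import KernelMatrix, pairwise_distances, triweight_kernel
from rvcluster.site_stats import SiteSummary, per_site_summaries

from .conftest import tiny_sim_config


def _summary(p, direction, w):
    return SiteSummary("s", 0, p, direction, w, 0.01)


class TestSignalVectors:
    def test_three_site_example(self):
        # p=(0.05,0.15,0.5), dirs=(del,pro,del), w=(2,1,3), tau=0.12
        s = [_summary(0.05, "deleterious_inclined", 2.0),
             _summary(0.15, "protective_inclined", 1.0),
             _summary(0.5, "deleterious_inclined", 3.0)]
        u_del, u_pro = signal_vectors(s, 0.12)
        np.testing.assert_array_equal(u_del, [2.0, 0.0, 0.0])
        np.testing.assert_array_equal(u_pro, [0.0, 0.0, 0.0])

    def test_truncation_zeroes_everything(self):
        s = [_summary(0.3, "deleterious_inclined", 2.0),
             _summary(0.9, "protective_inclined", 1.0)]
        u_del, u_pro = signal_vectors(s, 0.2)
        assert not u_del.any() and not u_pro.any()

    def test_tied_sites_enter_neither_vector(self):
        s = [_summary(0.01, "tied", 5.0)]
        u_del, u_pro = signal_vectors(s, 0.2)
        assert u_del[0] == 0 and u_pro[0] == 0

    def test_strict_threshold_comparison(self):
        s = [_summary(0.10, "deleterious_inclined", 1.0)]
        assert not signal_vectors(s, 0.10)[0].any()  # p == tau excluded

    def test_neglog10_transform(self):
        s = [_summary(0.01, "deleterious_inclined", 2.0)]
        u_del, _ = signal_vectors(s, 0.2, transform="neglog10")
        assert u_del[0] == pytest.approx(2.0 * 2.0)  # w * (-log10 0.01)


class TestThresholdStatistic:
    def test_single_term(self):
        C = identity_kernel(3)
        u = np.array([1.7, 0, 0])
        assert threshold_statistic(u, np.zeros(3), C) == pytest.approx(1.7 ** 2)

    def test_zero_vectors(self):
        assert threshold_statistic(np.zeros(2), np.zeros(2), identity_kernel(2)) == 0.0

    def test_hand_expanded_quadratic_form(self):
        # u_del=(1,0.5,0), C with c12=0.8: S = 1 + 0.25 + 2*0.8*0.5 = 2.05
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.8
        C = KernelMatrix(vals, d_max=1.0, measure="triweight")
        S = threshold_statistic(np.array([1.0, 0.5, 0.0]), np.zeros(3), C)
        assert S == pytest.approx(2.05)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            threshold_statistic(np.zeros(2), np.zeros(2), identity_kernel(3))

    def test_direction_classes_never_cross_multiplied(self):
        vals = np.eye(2)
        vals[0, 1] = vals[1, 0] = 0.9
        C = KernelMatrix(vals, d_max=1.0, measure="triweight")
        # one deleterious site and one protective site close together: the
        # 0.9 proximity must contribute nothing under the split statistic
        S = threshold_statistic(np.array([2.0, 0.0]), np.array([0.0, 3.0]), C)
        assert S == pytest.approx(4.0 + 9.0)


class TestMinPAdjustment:
    def test_hand_enumerated_micro_example(self):
        """B=4, J=2 worked example.

        threshold 1: obs 3.0 vs perms (2.0, 3.5, 1.0, 0.5) -> p_obs = 1/4;
        threshold 2: obs 1.0 vs perms (1.0, 2.0, 0.3, 0.9) -> p_obs = 2/4.
        minP_obs = 0.25.  Self-inclusive permuted per-threshold P-values give
        permuted minPs (0.5, 0.25, 0.75, 0.75), so one permuted minP <= 0.25
        and the adjusted P is (1 + 1)/(4 + 1) = 0.4.
        """
        S_obs = np.array([3.0, 1.0])
        S_perm = np.array([[2.0, 1.0], [3.5, 2.0], [1.0, 0.3], [0.5, 0.9]])
        p_obs, minp_obs, minp_perm, adj = _minp_adjust(S_obs, S_perm)
        np.testing.assert_allclose(p_obs, [0.25, 0.5])
        assert minp_obs == 0.25
        np.testing.assert_allclose(minp_perm, [0.5, 0.25, 0.75, 0.75])
        assert adj == pytest.approx(0.4)

    def test_boundary_estimate_when_observed_beats_all(self):
        S_obs = np.array([100.0])
        S_perm = np.linspace(0.0, 99.0, 999)[:, None]
        _, _, _, adj = _minp_adjust(S_obs, S_perm)
        assert adj == pytest.approx(1 / 1000)

    def test_rank_only_dependence(self, rng):
        """Any strictly increasing transform of the statistics leaves the
        adjusted P unchanged."""
        S_obs = rng.random(5)
        S_perm = rng.random((50, 5))
        *_, adj1 = _minp_adjust(S_obs, S_perm)
        f = lambda x: np.exp(3 * x) + x ** 3
        *_, adj2 = _minp_adjust(f(S_obs), f(S_perm))
        assert adj1 == adj2

    def test_monotonicity_of_evidence(self, rng):
        """A new permutation replicate that is everywhere weaker than every
        existing statistic cannot increase the adjusted-P numerator."""
        S_obs = rng.random(4) + 1.0
        S_perm = rng.random((30, 4)) + 1.0
        _, minp_obs, minp_perm, _ = _minp_adjust(S_obs, S_perm)
        count = (minp_perm <= minp_obs).sum()
        weak = np.zeros((1, 4))
        _, minp_obs2, minp_perm2, _ = _minp_adjust(
            S_obs, np.vstack([S_perm, weak]))
        assert (minp_perm2 <= minp_obs2).sum() == count


class TestEngineMatchesDefinitions:
    def test_vectorized_statistics_equal_per_site_construction(self):
        """The permutation engine's observed statistics must equal the ones
        assembled from per_site_summaries + signal_vectors + threshold_statistic."""
        panel, pheno, _ = simulate_dataset(tiny_sim_config(seed=5))
        panel = maf_filter(panel, pheno)
        C = triweight_kernel(pairwise_distances(panel.positions), 2000.0)
        taus = default_thresholds()
        S = _stats_for_labels(panel.counts, pheno.status[None, :], taus,
                              C.values, "indicator", "split")[0]
        summaries = per_site_summaries(panel, pheno)
        expected = [threshold_statistic(*signal_vectors(summaries, t), C)
                    for t in taus]
        np.testing.assert_allclose(S, expected, rtol=1e-12)

    def test_pooled_variant_mixes_directions(self):
        panel, pheno, _ = simulate_dataset(tiny_sim_config(seed=5))
        panel = maf_filter(panel, pheno)
        C = triweight_kernel(pairwise_distances(panel.positions), 2000.0)
        taus = default_thresholds()
        S = _stats_for_labels(panel.counts, pheno.status[None, :], taus,
                              C.values, "indicator", "pooled")[0]
        summaries = per_site_summaries(panel, pheno)
        expected = []
        for t in taus:
            u_del, u_pro = signal_vectors(summaries, t)
            u = u_del + u_pro
            expected.append(u @ C.values @ u)
        np.testing.assert_allclose(S, expected, rtol=1e-12)


class TestAdaEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identity_kernel_equals_ada(self, seed):
        panel, pheno, _ = simulate_dataset(tiny_sim_config(seed=seed))
        panel = maf_filter(panel, pheno)
        r1 = run_cluster_test(panel, pheno, C=identity_kernel(panel.n_sites),
                              B=60, seed=7, include_site_summaries=False)
        r2 = run_ada_test(panel, pheno, B=60, seed=7, include_site_summaries=False)
        assert r1.adjusted_p == r2.adjusted_p
        np.testing.assert_array_equal(r1.per_threshold_stats, r2.per_threshold_stats)
        assert r2.method == "ADA" and r1.method == "ADA"

    def test_small_dmax_reduces_cluster_to_ada(self):
        panel, pheno, _ = simulate_dataset(tiny_sim_config(seed=3))
        panel = maf_filter(panel, pheno)
        gap = float(np.diff(panel.positions).min())
        r1 = run_cluster_test(panel, pheno, B=60, seed=9, d_max=gap,
                              include_site_summaries=False)
        r2 = run_ada_test(panel, pheno, B=60, seed=9, include_site_summaries=False)
        assert r1.adjusted_p == r2.adjusted_p
        assert r1.method == "CLUSTER"  # tagged by kernel type, not by values

    def test_single_site_panel(self):
        counts = np.array([[1], [0], [1], [0], [1], [0], [0], [0]])
        panel = GenotypePanel([f"s{i}" for i in range(8)], ["v"], [50], counts)
        pheno = PhenotypeVector([1, 1, 1, 1, 0, 0, 0, 0])
        r1 = run_cluster_test(panel, pheno, B=40, seed=3, d_max=123456.0,
                              include_site_summaries=False)
        r2 = run_ada_test(panel, pheno, B=40, seed=3, include_site_summaries=False)
        assert r1.adjusted_p == r2.adjusted_p


class TestRunClusterTest:
    def test_exhaustive_label_enumeration_limit(self):
        """Monte-Carlo permutations converge to full enumeration over all
        case/control assignments on a tiny dataset."""
        counts = np.array([
            [1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 0],
            [1, 0, 0], [0, 0, 1], [0, 1, 0], [0, 0, 0]])
        X = counts
        taus = default_thresholds()
        C = np.eye(3)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        all_labels = np.array([
            [1 if i in picks else 0 for i in range(8)]
            for picks in itertools.combinations(range(8), 4)])
        S_all = _stats_for_labels(X, all_labels, taus, C, "indicator", "split")
        S_obs = _stats_for_labels(X, y[None, :], taus, C, "indicator", "split")[0]
        *_, adj_exact = _minp_adjust(S_obs, S_all)
        rng = np.random.default_rng(123)
        Y = np.tile(y, (4000, 1))
        rng.permuted(Y, axis=1, out=Y)
        S_mc = _stats_for_labels(X, Y, taus, C, "indicator", "split")
        *_, adj_mc = _minp_adjust(S_obs, S_mc)
        assert adj_mc == pytest.approx(adj_exact, abs=0.06)

    def test_all_tied_sites_give_p_one_with_warning(self, caplog):
        counts = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        panel = GenotypePanel(["a", "b", "c", "d"], ["v1", "v2"], [10, 20], counts)
        pheno = PhenotypeVector([1, 0, 0, 1])  # equal case/control freqs
        with caplog.at_level("WARNING", logger="rvcluster.cluster"):
            res = run_cluster_test(panel, pheno, B=30, seed=0,
                                   include_site_summaries=False)
        assert res.adjusted_p == 1.0
        assert any("no site passed" in r.message for r in caplog.records)

    def test_invalid_inputs(self, small_panel, small_pheno):
        with pytest.raises(ValueError):
            run_cluster_test(small_panel, small_pheno, B=0)
        with pytest.raises(ValueError):
            run_cluster_test(small_panel, small_pheno, thresholds=[0.2, 0.1], B=5)
        with pytest.raises(ValueError):
            run_cluster_test(small_panel, small_pheno, thresholds=[1.5], B=5)

    def test_result_metadata_and_consistency(self, small_panel, small_pheno):
        res = run_cluster_test(small_panel, small_pheno, B=50, seed=11)
        assert res.min_p_observed == min(res.per_threshold_pvalues)
        assert 0 < res.adjusted_p <= 1
        assert res.B == 50 and res.seed == 11
        assert len(res.site_summaries) == small_panel.n_sites
        d = res.to_dict()
        assert d["method"] == "CLUSTER"
        assert len(d["per_threshold_stats"]) == len(default_thresholds())

    def test_seed_reproducibility(self, small_panel, small_pheno):
        r1 = run_cluster_test(small_panel, small_pheno, B=80, seed=4,
                              include_site_summaries=False)
        r2 = run_cluster_test(small_panel, small_pheno, B=80, seed=4,
                              include_site_summaries=False)
        assert r1.adjusted_p == r2.adjusted_p
        np.testing.assert_array_equal(r1.per_threshold_pvalues,
                                      r2.per_threshold_pvalues)

    def test_logistic_engine_runs(self, small_panel, small_pheno):
        res = run_cluster_test(small_panel, small_pheno, B=5, seed=0,
                               engine="logistic", include_site_summaries=False)
        assert 0 < res.adjusted_p <= 1


class TestNullCalibrationLight:
    def test_adjusted_p_roughly_uniform_under_null(self):
        """Adjusted P-values from null data should be close to uniform;
        the full-scale calibration lives in the acceptance suite."""
        pvals = []
        for s in range(120):
            panel, pheno, _ = simulate_dataset(tiny_sim_config(seed=1000 + s))
            try:
                panel = maf_filter(panel, pheno)
            except ValueError:
                continue
            res = run_cluster_test(panel, pheno, B=60, seed=s,
                                   include_site_summaries=False)
            pvals.append(res.adjusted_p)
        pvals = np.array(pvals)
        assert 0.40 < pvals.mean() < 0.65
        assert (pvals <= 0.2).mean() < 0.35
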