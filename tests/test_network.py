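"""Correlation networks and bootstrap-FDR thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scnet as s

from conftest import constant_block_model


def brute_force_pearson(a, b):
    """Textbook two-pass Pearson formula, kept independent of numpy.corrcoef."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sum((x - ma) ** 2 for x in a) ** 0.5
    db = sum((y - mb) ** 2 for y in b) ** 0.5
    return num / (da * db)


def brute_force_bh(p):
    """Step-up BH adjusted p-values by direct enumeration."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestCorrelationMatrix:
    def test_perfect_linear_dependence_and_sign_flip(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        table = np.column_stack([a, 2 * a, -a])
        r = s.correlation_matrix(table).weights
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_pair(self):
        a = [1.0, 2.0, 3.0, 4.0]
        c = [1.0, 3.0, 2.0, 4.0]
        r = s.correlation_matrix(np.column_stack([a, c])).weights[0, 1]
        assert r == pytest.approx(brute_force_pearson(a, c), abs=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.standard_normal((10, 8))
            r = s.correlation_matrix(X).weights
            for i in range(8):
                for j in range(i + 1, 8):
                    assert r[i, j] == pytest.approx(
                        brute_force_pearson(X[:, i], X[:, j]), abs=1e-10)

    def test_zero_variance_region_named(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        X[:, 2] = 5.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            s.correlation_matrix(X)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="3 participants"):
            s.correlation_matrix(np.ones((2, 4)))


class TestDecomposeCorrelation:
    def test_identical_series_with_sd_two(self):
        base = np.array([1.0, 1.0, 3.0, 5.0, 5.0])  # sd = 2 (ddof=1)
        assert np.std(base, ddof=1) == pytest.approx(2.0)
        X = np.column_stack([base, base, base])
        mean_cov, mean_sdprod, ratio = s.decompose_correlation(X)
        assert mean_cov == pytest.approx(4.0)
        assert mean_sdprod == pytest.approx(4.0)
        assert ratio == pytest.approx(1.0)

    def test_independence_limit(self):
        X = np.random.default_rng(1).standard_normal((4000, 6))
        mean_cov, mean_sdprod, _ = s.decompose_correlation(X)
        assert abs(mean_cov) < 0.05
        assert mean_sdprod == pytest.approx(1.0, abs=0.05)

    def test_three_region_toy_table_against_elementwise_oracle(self):
        X = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 1.5], [4.0, 3.0, 1.0],
                      [3.0, 5.0, 2.5]])
        mean_cov, mean_sdprod, ratio = s.decompose_correlation(X)
        covs, prods = [], []
        for i in range(3):
            for j in range(i + 1, 3):
                xi, xj = X[:, i], X[:, j]
                covs.append(np.sum((xi - xi.mean()) * (xj - xj.mean())) / 3)
                prods.append(np.std(xi, ddof=1) * np.std(xj, ddof=1))
        assert mean_cov == pytest.approx(np.mean(covs), abs=1e-12)
        assert mean_sdprod == pytest.approx(np.mean(prods), abs=1e-12)
        assert ratio == pytest.approx(np.mean(covs) / np.mean(prods), abs=1e-12)


class TestBootstrapPvalues:
    def test_sign_consistent_edge_gets_p_zero(self):
        # population r ~ 0.95: every resample stays positive
        rng = np.random.default_rng(2)
        f = rng.standard_normal(60)
        X = np.column_stack([f + 0.2 * rng.standard_normal(60),
                             f + 0.2 * rng.standard_normal(60)])
        p = s.bootstrap_edge_pvalues(X, None, s.BootstrapConfig(n_boot=200, seed=0))
        assert p[0, 1] == 0.0

    def test_null_pvalues_approximately_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        ps = []
        for i in range(400):
            X = rng.standard_normal((60, 2))
            p = s.bootstrap_edge_pvalues(X, None,
                                         s.BootstrapConfig(n_boot=200, seed=i))
            ps.append(p[0, 1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_minimal_bootstrap_count_boundary(self):
        X = np.random.default_rng(4).standard_normal((10, 2))
        p = s.bootstrap_edge_pvalues(X, None, s.BootstrapConfig(n_boot=2, seed=0))
        assert p[0, 1] in (0.0, 1.0)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(5).standard_normal((30, 5))
        cfg = s.BootstrapConfig(n_boot=50, seed=9)
        p1 = s.bootstrap_edge_pvalues(X, None, cfg)
        p2 = s.bootstrap_edge_pvalues(X, None, cfg)
        assert np.array_equal(p1, p2)

    def test_retention_probability_nondecreasing_in_correlation(self):
        rates = []
        for r_pop in (0.0, 0.2, 0.4, 0.6):
            cov = np.array([[1.0, r_pop], [r_pop, 1.0]])
            chol = np.linalg.cholesky(cov)
            rng = np.random.default_rng(int(100 * r_pop))
            kept = 0
            reps = 100
            for i in range(reps):
                X = rng.standard_normal((60, 2)) @ chol.T
                net, _ = s.build_thresholded_network(
                    X, None, s.BootstrapConfig(n_boot=100, alpha=0.01, seed=i))
                kept += net.n_edges
            rates.append(kept / reps)
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))


class TestFdrAdjust:
    def test_hand_computed_bh(self):
        assert np.allclose(s.fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_stay_equal(self):
        assert np.allclose(s.fdr_adjust([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_single_pvalue_unchanged(self):
        assert s.fdr_adjust([0.123])[0] == pytest.approx(0.123)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            s.fdr_adjust([0.1, np.nan])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            s.fdr_adjust([0.1, 1.2])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_adjusted_never_below_raw_and_matches_oracle(self, pvals):
        adj = s.fdr_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        assert np.allclose(adj, brute_force_bh(pvals), atol=1e-10)


class TestThresholdNetwork:
    def _toy(self, n=6, seed=0):
        X = np.random.default_rng(seed).standard_normal((20, n))
        return s.correlation_matrix(X)

    def test_all_nonsignificant_gives_empty_network(self):
        corr = self._toy()
        p = np.full((6, 6), 0.5)
        net = s.threshold_network(corr, p, p, alpha=0.01)
        assert net.n_edges == 0
        assert np.all(net.weights == 0)

    def test_all_significant_gives_complete_network(self):
        corr = self._toy()
        p = np.full((6, 6), 0.001)
        net = s.threshold_network(corr, p, p, alpha=0.01)
        assert net.n_edges == 15
        offdiag = ~np.eye(6, dtype=bool)
        assert np.array_equal(net.weights[offdiag], corr.weights[offdiag])

    def test_positive_negative_edge_counts(self):
        corr = self._toy(seed=3)
        p = np.full((6, 6), 0.001)
        net = s.threshold_network(corr, p, p, alpha=0.01)
        iu = np.triu_indices(6, 1)
        assert net.n_positive == (corr.weights[iu] > 0).sum()
        assert net.n_negative == (corr.weights[iu] < 0).sum()
        assert net.n_positive + net.n_negative == net.n_edges

    def test_retained_weight_is_observed_correlation(self, regions60):
        model = constant_block_model(0.6, 0.0)
        ds, _ = s.generate_cohort(s.CohortSpec(n_participants=60, seed=0),
                                  regions60, model,
                                  ct_slope_mean=0.0, ct_slope_sd=0.0)
        net, corr = s.build_thresholded_network(
            ds, None, s.BootstrapConfig(n_boot=100, alpha=0.01, seed=0))
        assert np.all(net.weights[net.mask] == corr.weights[net.mask])
        assert np.all(net.weights[~net.mask] == 0.0)

    def test_pipeline_determinism(self, regions60):
        ds, _ = s.generate_cohort(s.CohortSpec(n_participants=60, seed=1),
                                  regions60)
        cfg = s.BootstrapConfig(n_boot=100, alpha=0.01, seed=5)
        n1, _ = s.build_thresholded_network(ds, None, cfg)
        n2, _ = s.build_thresholded_network(ds, None, cfg)
        assert np.array_equal(n1.mask, n2.mask)
        assert np.array_equal(n1.p, n2.p)

    def test_edge_list_shape(self, regions60):
        ds, _ = s.generate_cohort(s.CohortSpec(n_participants=40, seed=1),
                                  regions60)
        net, _ = s.build_thresholded_network(
            ds, None, s.BootstrapConfig(n_boot=50, alpha=0.01, seed=5))
        el = net.edge_list()
        assert len(el) == 60 * 59 // 2
        assert el["retained"].sum() == net.n_edges
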