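"""Similarity, dependent-correlation, FDR, and meta-analysis utilities."""

import numpy as np
import pytest

from latentfc import (
    bh_fdr,
    compare_similarity,
    dependent_correlation_test,
    devectorize,
    fc_similarity,
    fisher_z,
    inverse_fisher_z,
    meta_z,
)


def brute_force_bh(p, alpha=0.05):
    """Independent step-up BH implementation."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject


class TestFisher:
    def test_round_trip(self):
        r = np.linspace(-0.99, 0.99, 41)
        np.testing.assert_allclose(inverse_fisher_z(fisher_z(r)), r, atol=1e-12)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestSimilarity:
    def test_identity_gives_one(self, rng):
        m = rng.standard_normal((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        assert fc_similarity(m, m) == pytest.approx(1.0)

    def test_permutation_null_at_scale(self, rng):
        edges = rng.standard_normal(64620)
        permuted = edges[rng.permutation(edges.size)]
        assert abs(fc_similarity(edges, permuted)) < 0.02

    def test_matches_brute_force_upper_triangle_correlation(self, rng):
        a = rng.standard_normal(45)
        b = a + rng.standard_normal(45)
        ma, mb = devectorize(a, 10, diagonal=1.0), devectorize(b, 10, diagonal=1.0)
        iu = np.triu_indices(10, k=1)
        expected = np.corrcoef(ma[iu], mb[iu])[0, 1]
        assert fc_similarity(ma, mb) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fc_similarity(np.zeros(10), np.ones(10))


class TestCompareSimilarity:
    def test_identical_inputs_never_significant(self, rng):
        sims = rng.uniform(0.3, 0.7, (20, 5))
        table = compare_similarity(sims, sims)
        assert not table["significant"].any()
        assert (table["p"] == 1.0).all()

    def test_consistent_advantage_detected_everywhere(self, rng):
        base = rng.uniform(0.4, 0.6, (100, 6))
        better = np.clip(base + 0.1 + 0.02 * rng.standard_normal(base.shape), -0.99, 0.99)
        table = compare_similarity(better, base)
        assert table["significant"].all()
        assert (table["t"] > 0).all()

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            compare_similarity(rng.uniform(0, 0.5, (2, 3)), rng.uniform(0, 0.5, (2, 3)))


class TestDependentCorrelation:
    def test_equal_correlations_give_null(self):
        z, p = dependent_correlation_test(0.5, 0.5, 0.3, 100)
        assert z == 0.0 and p == 1.0

    def test_type_one_error_calibrated(self):
        # trivariate Gaussian null: both predictors share rho with the outcome
        g = np.random.default_rng(2024)
        n, reps = 176, 10000
        rho = 0.3
        cov = np.array([[1, rho, rho], [rho, 1, rho], [rho, rho, 1.0]])
        chol = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            x = g.standard_normal((n, 3)) @ chol.T
            c = np.corrcoef(x, rowvar=False)
            _, p = dependent_correlation_test(c[0, 2], c[1, 2], c[0, 1], n)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.01)

    def test_power_monotone_in_n(self):
        zs = [
            dependent_correlation_test(0.5, 0.3, 0.4, n)[0]
            for n in (30, 100, 300, 1000)
        ]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_sign_and_tails(self):
        z_pos, _ = dependent_correlation_test(0.5, 0.3, 0.4, 100)
        z_neg, _ = dependent_correlation_test(0.3, 0.5, 0.4, 100)
        assert z_pos > 0 > z_neg
        assert z_pos == pytest.approx(-z_neg)
        _, p_one = dependent_correlation_test(0.5, 0.3, 0.4, 100, tails="one")
        _, p_two = dependent_correlation_test(0.5, 0.3, 0.4, 100, tails="two")
        assert p_one == pytest.approx(p_two / 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dependent_correlation_test(1.0, 0.5, 0.3, 100)
        with pytest.raises(ValueError, match="n > 3"):
            dependent_correlation_test(0.5, 0.4, 0.3, 3)


class TestMetaZ:
    def test_printed_formula_hand_evaluation(self):
        res = meta_z([0.2, 0.0], [100, 300])
        assert res.pooled_z == pytest.approx(100 * np.arctanh(0.2) / 400, abs=1e-15)

    def test_equal_r_collapses_to_atanh(self):
        res = meta_z([0.4, 0.4, 0.4], [50, 500, 5000])
        assert res.pooled_z == pytest.approx(np.arctanh(0.4), abs=1e-12)

    def test_permutation_invariance(self):
        a = meta_z([0.1, 0.3, 0.5], [100, 200, 300])
        b = meta_z([0.5, 0.1, 0.3], [300, 100, 200])
        assert a.pooled_z == pytest.approx(b.pooled_z)
        assert a.chi_square == pytest.approx(b.chi_square)
        assert a.p == pytest.approx(b.p)

    def test_single_sample_reduces_to_z_test(self):
        r, n = 0.3, 100
        res = meta_z([r], [n])
        assert res.pooled_z == pytest.approx(np.arctanh(r))
        assert res.chi_square == pytest.approx(np.arctanh(r) ** 2 * n)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            meta_z([1.0], [100])


class TestBHFDR:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, 40) ** 2
            reject, _ = bh_fdr(p)
            np.testing.assert_array_equal(reject, brute_force_bh(p))

    def test_never_rejects_more_than_unadjusted(self, rng):
        p = rng.uniform(0, 1, 200)
        reject, _ = bh_fdr(p, alpha=0.05)
        assert reject.sum() <= (p < 0.05).sum()

    def test_monotone_in_alpha(self, rng):
        p = rng.uniform(0, 1, 100) ** 3
        r1, _ = bh_fdr(p, alpha=0.01)
        r2, _ = bh_fdr(p, alpha=0.10)
        assert r1.sum() <= r2.sum()
        assert np.all(r2[r1])  # rejections nest

    def test_empirical_fdr_controlled(self):
        # 1000 replicate units, 20% true effects: observed FDR <= alpha
        g = np.random.default_rng(99)
        n_units, n_sub = 1000, 40
        true_effect = np.zeros(n_units, dtype=bool)
        true_effect[:200] = True
        fdps = []
        for _ in range(20):
            x = g.standard_normal((n_sub, n_units))
            x[:, true_effect] += 1.0
            from scipy.stats import ttest_1samp

            p = ttest_1samp(x, 0.0, axis=0).pvalue
            reject, _ = bh_fdr(p, alpha=0.05)
            if reject.sum():
                fdps.append((reject & ~true_effect).sum() / reject.sum())
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= 0.05
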