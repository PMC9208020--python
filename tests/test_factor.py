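"""Single-factor fitting, regression scores, and the restricted average model."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latentfc import (
    fit_from_correlation,
    fit_single_factor,
    regression_scores,
    restricted_average_solution,
    simulate_fc_stack,
)
from latentfc.factor import FactorSolution


def implied_corr(lam):
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return r


class TestConstructionInversion:
    @pytest.mark.parametrize(
        "lam",
        [
            (0.8, 0.7, 0.6),
            (0.9, 0.5, 0.3, 0.2),
            (0.7, 0.7, 0.7, 0.7, 0.7),
            (0.95, 0.1, 0.4),
        ],
    )
    def test_minres_recovers_generating_loadings(self, lam):
        lam = np.array(lam)
        sol = fit_from_correlation(implied_corr(lam), method="minres")
        np.testing.assert_allclose(sol.loadings, lam, atol=1e-6)
        np.testing.assert_allclose(sol.uniquenesses, 1 - lam**2, atol=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=0.95), min_size=3, max_size=8)
    )
    def test_recovery_property_any_loadings(self, lam):
        lam = np.array(lam)
        sol = fit_from_correlation(implied_corr(lam))
        np.testing.assert_allclose(sol.loadings, lam, atol=1e-6)

    def test_identity_correlation_gives_null_loadings(self):
        sol = fit_from_correlation(np.eye(6))
        assert np.all(np.abs(sol.loadings) < 0.05)

    def test_sign_convention_sum_nonnegative(self):
        lam = np.array([-0.8, -0.7, -0.6])
        sol = fit_from_correlation(implied_corr(lam))
        assert sol.loadings.sum() >= 0
        np.testing.assert_allclose(sol.loadings, -lam, atol=1e-6)

    def test_minres_and_ml_agree_on_population_matrix(self):
        lam = np.array([0.8, 0.6, 0.5, 0.7])
        a = fit_from_correlation(implied_corr(lam), method="minres")
        b = fit_from_correlation(implied_corr(lam), method="ml")
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-3)

    def test_fewer_than_three_indicators_refused(self):
        with pytest.raises(ValueError, match="unidentified"):
            fit_from_correlation(np.eye(2))

    def test_heywood_case_flagged_and_floored(self):
        # correlations exceeding what any lambda in [0,1) can produce
        r = implied_corr(np.array([0.99, 0.99, 0.99]))
        r[0, 1] = r[1, 0] = 0.9999
        sol = fit_from_correlation(r)
        assert sol.heywood
        assert np.all(sol.uniquenesses >= 0.001 - 1e-12)


class TestAgainstRFactanal:
    """Cross-check ML loadings against R's stats::factanal."""

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_ml_loadings_match_factanal(self, tmp_path):
        lam = np.array([0.85, 0.7, 0.6, 0.5, 0.4])
        # a perturbed (sample-like) correlation matrix, still PSD
        g = np.random.default_rng(5)
        x = lam * g.standard_normal((2000, 1)) + np.sqrt(1 - lam**2) * g.standard_normal((2000, 5))
        r = np.corrcoef(x, rowvar=False)
        np.savetxt(tmp_path / "r.txt", r)
        script = textwrap.dedent(
            """
            R <- as.matrix(read.table(commandArgs(TRUE)[1]))
            fit <- factanal(covmat = R, factors = 1, n.obs = 2000)
            cat(sprintf('%.10f\\n', as.numeric(fit$loadings)))
            """
        )
        (tmp_path / "fit.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "fit.R"), str(tmp_path / "r.txt")],
            capture_output=True,
            text=True,
            check=True,
        )
        r_loadings = np.array([float(v) for v in out.stdout.split()])
        if r_loadings.sum() < 0:
            r_loadings = -r_loadings
        sol = fit_from_correlation(r, method="ml")
        np.testing.assert_allclose(sol.loadings, r_loadings, atol=0.01)


class TestRegressionScores:
    def test_exchangeable_solution_ranks_like_row_means(self, rng):
        lam = np.full(5, 0.7)
        sol = FactorSolution(
            loadings=lam, uniquenesses=1 - lam**2, indicator_corr=implied_corr(lam)
        )
        x = rng.standard_normal((200, 5))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        scores = regression_scores(sol, x)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(scores, x.mean(axis=1))
        assert rho == pytest.approx(1.0)

    def test_vanishing_uniqueness_dominates_scores(self):
        stack_lam = np.array([0.999, 0.5, 0.5, 0.5])
        g = np.random.default_rng(7)
        eta = g.standard_normal(3000)
        x = stack_lam * eta[:, None] + np.sqrt(1 - stack_lam**2) * g.standard_normal((3000, 4))
        sol = fit_single_factor(x)
        scores = regression_scores(sol, x)
        r = np.corrcoef(scores, x[:, 0])[0, 1]
        assert abs(r) > 0.999

    def test_scores_standardized(self, rng):
        x = rng.standard_normal((100, 4)) + 0.5 * rng.standard_normal((100, 1))
        sol = fit_single_factor(x)
        scores = regression_scores(sol, x)
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)
        assert scores.std() == pytest.approx(1.0, abs=1e-12)

    def test_score_validity_matches_population_formula(self):
        # validity of the regression score is lambda' R^{-1} lambda
        stack, truth = simulate_fc_stack(10000, 3, 6, loading_spec=0.7, seed=23)
        e = 0
        x = stack.values[:, :, e]
        sol = fit_single_factor(x)
        scores = regression_scores(sol, x)
        observed = np.corrcoef(scores, truth.latent_edge_scores[:, e])[0, 1] ** 2
        lam = np.full(6, 0.7)
        expected = lam @ np.linalg.solve(implied_corr(lam), lam)
        assert observed == pytest.approx(expected, abs=0.02)


class TestRestrictedAverage:
    def test_scores_are_raw_row_means(self):
        x = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        sol, scores = restricted_average_solution(x)
        np.testing.assert_array_equal(scores, [2.0, 5.0])
        assert np.all(sol.loadings == 1.0) and np.all(sol.uniquenesses == 0.0)

    def test_single_indicator_passthrough(self, rng):
        x = rng.standard_normal((10, 1))
        _, scores = restricted_average_solution(x)
        np.testing.assert_allclose(scores, x[:, 0])

    def test_equal_generating_loadings_make_free_model_match_average(self):
        stack, _ = simulate_fc_stack(2000, 3, 8, loading_spec=0.7, seed=29)
        x = stack.values[:, :, 0]
        sol = fit_single_factor(x)
        free = regression_scores(sol, x)
        _, avg = restricted_average_solution(x)
        r = np.corrcoef(free, avg)[0, 1]
        assert r > 0.99
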