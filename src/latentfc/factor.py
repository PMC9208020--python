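"""Single-factor model fitting and regression-method factor scores.

The model: S observed indicators (here, one state's FC value at one
edge, or one cognitive measure) are imperfect manifestations of one
latent variable.  In the standardized metric the indicator correlation
matrix is

    R = lambda lambda' + diag(1 - lambda^2)

with loadings lambda and uniquenesses eps = 1 - lambda^2.  Loadings are
extracted by minimum-residual (minres) fitting — minimize the sum of
squared off-diagonal residuals of R - lambda lambda' — or by Gaussian
maximum likelihood.  Factor scores use the Thurstone regression method:
weights W = R^{-1} lambda applied to column-standardized indicators.

The arithmetic average of the indicators is the restricted special case
with all loadings fixed at 1 and uniquenesses at 0; it is exposed here so
average-based connectivity is literally the same model with constrained
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "FactorSolution",
    "fit_single_factor",
    "fit_from_correlation",
    "regression_scores",
    "restricted_average_solution",
]

HEYWOOD_FLOOR = 0.001  # minimum uniqueness; loadings bounded at sqrt(1 - floor)
_MAX_ITER = 1000
_TOL = 1e-12


@dataclass
class FactorSolution:
    """Fitted single-factor parameters for one indicator set.

    loadings and uniquenesses are in the standardized metric, so
    loadings**2 + uniquenesses == 1 for an unconstrained converged fit.
    ``heywood`` flags solutions where a uniqueness hit the floor.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    indicator_corr: np.ndarray
    state_labels: list[str] | None = None
    converged: bool = True
    heywood: bool = False
    method: str = "minres"
    score_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.uniquenesses = np.asarray(self.uniquenesses, dtype=float)
        if self.score_weights is None and self.method != "restricted":
            # Thurstone regression weights W = R^{-1} lambda
            self.score_weights = _solve_weights(self.indicator_corr, self.loadings)

    @property
    def n_indicators(self) -> int:
        return self.loadings.shape[0]

    def score_validity(self) -> float:
        """Squared correlation between the factor and its regression score.

        Equals lambda' R^{-1} lambda in the population.
        """
        return float(self.loadings @ _solve_weights(self.indicator_corr, self.loadings))


def _solve_weights(corr: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(corr, loadings)
    except np.linalg.LinAlgError:
        jitter = 1e-8
        logger.warning("singular indicator correlation; ridge-stabilizing with %.0e", jitter)
        s = corr + jitter * np.eye(corr.shape[0])
        return np.linalg.solve(s, loadings)


def _initial_loadings(corr: np.ndarray) -> np.ndarray:
    """Start at sqrt(SMC) with signs from the first eigenvector.

    The squared multiple correlation of each indicator with the rest,
    h_i^2 = 1 - 1/(R^{-1})_ii, is the classical communality start; it is
    exactly 0 for independent indicators, which keeps the degenerate
    single-spike minimum of the minres objective out of reach there.
    """
    s = corr.shape[0]
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError:
        smc = np.full(s, 0.5)
    _, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    sign = np.where(v == 0, 1.0, np.sign(v))
    return sign * np.sqrt(np.clip(smc, 0.0, 0.95))


def _fit_minres(corr: np.ndarray) -> tuple[np.ndarray, bool]:
    s = corr.shape[0]
    iu, ju = np.triu_indices(s, k=1)
    target = corr[iu, ju]

    def resid(lam: np.ndarray) -> np.ndarray:
        return lam[iu] * lam[ju] - target

    def jac(lam: np.ndarray) -> np.ndarray:
        j = np.zeros((iu.size, s))
        j[np.arange(iu.size), iu] = lam[ju]
        j[np.arange(iu.size), ju] = lam[iu]
        return j

    bound = np.sqrt(1.0 - HEYWOOD_FLOOR)
    sol = optimize.least_squares(
        resid,
        _initial_loadings(corr),
        jac=jac,
        bounds=(-bound, bound),
        xtol=_TOL,
        ftol=_TOL,
        gtol=_TOL,
        max_nfev=_MAX_ITER,
    )
    return sol.x, bool(sol.success)


def _fit_ml(corr: np.ndarray) -> tuple[np.ndarray, bool]:
    """Gaussian ML with the standardized constraint eps = 1 - lambda^2."""
    s = corr.shape[0]
    sign, logdet_r = np.linalg.slogdet(corr)
    bound = np.sqrt(1.0 - HEYWOOD_FLOOR)

    def discrepancy(lam: np.ndarray) -> float:
        sigma = np.outer(lam, lam)
        np.fill_diagonal(sigma, 1.0)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10
        inv = np.linalg.inv(sigma)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return float(logdet + np.trace(corr @ inv) - logdet_r - s)

    sol = optimize.minimize(
        discrepancy,
        _initial_loadings(corr),
        method="L-BFGS-B",
        bounds=[(-bound, bound)] * s,
        options={"maxiter": _MAX_ITER, "ftol": 1e-14, "gtol": 1e-10},
    )
    return sol.x, bool(sol.success)


def fit_from_correlation(
    corr: np.ndarray,
    method: str = "minres",
    state_labels: list[str] | None = None,
) -> FactorSolution:
    """Fit the single-factor model directly to an indicator correlation matrix."""
    corr = np.asarray(corr, dtype=float)
    s = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != s:
        raise ValueError("correlation matrix must be square")
    if s < 3:
        raise ValueError("single-factor model unidentified with fewer than 3 indicators")
    if method == "minres":
        lam, converged = _fit_minres(corr)
    elif method == "ml":
        lam, converged = _fit_ml(corr)
    else:
        raise ValueError(f"unknown extraction method {method!r} (use 'minres' or 'ml')")
    if not converged:
        logger.warning("factor fit did not converge within %d iterations", _MAX_ITER)
    # sign convention: sum of loadings non-negative
    if lam.sum() < 0:
        lam = -lam
    uniq = 1.0 - lam**2
    heywood = bool(np.any(uniq < HEYWOOD_FLOOR + 1e-9))
    uniq = np.maximum(uniq, HEYWOOD_FLOOR)
    return FactorSolution(
        loadings=lam,
        uniquenesses=uniq,
        indicator_corr=corr,
        state_labels=state_labels,
        converged=converged,
        heywood=heywood,
        method=method,
    )


def fit_single_factor(
    indicators: np.ndarray,
    method: str = "minres",
    state_labels: list[str] | None = None,
) -> FactorSolution:
    """Fit a single-factor model to an N x S indicator matrix.

    The indicator Pearson correlation matrix is formed and loadings are
    extracted from it; see :func:`fit_from_correlation`.
    """
    x = np.asarray(indicators, dtype=float)
    if x.ndim != 2:
        raise ValueError("indicators must be 2-D (subjects x states)")
    n, s = x.shape
    if s < 3:
        raise ValueError("single-factor model unidentified with fewer than 3 indicators")
    if n <= s:
        raise ValueError("need more subjects than indicators")
    if not np.all(np.isfinite(x)):
        raise ValueError("indicators contain missing/non-finite values")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("indicator column with zero variance")
    corr = np.corrcoef(x, rowvar=False)
    return fit_from_correlation(corr, method=method, state_labels=state_labels)


def regression_scores(solution: FactorSolution, indicators: np.ndarray) -> np.ndarray:
    """Thurstone regression-method factor scores, standardized.

    Indicators are column-standardized, multiplied by W = R^{-1} lambda,
    and the resulting scores are re-standardized to mean 0, sd 1.
    """
    x = np.asarray(indicators, dtype=float)
    if x.ndim != 2 or x.shape[1] != solution.n_indicators:
        raise ValueError("indicator shape does not match the fitted solution")
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    raw = z @ solution.score_weights
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate factor scores (zero variance)")
    return (raw - raw.mean()) / sd


def restricted_average_solution(
    indicators: np.ndarray,
    state_labels: list[str] | None = None,
) -> tuple[FactorSolution, np.ndarray]:
    """The average as a constrained factor model.

    All loadings are fixed at 1 and uniquenesses at 0; the implied factor
    score is the per-subject arithmetic mean of the raw indicators.
    """
    x = np.asarray(indicators, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("indicators must be 2-D with >= 1 column")
    s = x.shape[1]
    corr = np.corrcoef(x, rowvar=False) if s > 1 and x.shape[0] > 1 else np.eye(s)
    solution = FactorSolution(
        loadings=np.ones(s),
        uniquenesses=np.zeros(s),
        indicator_corr=np.atleast_2d(corr),
        state_labels=state_labels,
        converged=True,
        heywood=False,
        method="restricted",
        score_weights=np.full(s, 1.0 / s),
    )
    return solution, x.mean(axis=1)
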