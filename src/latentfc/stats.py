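"""Similarity analysis, dependent-correlation tests, FDR, and meta-analysis.

FC-pattern similarity is the Pearson correlation of two connectomes over
their vectorized upper-triangle edges, computed per subject.  Two
dependent overlapping correlations (two predictors correlated with the
same outcome in one sample) are compared with the back-transformed
average Fisher-z method of Hittner, May & Silver (2003), a refinement of
Dunn & Clark's z; Steiger's (1980) variant is available by flag.
Correlations from independent samples are pooled as a sample-size-
weighted mean Fisher z,

    z_bar = sum_i w_i z_i / sum_i w_i,   w_i = n_i,

with significance from a chi-square test of the pooled z against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fc import FCMatrix, vectorize_edges

logger = logging.getLogger(__name__)

__all__ = [
    "MetaResult",
    "fisher_z",
    "inverse_fisher_z",
    "fc_similarity",
    "compare_similarity",
    "dependent_correlation_test",
    "meta_z",
    "bh_fdr",
]


def fisher_z(r):
    """Variance-stabilizing atanh transform of a correlation."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return np.arctanh(r)


def inverse_fisher_z(z):
    return np.tanh(np.asarray(z, dtype=float))


def _edge_vector(x) -> np.ndarray:
    if isinstance(x, FCMatrix):
        return vectorize_edges(x)
    x = np.asarray(x, float)
    return vectorize_edges(x) if x.ndim == 2 else x


def fc_similarity(fc_a, fc_b) -> float:
    """Pearson r between two connectomes over upper-triangle edges.

    Accepts square matrices (vectorized internally) or pre-vectorized
    edge vectors.
    """
    a = _edge_vector(fc_a)
    b = _edge_vector(fc_b)
    if a.shape != b.shape:
        raise ValueError("edge vectors differ in length (unequal region counts?)")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance edge vector; similarity undefined")
    return float(np.corrcoef(a, b)[0, 1])


def compare_similarity(
    sim_a: np.ndarray,
    sim_b: np.ndarray,
    alpha: float = 0.05,
    comparison_labels: list[str] | None = None,
    tails: str = "two",
) -> pd.DataFrame:
    """Paired t tests of Fisher-z similarities, per held-out comparison.

    ``sim_a``/``sim_b`` are subjects x comparisons matrices of
    similarities (e.g. latent-FC vs rest-FC similarity to each held-out
    state).  p values are Benjamini-Hochberg adjusted across comparisons.
    """
    a = np.atleast_2d(np.asarray(sim_a, float))
    b = np.atleast_2d(np.asarray(sim_b, float))
    if a.shape != b.shape:
        raise ValueError("similarity matrices must have the same shape")
    if a.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    za, zb = np.arctanh(np.clip(a, -0.999999, 0.999999)), np.arctanh(np.clip(b, -0.999999, 0.999999))
    n_cmp = a.shape[1]
    t_stats = np.empty(n_cmp)
    p_vals = np.empty(n_cmp)
    for c in range(n_cmp):
        d = za[:, c] - zb[:, c]
        if np.allclose(d, 0):
            t_stats[c], p_vals[c] = 0.0, 1.0
            continue
        t, p = sps.ttest_rel(za[:, c], zb[:, c])
        if tails == "one":
            p = p / 2 if t > 0 else 1 - p / 2
        t_stats[c], p_vals[c] = t, p
    reject, p_adj, *_ = multipletests(p_vals, alpha=alpha, method="fdr_bh")
    labels = comparison_labels or [f"cmp{c}" for c in range(n_cmp)]
    return pd.DataFrame(
        {
            "comparison": labels,
            "mean_r_a": np.tanh(za.mean(axis=0)),
            "mean_r_b": np.tanh(zb.mean(axis=0)),
            "t": t_stats,
            "p": p_vals,
            "p_fdr": p_adj,
            "significant": reject,
        }
    ).set_index("comparison")


def dependent_correlation_test(
    r1,
    r2,
    r12,
    n,
    method: str = "hittner2003",
    tails: str = "two",
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Compare two dependent overlapping correlations r(x1, y) vs r(x2, y).

    ``r12`` is the correlation between the two predictors within the same
    sample of ``n`` observations.  The default is the Hittner, May &
    Silver (2003) back-transformed-average Fisher z; 'steiger1980' uses
    the simple average of r1 and r2 instead.  Returns the signed z
    statistic (positive when r1 > r2) and its p value.  All arguments
    broadcast, so vectorized nulls are cheap.
    """
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    r12 = np.asarray(r12, float)
    n = np.asarray(n, float)
    for name, v in (("r1", r1), ("r2", r2), ("r12", r12)):
        if np.any(np.abs(v) >= 1.0):
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if np.any(n <= 3):
        raise ValueError("need n > 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if method == "hittner2003":
        rm = np.tanh((z1 + z2) / 2.0)  # back-transformed average
    elif method == "steiger1980":
        rm = (r1 + r2) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    rm2 = rm**2
    cov = (r12 * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r12**2)) / (
        (1.0 - rm2) ** 2
    )
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    if tails == "two":
        p = 2.0 * sps.norm.sf(np.abs(z))
    elif tails == "one":
        p = sps.norm.sf(z)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


@dataclass
class MetaResult:
    """Sample-size-weighted Fisher-z pooling across independent samples."""

    pooled_z: float
    pooled_r: float
    weights: np.ndarray
    per_sample_z: np.ndarray
    chi_square: float
    df: int
    p: float


def meta_z(r_values, sample_sizes) -> MetaResult:
    """Pool correlations from independent samples by weighted mean Fisher z.

    Weights are the sample sizes.  Significance: under the null the
    pooled z has variance 1/sum(w), so chi2(1) = pooled_z**2 * sum(w);
    this is the test of the pooled correlation against zero.
    """
    r = np.atleast_1d(np.asarray(r_values, float))
    w = np.atleast_1d(np.asarray(sample_sizes, float))
    if r.shape != w.shape:
        raise ValueError("r_values and sample_sizes must have the same length")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1")
    if np.any(w < 4):
        raise ValueError("sample sizes must be >= 4")
    z = np.arctanh(r)
    pooled = float(np.sum(w * z) / np.sum(w))
    chi2 = float(pooled**2 * np.sum(w))
    p = float(sps.chi2.sf(chi2, df=1))
    return MetaResult(
        pooled_z=pooled,
        pooled_r=float(np.tanh(pooled)),
        weights=w,
        per_sample_z=z,
        chi_square=chi2,
        df=1,
        p=p,
    )


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg rejection mask and adjusted p values."""
    p = np.asarray(p_values, float)
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj
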