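"""Activity flow mapping: predict held-out activations over connectivity.

A region's task activation is modeled as the connectivity-weighted sum of
every other region's activation:

    pred[j, c] = sum_{i != j} act[i, c] * fc[i, j]

The diagonal is always excluded, so a region's own activity never enters
its prediction.  Evaluation is estimate-then-average: correlations are
computed per subject (per region, per condition, or globally), Fisher
z-transformed, averaged across subjects, and back-transformed.  Model
comparison is a paired t test on the per-subject Fisher-z accuracies with
Benjamini-Hochberg FDR across units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simulate import ActivationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionEvaluation",
    "actflow_predict",
    "evaluate_predictions",
    "compare_prediction_models",
]


def _as_array(act) -> np.ndarray:
    return act.values if isinstance(act, ActivationMatrix) else np.asarray(act, float)


def actflow_predict(activations, fc) -> np.ndarray:
    """Activity-flow prediction for every region and condition.

    ``activations`` is regions x conditions (one subject); ``fc`` is a
    square connectivity matrix (Pearson FC, latent FC scores arranged as
    a matrix, or average FC).  The diagonal of ``fc`` is ignored.
    """
    a = _as_array(activations)
    w = fc.values.copy() if hasattr(fc, "values") and not isinstance(fc, np.ndarray) else np.asarray(fc, float).copy()
    if a.ndim != 2:
        raise ValueError("activations must be regions x conditions")
    if w.shape[0] != w.shape[1] or w.shape[0] != a.shape[0]:
        raise ValueError(
            f"connectivity {w.shape} does not match activations with {a.shape[0]} regions"
        )
    np.fill_diagonal(w, 0.0)
    return w.T @ a


@dataclass
class PredictionEvaluation:
    """Prediction accuracy pooled across subjects by mean Fisher z.

    ``per_subject_r`` (subjects x units) retains the unpooled
    correlations for paired model comparison; undefined correlations
    (zero-variance units) are NaN, never silently zero.
    """

    axis: str
    unit_labels: list[str]
    per_subject_r: np.ndarray
    pooled_r: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.per_subject_r.shape[0]

    @property
    def global_r(self) -> float:
        if self.axis != "global":
            raise ValueError("global_r is defined for axis='global' evaluations")
        return float(self.pooled_r[0])


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _pool_fisher(per_subject_r: np.ndarray) -> np.ndarray:
    """Mean of Fisher z across subjects, back-transformed; NaN-aware."""
    z = np.arctanh(np.clip(per_subject_r, -0.999999, 0.999999))
    with np.errstate(invalid="ignore"):
        pooled = np.tanh(np.nanmean(z, axis=0))
    return pooled


def evaluate_predictions(
    predicted: list[np.ndarray] | np.ndarray,
    actual: list[np.ndarray] | np.ndarray,
    axis: str = "region",
) -> PredictionEvaluation:
    """Correlate predicted with observed activations, per subject, then pool.

    axis='region'    : r across conditions, one value per region.
    axis='condition' : r across regions, one value per condition.
    axis='global'    : r across all cells, one value.
    Inputs are lists (or a stacked 3-D array) of per-subject
    regions x conditions matrices.
    """
    pred = [_as_array(p) for p in (predicted if isinstance(predicted, (list, tuple)) else list(predicted))]
    act = [_as_array(a) for a in (actual if isinstance(actual, (list, tuple)) else list(actual))]
    if len(pred) != len(act) or not pred:
        raise ValueError("predicted and actual must be non-empty and paired")
    n_regions, n_conditions = act[0].shape
    for p, a in zip(pred, act):
        if p.shape != (n_regions, n_conditions) or a.shape != (n_regions, n_conditions):
            raise ValueError("all subjects must share the regions x conditions shape")

    if axis == "region":
        units = [f"region{i}" for i in range(n_regions)]
        rows = [
            [_safe_corr(p[j], a[j]) for j in range(n_regions)] for p, a in zip(pred, act)
        ]
    elif axis == "condition":
        units = [f"cond{c}" for c in range(n_conditions)]
        rows = [
            [_safe_corr(p[:, c], a[:, c]) for c in range(n_conditions)]
            for p, a in zip(pred, act)
        ]
    elif axis == "global":
        units = ["global"]
        rows = [[_safe_corr(p.ravel(), a.ravel())] for p, a in zip(pred, act)]
    else:
        raise ValueError("axis must be 'region', 'condition', or 'global'")

    per_subject = np.asarray(rows, dtype=float)
    n_undef = int(np.isnan(per_subject).sum())
    if n_undef:
        logger.warning("%d undefined correlations (zero-variance units) reported as NaN", n_undef)
    return PredictionEvaluation(
        axis=axis,
        unit_labels=units,
        per_subject_r=per_subject,
        pooled_r=_pool_fisher(per_subject),
    )


def compare_prediction_models(
    eval_a: PredictionEvaluation,
    eval_b: PredictionEvaluation,
    alpha: float = 0.05,
    tails: str = "two",
) -> pd.DataFrame:
    """Paired t test of Fisher-z accuracies, model A vs B, per unit.

    Subjects with an undefined correlation in either model are dropped
    for that unit (count logged).  p values are Benjamini-Hochberg
    adjusted across units; ``favors`` marks units significant after FDR,
    signed toward the better model.
    """
    if eval_a.axis != eval_b.axis or eval_a.unit_labels != eval_b.unit_labels:
        raise ValueError("evaluations must share axis and units")
    if eval_a.n_subjects != eval_b.n_subjects:
        raise ValueError("evaluations must share subjects (paired design)")
    if eval_a.n_subjects < 3:
        raise ValueError("need >= 3 subjects for a paired t test")

    za = np.arctanh(np.clip(eval_a.per_subject_r, -0.999999, 0.999999))
    zb = np.arctanh(np.clip(eval_b.per_subject_r, -0.999999, 0.999999))
    diff = za - zb
    n_units = diff.shape[1]
    t_stats = np.full(n_units, np.nan)
    p_vals = np.full(n_units, np.nan)
    dropped = 0
    for u in range(n_units):
        d = diff[:, u]
        ok = np.isfinite(d)
        dropped += int((~ok).sum())
        d = d[ok]
        if d.size < 3:
            continue
        if np.allclose(d, 0):
            t_stats[u], p_vals[u] = 0.0, 1.0
            continue
        if np.allclose(d, d[0]):  # constant nonzero difference: infinite t
            t_stats[u], p_vals[u] = np.sign(d[0]) * np.inf, 0.0
            continue
        t, p = sps.ttest_rel(za[ok, u], zb[ok, u])
        if tails == "one":
            p = p / 2 if t > 0 else 1 - p / 2
        t_stats[u], p_vals[u] = t, p
    if dropped:
        logger.warning("dropped %d subject-unit pairs with undefined correlations", dropped)

    ok = np.isfinite(p_vals)
    reject = np.zeros(n_units, dtype=bool)
    p_adj = np.full(n_units, np.nan)
    if ok.any():
        rej, adj, *_ = multipletests(p_vals[ok], alpha=alpha, method="fdr_bh")
        reject[ok] = rej
        p_adj[ok] = adj

    favors = np.where(reject & (t_stats > 0), "A", np.where(reject & (t_stats < 0), "B", ""))
    table = pd.DataFrame(
        {
            "unit": eval_a.unit_labels,
            "t": t_stats,
            "p": p_vals,
            "p_fdr": p_adj,
            "significant": reject,
            "favors": favors,
        }
    ).set_index("unit")
    table.attrs["pct_favor_a"] = 100.0 * float(np.mean(favors == "A"))
    table.attrs["pct_favor_b"] = 100.0 * float(np.mean(favors == "B"))
    return table
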