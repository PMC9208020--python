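"""Psychometric g and cross-sample prediction of g from connectivity.

General intelligence is estimated exactly like latent FC, one level up: a
single-factor model over a battery of cognitive measures (11 in the
default configuration), with regression-method factor scores as the
manifest g.  Reaction-time-type measures are sign-flipped first so higher
always means better.

Prediction uses between-sample cross-validation with ridge regression:
the factor models for both the FC features and g are fit within each
split separately, a ridge model trained on one split predicts the other,
and vice versa — no quantity derived from a split's outcomes ever enters
that split's predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import RidgeCV

from .factor import fit_single_factor, regression_scores
from .simulate import BehaviorMatrix
from .stats import MetaResult, dependent_correlation_test

logger = logging.getLogger(__name__)

__all__ = [
    "GScores",
    "DEFAULT_MEASURE_DIRECTIONS",
    "fit_g_scores",
    "cross_sample_ridge_predict",
    "evaluate_behavior_prediction",
]

# The standard 11-measure cognitive battery (NIH Toolbox + Penn CNB) with
# polarity: -1 marks reaction-time-type scores where lower is better.
DEFAULT_MEASURE_DIRECTIONS: dict[str, int] = {
    "PicSeq_Unadj": 1,
    "CardSort_Unadj": 1,
    "Flanker_Unadj": 1,
    "PMAT24_A_CR": 1,
    "ReadEng_Unadj": 1,
    "PicVocab_Unadj": 1,
    "ProcSpeed_Unadj": 1,
    "VSPLOT_TC": 1,
    "IWRD_TOT": 1,
    "IWRD_RTC": -1,
    "ListSort_Unadj": 1,
}

DEFAULT_ALPHAS = np.logspace(-3, 5, 9)


@dataclass
class GScores:
    """Standardized general-intelligence factor scores."""

    scores: np.ndarray
    loadings: np.ndarray
    measure_labels: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.loadings = np.asarray(self.loadings, float)


def fit_g_scores(
    behavior: BehaviorMatrix | np.ndarray,
    directions: dict[str, int] | None = None,
    method: str = "minres",
) -> GScores:
    """Single-factor g from a battery of cognitive measures.

    ``directions`` maps measure label to +1/-1; -1 measures are negated
    before fitting so the positive manifold points the same way.
    """
    if isinstance(behavior, BehaviorMatrix):
        values = behavior.values.copy()
        labels = list(behavior.measure_labels)
    else:
        values = np.asarray(behavior, float).copy()
        labels = [f"measure{k}" for k in range(values.shape[1])]
    if directions:
        for k, lab in enumerate(labels):
            if directions.get(lab, 1) < 0:
                values[:, k] = -values[:, k]
    corr = np.corrcoef(values, rowvar=False)
    if np.linalg.matrix_rank(corr) < corr.shape[0]:
        raise ValueError("singular measure correlation matrix (duplicated measure?)")
    sol = fit_single_factor(values, method=method, state_labels=labels)
    scores = regression_scores(sol, values)
    return GScores(scores=scores, loadings=sol.loadings, measure_labels=labels)


def _ridge_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    alphas: np.ndarray,
) -> np.ndarray:
    """Ridge trained on one split, applied to the other.

    Features are standardized by the training split's statistics only;
    the penalty is chosen by 5-fold cross-validation within the training
    split.
    """
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd[sd == 0] = 1.0
    model = RidgeCV(alphas=alphas, cv=5)
    model.fit((train_x - mu) / sd, train_y)
    return model.predict((test_x - mu) / sd)


def cross_sample_ridge_predict(
    features: np.ndarray,
    behavior: BehaviorMatrix | np.ndarray,
    split_labels: np.ndarray,
    directions: dict[str, int] | None = None,
    alphas: np.ndarray = DEFAULT_ALPHAS,
    method: str = "minres",
) -> tuple[np.ndarray, np.ndarray]:
    """Between-sample cross-validated prediction of g from FC edges.

    ``features`` is subjects x edges (rest FC, latent FC scores, or
    average FC); ``split_labels`` assigns each subject to one of exactly
    two disjoint splits.  g is estimated within each split separately;
    the model trained on split B predicts split A and vice versa.
    Returns ``(predicted_g, actual_g)`` aligned to the input subjects.
    """
    features = np.asarray(features, float)
    split_labels = np.asarray(split_labels)
    if features.shape[0] != split_labels.shape[0]:
        raise ValueError("features and split_labels must align on subjects")
    groups = np.unique(split_labels)
    if groups.shape[0] != 2:
        raise ValueError("need exactly two disjoint splits")
    masks = {g: split_labels == g for g in groups}
    for g, m in masks.items():
        if m.sum() < 20:
            raise ValueError(f"split {g!r} has {int(m.sum())} subjects; need >= 20")

    values = behavior.values if isinstance(behavior, BehaviorMatrix) else np.asarray(behavior, float)
    if values.shape[0] != features.shape[0]:
        raise ValueError("behavior and features must align on subjects")

    actual = np.empty(features.shape[0])
    g_by_split: dict = {}
    for g, m in masks.items():
        beh = values[m]
        sub = BehaviorMatrix(
            values=beh,
            measure_labels=(
                list(behavior.measure_labels)
                if isinstance(behavior, BehaviorMatrix)
                else [f"measure{k}" for k in range(beh.shape[1])]
            ),
            subject_ids=[f"s{i}" for i in range(int(m.sum()))],
        )
        g_by_split[g] = fit_g_scores(sub, directions=directions, method=method)
        actual[m] = g_by_split[g].scores

    predicted = np.empty(features.shape[0])
    a, b = groups
    predicted[masks[a]] = _ridge_predict(
        features[masks[b]], g_by_split[b].scores, features[masks[a]], alphas
    )
    predicted[masks[b]] = _ridge_predict(
        features[masks[a]], g_by_split[a].scores, features[masks[b]], alphas
    )
    return predicted, actual


def evaluate_behavior_prediction(
    predicted: np.ndarray,
    actual: np.ndarray,
    split_labels: np.ndarray,
    predicted_b: np.ndarray | None = None,
    tails: str = "two",
) -> dict:
    """Accuracy of predicted g, per split and overall.

    Returns r and R^2 (= r^2) per split and pooled across all subjects.
    With a second prediction vector the difference between the two
    feature sets is tested per split with the dependent-overlapping-
    correlation z test and pooled across splits by sample-size-weighted
    meta-analysis of the per-split Fisher-z differences.
    """
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    split_labels = np.asarray(split_labels)
    if predicted.shape != actual.shape or predicted.shape[0] != split_labels.shape[0]:
        raise ValueError("predicted, actual, and split_labels must align")

    def _r(x, y):
        return float(np.corrcoef(x, y)[0, 1])

    out: dict = {"overall": {"r": _r(predicted, actual)}}
    out["overall"]["r2"] = out["overall"]["r"] ** 2
    groups = np.unique(split_labels)
    for g in groups:
        m = split_labels == g
        r = _r(predicted[m], actual[m])
        out[str(g)] = {"r": r, "r2": r**2, "n": int(m.sum())}

    if predicted_b is not None:
        predicted_b = np.asarray(predicted_b, float)
        delta_z, ns = [], []
        for g in groups:
            m = split_labels == g
            r1 = _r(predicted[m], actual[m])
            r2 = _r(predicted_b[m], actual[m])
            r12 = _r(predicted[m], predicted_b[m])
            n = int(m.sum())
            z, p = dependent_correlation_test(r1, r2, r12, n, tails=tails)
            out[str(g)].update({"r_b": r2, "delta_r": r1 - r2, "z": z, "p": p})
            delta_z.append(np.arctanh(r1) - np.arctanh(r2))
            ns.append(n)
        delta_z = np.asarray(delta_z)
        w = np.asarray(ns, float)
        pooled = float(np.sum(w * delta_z) / w.sum())
        # chi-square test of the pooled z difference against zero
        chi2 = pooled**2 * w.sum()
        out["meta"] = MetaResult(
            pooled_z=pooled,
            pooled_r=float(np.tanh(pooled)),
            weights=w,
            per_sample_z=delta_z,
            chi_square=float(chi2),
            df=1,
            p=float(sps.chi2.sf(chi2, df=1)),
        )
    return out
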