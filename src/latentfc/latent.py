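"""Edgewise latent FC: one independent single-factor model per connection.

For each edge, the per-state FC values across subjects form the indicator
matrix of a single-factor model; the regression-method factor score is
that subject's latent FC for the edge.  Leave-one-state-out (LOSO)
estimation drops the held-out state's slice before any fitting, so latent
FC can be compared with that state without circularity.  Fitting the
restricted equal-loading model instead reproduces cross-state average FC
("general functional connectivity") — the baseline the free model is
measured against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factor import FactorSolution, fit_single_factor, regression_scores, restricted_average_solution
from .fc import FCStack, devectorize

logger = logging.getLogger(__name__)

__all__ = [
    "LatentFCMatrix",
    "estimate_latent_fc",
    "average_fc",
    "summarize_loadings",
]


@dataclass
class LatentFCMatrix:
    """Per-subject latent FC scores plus group-level summaries.

    scores        : subjects x edges standardized factor scores (eta-hat).
    group_matrix  : regions x regions group-level latent edge values
                    (normalized-score-weight combination of the states'
                    group-mean indicators), zero diagonal.
    loadings      : included-states x edges fitted loadings.
    uniquenesses  : included-states x edges.
    fallback_mask : edges where fitting failed and the restricted
                    (average) score was substituted.
    """

    scores: np.ndarray
    group_matrix: np.ndarray
    loadings: np.ndarray
    uniquenesses: np.ndarray
    state_labels: list[str]
    edge_index: list[tuple[int, int]]
    subject_ids: list[str]
    fallback_mask: np.ndarray
    heywood_mask: np.ndarray
    method: str = "minres"
    excluded_state: str | None = None

    @property
    def n_edges(self) -> int:
        return self.scores.shape[1]


def estimate_latent_fc(
    stack: FCStack,
    exclude_state: str | None = None,
    method: str = "minres",
) -> LatentFCMatrix:
    """Fit an independent single-factor model to every edge of the stack.

    ``exclude_state`` removes that state's slice before fitting
    (leave-one-state-out); the held-out values never enter the model.
    Edges whose fit fails (zero variance, non-convergence without a
    usable solution) fall back to the restricted average score and are
    flagged rather than dropped.
    """
    labels = list(stack.state_labels)
    values = stack.values
    if exclude_state is not None:
        if exclude_state not in labels:
            raise ValueError(f"state {exclude_state!r} not in stack")
        keep = [i for i, lab in enumerate(labels) if lab != exclude_state]
        values = values[:, keep, :]
        labels = [labels[i] for i in keep]
    n_sub, n_states, n_edge = values.shape
    if n_states < 3:
        raise ValueError("need >= 3 included states for edgewise factor analysis")
    if n_sub < 10:
        raise ValueError("need >= 10 subjects for edgewise factor analysis")

    scores = np.empty((n_sub, n_edge))
    loadings = np.full((n_states, n_edge), np.nan)
    uniquenesses = np.full((n_states, n_edge), np.nan)
    fallback = np.zeros(n_edge, dtype=bool)
    heywood = np.zeros(n_edge, dtype=bool)
    group_edges = np.empty(n_edge)

    for e in range(n_edge):
        indicators = values[:, :, e]
        try:
            sol = fit_single_factor(indicators, method=method, state_labels=labels)
            scores[:, e] = regression_scores(sol, indicators)
            loadings[:, e] = sol.loadings
            uniquenesses[:, e] = sol.uniquenesses
            heywood[e] = sol.heywood
            weights = sol.score_weights
        except (ValueError, np.linalg.LinAlgError):
            _, avg = restricted_average_solution(indicators, state_labels=labels)
            sd = avg.std()
            scores[:, e] = (avg - avg.mean()) / sd if sd > 0 else 0.0
            loadings[:, e] = 1.0
            uniquenesses[:, e] = 0.0
            fallback[e] = True
            weights = np.full(n_states, 1.0 / n_states)
        # group-level edge value: score-weight-weighted mean of the states'
        # group-mean indicators (subject scores themselves are standardized
        # to mean 0, so their plain mean carries no group information)
        wsum = weights.sum()
        w = weights / wsum if wsum > 1e-12 else np.full(n_states, 1.0 / n_states)
        group_edges[e] = float(w @ indicators.mean(axis=0))
    n_fb = int(fallback.sum())
    if n_fb:
        logger.warning("restricted fallback used for %d/%d edges", n_fb, n_edge)

    group_matrix = devectorize(group_edges, stack.n_regions, diagonal=0.0)
    return LatentFCMatrix(
        scores=scores,
        group_matrix=group_matrix,
        loadings=loadings,
        uniquenesses=uniquenesses,
        state_labels=labels,
        edge_index=list(stack.edge_index),
        subject_ids=list(stack.subject_ids),
        fallback_mask=fallback,
        heywood_mask=heywood,
        method=method,
        excluded_state=exclude_state,
    )


def average_fc(stack: FCStack, exclude_state: str | None = None) -> np.ndarray:
    """Cross-state mean of each edge per subject (subjects x edges).

    Identical to the restricted equal-loading factor model applied
    edgewise: the score is the arithmetic mean of the raw indicators.
    """
    labels = list(stack.state_labels)
    values = stack.values
    if exclude_state is not None:
        if exclude_state not in labels:
            raise ValueError(f"state {exclude_state!r} not in stack")
        keep = [i for i, lab in enumerate(labels) if lab != exclude_state]
        values = values[:, keep, :]
    if values.shape[1] < 1:
        raise ValueError("need >= 1 state")
    return values.mean(axis=1)


def summarize_loadings(latent: LatentFCMatrix, threshold: float = 0.4) -> pd.DataFrame:
    """Per-state loading summary over all edges.

    Columns: percent of loadings >= 0, percent >= ``threshold``
    (inclusive), and the mean loading.  Percentages are over every edge,
    including fallback edges (whose loadings are the restricted 1s).
    """
    rows = []
    for s, label in enumerate(latent.state_labels):
        lam = latent.loadings[s]
        rows.append(
            {
                "state": label,
                "pct_nonneg": 100.0 * float(np.mean(lam >= 0)),
                f"pct_ge_{threshold:g}": 100.0 * float(np.mean(lam >= threshold)),
                "mean_loading": float(lam.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("state")
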