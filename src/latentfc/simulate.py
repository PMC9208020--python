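"""Synthetic data with the generative structure the latent-FC model assumes.

Each edge carries a subject-level latent connectivity score eta.  A
state's observed edge value is a noisy indicator of that score:

    y[i, s, e] = lambda[s, e] * eta[i, e] + sqrt(1 - lambda[s, e]^2) * noise

so lambda is the factor loading (standardized metric) and
lambda^2 + unique_sd^2 = 1 per state and edge.  A general-ability score g
is coupled to a sparse subset of edges, and behavioral measures load on g
— the same single-factor structure, one level up.

All generators are pure functions of their arguments: one integer seed is
expanded into fixed per-stream substreams (latent scores, per-state noise,
behavior), so e.g. adding a state never perturbs earlier streams.  Noise
is Gaussian throughout; no hemodynamics, autocorrelation, or motion are
simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

from .fc import (
    FCMatrix,
    FCStack,
    ParcellatedTimeSeries,
    edge_index_pairs,
    n_edges,
)

__all__ = [
    "GroundTruth",
    "BehaviorMatrix",
    "ActivationMatrix",
    "simulate_fc_stack",
    "simulate_timeseries_from_fc",
    "simulate_actflow_activations",
    "simulate_behavior",
]

# fixed substream tags, so streams are independent and stable across calls
_STREAM_ETA = 0
_STREAM_STATE = 1
_STREAM_COUPLING = 2
_STREAM_G = 3
_STREAM_BEHAVIOR = 4
_STREAM_TIMESERIES = 5
_STREAM_ACTFLOW = 6


def _rng(seed: int, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream) + key))


@dataclass
class GroundTruth:
    """Generative parameters behind a simulated study.

    latent_edge_scores : subjects x edges eta (standardized).
    state_loadings     : states x edges lambda in [-1, 1].
    unique_sd          : states x edges sqrt(1 - lambda^2).
    g_true             : subjects vector, coupled to latent edges.
    coupling_weights   : edges vector mapping eta to the g signal.
    """

    latent_edge_scores: np.ndarray
    state_loadings: np.ndarray
    unique_sd: np.ndarray
    g_true: np.ndarray | None = None
    coupling_weights: np.ndarray | None = None


@dataclass
class BehaviorMatrix:
    """Subjects x measures behavioral scores (columns standardized)."""

    values: np.ndarray
    measure_labels: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("behavior matrix must be 2-D")
        if self.values.shape[1] < 3:
            raise ValueError("need >= 3 measures (g factor unidentifiable below 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("behavior matrix contains missing/non-finite values")


@dataclass
class ActivationMatrix:
    """Regions x conditions task activation coefficients (GLM-beta units)."""

    values: np.ndarray
    subject_id: str = "sub-0"
    condition_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("activations must be regions x conditions with >= 1 condition")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activations contain non-finite values")
        if self.condition_labels is None:
            self.condition_labels = [f"cond{i}" for i in range(self.values.shape[1])]


def _expand_loadings(loading_spec, n_states: int, n_edge: int) -> np.ndarray:
    lam = np.asarray(loading_spec, dtype=float)
    if lam.ndim == 0:
        lam = np.full((n_states, n_edge), float(lam))
    elif lam.ndim == 1:
        if lam.shape[0] != n_states:
            raise ValueError("per-state loading vector must have one entry per state")
        lam = np.repeat(lam[:, None], n_edge, axis=1)
    elif lam.shape != (n_states, n_edge):
        raise ValueError("loading matrix must be states x edges")
    bad = np.argwhere(np.abs(lam) > 1.0)
    if bad.size:
        s, e = bad[0]
        raise ValueError(
            f"|loading| > 1 at state {s}, edge {e} (value {lam[s, e]:.4g})"
        )
    return lam


def simulate_fc_stack(
    n_subjects: int,
    n_regions: int,
    n_states: int,
    loading_spec=0.7,
    seed: int = 0,
    state_labels: list[str] | None = None,
    coupling_fraction: float = 0.1,
    coupling_strength: float = 0.5,
) -> tuple[FCStack, GroundTruth]:
    """Draw an edge-indicator stack from the single-factor generative model.

    ``loading_spec`` may be a scalar, a per-state vector, or a full
    states x edges matrix of loadings in [-1, 1].  A fraction
    ``coupling_fraction`` of edges (first block, unit weights) carries the
    g signal; ``coupling_strength`` is corr(g_true, edge signal), so 0
    disconnects behavior from connectivity entirely.
    """
    if n_subjects < 3 or n_regions < 3 or n_states < 3:
        raise ValueError("need n_subjects >= 3, n_regions >= 3, n_states >= 3")
    n_edge = n_edges(n_regions)
    lam = _expand_loadings(loading_spec, n_states, n_edge)
    unique_sd = np.sqrt(1.0 - lam**2)

    eta = _rng(seed, _STREAM_ETA).standard_normal((n_subjects, n_edge))
    values = np.empty((n_subjects, n_states, n_edge))
    for s in range(n_states):
        noise = _rng(seed, _STREAM_STATE, s).standard_normal((n_subjects, n_edge))
        values[:, s, :] = lam[s] * eta + unique_sd[s] * noise

    n_coupled = max(1, int(round(coupling_fraction * n_edge))) if coupling_fraction > 0 else 0
    coupling = np.zeros(n_edge)
    coupling[:n_coupled] = 1.0
    if n_coupled > 0 and coupling_strength != 0.0:
        signal = eta @ coupling
        signal = (signal - signal.mean()) / signal.std()
        g_noise = _rng(seed, _STREAM_G).standard_normal(n_subjects)
        c = float(coupling_strength)
        if not -1.0 <= c <= 1.0:
            raise ValueError("coupling_strength must lie in [-1, 1]")
        g_true = c * signal + np.sqrt(1.0 - c**2) * g_noise
    else:
        coupling[:] = 0.0
        g_true = _rng(seed, _STREAM_G).standard_normal(n_subjects)

    if state_labels is None:
        state_labels = ["rest"] + [f"task{i}" for i in range(1, n_states)]
    stack = FCStack(
        values=values,
        edge_index=edge_index_pairs(n_regions),
        state_labels=list(state_labels),
        subject_ids=[f"sub-{i}" for i in range(n_subjects)],
    )
    truth = GroundTruth(
        latent_edge_scores=eta,
        state_loadings=lam,
        unique_sd=unique_sd,
        g_true=g_true,
        coupling_weights=coupling,
    )
    return stack, truth


def simulate_timeseries_from_fc(
    target_fc: FCMatrix | np.ndarray,
    n_timepoints: int,
    seed: int = 0,
    subject_id: str = "sub-0",
    state: str = "rest",
    run: str = "run-1",
) -> ParcellatedTimeSeries:
    """Multivariate Gaussian draws whose population correlation is ``target_fc``.

    The target correlation matrix is factorized by eigendecomposition
    (Cholesky would reject exactly-singular targets); sample correlations
    converge to the target at rate 1/sqrt(T).
    """
    target = target_fc.values if isinstance(target_fc, FCMatrix) else np.asarray(target_fc, float)
    r = target.shape[0]
    if n_timepoints <= r:
        raise ValueError(f"n_timepoints must exceed n_regions ({n_timepoints} <= {r})")
    evals, evecs = np.linalg.eigh((target + target.T) / 2.0)
    if evals.min() < -1e-8:
        raise ValueError(
            f"target FC is not positive semi-definite (min eigenvalue {evals.min():.4g})"
        )
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    z = _rng(seed, _STREAM_TIMESERIES).standard_normal((n_timepoints, r))
    return ParcellatedTimeSeries(
        data=z @ root.T, subject_id=subject_id, state=state, run=run
    )


def simulate_actflow_activations(
    fc: FCMatrix | np.ndarray,
    n_conditions: int,
    input_scale: float = 1.0,
    seed: int = 0,
    spectral_bound: float = 0.9,
) -> tuple[ActivationMatrix, np.ndarray]:
    """Activations that satisfy the activity-flow propagation rule exactly.

    With W the zero-diagonal connectivity weight matrix, inputs s are
    drawn per condition and activations solve (I - W) a = s, so the
    activity-flow prediction W a equals a - s: the prediction error is
    exactly the injected local input.  W is rescaled to spectral radius
    ``spectral_bound`` when necessary; the rescale factor is logged.
    """
    w = fc.values.copy() if isinstance(fc, FCMatrix) else np.asarray(fc, float).copy()
    np.fill_diagonal(w, 0.0)
    radius = float(np.max(np.abs(np.linalg.eigvalsh((w + w.T) / 2.0))))
    if radius >= 1.0:
        logger.info("rescaling W by %.4f to spectral radius %.2f", spectral_bound / radius, spectral_bound)
        w = w * (spectral_bound / radius)
        radius = spectral_bound
    if radius >= 1.0:
        raise ValueError(f"spectral radius {radius:.3f} >= 1 after rescaling")
    n = w.shape[0]
    s = input_scale * _rng(seed, _STREAM_ACTFLOW).standard_normal((n, n_conditions))
    a = np.linalg.solve(np.eye(n) - w, s)
    act = ActivationMatrix(values=a)
    return act, s


def simulate_behavior(
    ground_truth: GroundTruth,
    n_measures: int = 11,
    g_loadings=0.7,
    noise_sd: float | None = None,
    seed: int = 0,
) -> BehaviorMatrix:
    """Behavioral measures loading on the ground-truth g factor.

    Each measure is ``g_loadings[k] * g + noise``; with ``noise_sd`` left
    as None the noise sd is sqrt(1 - loading^2), giving standardized
    indicators whose correlation with g equals the loading.  Columns are
    standardized on output.
    """
    if n_measures < 3:
        raise ValueError("need >= 3 measures (g factor unidentifiable below 3)")
    if ground_truth.g_true is None:
        raise ValueError("ground truth carries no g_true")
    g = np.asarray(ground_truth.g_true, float)
    load = np.asarray(g_loadings, float)
    if load.ndim == 0:
        load = np.full(n_measures, float(load))
    if load.shape[0] != n_measures:
        raise ValueError("g_loadings length must equal n_measures")
    if np.any(np.abs(load) > 1.0):
        raise ValueError("|g loading| > 1")
    sd = np.sqrt(1.0 - load**2) if noise_sd is None else np.full(n_measures, float(noise_sd))
    noise = _rng(seed, _STREAM_BEHAVIOR).standard_normal((g.shape[0], n_measures))
    m = load[None, :] * g[:, None] + sd[None, :] * noise
    col_sd = m.std(axis=0)
    keep = col_sd > 0
    m = np.where(keep[None, :], (m - m.mean(axis=0)) / np.where(keep, col_sd, 1.0), m)
    return BehaviorMatrix(
        values=m,
        measure_labels=[f"measure{k}" for k in range(n_measures)],
        subject_ids=[f"sub-{i}" for i in range(g.shape[0])],
    )
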