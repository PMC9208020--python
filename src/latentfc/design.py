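"""Nuisance and FIR design matrices, residualization, run normalization.

The nuisance model follows the standard parcellated-fMRI recipe: 6 motion
parameters, their temporal derivatives, and the quadratics of all 12 (24
motion regressors), plus 5 white-matter and 5 ventricle aCompCor
components, their derivatives, and the quadratics of all 20 (40
physiological regressors) — 64 columns in total.  Task-evoked responses
are removed with a finite impulse response (FIR) model: one indicator
column per within-block timepoint per condition, pooled across blocks,
with lag columns extending 25 TRs past block offset.

Conventions: TR indices are 0-based; blocks are half-open
[onset, onset + duration); derivatives are backward first differences
with a leading zero; quadratics are computed after derivative assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fc import ParcellatedTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionTiming",
    "DesignMatrix",
    "build_nuisance_regressors",
    "build_fir_design",
    "residualize",
    "znormalize_runs",
    "select_on_task_trs",
    "drop_initial_frames",
]


@dataclass
class ConditionTiming:
    """Block timing for one task condition, in TR units (0-based onsets)."""

    condition_name: str
    block_onsets: list[int]
    block_durations: list[int]

    def __post_init__(self) -> None:
        if len(self.block_onsets) != len(self.block_durations):
            raise ValueError("onsets and durations must have equal length")
        if not self.block_onsets:
            raise ValueError(f"condition {self.condition_name!r} has no blocks")
        onsets = list(self.block_onsets)
        if any(o2 <= o1 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError("block onsets must be strictly increasing")
        if any(d <= 0 for d in self.block_durations):
            raise ValueError("block durations must be positive")
        for (o1, d1), o2 in zip(zip(onsets, self.block_durations), onsets[1:]):
            if o1 + d1 > o2:
                raise ValueError(
                    f"overlapping blocks in condition {self.condition_name!r}"
                )

    def validate_run_length(self, run_length_trs: int) -> None:
        last = self.block_onsets[-1] + self.block_durations[-1]
        if last > run_length_trs:
            raise ValueError(
                f"condition {self.condition_name!r} extends to TR {last}, "
                f"beyond run length {run_length_trs}"
            )


@dataclass
class DesignMatrix:
    """Timepoints x regressors matrix with ordered column labels."""

    values: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design must be 2-D")
        if len(self.column_labels) != self.values.shape[1]:
            raise ValueError("label count must equal column count")

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]


def _derivative(x: np.ndarray) -> np.ndarray:
    """Backward first difference, leading row zero (length-preserving)."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def build_nuisance_regressors(
    motion: np.ndarray,
    wm_components: np.ndarray,
    ventricle_components: np.ndarray,
) -> DesignMatrix:
    """Assemble the 64-parameter nuisance design.

    Column order: [6 motion, 6 motion derivatives, quadratics of those 12]
    then [10 aCompCor components, 10 derivatives, quadratics of those 20].
    """
    motion = np.asarray(motion, float)
    wm = np.asarray(wm_components, float)
    vent = np.asarray(ventricle_components, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    if wm.ndim != 2 or wm.shape[1] != 5:
        raise ValueError("wm_components must be T x 5")
    if vent.ndim != 2 or vent.shape[1] != 5:
        raise ValueError("ventricle_components must be T x 5")
    t = motion.shape[0]
    if wm.shape[0] != t or vent.shape[0] != t:
        raise ValueError("all nuisance inputs must share the same number of rows")

    mot_block = np.hstack([motion, _derivative(motion)])  # T x 12
    phys = np.hstack([wm, vent])  # T x 10
    phys_block = np.hstack([phys, _derivative(phys)])  # T x 20

    values = np.hstack([mot_block, mot_block**2, phys_block, phys_block**2])
    labels = (
        [f"motion{i}" for i in range(6)]
        + [f"motion{i}_d" for i in range(6)]
        + [f"motion{i}_sq" for i in range(6)]
        + [f"motion{i}_d_sq" for i in range(6)]
        + [f"wm{i}" for i in range(5)]
        + [f"vent{i}" for i in range(5)]
        + [f"wm{i}_d" for i in range(5)]
        + [f"vent{i}_d" for i in range(5)]
        + [f"wm{i}_sq" for i in range(5)]
        + [f"vent{i}_sq" for i in range(5)]
        + [f"wm{i}_d_sq" for i in range(5)]
        + [f"vent{i}_d_sq" for i in range(5)]
    )
    assert values.shape[1] == 64 and len(labels) == 64
    return DesignMatrix(values=values, column_labels=labels)


def build_fir_design(
    timings: list[ConditionTiming],
    run_length_trs: int,
    extra_lags: int = 25,
) -> DesignMatrix:
    """FIR task design: per condition, one column per post-onset offset.

    A condition with maximum block duration D contributes D + extra_lags
    columns; column k carries a 1 at TR (onset + k) of every block of
    that condition (entries past the run end are simply absent).  Lag
    windows of different conditions may overlap — that is inherent to
    back-to-back block designs and left to the regression to resolve.
    """
    if not timings:
        raise ValueError("no condition timings supplied")
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for timing in timings:
        timing.validate_run_length(run_length_trs)
        max_dur = max(timing.block_durations)
        n_cols = max_dur + extra_lags
        block = np.zeros((run_length_trs, n_cols))
        for onset, dur in zip(timing.block_onsets, timing.block_durations):
            # offsets 0..dur-1 are on-block, dur..dur+extra_lags-1 post-offset lags
            for k in range(dur + extra_lags):
                t = onset + k
                if t < run_length_trs:
                    block[t, k] = 1.0
        cols.append(block)
        labels.extend(f"{timing.condition_name}_t{k}" for k in range(n_cols))
    return DesignMatrix(values=np.hstack(cols), column_labels=labels)


def residualize(
    ts: ParcellatedTimeSeries | np.ndarray,
    design: DesignMatrix | np.ndarray,
    add_mean_and_trend: bool = True,
) -> ParcellatedTimeSeries | np.ndarray:
    """OLS residuals of each region's series on the design.

    With ``add_mean_and_trend`` an intercept and linear trend are
    prepended, i.e. the series is de-meaned and de-trended as part of the
    same regression.  Rank-deficient designs fall back to the
    pseudoinverse (least-norm coefficients; residuals are unaffected).
    """
    is_ts = isinstance(ts, ParcellatedTimeSeries)
    y = ts.data if is_ts else np.asarray(ts, float)
    x = design.values if isinstance(design, DesignMatrix) else np.asarray(design, float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("design and time series must share the number of timepoints")
    if add_mean_and_trend:
        t = y.shape[0]
        trend = np.linspace(-1.0, 1.0, t)
        x = np.hstack([np.ones((t, 1)), trend[:, None], x])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        logger.warning("rank-deficient design (rank %d < %d); using pseudoinverse", rank, x.shape[1])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    if is_ts:
        return ParcellatedTimeSeries(
            data=resid,
            subject_id=ts.subject_id,
            state=ts.state,
            run=ts.run,
            region_labels=ts.region_labels,
        )
    return resid


def znormalize_runs(
    runs: list[ParcellatedTimeSeries],
) -> list[ParcellatedTimeSeries]:
    """Per run, per region: subtract the mean and scale to unit variance.

    Puts variance across runs on a common scale before concatenation.
    """
    out = []
    for ts in runs:
        data = ts.data
        if data.shape[0] < 2:
            raise ValueError(f"run {ts.run!r} has fewer than 2 timepoints")
        sd = data.std(axis=0, ddof=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"zero-variance region {ts.region_labels[dead[0]]!r} in run {ts.run!r}"
            )
        out.append(
            ParcellatedTimeSeries(
                data=(data - data.mean(axis=0)) / sd,
                subject_id=ts.subject_id,
                state=ts.state,
                run=ts.run,
                region_labels=ts.region_labels,
            )
        )
    return out


def select_on_task_trs(
    timings: list[ConditionTiming],
    run_length_trs: int,
) -> np.ndarray:
    """Boolean mask over TRs that fall inside any task block.

    The union over conditions of [onset, onset + duration); interblock
    fixation and post-block lag periods are excluded.
    """
    mask = np.zeros(run_length_trs, dtype=bool)
    for timing in timings:
        timing.validate_run_length(run_length_trs)
        for onset, dur in zip(timing.block_onsets, timing.block_durations):
            mask[onset : onset + dur] = True
    if not mask.any():
        logger.warning("on-task mask is empty (no blocks in any condition)")
    return mask


def drop_initial_frames(ts: ParcellatedTimeSeries, n_frames: int = 5) -> ParcellatedTimeSeries:
    """Discard the first frames of a run (scanner equilibration)."""
    if n_frames >= ts.n_timepoints:
        raise ValueError("cannot drop all timepoints")
    return ParcellatedTimeSeries(
        data=ts.data[n_frames:],
        subject_id=ts.subject_id,
        state=ts.state,
        run=ts.run,
        region_labels=ts.region_labels,
    )
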