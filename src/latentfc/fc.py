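"""Functional connectivity estimation and edge vectorization.

Connectivity is estimated with zero-lag Pearson correlations over
(optionally masked) time points, concatenated across runs of the same
state.  All modules share a single edge convention: the strict upper
triangle in row-major order, 0-based, so ``R`` regions yield
``R*(R-1)/2`` edges (360 regions -> 64,620 edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcellatedTimeSeries",
    "FCMatrix",
    "FCStack",
    "compute_fc",
    "vectorize_edges",
    "devectorize",
    "edge_index_pairs",
    "n_edges",
    "match_tr_budget",
]

_SYMMETRY_TOL = 1e-8


@dataclass
class ParcellatedTimeSeries:
    """Region-level BOLD time series: a timepoints x regions matrix."""

    data: np.ndarray
    subject_id: str = "sub-0"
    state: str = "rest"
    run: str = "run-1"
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be 2-D (timepoints x regions)")
        if self.region_labels is None:
            self.region_labels = [f"R{i}" for i in range(self.data.shape[1])]
        if len(self.region_labels) != self.data.shape[1]:
            raise ValueError("region_labels length must match region count")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Symmetric region x region Pearson correlation matrix."""

    values: np.ndarray
    state_label: str = "rest"
    subject_id: str = "sub-0"
    n_trs_used: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("FC matrix contains non-finite values")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"FC matrix asymmetric (max |A - A.T| = {asym:.3g})")
        v = (v + v.T) / 2.0
        if np.max(np.abs(np.diag(v) - 1.0)) > 1e-6:
            raise ValueError("FC matrix diagonal must be 1")
        np.fill_diagonal(v, 1.0)
        if np.max(np.abs(v)) > 1.0 + 1e-9:
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def n_edges(n_regions: int) -> int:
    """Number of unique region pairs: R*(R-1)/2."""
    return n_regions * (n_regions - 1) // 2


def edge_index_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Ordered (i, j) pairs, i < j, upper-triangle row-major."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class FCStack:
    """Vectorized edges for every subject and state.

    ``values`` is subjects x states x edges; ``edge_index`` records the
    (i, j) region pair behind each edge column, in the shared
    upper-triangle row-major order.
    """

    values: np.ndarray
    edge_index: list[tuple[int, int]]
    state_labels: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("stack must be 3-D (subjects x states x edges)")
        n, s, e = self.values.shape
        if len(self.state_labels) != s:
            raise ValueError("state_labels length mismatch")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")
        if len(self.edge_index) != e:
            raise ValueError("edge_index length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    @property
    def n_edges(self) -> int:
        return self.values.shape[2]

    @property
    def n_regions(self) -> int:
        # e = R(R-1)/2  =>  R = (1 + sqrt(1 + 8e)) / 2
        e = self.n_edges
        r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
        if n_edges(r) != e:
            raise ValueError(f"edge count {e} is not R*(R-1)/2 for integer R")
        return r

    def state_slice(self, state_label: str) -> np.ndarray:
        """Subjects x edges matrix for one state."""
        idx = self.state_labels.index(state_label)
        return self.values[:, idx, :]


def compute_fc(
    runs: list[ParcellatedTimeSeries] | ParcellatedTimeSeries,
    mask: np.ndarray | None = None,
) -> FCMatrix:
    """Pearson FC over run-concatenated (and optionally masked) time points.

    Runs of the same state are concatenated in the given order before the
    correlation is taken; no per-run averaging or Fisher transform is
    applied.  ``mask`` is a boolean vector over the concatenated
    timepoints selecting which TRs enter the correlation.
    """
    if isinstance(runs, ParcellatedTimeSeries):
        runs = [runs]
    if not runs:
        raise ValueError("need at least one run")
    n_regions = runs[0].n_regions
    for r in runs:
        if r.n_regions != n_regions:
            raise ValueError("runs disagree on region count")
    data = np.vstack([r.data for r in runs])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != data.shape[0]:
            raise ValueError(
                f"mask length {mask.shape[0]} != concatenated length {data.shape[0]}"
            )
        data = data[mask]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to correlate")
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [runs[0].region_labels[i] for i in dead[:5]]
        raise ValueError(f"zero-variance region(s) after masking: {names}")
    corr = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(
        values=np.clip(corr, -1.0, 1.0),
        state_label=runs[0].state,
        subject_id=runs[0].subject_id,
        n_trs_used=int(data.shape[0]),
    )


def vectorize_edges(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Strict upper triangle, row-major — the shared edge ordering."""
    m = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g})")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju].copy()


def devectorize(edges: np.ndarray, n_regions: int, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from its upper-triangle edge vector."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape[0] != n_edges(n_regions):
        raise ValueError(
            f"edge vector length {edges.shape[0]} != {n_edges(n_regions)} for R={n_regions}"
        )
    m = np.full((n_regions, n_regions), diagonal, dtype=float)
    iu, ju = np.triu_indices(n_regions, k=1)
    m[iu, ju] = edges
    m[ju, iu] = edges
    return m


def match_tr_budget(
    states: list[tuple[str, np.ndarray]],
    rest_budget: int = 2112,
    task_budget: int = 264,
    rest_label: str = "rest",
) -> dict[str, np.ndarray]:
    """Equalize TR counts across states before FC estimation.

    Each entry of ``states`` is ``(state_label, eligibility_mask)`` where
    the mask marks TRs usable for that state (on-task TRs for tasks, all
    retained TRs for rest).  The rest state keeps ``rest_budget`` TRs and
    each task keeps ``task_budget``; with eight tasks at the default 264
    this matches the 2,112 rest TRs to 2,112 total task TRs.  Selection is
    the first N eligible TRs in scan order, which is deterministic.
    """
    out: dict[str, np.ndarray] = {}
    for label, eligible in states:
        eligible = np.asarray(eligible, dtype=bool)
        budget = rest_budget if label == rest_label else task_budget
        avail = int(eligible.sum())
        if avail < budget:
            raise ValueError(
                f"state {label!r} has {avail} eligible TRs, "
                f"short of its budget {budget} by {budget - avail}"
            )
        idx = np.flatnonzero(eligible)[:budget]
        sel = np.zeros_like(eligible)
        sel[idx] = True
        out[label] = sel
    return out
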