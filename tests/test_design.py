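"""Nuisance/FIR design construction and residualization."""

import numpy as np
import pytest

from latentfc.design import (
    ConditionTiming,
    build_fir_design,
    build_nuisance_regressors,
    drop_initial_frames,
    residualize,
    select_on_task_trs,
    znormalize_runs,
)
from latentfc.fc import ParcellatedTimeSeries


@pytest.fixture()
def nuisance_inputs(rng):
    t = 100
    return rng.standard_normal((t, 6)), rng.standard_normal((t, 5)), rng.standard_normal((t, 5))


class TestNuisance:
    def test_total_of_64_labeled_columns(self, nuisance_inputs):
        dm = build_nuisance_regressors(*nuisance_inputs)
        assert dm.n_regressors == 64
        assert len(dm.column_labels) == 64
        # 24 motion + 40 physiological
        assert sum(l.startswith("motion") for l in dm.column_labels) == 24
        assert sum(l.startswith(("wm", "vent")) for l in dm.column_labels) == 40

    def test_derivative_of_constant_column_is_zero(self, nuisance_inputs):
        motion, wm, vent = nuisance_inputs
        motion = motion.copy()
        motion[:, 2] = 3.14
        dm = build_nuisance_regressors(motion, wm, vent)
        col = dm.column_labels.index("motion2_d")
        assert np.all(dm.values[:, col] == 0)

    def test_quadratic_is_elementwise_square(self, nuisance_inputs):
        motion, wm, vent = nuisance_inputs
        motion = motion.copy()
        motion[:3, 0] = [1.0, 2.0, 3.0]
        dm = build_nuisance_regressors(motion, wm, vent)
        col = dm.column_labels.index("motion0_sq")
        np.testing.assert_allclose(dm.values[:3, col], [1.0, 4.0, 9.0])

    def test_mismatched_rows_rejected(self, nuisance_inputs):
        motion, wm, vent = nuisance_inputs
        with pytest.raises(ValueError, match="rows"):
            build_nuisance_regressors(motion, wm[:-1], vent)

    def test_wrong_column_count_rejected(self, nuisance_inputs):
        motion, wm, vent = nuisance_inputs
        with pytest.raises(ValueError, match="T x 6"):
            build_nuisance_regressors(motion[:, :5], wm, vent)


class TestFIR:
    def test_column_count_is_duration_plus_lags(self):
        timing = ConditionTiming("wm", [10, 60, 110], [10, 10, 10])
        dm = build_fir_design([timing], 200, extra_lags=25)
        assert dm.n_regressors == 35

    def test_two_conditions_sum_their_columns(self):
        t1 = ConditionTiming("a", [0, 50], [10, 10])
        t2 = ConditionTiming("b", [20, 80], [8, 8])
        dm = build_fir_design([t1, t2], 200, extra_lags=25)
        assert dm.n_regressors == 35 + 33

    def test_block_at_run_end_truncates_lags(self):
        timing = ConditionTiming("a", [90], [10])
        dm = build_fir_design([timing], 100, extra_lags=25)
        assert dm.n_regressors == 35  # columns retained
        # lag columns beyond the run have no entries
        assert np.all(dm.values[:, 10:].sum(axis=0) == 0)
        assert np.all(dm.values[:, :10].sum(axis=0) == 1)

    def test_indicator_placement(self):
        timing = ConditionTiming("a", [5, 40], [3, 3])
        dm = build_fir_design([timing], 100, extra_lags=2)
        assert dm.n_regressors == 5
        col0 = dm.values[:, 0]
        assert col0[5] == 1 and col0[40] == 1 and col0.sum() == 2

    def test_empty_timing_rejected(self):
        with pytest.raises(ValueError, match="no blocks"):
            ConditionTiming("a", [], [])
        with pytest.raises(ValueError, match="no condition"):
            build_fir_design([], 100)

    def test_overlapping_blocks_within_condition_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ConditionTiming("a", [0, 5], [10, 5])


class TestResidualize:
    def test_self_regression_zeroes_series(self, rng):
        y = rng.standard_normal((50, 3))
        resid = residualize(y, y[:, [0]], add_mean_and_trend=False)
        assert np.max(np.abs(resid[:, 0])) < 1e-10

    def test_orthogonal_design_leaves_demeaned_series(self, rng):
        t = 60
        y = rng.standard_normal((t, 2))
        x = rng.standard_normal((t, 2))
        # project the design onto the orthogonal complement of span(y)
        x = x - y @ np.linalg.solve(y.T @ y, y.T @ x)
        resid = residualize(y, x, add_mean_and_trend=False)
        # X'y = 0 exactly: all coefficients are 0, residual equals the series
        np.testing.assert_allclose(resid, y, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.standard_normal((50, 3))
        x = rng.standard_normal((50, 4))
        resid = residualize(y, x, add_mean_and_trend=False)
        beta = np.linalg.solve(x.T @ x, x.T @ y)  # independent normal-equations solve
        np.testing.assert_allclose(resid, y - x @ beta, atol=1e-10)

    def test_projection_idempotent(self, rng):
        y = rng.standard_normal((80, 2))
        x = rng.standard_normal((80, 5))
        once = residualize(y, x)
        twice = residualize(once, x)
        np.testing.assert_allclose(once, twice, atol=1e-10)


class TestZNormalize:
    def _runs(self, rng):
        return [
            ParcellatedTimeSeries(rng.standard_normal((40, 3)) * 5 + 2, run="run-1"),
            ParcellatedTimeSeries(rng.standard_normal((40, 3)) * 0.1, run="run-2"),
        ]

    def test_each_run_has_zero_mean_unit_sd(self, rng):
        for ts in znormalize_runs(self._runs(rng)):
            np.testing.assert_allclose(ts.data.mean(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(ts.data.std(axis=0), 1.0, atol=1e-12)

    def test_idempotent(self, rng):
        once = znormalize_runs(self._runs(rng))
        twice = znormalize_runs(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_zero_variance_region_rejected_by_name(self, rng):
        runs = self._runs(rng)
        runs[0].data[:, 1] = 7.0
        with pytest.raises(ValueError, match="R1.*run-1"):
            znormalize_runs(runs)


class TestOnTaskMask:
    def test_mask_covers_exactly_block_trs(self):
        timings = [
            ConditionTiming("a", [0, 100], [25, 25]),
            ConditionTiming("b", [50], [50]),
        ]
        mask = select_on_task_trs(timings, 200)
        assert mask.sum() == 100

    def test_overlapping_conditions_count_once(self):
        timings = [ConditionTiming("a", [0], [10]), ConditionTiming("b", [5], [10])]
        mask = select_on_task_trs(timings, 50)
        assert mask.sum() == 15

    def test_drop_initial_frames(self, rng):
        ts = ParcellatedTimeSeries(rng.standard_normal((20, 3)))
        out = drop_initial_frames(ts, 5)
        assert out.n_timepoints == 15
        np.testing.assert_array_equal(out.data, ts.data[5:])
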