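import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinconn.connectivity import (ConnMatrix, ConnectivityError,
                                   EdgePhenotypeTable, WindowParams,
                                   differential_phenotype, dfc_summary,
                                   dynamic_fc, select_condition_frames,
                                   standardize_timeseries, static_fc,
                                   window_indices)
from twinconn.io import Block, RoiTimeSeries, TaskDesign

from _oracles import pearson_by_hand


def make_ts(data, tr=0.72, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels or [f"r{i}" for i in range(data.shape[1])]
    return RoiTimeSeries("s", "run1", data, tr, labels)


class TestStandardize:
    def test_hand_zscore(self):
        z = standardize_timeseries(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        z = standardize_timeseries(rng.standard_normal((50, 3)))
        np.testing.assert_allclose(standardize_timeseries(z), z, atol=1e-12)

    def test_constant_column_names_roi(self):
        data = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ConnectivityError, match="flat"):
            standardize_timeseries(data, ["good", "flat"])


class TestConditionFrames:
    def test_block_frame_arithmetic(self):
        # tr=0.72, block [10, 35): first frame ceil(10/0.72)=14,
        # last frame with t < 35 is 48
        ts = make_ts(np.zeros((100, 1)) + np.arange(100)[:, None])
        design = TaskDesign([Block(10, 25, "0bk")])
        frames = select_condition_frames(ts, design, "0bk")
        assert frames == [list(range(14, 49))]

    def test_lag_shifts_frames(self):
        ts = make_ts(np.arange(200.0)[:, None])
        design = TaskDesign([Block(10, 25, "0bk")])
        base = select_condition_frames(ts, design, "0bk")[0]
        lagged = select_condition_frames(ts, design, "0bk", lag=5.0)[0]
        shift = int(np.ceil(5.0 / 0.72 - 1e-9))
        assert lagged[0] - base[0] in (shift - 1, shift, shift + 1)
        assert lagged[0] == int(np.ceil(15.0 / 0.72 - 1e-9))

    def test_missing_condition_errors(self):
        ts = make_ts(np.zeros((10, 1)))
        design = TaskDesign([Block(0, 5, "0bk")])
        with pytest.raises(ConnectivityError, match="2bk"):
            select_condition_frames(ts, design, "2bk")


class TestStaticFc:
    def test_duplicate_roi_perfect_correlation(self):
        x = np.random.default_rng(1).standard_normal(30)
        ts = make_ts(np.column_stack([x, x]), labels=["x", "y"])
        assert static_fc(ts, range(30)).edge("x", "y") == pytest.approx(1.0)

    def test_hand_pearson(self):
        ts = make_ts(np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]]))
        r = static_fc(ts, [0, 1, 2]).values[0, 1]
        assert r == pytest.approx(0.5)
        assert r == pytest.approx(pearson_by_hand([1, 2, 3], [1, 3, 2]))

    def test_anticorrelated(self):
        x = np.random.default_rng(2).standard_normal(30)
        ts = make_ts(np.column_stack([x, -x]), labels=["x", "y"])
        assert static_fc(ts, range(30)).edge("x", "y") == pytest.approx(-1.0)

    def test_partial_matches_pearson_for_two_rois(self):
        # with only two variables there is nothing to partial out, so the
        # shrunk partial correlation must carry the same sign and a similar
        # magnitude as the Pearson estimate
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        y = 0.7 * x + rng.standard_normal(500) * 0.5
        ts = make_ts(np.column_stack([x, y]), labels=["x", "y"])
        r_p = static_fc(ts, range(500), "pearson").edge("x", "y")
        r_q = static_fc(ts, range(500), "partial").edge("x", "y")
        assert np.sign(r_p) == np.sign(r_q)
        assert abs(r_p - r_q) < 0.15

    def test_conn_matrix_invariants(self):
        rng = np.random.default_rng(4)
        ts = make_ts(rng.standard_normal((60, 5)))
        m = static_fc(ts, range(60))
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.abs(m.values).max() <= 1.0


class TestWindows:
    def test_count_formula(self):
        params = WindowParams(window_seconds=25 * 0.72, step_frames=3)
        wins = window_indices(100, params)
        assert len(wins) == 26
        assert wins[0] == (0, 25) and wins[-1] == (75, 100)

    def test_exact_fit_single_window(self):
        params = WindowParams(window_seconds=25 * 0.72, step_frames=3)
        assert window_indices(25, params) == [(0, 25)]

    def test_short_block_zero_windows(self):
        params = WindowParams(window_seconds=25 * 0.72, step_frames=3)
        assert window_indices(20, params) == []

    @given(n=st.integers(2, 400), w=st.integers(2, 60), step=st.integers(1, 10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_window_layout_properties(self, n, w, step):
        params = WindowParams(window_seconds=w * 0.72, step_frames=step)
        wins = window_indices(n, params)
        expected = (n - w) // step + 1 if n >= w else 0
        assert len(wins) == expected
        for s, e in wins:
            assert e - s == w and 0 <= s and e <= n

    def test_default_window_is_25_frames(self):
        assert WindowParams().window_frames == 25


class TestDynamicFc:
    def _long_design(self, n_frames, tr=0.72):
        return TaskDesign([Block(0, 3 * tr, "0bk"),
                           Block(3 * tr, n_frames * tr, "2bk")])

    def test_windows_match_static_fc_slices(self):
        rng = np.random.default_rng(5)
        ts = make_ts(rng.standard_normal((200, 4)))
        design = self._long_design(200)
        params = WindowParams(window_seconds=25 * 0.72, step_frames=3)
        stack = dynamic_fc(ts, design, "2bk", params)
        assert len(stack) > 5
        for info, mat in zip(stack.windows, stack.matrices):
            direct = static_fc(ts, range(info.start, info.end))
            np.testing.assert_array_equal(mat.values, direct.values)

    def test_degenerate_window_dropped(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((120, 3))
        data[40:70, 0] = 5.0  # one ROI flat inside some windows
        ts = make_ts(data)
        design = self._long_design(120)
        params = WindowParams(window_seconds=10 * 0.72, step_frames=10)
        stack = dynamic_fc(ts, design, "2bk", params)
        assert len(stack) >= 1
        # the flat segment's windows are gone, the rest are finite matrices
        assert all(data[w.start:w.end, 0].std() > 0 for w in stack.windows)
        assert all(np.isfinite(m.values).all() for m in stack.matrices)

    def test_zero_windows_errors(self):
        ts = make_ts(np.random.default_rng(7).standard_normal((30, 2)))
        design = TaskDesign([Block(0, 5, "0bk"), Block(5, 5, "2bk")])
        params = WindowParams(window_seconds=25 * 0.72, step_frames=3)
        with pytest.raises(ConnectivityError, match="window"):
            dynamic_fc(ts, design, "2bk", params)

    def test_regime_windows_match_their_regime(self, roi12, two_state_plan):
        # windows drawn wholly inside one covariance regime estimate that
        # regime's correlations within sampling error
        labels, _ = roi12
        rng = np.random.default_rng(8)
        cov0, cov1 = two_state_plan.state_cov
        n_half = 1000
        chol0, chol1 = np.linalg.cholesky(cov0), np.linalg.cholesky(cov1)
        data = np.vstack([rng.standard_normal((n_half, 12)) @ chol0.T,
                          rng.standard_normal((n_half, 12)) @ chol1.T])
        ts = make_ts(data, labels=labels)
        design = self._long_design(2 * n_half)
        params = WindowParams(window_seconds=250 * 0.72, step_frames=250)
        stack = dynamic_fc(ts, design, "2bk", params)
        checked = 0
        for info, mat in zip(stack.windows, stack.matrices):
            if info.end <= n_half:
                ref = cov0
            elif info.start >= n_half:
                ref = cov1
            else:
                continue
            checked += 1
            # 250-frame correlation sampling error: sd ~ 1/sqrt(250) ~ 0.06
            assert np.abs(mat.values - ref).max() < 0.3
        assert checked >= 4


class TestDfcSummaryAndDiff:
    def _stack_from_values(self, edge_vals):
        from twinconn.connectivity import WindowedConnStack, WindowInfo
        mats = []
        infos = []
        for k, v in enumerate(edge_vals):
            m = np.array([[1.0, v], [v, 1.0]])
            mats.append(ConnMatrix(m, ["a", "b"]))
            infos.append(WindowInfo(0, k * 5, k * 5 + 5))
        return WindowedConnStack(mats, infos)

    def test_hand_mean_variance(self):
        mean, var = dfc_summary(self._stack_from_values([0.2, 0.4]))
        assert mean[("a", "b")] == pytest.approx(0.3)
        assert var[("a", "b")] == pytest.approx(0.02)

    def test_identical_windows_zero_variance(self):
        _, var = dfc_summary(self._stack_from_values([0.3, 0.3, 0.3]))
        assert var[("a", "b")] == 0.0

    def test_single_window_variance_errors(self):
        with pytest.raises(ConnectivityError, match="2 windows"):
            dfc_summary(self._stack_from_values([0.3]))

    def _table(self, cond, values):
        df = pd.DataFrame(values, index=["s1", "s2"],
                          columns=pd.Index([("a", "b")], tupleize_cols=False))
        return EdgePhenotypeTable("staticFC", cond, df)

    def test_differential_subtraction(self):
        diff = differential_phenotype(self._table("2bk", [[0.5], [0.4]]),
                                      self._table("0bk", [[0.2], [0.4]]))
        assert diff.condition == "diff"
        assert diff.values.iloc[0, 0] == pytest.approx(0.3)
        assert diff.values.iloc[1, 0] == pytest.approx(0.0)

    def test_subject_mismatch_errors(self):
        t2 = self._table("2bk", [[0.5], [0.4]])
        t0 = self._table("0bk", [[0.2], [0.4]])
        t0.values.index = ["s1", "OTHER"]
        with pytest.raises(ConnectivityError, match="subject"):
            differential_phenotype(t2, t0)

    def test_window_length_monotonically_damps_variance(self):
        # a single stationary regime: longer windows average more frames, so
        # every edge's across-window variance shrinks
        rng = np.random.default_rng(9)
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        data = rng.standard_normal((3000, 2)) @ np.linalg.cholesky(cov).T
        ts = make_ts(data, labels=["a", "b"])
        design = TaskDesign([Block(0, 3 * 0.72, "0bk"),
                             Block(3 * 0.72, 3000 * 0.72, "2bk")])
        med = []
        for w in (10, 40, 160):
            params = WindowParams(window_seconds=w * 0.72, step_frames=10)
            _, var = dfc_summary(dynamic_fc(ts, design, "2bk", params))
            med.append(var.median())
        assert med[0] > med[1] > med[2]
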