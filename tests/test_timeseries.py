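"""Cleaning projection, task regressors, time-point selection and Pearson
edge matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfconn.timeseries import (
    ExclusionError,
    ParcellatedScan,
    build_nuisance_matrix,
    build_task_regressor,
    clean_timeseries,
    connectivity_matrix,
    double_gamma_hrf,
    n_edges,
    select_timepoints,
    unvectorize_edges,
    vectorize_edges,
)


def _scan(series, tr=2.0, **kw):
    return ParcellatedScan(np.asarray(series, dtype=float), tr, **kw)


class TestNuisanceMatrix:
    def test_motion_only_column_count(self):
        rng = np.random.default_rng(0)
        scan = _scan(rng.standard_normal((50, 3)), motion=rng.standard_normal((50, 6)))
        mat = build_nuisance_matrix(scan, use_motion=True)
        assert mat.shape == (50, 13)  # intercept + 6 motion + 6 derivatives

    def test_all_flags_off_gives_intercept(self):
        scan = _scan(np.random.default_rng(1).standard_normal((20, 2)))
        mat = build_nuisance_matrix(scan)
        assert mat.shape == (20, 1)
        assert np.all(mat == 1.0)

    def test_constant_motion_derivative_flagged(self):
        rng = np.random.default_rng(2)
        motion = rng.standard_normal((30, 6))
        motion[:, 0] = 5.0  # constant parameter -> zero column twice over
        scan = _scan(rng.standard_normal((30, 2)), motion=motion)
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            mat = build_nuisance_matrix(scan, use_motion=True)
        assert mat.shape[1] == 13

    def test_missing_input_raises(self):
        scan = _scan(np.zeros((10, 2)) + np.arange(10)[:, None])
        with pytest.raises(ValueError, match="motion"):
            build_nuisance_matrix(scan, use_motion=True)


class TestTaskRegressor:
    def test_empty_events_zero_column(self):
        cols, names = build_task_regressor([], 40, 2.0)
        assert cols.shape == (40, 1)
        assert np.all(cols == 0)

    def test_integral_matches_fine_grid_oracle(self):
        """Column sum * TR approximates duration x HRF integral (the
        convolution preserves area)."""
        tr, n = 0.5, 400
        cols, _ = build_task_regressor([(10.0, 1.0, "a")], n, tr, dt=0.01)
        dt = 0.001
        t = np.arange(0, 60, dt)
        hrf_integral = double_gamma_hrf(t).sum() * dt
        assert cols[:, 0].sum() * tr == pytest.approx(1.0 * hrf_integral, rel=0.01)

    def test_conditions_are_independent_columns(self):
        events = [(5.0, 2.0, "a"), (30.0, 2.0, "b")]
        cols, names = build_task_regressor(events, 60, 2.0)
        only_a, _ = build_task_regressor([events[0]], 60, 2.0)
        assert names == ["a", "b"]
        np.testing.assert_allclose(cols[:, 0], only_a[:, 0])

    def test_onset_beyond_scan_rejected(self):
        with pytest.raises(ValueError):
            build_task_regressor([(1000.0, 1.0, "a")], 40, 2.0)


class TestCleanTimeseries:
    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(3)
        scan = _scan(rng.standard_normal((120, 4)),
                     motion=rng.standard_normal((120, 6)),
                     censored=rng.random(120) < 0.1)
        nuis = build_nuisance_matrix(scan, use_motion=True, use_global=True)
        cleaned = clean_timeseries(scan, nuis, band=(0.008, 0.1))
        kept = ~scan.censored
        for j in range(nuis.shape[1]):
            col = nuis[kept, j]
            dots = np.abs(cleaned.series.T @ col)
            assert np.all(dots < 1e-8 * max(np.linalg.norm(col), 1.0))

    def test_bandstop_attenuates_out_of_band_sine(self):
        rng = np.random.default_rng(4)
        n, tr = 400, 2.0
        t = np.arange(n) * tr
        sine = np.sin(2 * np.pi * 0.15 * t)
        scan = _scan(rng.standard_normal((n, 3)) + sine[:, None],
                     censored=rng.random(n) < 0.1)
        cleaned = clean_timeseries(scan, band=(0.008, 0.1))
        tk = t[~scan.censored]
        basis = np.column_stack([np.cos(2 * np.pi * 0.15 * tk),
                                 np.sin(2 * np.pi * 0.15 * tk)])
        def power(y):
            beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
            return (basis @ beta).var()
        before = power(scan.series[~scan.censored, 0])
        after = power(cleaned.series[:, 0])
        assert after < 0.01 * before

    def test_highpass_only_keeps_slow_signal(self):
        n, tr = 400, 2.0
        t = np.arange(n) * tr
        sine = np.sin(2 * np.pi * 0.05 * t)
        rng = np.random.default_rng(5)
        scan = _scan(sine[:, None] + 0.1 * rng.standard_normal((n, 1)))
        cleaned = clean_timeseries(scan, band=(0.008, None))
        basis = np.column_stack([np.cos(2 * np.pi * 0.05 * t),
                                 np.sin(2 * np.pi * 0.05 * t)])
        def power(y):
            beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
            return (basis @ beta).var()
        assert power(cleaned.series[:, 0]) > 0.95 * power(scan.series[:, 0])

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        scan = _scan(rng.standard_normal((200, 3)), censored=rng.random(200) < 0.05)
        once = clean_timeseries(scan, band=(0.008, 0.1))
        twice = clean_timeseries(once, band=(0.008, 0.1))
        assert np.abs(twice.series - once.series).max() < 1e-10

    def test_insufficient_dof_excluded(self):
        rng = np.random.default_rng(7)
        scan = _scan(rng.standard_normal((30, 2)), censored=np.arange(30) >= 10)
        with pytest.raises(ExclusionError):
            clean_timeseries(scan, np.column_stack([np.ones(30),
                                                    rng.standard_normal((30, 15))]))


class TestSelectTimepoints:
    def _menu(self, rng, specs):
        return [_scan(rng.standard_normal((n, 3)), scan_type=t, phase_label=p)
                for t, n, p in specs]

    def test_equal_split_exact_counts(self):
        rng = np.random.default_rng(8)
        scans = self._menu(rng, [(f"t{i}", 100, "LR") for i in range(8)])
        series, comp = select_timepoints(scans, budget_minutes=16.0)  # 480 frames
        assert series.shape[0] == 480
        assert sorted(comp.n_frames) == [60] * 8  # budget/8 from each type

    def test_lr_before_rl_within_type(self):
        rng = np.random.default_rng(9)
        scans = self._menu(rng, [("rest", 100, "RL"), ("rest", 100, "LR")])
        series, comp = select_timepoints(scans, budget_minutes=5.0)  # 150 frames
        comp = comp.set_index("scan_index")
        assert comp.loc[1, "n_frames"] == 100  # LR exhausted first
        assert comp.loc[0, "n_frames"] == 50

    def test_random_remainder_deterministic(self):
        rng = np.random.default_rng(10)
        specs = [("a", 40, "LR"), ("b", 200, "LR"), ("c", 200, "RL")]
        scans = self._menu(rng, specs)
        out1 = select_timepoints(scans, budget_minutes=10.0, seed=5)  # 300 frames
        out2 = select_timepoints(scans, budget_minutes=10.0, seed=5)
        assert np.array_equal(out1[0], out2[0])
        assert out1[1].equals(out2[1])
        assert out1[1].n_frames.sum() == 300
        # type "a" fully consumed; shortfall drawn from the rest
        assert out1[1].set_index("scan_index").loc[0, "n_frames"] == 40

    def test_budget_and_feasibility_errors(self):
        rng = np.random.default_rng(11)
        scans = self._menu(rng, [("rest", 50, "LR")])
        with pytest.raises(ValueError):
            select_timepoints(scans, budget_minutes=0.0)
        with pytest.raises(ExclusionError):
            select_timepoints(scans, budget_minutes=60.0)


class TestConnectivity:
    def test_duplicate_and_negated_regions(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(50)
        series = np.column_stack([x, x, -x, rng.standard_normal(50)])
        mat = connectivity_matrix(series)
        assert mat[0, 1] == pytest.approx(1.0)
        assert mat[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(13)
        series = rng.standard_normal((50, 5))
        mat = connectivity_matrix(series)
        c = series - series.mean(axis=0)
        cov = c.T @ c / (50 - 1)
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        np.fill_diagonal(expected, 1.0)
        assert np.abs(mat - expected).max() < 1e-12

    def test_zero_variance_region_flagged(self):
        series = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0) ** 2])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            mat = connectivity_matrix(series)
        assert np.isnan(mat[0, 1])
        assert mat[0, 0] == 1.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(14)
        series = rng.standard_normal((60, 4))
        scaled = series.copy()
        scaled[:, 2] = 3.5 * scaled[:, 2] + 7.0
        np.testing.assert_allclose(connectivity_matrix(series),
                                   connectivity_matrix(scaled), atol=1e-12)


class TestEdgeVectorization:
    @pytest.mark.parametrize("r, expected", [(264, 34716), (44, 946)])
    def test_edge_counts(self, r, expected):
        assert n_edges(r) == expected

    @given(st.integers(min_value=2, max_value=20), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip(self, r, seed):
        rng = np.random.default_rng(seed)
        mat = connectivity_matrix(rng.standard_normal((r + 3, r)))
        assert np.array_equal(unvectorize_edges(vectorize_edges(mat), r), mat)

    def test_canonical_row_major_order(self):
        mat = np.zeros((3, 3))
        mat[0, 1], mat[0, 2], mat[1, 2] = 1, 2, 3
        mat = mat + mat.T
        np.fill_diagonal(mat, 1.0)
        assert vectorize_edges(mat).tolist() == [1, 2, 3]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            vectorize_edges(np.zeros((3, 4)))
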