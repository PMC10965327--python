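import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transientad import (ForecastSeries, Library, SmapConfig, TimeSeries,
                         control_forecasts, monitoring_forecasts,
                         smap_forecast, smap_weights)
from transientad.smap import DegenerateLibraryError


def weighted_ls_oracle(states, targets, weights, query):
    """Independent dense solve of the weighted normal equations."""
    A = weights[:, None] * states
    B = weights * targets
    C = np.linalg.solve(A.T @ A, A.T @ B)
    return C @ query


def geometric_series(n, rho=0.9, start=(8.0, 4.0, 2.0, 1.0), dt=1.0):
    """All four components decay by the same factor each step, so every
    state is a multiple of the start vector (rank-1 trajectory)."""
    states = np.array(start) * rho ** np.arange(n)[:, None]
    return TimeSeries(times=np.arange(n) * dt, states=states)


def linear_map_series(n, map_seed=0, init_seed=1, dt=1.0):
    """Trajectory of a stable full-rank 4x4 linear map."""
    rng = np.random.default_rng(map_seed)
    A = rng.uniform(-1, 1, size=(4, 4))
    A *= 0.9 / np.max(np.abs(np.linalg.eigvals(A)))
    states = np.empty((n, 4))
    states[0] = np.random.default_rng(init_seed).uniform(1, 2, size=4)
    for i in range(1, n):
        states[i] = A @ states[i - 1]
    return TimeSeries(times=np.arange(n) * dt, states=states)


class TestWeights:
    def test_theta_zero_gives_unit_weights(self):
        lib = Library(states=[[0.0, 1], [2, 3], [4, 5]], targets=[1, 2, 3])
        np.testing.assert_array_equal(smap_weights(lib, [1, 1], 0.0),
                                      np.ones(3))

    def test_zero_distance_gives_weight_one(self):
        lib = Library(states=[[1.0, 2], [5, 5]], targets=[0, 0])
        w = smap_weights(lib, [1, 2], theta=7.0)
        assert w[0] == 1.0

    def test_hand_worked_triple(self):
        lib = Library(states=[[0.0, 0], [1, 0], [0, 1]], targets=[0, 0, 0])
        w = smap_weights(lib, [0, 0], theta=5.0)
        np.testing.assert_allclose(w, [1.0, np.exp(-7.5), np.exp(-7.5)],
                                   rtol=1e-12)
        assert w[1] == pytest.approx(5.531e-4, rel=1e-3)

    def test_dimension_mismatch(self):
        lib = Library(states=[[1.0, 2]], targets=[3])
        with pytest.raises(ValueError, match="dimension"):
            smap_weights(lib, [1, 2, 3], 1.0)

    @given(st.integers(min_value=1, max_value=8),
           st.integers(min_value=0, max_value=10 ** 6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_weights_in_unit_interval(self, k, seed):
        rng = np.random.default_rng(seed)
        lib = Library(states=rng.normal(size=(k, 3)), targets=rng.normal(size=k))
        w = smap_weights(lib, rng.normal(size=3), theta=5.0)
        assert np.all(w > 0) and np.all(w <= 1)


class TestForecast:
    def test_single_pair_scalar_solve(self):
        lib = Library(states=[[2.0]], targets=[6.0])
        for q in (0.5, 1.0, 7.0):
            assert smap_forecast(lib, [q], theta=5.0) == pytest.approx(3 * q)

    @pytest.mark.parametrize("theta", [0.0, 2.0, 5.0])
    def test_exact_on_scalar_linear_rule(self, theta):
        c = -0.7
        states = np.linspace(1, 5, 8)[:, None]
        lib = Library(states=states, targets=c * states.ravel())
        for q in (0.3, 2.2, 9.0):
            assert smap_forecast(lib, [q], theta) == pytest.approx(
                c * q, abs=1e-10)

    def test_agrees_with_dense_oracle(self):
        rng = np.random.default_rng(2)
        states = rng.normal(size=(3, 2))
        targets = rng.normal(size=3)
        lib = Library(states=states, targets=targets)
        q = rng.normal(size=2)
        w = smap_weights(lib, q, 5.0)
        expected = weighted_ls_oracle(states, targets, w, q)
        assert smap_forecast(lib, q, 5.0) == pytest.approx(expected,
                                                           abs=1e-10)

    def test_degenerate_library(self):
        lib = Library(states=np.zeros((3, 2)), targets=[1.0, 2, 3])
        with pytest.raises(DegenerateLibraryError):
            smap_forecast(lib, [1, 1], 5.0)


class TestMonitoring:
    def test_exact_on_geometric_series(self):
        ts = geometric_series(30)
        fc = monitoring_forecasts(ts, SmapConfig(theta=5.0, h=20))
        assert np.abs(fc.predicted - fc.actual).max() < 1e-10

    def test_exact_on_full_rank_linear_map_after_warmup(self):
        ts = linear_map_series(40)
        fc = monitoring_forecasts(ts, SmapConfig(theta=5.0, h=20))
        # once the trailing library holds >= 4 pairs the map is identified
        assert np.abs(fc.predicted[4:] - fc.actual[4:]).max() < 1e-8

    def test_large_h_equals_whole_history(self, noisy_series):
        short = noisy_series
        a = monitoring_forecasts(short, SmapConfig(h=10_000))
        b = monitoring_forecasts(short, SmapConfig(h=len(short.times) + 5))
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_library_index_bookkeeping(self):
        # 6-point series, h=3, forecast of the last point: the library
        # must pair states at positions 1..3 with targets at 2..4
        rng = np.random.default_rng(3)
        ts = TimeSeries(times=np.arange(6.0), states=rng.uniform(1, 2, (6, 4)))
        cfg = SmapConfig(theta=5.0, h=3)
        fc = monitoring_forecasts(ts, cfg)
        lib = Library(states=ts.states[1:4], targets=ts.states[2:5, 0])
        expected = smap_forecast(lib, ts.states[4], cfg.theta)
        assert fc.predicted[-1] == pytest.approx(expected, rel=1e-14)
        np.testing.assert_array_equal(fc.times, ts.times[2:])

    def test_short_series_rejected(self):
        ts2 = TimeSeries(times=[0.0, 1.0], states=np.ones((2, 4)))
        with pytest.raises(ValueError, match="length"):
            monitoring_forecasts(ts2, SmapConfig())


class TestControl:
    def test_exact_with_linear_control(self):
        # theta=0 is a global linear fit: with a full-rank control
        # library the map is identified exactly for any target query.
        # (Localized weighting concentrates on the contracted tail of
        # the trajectory and loses rank for generic queries.)
        control = linear_map_series(40, map_seed=4, init_seed=1)
        target = linear_map_series(25, map_seed=4, init_seed=2)
        fc = control_forecasts(control, target, SmapConfig(theta=0.0))
        assert np.abs(fc.predicted - fc.actual).max() < 1e-8

    def test_deterministic(self, noisy_series):
        cfg = SmapConfig(theta=5.0)
        a = control_forecasts(noisy_series, noisy_series, cfg)
        b = control_forecasts(noisy_series, noisy_series, cfg)
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_grid_mismatch_rejected(self, noisy_series):
        stretched = TimeSeries(times=noisy_series.times * 2,
                               states=noisy_series.states)
        with pytest.raises(ValueError, match="spacing"):
            control_forecasts(stretched, noisy_series, SmapConfig())


class TestForecastSeriesType:
    def test_alignment_enforced(self):
        with pytest.raises(ValueError, match="align"):
            ForecastSeries(times=[0, 1], predicted=[1.0], actual=[1.0, 2.0])
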