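"""S-map: sequential locally weighted global linear forecasting.

The S-map forecasts a target variable one grid step ahead from a library
of (state vector, next-step target) pairs.  Library points are weighted
by their distance to the query point,

    w_i = exp(-theta * ||D(t_i) - q|| / dbar),

with dbar the mean distance from the query to all library states.  The
weighted linear map C solves B = A C in the least-squares sense, where
A_ij = w_i d_j(t_i) and B_i = w_i d*(t_{i+1}); the forecast is
Y = sum_j C_j q_j (no intercept term).  theta = 0 recovers a global
linear model; larger theta localizes the fit around the query.

Two library regimes are provided: *monitoring* (trailing window of at
most h points of the series being forecast) and *control* (one fully
observed reference series reused for every forecast).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ad_models import TimeSeries

#: relative singular-value cutoff for the least-squares solve
SVD_RCOND = 1e-10


class DegenerateLibraryError(ValueError):
    """Library state vectors are all zero; no linear map is identifiable."""


@dataclass(frozen=True)
class SmapConfig:
    """S-map configuration.

    theta: nonlinearity weighting (default 5).
    E: embedding dimension; default 4, the four observed state variables.
    h: maximum trailing-library size for monitoring mode (>= 2).
    target: column index of the forecast variable (default 0 = S1).
    """

    theta: float = 5.0
    E: int = 4
    h: int = 20
    target: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.E < 1:
            raise ValueError("E must be >= 1")
        if self.h < 2:
            raise ValueError("h must be >= 2")


@dataclass
class Library:
    """Paired training data: E-dim state vectors and next-step targets."""

    states: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        if len(self.states) != len(self.targets):
            raise ValueError("states and targets must have equal length")
        if len(self.states) < 1:
            raise ValueError("library must contain at least one pair")

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class ForecastSeries:
    """Per-time one-step forecasts of the target variable."""

    times: np.ndarray
    predicted: np.ndarray
    actual: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.actual = np.asarray(self.actual, dtype=float)
        if not (len(self.times) == len(self.predicted) == len(self.actual)):
            raise ValueError("times, predicted and actual must align")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "predicted": self.predicted,
                             "actual": self.actual})


def smap_weights(library: Library, query, theta: float) -> np.ndarray:
    """Exponential distance weights of every library state w.r.t. query."""
    q = np.asarray(query, dtype=float).ravel()
    if q.shape[0] != library.states.shape[1]:
        raise ValueError("query dimension does not match library states")
    dist = np.linalg.norm(library.states - q, axis=1)
    dbar = dist.mean()
    if dbar == 0:
        return np.ones_like(dist)
    return np.exp(-theta * dist / dbar)


def smap_forecast(library: Library, query, theta: float) -> float:
    """One S-map forecast of the target at the query point.

    Solves the weighted least-squares system by SVD (minimum-norm when
    rank-deficient; singular values below SVD_RCOND * s_max discarded).
    """
    q = np.asarray(query, dtype=float).ravel()
    if not np.any(library.states):
        raise DegenerateLibraryError("all library states are zero")
    w = smap_weights(library, q, theta)
    A = w[:, None] * library.states
    B = w * library.targets
    C, *_ = np.linalg.lstsq(A, B, rcond=SVD_RCOND)
    return float(C @ q)


def _trailing_library(states: np.ndarray, target_col: np.ndarray,
                      j: int, h: int) -> Library:
    """Library for a forecast from query index j: states up to j-1,
    targets one step later (up to index j), at most h pairs.

    Isolated here so the pairing convention can be changed in one place.
    """
    lo = max(0, j - h)
    return Library(states=states[lo:j], targets=target_col[lo + 1:j + 1])


def monitoring_forecasts(ts: TimeSeries, cfg: SmapConfig) -> ForecastSeries:
    """Trailing-window forecasts along a single monitored series.

    The forecast evaluated at grid index i uses the query D(t_{i-1}) and
    a library of the (at most h) preceding transition pairs; all available
    history is used while fewer than h pairs exist.  The first feasible
    forecast needs one library pair, so forecasts cover indices 2..n-1.
    """
    if len(ts.times) < 3:
        raise ValueError("monitoring forecasts need a series of length >= 3")
    states = ts.states
    target_col = states[:, cfg.target]
    n = len(ts.times)
    predicted = np.empty(n - 2)
    for i in range(2, n):
        lib = _trailing_library(states, target_col, i - 1, cfg.h)
        predicted[i - 2] = smap_forecast(lib, states[i - 1], cfg.theta)
    return ForecastSeries(times=ts.times[2:], predicted=predicted,
                          actual=target_col[2:])


def control_forecasts(control: TimeSeries, target_ts: TimeSeries,
                      cfg: SmapConfig) -> ForecastSeries:
    """Forecast a series using one fully observed control series.

    The library holds every consecutive pair of the control series and is
    reused for every forecast; queries are the target series' own states.
    """
    if len(control.times) < 2:
        raise ValueError("control series needs at least 2 points")
    if abs(control.dt - target_ts.dt) > 1e-9 * control.dt:
        raise ValueError(
            f"grid spacing mismatch: control dt = {control.dt:g}, "
            f"target dt = {target_ts.dt:g}")
    c_target = control.states[:, cfg.target]
    lib = Library(states=control.states[:-1], targets=c_target[1:])
    states = target_ts.states
    target_col = states[:, cfg.target]
    n = len(target_ts.times)
    predicted = np.empty(n - 1)
    for j in range(n - 1):
        predicted[j] = smap_forecast(lib, states[j], cfg.theta)
    return ForecastSeries(times=target_ts.times[1:], predicted=predicted,
                          actual=target_col[1:])
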