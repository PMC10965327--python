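"""Prediction-error curves and transient-end detectors.

Two error measures are derived from an S-map forecast series:

    R_abs(t_i) = |Y(t_i) - d*(t_i)|           (target-variable units)
    R_rel(t_i) = |(Y(t_i) - d*(t_i)) / d*(t_i)|   (dimensionless)

Both are smoothed with a strictly causal Gaussian-weighted trailing
average before detection.  Two rules predict the end of the transient:

* absolute rule: the first time the smoothed absolute error drops below a
  floor delta_a — near an attractor the S-map forecasts well, so a low
  absolute error signals the equilibrium phase has begun;
* relative rule: the first time the smoothed relative error exceeds
  delta_r *and* is a local maximum — the relative error stays low while
  the dynamics linger near the transient pseudo-attractor and spikes as
  they break away toward the true equilibrium.

Either rule may legitimately return no prediction (threshold never met).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .smap import ForecastSeries

#: |actual| below this floor makes the relative error ill-defined
RELATIVE_FLOOR = 1e-8

#: smoothing defaults: trailing window length and Gaussian bandwidth
DEFAULT_WINDOW = 10
DEFAULT_BANDWIDTH = DEFAULT_WINDOW / 3.0


@dataclass
class ErrorCurve:
    """Raw and (optionally) smoothed prediction-error sequence.

    ``kind`` is ``"absolute"`` or ``"relative"``.  ``n_excluded`` counts
    relative-error points dropped because |actual| < RELATIVE_FLOOR.
    """

    times: np.ndarray
    raw: np.ndarray
    kind: str
    smoothed: np.ndarray | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.times) != len(self.raw):
            raise ValueError("times and raw must have equal length")
        if np.any(self.raw < 0):
            raise ValueError("error values must be non-negative")
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if len(self.smoothed) != len(self.raw):
                raise ValueError("smoothed must align with raw")

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times, "raw": self.raw}
        if self.smoothed is not None:
            data["smoothed"] = self.smoothed
        return pd.DataFrame(data)


@dataclass(frozen=True)
class DetectionResult:
    """Predicted transient end time (or none) from one detection rule."""

    t_pred: float | None
    rule: str
    threshold: float
    triggered_index: int | None

    @property
    def predicted(self) -> bool:
        return self.t_pred is not None


def absolute_error_curve(fc: ForecastSeries) -> ErrorCurve:
    """Absolute forecast error |Y - d*| per time point."""
    raw = np.abs(fc.predicted - fc.actual)
    return ErrorCurve(times=fc.times.copy(), raw=raw, kind="absolute")


def relative_error_curve(fc: ForecastSeries) -> ErrorCurve:
    """Relative forecast error |(Y - d*)/d*| per time point.

    Points with |d*| < RELATIVE_FLOOR are excluded (not zero-filled) so a
    near-zero observation cannot fabricate a spike; the count of dropped
    points is recorded on the curve.
    """
    keep = np.abs(fc.actual) >= RELATIVE_FLOOR
    raw = np.abs((fc.predicted[keep] - fc.actual[keep]) / fc.actual[keep])
    return ErrorCurve(times=fc.times[keep].copy(), raw=raw, kind="relative",
                      n_excluded=int((~keep).sum()))


def smooth(curve: ErrorCurve, window: int = DEFAULT_WINDOW,
           bandwidth: float = DEFAULT_BANDWIDTH) -> ErrorCurve:
    """Gaussian-weighted trailing moving average of the raw curve.

    smoothed_i averages raw_{i-m} for m = 0..window-1 (clipped at the
    series start) with weights g_m = exp(-m^2 / (2 bandwidth^2)),
    renormalized over the available points.  Strictly causal: no value
    after index i contributes to smoothed_i.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    m = np.arange(window)
    g = np.exp(-m ** 2 / (2.0 * bandwidth ** 2))
    raw = curve.raw
    n = len(raw)
    smoothed = np.empty(n)
    for i in range(n):
        k = min(i + 1, window)
        smoothed[i] = (g[:k] @ raw[i - k + 1:i + 1][::-1]) / g[:k].sum()
    return ErrorCurve(times=curve.times.copy(), raw=raw.copy(),
                      kind=curve.kind, smoothed=smoothed,
                      n_excluded=curve.n_excluded)


def _require_smoothed(curve: ErrorCurve) -> np.ndarray:
    if curve.smoothed is None:
        raise ValueError("detection requires a smoothed curve; call smooth()")
    if len(curve.smoothed) == 0:
        raise ValueError("empty error curve")
    return curve.smoothed


def detect_absolute(curve: ErrorCurve, delta_a: float) -> DetectionResult:
    """First time the smoothed error drops below the floor delta_a."""
    if delta_a <= 0:
        raise ValueError("delta_a must be positive")
    s = _require_smoothed(curve)
    hits = np.flatnonzero(s < delta_a)
    if hits.size == 0:
        return DetectionResult(t_pred=None, rule="absolute",
                               threshold=delta_a, triggered_index=None)
    i = int(hits[0])
    return DetectionResult(t_pred=float(curve.times[i]), rule="absolute",
                           threshold=delta_a, triggered_index=i)


def detect_relative(curve: ErrorCurve, delta_r: float) -> DetectionResult:
    """First smoothed-curve local maximum exceeding the spike level delta_r.

    A trigger at index i requires smoothed_i > delta_r and a strict local
    maximum: greater than the previous value and greater than the next
    distinct value.  Exact-tie plateaus resolve to their last point.
    Boundary points are ineligible (a causal detector confirms a maximum
    only once the following value is available).
    """
    if delta_r <= 0:
        raise ValueError("delta_r must be positive")
    s = _require_smoothed(curve)
    n = len(s)
    i = 1
    while i < n - 1:
        if s[i] > delta_r and s[i] > s[i - 1]:
            # advance over an exact-tie plateau to its last point
            j = i
            while j + 1 < n and s[j + 1] == s[i]:
                j += 1
            if j + 1 < n and s[j + 1] < s[i]:
                return DetectionResult(t_pred=float(curve.times[j]),
                                       rule="relative", threshold=delta_r,
                                       triggered_index=j)
            i = j + 1
        else:
            i += 1
    return DetectionResult(t_pred=None, rule="relative", threshold=delta_r,
                           triggered_index=None)
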