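"""Stochastic analogue of the dimensional model and synthetic series.

Each state variable follows its deterministic ("core") rate plus an
independent multiplicative Gaussian increment w ~ Normal(0, sigma^2 x^2 dt)
truncated so the state can reach exactly zero but never goes negative: if
x + w would be negative the next value is exactly 0, which places an atom
of mass Phi(-1/(sigma sqrt(dt))) at extinction.  Zero is absorbing for the
noise term (the variance vanishes with x).

Ground truth for the end of the transient is the first grid time at which
S1 enters the band |S1 - S1*| < delta_eq around the deterministic
equilibrium S1*.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ad_models import ADParams, TimeSeries, as_state, dimensional_rhs

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """The stochastic simulation produced a non-finite state."""


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise level and simulation step.

    ``sigma`` is dimensionless (studied range 0.0005-5); ``dt`` is the
    Euler step in days (default 0.01 d; working series are produced by
    subsampling, not by coarsening the simulation step).
    """

    sigma: float
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """First entry of S1 into the equilibrium band."""

    t_end: float
    delta_eq: float
    s1_star: float
    index: int


def default_delta_eq(sigma: float) -> float:
    """Equilibrium-band half-width in S1 units; wider for noisier series."""
    return max(0.25, 0.5 * sigma)


def sample_increment(x: float, noise: NoiseModel, rng) -> float:
    """One truncated multiplicative-noise increment for current value x.

    Draws w ~ Normal(0, sigma^2 x^2 dt); returns -x (so the next value is
    exactly 0) whenever x + w < 0.  For x = 0 or sigma = 0 the variance is
    zero and the increment is exactly 0.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    scale = noise.sigma * x * np.sqrt(noise.dt)
    if scale == 0:
        # keep the stream position independent of the state value
        rng.standard_normal()
        return 0.0
    w = scale * rng.standard_normal()
    if x + w < 0:
        return -x
    return float(w)


def _coerce_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_init(seed) -> np.ndarray:
    """Uniform random initial condition in the study box.

    S1(0) ~ U(0,1), S2(0) ~ U(0,1), X1(0) ~ U(0,0.5), X2(0) ~ U(0,1),
    independent — small compared with the transient excursion, so every
    draw starts well away from equilibrium.
    """
    rng = _coerce_rng(seed)
    draw = rng.uniform(size=4)
    draw[2] *= 0.5
    return draw


def simulate_stochastic(params: ADParams, noise: NoiseModel, init,
                        t_max: float, seed) -> TimeSeries:
    """Euler simulation of the stochastic analogue.

    Per step: drift-update the state with the deterministic rates (any
    component driven negative by the drift alone is clamped to 0 and
    counted), then add one independent truncated multiplicative increment
    per variable.  Positivity holds at every step by construction.  Fully
    reproducible from ``seed``.
    """
    state = as_state(init).copy()
    if np.any(state < 0):
        raise ValueError("initial state must be non-negative")
    rng = _coerce_rng(seed)
    dt = noise.dt
    n = int(round(t_max / dt))
    times = np.arange(n + 1) * dt
    out = np.empty((n + 1, 4))
    out[0] = state
    sig_sqdt = noise.sigma * np.sqrt(dt)
    drift_clamped = 0
    for i in range(1, n + 1):
        state = state + dimensional_rhs(state, params) * dt
        if np.any(state < 0):
            drift_clamped += 1
            state = np.maximum(state, 0.0)
        w = sig_sqdt * state * rng.standard_normal(4)
        state = np.maximum(state + w, 0.0)
        if not np.all(np.isfinite(state)):
            raise SimulationError(f"non-finite state at t = {times[i]:g}")
        out[i] = state
    if drift_clamped:
        logger.warning("drift clamped to zero on %d of %d steps",
                       drift_clamped, n)
    return TimeSeries(times=times, states=out, frame="dimensional")


def generate_ensemble(params: ADParams, noise: NoiseModel, n_series: int,
                      t_max: float, base_seed) -> list[dict]:
    """n_series seeded realizations with random initial conditions.

    One base seed spawns an independent child stream per series (numpy
    SeedSequence splitting); each child draws its initial condition and
    then drives its own simulation.  Returns one record per series with
    keys ``seed_entropy``, ``init`` and ``series``.
    """
    if isinstance(base_seed, np.random.SeedSequence):
        ss = base_seed
    else:
        ss = np.random.SeedSequence(base_seed)
    records = []
    for child in ss.spawn(n_series):
        rng = np.random.default_rng(child)
        init = random_init(rng)
        series = simulate_stochastic(params, noise, init, t_max, rng)
        records.append({"seed_entropy": child.entropy,
                        "spawn_key": child.spawn_key,
                        "init": init, "series": series})
    return records


def subsample(ts: TimeSeries, delta_t: float) -> TimeSeries:
    """Every k-th row of ``ts`` where k = delta_t / dt (exact multiple).

    Mirrors the extraction of a sparser working series from the densely
    simulated one; the grid stays exactly uniform.
    """
    ratio = delta_t / ts.dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9 * max(1.0, ratio):
        raise ValueError(
            f"delta_t = {delta_t:g} is not an integer multiple of the "
            f"source spacing {ts.dt:g}")
    if k == 1:
        return TimeSeries(times=ts.times.copy(), states=ts.states.copy(),
                          frame=ts.frame)
    return TimeSeries(times=ts.times[::k].copy(),
                      states=ts.states[::k].copy(), frame=ts.frame)


def true_end_time(ts: TimeSeries, s1_star: float, delta_eq: float,
                  from_index: int = 0) -> GroundTruth | None:
    """First grid time with |S1 - s1_star| < delta_eq, or None if never.

    ``from_index`` restricts the scan to grid indices >= from_index; the
    default scans the whole series.
    """
    if delta_eq <= 0:
        raise ValueError("delta_eq must be positive")
    s1 = ts.states[:, 0]
    hits = np.flatnonzero(np.abs(s1[from_index:] - s1_star) < delta_eq)
    if hits.size == 0:
        return None
    i = int(hits[0]) + from_index
    return GroundTruth(t_end=float(ts.times[i]), delta_eq=delta_eq,
                       s1_star=s1_star, index=i)


def ground_truth_end_time(ts: TimeSeries, s1_star: float,
                          delta_eq: float) -> GroundTruth | None:
    """Transient-end ground truth: first band entry on the approach phase.

    The transient of interest overshoots S1* by orders of magnitude and
    then decays toward it, but S1 also sweeps upward *through* the
    equilibrium band within the first few steps of a run started at small
    concentrations.  The transient ends when S1 begins to approach the
    equilibrium, so the scan starts at the overshoot peak (the global
    maximum of S1) rather than at t = 0; a series started inside the band
    (no overshoot ever leaves it) still resolves to its first point.
    """
    peak = int(np.argmax(ts.states[:, 0]))
    return true_end_time(ts, s1_star, delta_eq, from_index=peak)
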