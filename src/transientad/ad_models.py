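"""Deterministic anaerobic-digestion chemostat models.

Two-guild chemostat: acidogens ``X1`` degrade a simple substrate ``S1``
(g l^-1) into volatile fatty acids ``S2`` (mmol l^-1), which methanogens
``X2`` consume.  Both guilds obey Monod kinetics and are washed out at the
dilution rate ``D``.  A non-dimensional form ``(u, v, x, y)`` with a small
timescale ratio ``eps = D / mu1`` exposes the fast-slow structure that
drives the overshoot-then-settle transient in ``S1``.

The module provides the right-hand sides of both models, the coexistence
equilibrium of the dimensional model, and a fixed-step RK4 integrator that
returns exactly uniform time grids (required by the downstream subsampling
and S-map machinery).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: column order of dimensional state vectors
DIMENSIONAL_COLUMNS = ("S1", "S2", "X1", "X2")
#: column order of dimensionless state vectors
DIMENSIONLESS_COLUMNS = ("u", "v", "x", "y")

#: negative excursions smaller than this are clipped silently-by-design
CLIP_TOL = 1e-12


class NoEquilibriumError(ValueError):
    """No positive equilibrium exists for the supplied parameters."""


class IntegrationError(RuntimeError):
    """The integrator produced a non-finite state."""


@dataclass(frozen=True)
class ADParams:
    """Dimensional chemostat parameters.

    Attributes
    ----------
    D : dilution rate (d^-1)
    S0 : inflow substrate concentration (g l^-1)
    y1 : degradation yield (g[S1] / g[X1])
    y2 : production yield (mmol[S2] / g[X1])
    y3 : consumption yield (mmol[S2] / g[X2])
    k1, k2 : acidogen / methanogen decay rates (d^-1)
    H1 : half-saturation for S1 degradation (g l^-1)
    H2 : half-saturation for S2 consumption (mmol l^-1)
    mu1_max, mu2_max : maximal growth rates (d^-1)
    """

    D: float
    S0: float
    y1: float
    y2: float
    y3: float
    k1: float
    k2: float
    H1: float
    H2: float
    mu1_max: float
    mu2_max: float

    def __post_init__(self) -> None:
        for name in ("D", "S0", "y1", "y2", "y3", "k1", "k2",
                     "H1", "H2", "mu1_max", "mu2_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ADParams.{name} must be strictly positive")
        if not self.mu1_max > self.D + self.k1:
            raise ValueError(
                "mu1_max must exceed D + k1 for a positive acidogen equilibrium"
            )

    @classmethod
    def default(cls) -> "ADParams":
        """Reference parameterization used for synthetic-data generation."""
        return cls(D=0.055, S0=700.0, y1=42.14, y2=116.5, y3=268.0,
                   k1=0.1, k2=0.001, H1=10.0, H2=9.28,
                   mu1_max=0.5, mu2_max=0.0064)


@dataclass(frozen=True)
class DimlessParams:
    """Dimensionless parameter groups of the reduced model.

    ``eps`` is the timescale ratio D/mu1 and must be small for the
    fast-slow reduction to be meaningful (a warning is emitted at
    eps >= 0.1).  ``sigma1 = k1/mu1`` must be < 1 for a positive fast
    equilibrium u* = sigma1/(1 - sigma1).
    """

    eps: float
    alpha: float
    beta: float
    sigma1: float
    sigma2: float
    omega: float

    def __post_init__(self) -> None:
        for name in ("eps", "alpha", "beta", "sigma1", "sigma2", "omega"):
            if not getattr(self, name) > 0:
                raise ValueError(f"DimlessParams.{name} must be strictly positive")
        if self.sigma1 >= 1:
            raise ValueError("sigma1 must be < 1 for a positive fast equilibrium")
        if self.eps >= 0.1:
            warnings.warn(
                f"eps = {self.eps} is not small; the fast-slow reduction "
                "assumes eps << 1", stacklevel=2)

    @classmethod
    def default(cls, alpha: float = 6.0, eps: float = 0.11) -> "DimlessParams":
        """Reference dimensionless set (intermediate-order alpha)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(eps=eps, alpha=alpha, beta=0.336,
                       sigma1=0.1, sigma2=0.0667, omega=4.27)


def as_state(state) -> np.ndarray:
    """Coerce a 4-component state (or stack of states) to a float array."""
    arr = np.asarray(state, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError(f"state must have 4 components, got shape {arr.shape}")
    return arr


@dataclass
class TimeSeries:
    """Uniformly spaced multivariate trajectory.

    ``times`` is a strictly increasing uniform grid and ``states`` has one
    4-component row per grid point.  ``frame`` tags the column convention:
    ``"dimensional"`` -> (S1, S2, X1, X2), ``"dimensionless"`` -> (u, v, x, y).
    """

    times: np.ndarray
    states: np.ndarray
    frame: str = "dimensional"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = as_state(self.states)
        if self.frame not in ("dimensional", "dimensionless"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two time points")
        if self.states.shape != (len(self.times), 4):
            raise ValueError("states must be (n_times, 4)")
        steps = np.diff(self.times)
        dt = steps[0]
        if dt <= 0 or np.any(np.abs(steps - dt) > 1e-9 * dt):
            bad = int(np.argmax(np.abs(steps - dt))) + 1
            raise ValueError(f"time grid is not uniform at row {bad}")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def columns(self) -> tuple:
        return (DIMENSIONAL_COLUMNS if self.frame == "dimensional"
                else DIMENSIONLESS_COLUMNS)

    def column(self, name: str) -> np.ndarray:
        """One named component as a 1-d array."""
        return self.states[:, self.columns.index(name)]

    def to_frame(self):
        """As a pandas DataFrame with a leading ``time`` column."""
        import pandas as pd

        data = {"time": self.times}
        for j, name in enumerate(self.columns):
            data[name] = self.states[:, j]
        return pd.DataFrame(data)


def _check_nonnegative(state: np.ndarray) -> None:
    if np.any(state < 0):
        raise ValueError("state components must be non-negative")


def dimensional_rhs(state, params: ADParams) -> np.ndarray:
    """Time derivatives of (S1, S2, X1, X2) for the dimensional model.

    Accepts a single state or a (..., 4) stack; broadcasts over leading axes.
    """
    st = as_state(state)
    _check_nonnegative(st)
    S1, S2, X1, X2 = st[..., 0], st[..., 1], st[..., 2], st[..., 3]
    p = params
    mu1 = p.mu1_max * S1 / (p.H1 + S1)
    mu2 = p.mu2_max * S2 / (p.H2 + S2)
    dS1 = p.D * (p.S0 - S1) - p.y1 * mu1 * X1
    dS2 = -p.D * S2 + p.y2 * mu1 * X1 - p.y3 * mu2 * X2
    dX1 = -(p.D + p.k1) * X1 + mu1 * X1
    dX2 = -(p.D + p.k2) * X2 + mu2 * X2
    return np.stack([dS1, dS2, dX1, dX2], axis=-1)


def dimensionless_rhs(state, params: DimlessParams) -> np.ndarray:
    """Time derivatives of (u, v, x, y) for the dimensionless model."""
    st = as_state(state)
    _check_nonnegative(st)
    u, v, x, y = st[..., 0], st[..., 1], st[..., 2], st[..., 3]
    p = params
    fu = u / (1.0 + u)
    fv = v / (1.0 + v)
    du = p.alpha - p.eps * u - p.beta * fu * x
    dv = -p.eps * v + fu * x - fv * y
    dx = -p.eps * x - p.sigma1 * x + fu * x
    dy = -p.eps * (1.0 + p.sigma2) * y + p.eps * p.omega * fv * y
    return np.stack([du, dv, dx, dy], axis=-1)


def dimensional_equilibrium(params: ADParams) -> tuple[np.ndarray, bool]:
    """Coexistence-branch equilibrium of the dimensional model.

    Returns ``(state, washout)``.  S1* solves mu1(S1*) = D + k1.  If the
    methanogens cannot sustain themselves (mu2_max <= D + k2) they wash
    out: X2* = 0, S2* balances the VFA equation, and ``washout`` is True.

    Raises
    ------
    NoEquilibriumError
        If mu1_max <= D + k1 (no positive acidogen equilibrium).
    """
    p = params
    net1 = p.D + p.k1
    if p.mu1_max <= net1:
        raise NoEquilibriumError("mu1_max <= D + k1: acidogens wash out")
    s1 = p.H1 * net1 / (p.mu1_max - net1)
    x1 = p.D * (p.S0 - s1) / (p.y1 * net1)
    net2 = p.D + p.k2
    if p.mu2_max <= net2:
        s2 = p.y2 * net1 * x1 / p.D
        return np.array([s1, s2, x1, 0.0]), True
    s2 = p.H2 * net2 / (p.mu2_max - net2)
    x2 = (p.y2 * net1 * x1 - p.D * s2) / (p.y3 * net2)
    return np.array([s1, s2, x1, x2]), False


def integrate(rhs, init, t_max: float, dt: float, params) -> TimeSeries:
    """Fixed-step 4th-order Runge-Kutta on the grid {0, dt, 2 dt, ...}.

    RK4 sub-stage states are clipped at zero before the rhs is evaluated
    (Monod terms are not meaningful for negative concentrations); any
    negative component after a full step is clipped to zero and, if the
    excursion exceeds CLIP_TOL, counted and reported via a log warning.

    The ``frame`` tag of the returned series follows the rhs: it is
    ``"dimensional"`` for :func:`dimensional_rhs` and ``"dimensionless"``
    otherwise.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    state = as_state(init).copy()
    _check_nonnegative(state)
    n = int(round(t_max / dt))
    times = np.arange(n + 1) * dt
    out = np.empty((n + 1, 4))
    out[0] = state
    clipped = 0

    def f(s):
        return rhs(np.maximum(s, 0.0), params)

    for i in range(1, n + 1):
        k1 = f(state)
        k2 = f(state + 0.5 * dt * k1)
        k3 = f(state + 0.5 * dt * k2)
        k4 = f(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise IntegrationError(
                f"non-finite state at t = {times[i]:g}")
        neg = state < 0
        if np.any(neg):
            if np.any(state < -CLIP_TOL):
                clipped += 1
            state = np.maximum(state, 0.0)
        out[i] = state
    if clipped:
        logger.warning("clipped negative components on %d of %d steps",
                       clipped, n)
    frame = "dimensional" if rhs is dimensional_rhs else "dimensionless"
    return TimeSeries(times=times, states=out, frame=frame)
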