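"""Fast-slow decomposition of the dimensionless chemostat model.

With the timescale ratio eps -> 0 the model splits into a fast subsystem
for (u, v, x) in which the methanogen density y is frozen, and a slow flow
for y constrained to the critical manifold where the fast right-hand side
vanishes.  The fast subsystem has a single equilibrium

    u* = sigma1 / (1 - sigma1),  v* = alpha / (beta y - alpha),
    x* = alpha / (beta sigma1),

which is stable over the parameter ranges of interest (checked here by a
numerical Jacobian eigensolve).

The transient itself proceeds in three stages: an inflow-dominated stage
in which u grows linearly at rate alpha, an exponential-bacterial-growth
stage once u/(1+u) has saturated, and the relaxation of the full fast
subsystem.  The stage boundaries tau1 and tau2 have closed forms:

    u_tol = (1 - eps_tol) / eps_tol
    tau1  = (u_tol - u0) / alpha
    tau2  = ln(alpha / (beta x0)) + tau1
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .ad_models import (DimlessParams, TimeSeries, as_state, dimensionless_rhs,
                        integrate)

logger = logging.getLogger(__name__)


class ManifoldSolveError(RuntimeError):
    """Root-solve for the critical manifold did not converge."""


@dataclass(frozen=True)
class StageTimes:
    """Closed-form stage boundaries of the three-stage transient.

    ``tau1``/``tau2`` are in fast-time units.  ``u_tol`` is the u value at
    which u/(1+u) is within ``eps_tol`` of saturation.  ``degenerate`` is
    set when alpha <= beta * x0, in which case tau2 <= tau1 and the
    exponential stage is empty.
    """

    tau1: float
    tau2: float
    u_tol: float
    eps_tol: float
    degenerate: bool = False


def fast_rhs(state, params: DimlessParams) -> np.ndarray:
    """Fast-subsystem rates (udot, vdot, xdot, 0); y acts as a constant.

    Identical to the full dimensionless rhs with eps set to zero.
    """
    st = as_state(state)
    if np.any(st < 0):
        raise ValueError("state components must be non-negative")
    u, v, x, y = st[..., 0], st[..., 1], st[..., 2], st[..., 3]
    p = params
    fu = u / (1.0 + u)
    fv = v / (1.0 + v)
    du = p.alpha - p.beta * fu * x
    dv = fu * x - fv * y
    dx = -p.sigma1 * x + fu * x
    return np.stack([du, dv, dx, np.zeros_like(du)], axis=-1)


def fast_equilibrium(params: DimlessParams, y: float) -> tuple[float, float, float]:
    """The unique positive equilibrium (u*, v*, x*) of the fast subsystem.

    Requires sigma1 < 1 (enforced by DimlessParams) and beta * y > alpha
    for a positive v*.
    """
    p = params
    if p.beta * y <= p.alpha:
        raise ValueError(
            f"beta*y = {p.beta * y:g} must exceed alpha = {p.alpha:g} "
            "for a positive fast equilibrium")
    u = p.sigma1 / (1.0 - p.sigma1)
    v = p.alpha / (p.beta * y - p.alpha)
    x = p.alpha / (p.beta * p.sigma1)
    return u, v, x


def _fast_jacobian(params: DimlessParams, point: np.ndarray, y: float,
                   step_scale: float = 1e-6) -> np.ndarray:
    """Central-difference 3x3 Jacobian of the fast subsystem at ``point``."""
    jac = np.empty((3, 3))
    for j in range(3):
        h = step_scale * max(1.0, abs(point[j]))
        up = point.copy()
        dn = point.copy()
        up[j] += h
        dn[j] -= h
        fu = fast_rhs(np.append(np.maximum(up, 0.0), y), params)[:3]
        fd = fast_rhs(np.append(np.maximum(dn, 0.0), y), params)[:3]
        jac[:, j] = (fu - fd) / (2 * h)
    return jac


def fast_stability(params: DimlessParams, y: float,
                   step_scale: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Eigenvalues of the fast-subsystem Jacobian at its equilibrium.

    Returns ``(eigenvalues, stable)`` with eigenvalues sorted by
    non-increasing real part (ties broken by imaginary part) and
    ``stable`` true when all real parts are negative.
    """
    point = np.array(fast_equilibrium(params, y))
    jac = _fast_jacobian(params, point, y, step_scale)
    eig = np.linalg.eigvals(jac)
    order = np.lexsort((eig.imag, -eig.real))
    eig = eig[order]
    return eig, bool(np.all(eig.real < 0))


def slow_manifold_point(y: float, params: DimlessParams,
                        max_iter: int = 100) -> tuple[float, float, float]:
    """Solve the algebraic constraint of the slow DAE for (u, v, x).

    The constraint is the vanishing of the fast rates at frozen y; the
    solve is initialized from the closed-form fast equilibrium and refined
    by a damped Newton-type root-finder.
    """
    guess = np.array(fast_equilibrium(params, y))

    def residual(p3):
        return fast_rhs(np.append(np.maximum(p3, 0.0), y), params)[:3]

    sol = optimize.root(residual, guess, method="hybr",
                        options={"maxfev": max_iter * 4, "xtol": 1e-13})
    res = np.linalg.norm(residual(sol.x))
    if res > 1e-10:
        raise ManifoldSolveError(
            f"manifold solve failed at y = {y:g}: residual {res:g}")
    return tuple(sol.x)


def slow_flow(y0: float, params: DimlessParams, s_max: float,
              ds: float = 1e-2) -> TimeSeries:
    """Slow (DAE) flow of y on the critical manifold.

    y evolves on the slow timescale s via
    y' = -(1 + sigma2) y + omega v/(1+v) y with (u, v, x) re-solved from
    the manifold constraint at every Euler step.  If the manifold solve
    fails mid-run the trajectory is truncated at the last valid state.
    """
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    p = params
    n = int(round(s_max / ds))
    times = np.arange(n + 1) * ds
    out = np.empty((n + 1, 4))
    y = float(y0)
    m = 0
    for i in range(n + 1):
        try:
            u, v, x = slow_manifold_point(y, params)
        except (ManifoldSolveError, ValueError) as exc:
            if i == 0:
                raise
            logger.warning("slow flow truncated at s = %g: %s", times[i], exc)
            break
        out[i] = (u, v, x, y)
        m = i
        y = y + ds * (-(1.0 + p.sigma2) * y + p.omega * v / (1.0 + v) * y)
    if m < 1:
        raise ManifoldSolveError("slow flow produced fewer than two points")
    return TimeSeries(times=times[:m + 1], states=out[:m + 1],
                      frame="dimensionless")


def stage_times(init, params: DimlessParams,
                eps_tol: float = 0.05) -> StageTimes:
    """Closed-form stage boundaries tau1, tau2 for small initial conditions.

    Raises
    ------
    ValueError
        If x0 = 0 (tau2 undefined) or eps_tol outside (0, 1).
    """
    if not 0 < eps_tol < 1:
        raise ValueError("eps_tol must lie in (0, 1)")
    st = as_state(init)
    u0, x0 = float(st[0]), float(st[2])
    p = params
    u_tol = (1.0 - eps_tol) / eps_tol
    if u0 > u_tol:
        warnings.warn(f"u0 = {u0:g} already exceeds u_tol = {u_tol:g}; "
                      "the staged approximation assumes small u0",
                      stacklevel=2)
    if x0 == 0:
        raise ValueError("x0 = 0: tau2 is undefined (no bacterial growth)")
    tau1 = max((u_tol - u0) / p.alpha, 0.0)
    degenerate = p.alpha <= p.beta * x0
    tau2 = np.log(p.alpha / (p.beta * x0)) + tau1
    if degenerate:
        logger.warning("alpha <= beta*x0: tau2 <= tau1, staged "
                       "approximation degenerate")
    return StageTimes(tau1=tau1, tau2=tau2, u_tol=u_tol, eps_tol=eps_tol,
                      degenerate=degenerate)


def _stage1_rhs(state, params: DimlessParams) -> np.ndarray:
    """Inflow-dominated stage: udot = alpha, everything else frozen."""
    st = as_state(state)
    du = np.broadcast_to(params.alpha, st.shape[:-1])
    zero = np.zeros_like(du)
    return np.stack([du, zero, zero, zero], axis=-1)


def _stage2_rhs(state, params: DimlessParams) -> np.ndarray:
    """Saturated-uptake stage: u/(1+u) ~ 1, x grows exponentially."""
    st = as_state(state)
    v, x, y = st[..., 1], st[..., 2], st[..., 3]
    p = params
    du = p.alpha - p.beta * x
    dv = x - v / (1.0 + v) * y
    dx = (1.0 - p.sigma1) * x
    return np.stack([du, dv, dx, np.zeros_like(dx)], axis=-1)


def piecewise_transient(init, params: DimlessParams, eps_tol: float = 0.05,
                        t_max: float = 20.0, dt: float = 0.01
                        ) -> tuple[TimeSeries, StageTimes]:
    """Three-stage approximation of the fast-subsystem transient.

    Integrates the stage-1 linear flow up to tau1, the stage-2
    exponential-growth flow up to tau2, and the full fast subsystem
    beyond, carrying the state continuously across both hand-offs.
    Hand-offs happen at the grid point nearest the closed-form stage time
    so the output grid stays exactly uniform.
    """
    st = stage_times(init, params, eps_tol)
    n = int(round(t_max / dt))
    i1 = min(int(round(st.tau1 / dt)), n)
    i2 = min(max(int(round(st.tau2 / dt)), i1), n)
    times = np.arange(n + 1) * dt
    out = np.empty((n + 1, 4))
    state = as_state(init).copy()
    out[0] = state

    segments = [(0, i1, _stage1_rhs), (i1, i2, _stage2_rhs),
                (i2, n, fast_rhs)]
    for lo, hi, rhs in segments:
        if hi <= lo:
            continue
        seg = integrate(rhs, np.maximum(out[lo], 0.0),
                        t_max=(hi - lo) * dt, dt=dt, params=params)
        out[lo:hi + 1] = seg.states
    ts = TimeSeries(times=times, states=out, frame="dimensionless")
    return ts, st
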