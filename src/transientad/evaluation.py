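"""Scoring of predicted vs ground-truth transient end times and sweeps.

Accuracy is measured with the coefficient of determination computed
against the identity line y = x (not a fitted regression): R^2 = 1 only
for perfect prediction, and systematic bias drives it negative.
Pearson's r complements it by measuring association irrespective of bias.
Series for which a rule produced no prediction enter only the success
proportion, never the accuracy scores.

:func:`run_sweep` runs the full factorial experiment over noise level
(sigma), detection threshold (delta), working grid spacing (Delta t) and
trailing-library size (h), reusing one batch of simulated series per
noise level and one set of forecasts per (sigma, Delta t, h) cell.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ad_models import ADParams, dimensional_equilibrium
from .detection import (absolute_error_curve, detect_absolute,
                        detect_relative, relative_error_curve, smooth)
from .smap import SmapConfig, control_forecasts, monitoring_forecasts
from .synthetic_data import (NoiseModel, default_delta_eq, generate_ensemble,
                             ground_truth_end_time, simulate_stochastic,
                             random_init, subsample)

#: default sweep grids (all configurable through run_sweep arguments)
DEFAULT_SIGMAS = np.logspace(np.log10(5e-4), np.log10(5.0), 10)
DEFAULT_DELTAS = np.logspace(-3, 2, 15)
DEFAULT_DTS = (0.05, 0.1, 0.5, 1.0)
DEFAULT_HS = (2, 5, 10, 20)


class UndefinedScoreError(ValueError):
    """Score undefined (zero variance or too few prediction pairs)."""


def r2_identity(predicted, truth) -> float:
    """Coefficient of determination against the line y = x.

    1 - sum (p_i - t_i)^2 / sum (t_i - mean t)^2.  Unclipped: systematic
    bias makes it negative, which is diagnostic, not an error.
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    ss_tot = np.sum((t - t.mean()) ** 2)
    if ss_tot == 0:
        raise UndefinedScoreError("truth has zero variance")
    return float(1.0 - np.sum((p - t) ** 2) / ss_tot)


def pearson_corr(predicted, truth) -> float:
    """Sample Pearson correlation between predicted and true end times."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.size < 2:
        raise UndefinedScoreError("need at least two pairs")
    if np.all(p == p[0]) or np.all(t == t[0]):
        raise UndefinedScoreError("zero variance in predicted or truth")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        r = float(stats.pearsonr(p, t).statistic)
    if np.isnan(r):
        raise UndefinedScoreError("correlation undefined for these pairs")
    return r


@dataclass
class SweepCell:
    """One (sigma, delta, Delta t, h) combination of the sweep."""

    sigma: float
    delta: float
    dt: float
    h: int
    n_attempted: int
    n_predicted: int
    predicted: np.ndarray
    truth: np.ndarray
    r2_identity: float | None
    pearson_r: float | None

    @property
    def success_rate(self) -> float:
        return success_rate(self)


def success_rate(cell: SweepCell) -> float:
    """Proportion of attempted series for which a prediction was made."""
    if cell.n_attempted < 1:
        raise ValueError("cell has no attempted series")
    return cell.n_predicted / cell.n_attempted


@dataclass
class SweepResult:
    """Factorial sweep output: axes plus one record per combination."""

    sigmas: np.ndarray
    deltas: np.ndarray
    dts: np.ndarray
    hs: np.ndarray
    mode: str
    rule: str
    cells: list[SweepCell] = field(default_factory=list)

    def cell(self, sigma, delta, dt, h) -> SweepCell:
        for c in self.cells:
            if (np.isclose(c.sigma, sigma) and np.isclose(c.delta, delta)
                    and np.isclose(c.dt, dt) and c.h == h):
                return c
        raise KeyError(f"no cell for sigma={sigma}, delta={delta}, "
                       f"dt={dt}, h={h}")

    def to_frame(self):
        """Tidy DataFrame, one row per cell."""
        import pandas as pd

        rows = []
        for c in self.cells:
            rows.append({"sigma": c.sigma, "delta": c.delta, "dt": c.dt,
                         "h": c.h, "n_attempted": c.n_attempted,
                         "n_predicted": c.n_predicted,
                         "success_rate": success_rate(c),
                         "r2_identity": c.r2_identity,
                         "pearson_r": c.pearson_r})
        return pd.DataFrame(rows)


def _detect_one(err_smoothed, rule: str, delta: float):
    if rule == "abs":
        return detect_absolute(err_smoothed, delta)
    return detect_relative(err_smoothed, delta)


def run_sweep(sigmas=DEFAULT_SIGMAS, deltas=DEFAULT_DELTAS,
              dts=DEFAULT_DTS, hs=DEFAULT_HS, *, n_series: int = 100,
              base_seed: int = 0, mode: str = "monitoring",
              rule: str = "rel", params: ADParams | None = None,
              theta: float = 5.0, t_max: float = 200.0,
              sim_dt: float = 0.01, window: int = 10) -> SweepResult:
    """Full factorial sweep over (sigma, delta, Delta t, h).

    Per noise level, one batch of ``n_series`` seeded series is generated
    once and reused across every (Delta t, h, delta) cell; forecasts are
    computed once per (Delta t, h) and reused across thresholds.  Control
    mode draws one additional designated control series per noise level
    (h does not affect its whole-series library).  Cells with fewer than
    two predictions carry ``None`` scores rather than aborting the sweep.
    """
    if mode not in ("monitoring", "control"):
        raise ValueError(f"unknown mode {mode!r}")
    if rule not in ("abs", "rel"):
        raise ValueError(f"unknown rule {rule!r}")
    if n_series < 2:
        raise ValueError("n_series must be >= 2")
    params = params or ADParams.default()
    s1_star = dimensional_equilibrium(params)[0][0]
    result = SweepResult(sigmas=np.asarray(sigmas, dtype=float),
                         deltas=np.asarray(deltas, dtype=float),
                         dts=np.asarray(dts, dtype=float),
                         hs=np.asarray(hs, dtype=int), mode=mode, rule=rule)
    ss = np.random.SeedSequence(base_seed)
    sigma_seeds = ss.spawn(len(result.sigmas))
    for sigma, sig_ss in zip(result.sigmas, sigma_seeds):
        noise = NoiseModel(sigma=float(sigma), dt=sim_dt)
        batch_ss, control_ss = sig_ss.spawn(2)
        records = generate_ensemble(params, noise, n_series, t_max, batch_ss)
        control_full = None
        if mode == "control":
            rng = np.random.default_rng(control_ss)
            control_full = simulate_stochastic(
                params, noise, random_init(rng), t_max, rng)
        delta_eq = default_delta_eq(float(sigma))
        for dt in result.dts:
            working = [subsample(r["series"], float(dt)) for r in records]
            truths = [ground_truth_end_time(w, s1_star, delta_eq) for w in working]
            control_ts = (subsample(control_full, float(dt))
                          if control_full is not None else None)
            for h in result.hs:
                cfg = SmapConfig(theta=theta, h=int(h))
                curves = []
                for w in working:
                    if mode == "monitoring":
                        fc = monitoring_forecasts(w, cfg)
                    else:
                        fc = control_forecasts(control_ts, w, cfg)
                    err = (absolute_error_curve(fc) if rule == "abs"
                           else relative_error_curve(fc))
                    curves.append(smooth(err, window=window))
                for delta in result.deltas:
                    pred, tru = [], []
                    n_predicted = 0
                    for curve, gt in zip(curves, truths):
                        det = _detect_one(curve, rule, float(delta))
                        if det.predicted:
                            n_predicted += 1
                            if gt is not None:
                                pred.append(det.t_pred)
                                tru.append(gt.t_end)
                    pred = np.asarray(pred)
                    tru = np.asarray(tru)
                    r2 = pr = None
                    if len(pred) >= 2:
                        try:
                            r2 = r2_identity(pred, tru)
                        except UndefinedScoreError:
                            pass
                        try:
                            pr = pearson_corr(pred, tru)
                        except UndefinedScoreError:
                            pass
                    result.cells.append(SweepCell(
                        sigma=float(sigma), delta=float(delta),
                        dt=float(dt), h=int(h), n_attempted=n_series,
                        n_predicted=n_predicted, predicted=pred, truth=tru,
                        r2_identity=r2, pearson_r=pr))
    return result


def plot_sweep(result: SweepResult, metric: str = "r2_identity",
               dt=None, h=None, ax=None):
    """Heat map of one sweep panel (fixed Delta t and h): sigma vs delta.

    ``metric`` is a SweepCell attribute name or ``"success_rate"``.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    dt = float(dt if dt is not None else result.dts[0])
    h = int(h if h is not None else result.hs[0])
    grid = np.full((len(result.sigmas), len(result.deltas)), np.nan)
    for i, sigma in enumerate(result.sigmas):
        for j, delta in enumerate(result.deltas):
            c = result.cell(sigma, delta, dt, h)
            val = (success_rate(c) if metric == "success_rate"
                   else getattr(c, metric))
            if val is not None:
                grid[i, j] = val
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(grid, origin="lower", aspect="auto")
    ax.set_xlabel("threshold index")
    ax.set_ylabel("noise-level index")
    ax.set_title(f"{metric} (dt={dt}, h={h}, {result.mode}/{result.rule})")
    ax.figure.colorbar(im, ax=ax)
    return ax
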