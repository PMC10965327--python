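# transientad

Model-free prediction of when a noisy multivariate time series leaves a
transient state, demonstrated on a two-guild anaerobic-digestion (AD)
chemostat.

Bioreactors and many other ecological systems spend operationally
relevant stretches of time far from equilibrium: substrate overshoots,
crashes, and only then settles into fluctuation around a steady state.
Operators deciding when to intervene need to know whether the system is
still in that transient excursion — from data alone, without fitting a
mechanistic model.  `transientad` provides:

* **a mechanistic generator** — a four-state AD chemostat (substrate S1,
  volatile fatty acids S2, acidogens X1, methanogens X2 with Monod
  kinetics) in dimensional and non-dimensional form, plus a stochastic
  analogue with truncated multiplicative noise that yields strictly
  non-negative, reproducible synthetic series with a knowable
  ground-truth transient end time;
* **fast–slow analysis** of the non-dimensional model: critical
  manifold, fast-subsystem equilibrium u* = σ₁/(1−σ₁),
  v* = α/(βy−α), x* = α/(βσ₁) and its stability, and the closed-form
  stage boundaries τ₁ = (u_tol − u₀)/α, τ₂ = ln(α/(βx₀)) + τ₁ of the
  three-stage transient;
* **an S-map forecaster** (locally weighted global linear map with
  weights wᵢ = exp(−θ‖D(tᵢ) − q‖/d̄)) in monitoring mode (trailing
  library of h points) and control mode (one fully observed reference
  series);
* **transient-end detectors** on the smoothed forecast-error curves:
  an absolute-error floor rule (error < δ_a ⇒ the attractor has been
  reached) and a relative-error spike rule (first local maximum > δ_r ⇒
  the trajectory is breaking away from the transient pseudo-attractor);
* **an evaluation harness** scoring predicted against true end times
  with identity-line R² and Pearson r over factorial sweeps of noise
  level, threshold, sampling interval and library size.

See `docs/methods.md` for the model equations, numerical choices and
known limitations.

## Worked example

```python
import numpy as np
from transientad import (ADParams, NoiseModel, SmapConfig,
                         dimensional_equilibrium, detect_absolute,
                         absolute_error_curve, ground_truth_end_time,
                         monitoring_forecasts, random_init,
                         simulate_stochastic, smooth, subsample)

params = ADParams.default()
eq, washout = dimensional_equilibrium(params)
print(f"S1* = {eq[0]:.4f} g/l  (methanogen washout: {washout})")

rng = np.random.default_rng(42)
series = simulate_stochastic(params, NoiseModel(sigma=0.1),
                             random_init(rng), t_max=200.0, seed=rng)
working = subsample(series, 0.1)            # 0.1 d working grid
truth = ground_truth_end_time(working, eq[0], delta_eq=0.25)
print(f"ground-truth transient end: t_end = {truth.t_end:.1f} d")

fc = monitoring_forecasts(working, SmapConfig(theta=5.0, h=20))
curve = smooth(absolute_error_curve(fc))
det = detect_absolute(curve, delta_a=0.5)
print(f"absolute-rule prediction:   t_pred = {det.t_pred:.1f} d")
```

prints

```
S1* = 4.4928 g/l  (methanogen washout: True)
ground-truth transient end: t_end = 14.3 d
absolute-rule prediction:   t_pred = 12.3 d
```

Reading the numbers: at this parameter set the methanogens cannot grow
fast enough to survive dilution, so the equilibrium has X2 = 0 and the
substrate settles at S1* ≈ 4.49 g l⁻¹.  The seeded stochastic run
overshoots to S1 in the hundreds before crashing back; it first re-enters
the ±0.25 band around S1* on the way down at t = 14.3 d.  Forecasting
the series one step at a time from its own trailing 20 points, the
smoothed absolute forecast error stays high through the excursion and
first drops below δ_a = 0.5 at t = 12.3 d — a detection two days ahead
of the ground truth, from data alone.

The same machinery is scriptable from the shell:

```sh
transientad generate --n 10 --sigma 0.1 --tmax 200 --seed 42 --outdir runs/demo
transientad forecast --series runs/demo/series_0000.csv --delta-t 0.1 \
    --h 20 --out runs/demo/fc.csv
transientad detect --forecasts runs/demo/fc.csv --rule abs --delta 0.5
transientad pipeline --outdir runs/pipe          # end-to-end with defaults
transientad sweep --out runs/sweep.csv           # scaled factorial sweep
```

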