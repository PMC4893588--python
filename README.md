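# greycast

Short-horizon blood glucose forecasting for continuous glucose
monitoring (CGM) traces with the log-smoothed grey GM(1,1) model.

CGM devices report interstitial glucose every 5 minutes. Predicting the
next 5–30 minutes from a short recent history lets patients and
clinicians act before a postprandial spike or a hypoglycaemic dip
develops. Long-history methods (AR with long windows, neural networks,
SVMs) need more data than a single meal excursion provides; the grey
GM(1,1) model is designed for exactly this small-sample regime.

`greycast` is for researchers and engineers evaluating short-horizon
glucose predictors: it provides the model, the grey-systems
model-acceptance diagnostics, clinical and statistical scoring (Clarke
Error Grid, MSE, MAE), a persistence and an AR baseline, a
rolling-origin experiment engine, and a synthetic CGM generator for
reproducible benchmarks.

## The model

Given a positive glucose window x(1..n) (mmol/L), the improved model
works on y(i) = ln x(i) — logging flattens near-exponential postprandial
rises, improving the smoothness the grey machinery relies on. The
first-order accumulation y1(k) = Σ_{i≤k} y(i) is assumed to follow the
whitening equation

    dy1/dt + a·y1 = b,

whose discrete counterpart y(k) + a·z1(k) = b, with background values
z1(k) = (y1(k) + y1(k−1))/2, is solved for (a, b) by least squares.
a is the *development coefficient* (a < 0 ⇒ growth) and b the *grey
control*. The time response

    ŷ1(i) = (y(1) − b/a)·e^(−a(i−1)) + b/a

is differenced back to ŷ(i) and exponentiated to glucose. Indices i ≤ n
give fitted values; i > n gives forecasts, always positive in the log
domain. The textbook GM(1,1) on raw glucose (`domain="identity"`) is
included for comparison.

Before a fit is trusted it passes three grey-systems gates: relative
error accuracy p° = (1 − mean ε)·100 > 80%, the posterior deviation test
(variance ratio C = S2/S1 with the four-level superior/qualified/
marginal/disqualified grade), and the grey relational degree ξ > 0.6.

## Worked example

```python
import numpy as np
from greycast import (RollingConfig, clarke_ega, fit_gm11, generate_day72h,
                      generate_postprandial, rolling_predict, run_diagnostics)

# a 2-h postprandial window: 24 samples, rise from ~6 toward ~13.5 mmol/L
pp = generate_postprandial(n=24, seed=7, noise_sd=0.05)
window = pp.window(1, 18)
fit = fit_gm11(window, domain="log")
print(f"a = {fit.params.a:+.4f}  b = {fit.params.b:+.4f}")
report = run_diagnostics(window.values[1:], fit.fitted_glucose)
print(f"p_deg = {report.relative.accuracy:.2f}%  C = {report.posterior.c_ratio:.3f}  "
      f"p = {report.posterior.posterior_p:.3f}  xi = {report.relational.degree:.3f}")

# rolling 5..30-min-ahead forecasting over a seeded 72-h trace
trace = generate_day72h(seed=123)
result = rolling_predict(trace, RollingConfig())
for h, m in sorted(result.per_horizon.items()):
    print(f"h={h} ({5*h:>2d} min): MSE {m.mse:.4f}  MAE {m.mae:.4f}")
actual, pred = result.scored_pairs()
print("zone A:", round(clarke_ega(actual, pred).percentages["A"], 2), "%")
```

prints

```
a = -0.0147  b = +2.0517
p_deg = 94.43%  C = 0.361  p = 0.941  xi = 0.646
h=1 ( 5 min): MSE 0.3395  MAE 0.3663
h=2 (10 min): MSE 0.5702  MAE 0.4674
h=3 (15 min): MSE 0.8807  MAE 0.5729
h=4 (20 min): MSE 1.2821  MAE 0.6826
h=5 (25 min): MSE 1.7864  MAE 0.7988
h=6 (30 min): MSE 2.4058  MAE 0.9209
zone A: 92.89 %
```

The negative development coefficient identifies the rising postprandial
regime; the diagnostics grade the 18-sample fit as acceptable
(p° > 80%, qualified, ξ > 0.6). Over the 72-hour trace the error grows
with horizon, as it must for an honest forecaster — mean absolute error
roughly 0.37 mmol/L five minutes ahead and 0.92 mmol/L half an hour
ahead — and ~93% of the 5-min-ahead through 30-min-ahead predictions
fall in Clarke zone A (clinically benign).

The same pipeline is scriptable from the shell:

```sh
greycast simulate --mode day72h --seed 123 -o trace.csv
greycast roll trace.csv --window 18 --horizons 1-6 --summary summary.json -o roll.csv
greycast fit trace.csv --window 18
```

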