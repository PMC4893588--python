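# Methods

## Model

The forecaster is a grey GM(1,1) — "grey model, first-order differential,
one variable" — applied to log-transformed glucose. The modelling chain
for a fitting window x(1..n), x(i) > 0 in mmol/L:

1. **Transform.** y(i) = ln x(i) (`domain="log"`), or y = x for the
   plain variant (`domain="identity"`). The log step is the improvement:
   postprandial glucose rises roughly exponentially over the 2-h
   post-meal window, so its log is near-linear and the sequence's
   smoothness (the ratio of each value to the accumulated history)
   improves, which is the regime in which GM(1,1) is accurate.
2. **Accumulate (1-AGO).** y1(k) = Σ_{i≤k} y(i). Accumulation turns a
   noisy short series into a near-monotone one obeying, by assumption,
   the whitening equation dy1/dt + a·y1 = b.
3. **Estimate.** The discrete grey equation y(k) + a·z1(k) = b with
   trapezoid background z1(k) = (y1(k)+y1(k−1))/2, k = 2..n, is solved
   for (a, b) by ordinary least squares (2×2 normal equations).
4. **Respond, difference, invert.** ŷ1(i) = (y(1) − b/a)e^(−a(i−1)) + b/a;
   increments ŷ(i) = ŷ1(i) − ŷ1(i−1), equivalently the closed form
   (1 − e^a)(y(1) − b/a)e^(−a(i−1)); glucose x̂(i) = e^(ŷ(i)) (log
   domain) or ŷ(i) (identity domain). i = 2..n are fitted values
   (the first sample is the exact initial condition and is never
   fitted); i > n are forecasts.

Assumptions worth stating: the window is short (default 18 samples =
90 min) and locally exponential-trended; values are strictly positive;
one model is fit per window, so regime changes are handled by refitting,
not by the model itself. Log-domain forecasts are positive by
construction; identity-domain forecasts are not, and a non-positive
prediction sets a flag rather than raising (the model is declared
inadequate, the number preserved for inspection).

## Model-acceptance diagnostics

Three standard grey-systems gates are computed on the fitted window
(points 2..n, residuals in mmol/L):

- **Relative error**: ε(i) = |x − x̂|/x, accuracy p° = (1 − ε̄)·100,
  gate p° > 80%.
- **Posterior deviation**: C = S2/S1, the ratio of population standard
  deviations of residuals and data, and p = fraction of centred
  residuals within 0.6745·S1. Grade: superior (p > 0.95 ∧ C < 0.35),
  qualified (p > 0.80 ∧ C < 0.50), marginal (p > 0.70 ∧ C < 0.65), else
  disqualified — the worse of the two indicator levels, the conventional
  grey-forecasting table. A constant window makes C undefined
  (S1 = 0) and raises; the rolling engine then accepts the origin only
  if the fit reproduces the constant.
- **Grey relational degree**: with deviations Δᵢ and resolution ratio
  ρ = 0.5, ξᵢ = (Δmin + ρΔmax)/(Δᵢ + ρΔmax) ∈ [ρ/(1+ρ), 1], degree
  ξ = mean ξᵢ, gate ξ > 0.6. Δmax = 0 (perfect fit) is defined as
  ξᵢ = 1 by the continuity limit.

A practical note on ξ: the degree is scale-free in the deviations. When
a model is *correctly specified* and deviations are i.i.d. noise, ξ
concentrates near 2/3 regardless of how small the noise is; values
above ~0.9 arise only when deviations are bias-dominated and therefore
nearly uniform across points. High ξ on real data thus signals smooth,
systematic misfit rather than accuracy, and a well-specified fit on
noisy data should not be expected to exceed it.

## Evaluation

MSE ((mmol/L)²) and MAE (mmol/L) use the plain mean over pairs. The
Clarke Error Grid is evaluated in mg/dL with the conventional clinical
conversion 18.0 exactly; the zone rule table (A through E, precedence
A → E → C → D → B, all boundary inequalities inclusive) is stated in
`clarke_zone`'s docstring so classification is deterministic and
testable against an independent implementation.

## Numerical choices

- **Degenerate development coefficient.** |a| < 1e−10 switches to the
  a → 0 limit: linear accumulated response, constant increments b.
  Constant glucose (a legitimate stable regime) flows through this path
  and is reproduced exactly.
- **Least squares.** The 2×2 normal equations are solved directly; a
  condition number above 1e12 falls back to a rank-revealing `lstsq`
  and flags the fit. The problem is tiny; a guard, not QR, is all the
  robustness it needs.
- **Discretization gap.** For data whose transformed increments are
  exactly geometric with ratio q, the least-squares estimate is
  â = −2(q−1)/(q+1), the (1,1)-Padé approximant of −ln q — the grey
  difference equation is then satisfied exactly, but the continuous-time
  response forecasts with a relative drift of order |ln q|³/12 per step.
  At CGM-scale coefficients (|a| ≈ 0.01–0.05) this is ~1e−4 relative
  over a 24-sample window: invisible next to sensor noise, but the
  reason "refit then forecast" cannot reproduce even noise-free
  model-generated data to machine precision. Generator/model consistency
  is therefore checked by forecasting from the generating parameters.
- **Increment forms.** The differencing and closed forms agree
  algebraically; the differencing route loses precision to cancellation
  in b/a as a → 0, so equivalence is asserted at 1e−12 absolute over the
  CGM-realistic coefficient range and with a relative tolerance over
  wider property-test draws.
- **Indexing.** All public indices are 1-based, matching grey-systems
  notation; storage is 0-based internally.

## Rolling experiments

`rolling_predict` slides an 18-sample window along the trace, refits at
every origin (the "correct with real values as they arrive" mode; a
single grey fit extrapolated hundreds of steps diverges exponentially
and is available only as `refit_every_step=False` for demonstration),
forecasts horizons 1..6 (5–30 min), gates each origin on the
diagnostics (`warn` records the failure and predicts anyway;
`fallback_naive` substitutes persistence), and scores per horizon and
per labelled stage. `static_predict` keeps the one-shot protocol: fit
the first 18 samples, forecast 6, score against the held-out tail.

## Synthetic data

Hospital CGM exports are not shareable, so benchmarks run on generated
traces:

- `exact_grey` — data produced by the model's own time response
  (defaults a = −0.012, b = 1.9165, y0 = ln 7: a rise from 7 to
  ≈12.7 mmol/L over 24 samples, the postprandial range seen in type 2
  diabetes), optionally with additive Gaussian sensor noise. These are
  oracle fixtures: recovery is a correctness check, not evidence about
  real data.
- `postprandial` — 24 samples at 5-min cadence: baseline 6 mmol/L plus
  a saturating-exponential excursion of amplitude 8 (rate 0.12/step,
  ~90% of the rise within 2 h) plus AR(1) noise (σ = 0.05 mmol/L,
  φ = 0.5, mimicking CGM sensor autocorrelation).
- `day72h` — 864 samples/72 h: baseline 6, three meals per day (08:00,
  12:30, 18:00; amplitudes 5.5/6.5/6.0 mmol/L) each with a
  near-exponential 2-h rise (rate 0.10/step) and exponential return
  (τ = 2.5 h), a ±0.4 mmol/L circadian drift, and AR(1) noise
  (σ = 0.15 mmol/L). Values are clipped to the physiological band
  [2.0, 33.3] mmol/L.

What the generator does *not* emulate: insulin dynamics, exercise,
sensor dropouts and recalibration jumps, meal-size variability, or
inter-patient heterogeneity. Passing tests on these traces shows the
pipeline is correct and behaves sensibly under the structure the model
assumes; it does not certify clinical accuracy on real patients.

## Problem sizes

The test suite and the acceptance script run everything at the scale the
method targets: 18-sample fits with 6-step forecasts, 100-series oracle
sweeps, 1000-draw equivalence sweeps, a 10,000-pair Clarke grid,
200-replicate noise corridors, and full rolling runs over one 864-sample
trace per model. Each completes in seconds.

## Known limitations

- The grey model overshoots once a rise saturates (it is a homogeneous
  exponential; a plateau has no representation), which is visible in the
  one-shot 2-h protocol on saturating synthetic windows and is the
  reason rolling refit is the default.
- At horizon 1 on gently curved segments the plain model can match or
  beat the log model; the log model's advantage concentrates where
  glucose rises near-exponentially.
- The AR baseline is deliberately minimal (OLS, iterated forecasting,
  default order 3) — a pipeline comparator, not a tuned competitor.
- No physiological model underlies the generator; conclusions about
  clinical performance require real CGM data.
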