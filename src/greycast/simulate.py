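"""Synthetic CGM trace generator.

Hospital CGM exports are rarely shareable, so the package carries a
generator that reproduces the statistical structure the grey model
assumes, at three levels of realism:

* ``exact_grey`` — sequences generated by the grey time response itself
  (optionally with additive Gaussian sensor noise).  These are the
  oracle fixtures: with zero noise the model must recover them exactly.
* ``postprandial`` — a 2-hour post-meal window (24 samples at 5-minute
  cadence by default): a saturating-exponential rise from a fasting
  baseline toward a post-meal plateau, plus AR(1)-correlated sensor
  noise.  Mirrors the 18-sample-fit / 6-step-forecast protocol.
* ``day72h`` — a 72-hour trace (864 samples): baseline, three meal
  excursions per day with fast rise and slow decay, a slow circadian
  drift, and AR(1) noise.

All values are clipped to the physiological band [2.0, 33.3] mmol/L so
logs stay well behaved.  The AR(1) noise (lag-1 correlation 0.5 by
default) mimics the autocorrelation of CGM sensor error; true
glucose-insulin dynamics (Bergman-style models) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidConfigError
from .series import GlucoseSeries

#: Physiological clipping band, mmol/L.
GLUCOSE_FLOOR = 2.0
GLUCOSE_CEILING = 33.3

#: Samples per 24 h at 5-minute cadence.
STEPS_PER_DAY = 288


@dataclass(frozen=True)
class MealParams:
    """Shape parameters of a postprandial excursion.

    ``baseline`` is the pre-meal glucose (mmol/L), ``amplitude`` the
    asymptotic rise above baseline, ``rise_rate`` the per-step (5-min)
    exponential rate of approach to the plateau, ``decay_rate`` the
    per-step rate of the post-peak return toward baseline (72-h mode
    only), and ``meal_times`` the 0-based sample indices of meals within
    a day (72-h mode only; defaults to 08:00, 12:30 and 18:00).
    """

    baseline: float = 6.0
    amplitude: float = 8.0
    rise_rate: float = 0.12
    decay_rate: float = 0.04
    meal_times: Tuple[int, ...] = (96, 150, 216)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for :func:`generate`."""

    mode: str = "postprandial"  # exact_grey | postprandial | day72h
    n_samples: Optional[int] = None
    seed: int = 0
    noise_sd: float = 0.05
    noise_phi: float = 0.5
    grey_params: Tuple[float, float, float] = (-0.012, 1.9165, float(np.log(7.0)))
    meal_params: MealParams = field(default_factory=MealParams)

    def __post_init__(self) -> None:
        if self.mode not in ("exact_grey", "postprandial", "day72h"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.n_samples is not None and self.n_samples < 4:
            raise InvalidConfigError("n_samples must be >= 4")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if not 0 <= self.noise_phi < 1:
            raise InvalidConfigError("noise_phi must lie in [0, 1)")


def _ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    w = rng.normal(0.0, sd, size=n)
    if phi == 0.0:
        return w
    e = np.empty(n)
    e[0] = w[0]
    innov_scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov_scale * w[t]
    return e


def _clip(values: np.ndarray) -> np.ndarray:
    return np.clip(values, GLUCOSE_FLOOR, GLUCOSE_CEILING)


def generate_exact_grey(
    n: int = 24,
    a: float = -0.012,
    b: float = 1.9165,
    y0: float = float(np.log(7.0)),
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_interval: float = 5.0,
) -> GlucoseSeries:
    """Generate glucose exactly from the grey time response.

    The accumulated log-glucose follows
    ``y1(i) = (y0 - b/a) * exp(-a*(i-1)) + b/a`` (linear when ``a = 0``);
    its increments are exponentiated to glucose.  The defaults give a
    postprandial-like rise from 7 to roughly 15 mmol/L over 24 samples.
    Gaussian noise, when requested, is added after exponentiation and
    the result clipped to the physiological band.
    """
    if n < 4:
        raise InvalidConfigError("n must be >= 4")
    i = np.arange(1, n + 1, dtype=float)
    if abs(a) < 1e-15:
        y1 = y0 + b * (i - 1)
    else:
        ba = b / a
        y1 = (y0 - ba) * np.exp(-a * (i - 1)) + ba
    y0_seq = np.empty(n)
    y0_seq[0] = y0
    y0_seq[1:] = np.diff(y1)
    glucose = np.exp(y0_seq)
    if not np.all(np.isfinite(glucose)) or np.any(glucose <= 0):
        raise InvalidConfigError("grey parameters yield non-positive glucose")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        glucose = _clip(glucose + rng.normal(0.0, noise_sd, size=n))
    return GlucoseSeries(glucose, sample_interval=sample_interval)


def generate_postprandial(
    n: int = 24,
    baseline: float = 6.0,
    amplitude: float = 8.0,
    rise_rate: float = 0.12,
    noise_sd: float = 0.05,
    noise_phi: float = 0.5,
    seed: int = 0,
    sample_interval: float = 5.0,
) -> GlucoseSeries:
    """2-hour post-meal window: saturating rise plus AR(1) sensor noise.

    The deterministic component is
    ``baseline + amplitude * (1 - exp(-rise_rate * t))`` with ``t`` in
    samples since the meal; the defaults rise from 6 toward ~13.5 mmol/L
    over two hours, the range typical of a type 2 diabetes postprandial
    excursion.
    """
    if baseline <= 0 or amplitude < 0 or rise_rate < 0:
        raise InvalidConfigError("baseline must be > 0, amplitude and rise_rate >= 0")
    t = np.arange(n, dtype=float)
    mean = baseline + amplitude * (1.0 - np.exp(-rise_rate * t))
    rng = np.random.default_rng(seed)
    noise = _ar1_noise(n, noise_sd, noise_phi, rng)
    return GlucoseSeries(_clip(mean + noise), sample_interval=sample_interval)


def generate_day72h(
    n: int = 864,
    baseline: float = 6.0,
    meal_times: Sequence[int] = (96, 150, 216),
    meal_amplitudes: Sequence[float] = (5.5, 6.5, 6.0),
    rise_width: int = 24,
    rise_rate: float = 0.10,
    decay_tau: float = 30.0,
    circadian_amplitude: float = 0.4,
    noise_sd: float = 0.15,
    noise_phi: float = 0.5,
    seed: int = 0,
    sample_interval: float = 5.0,
) -> GlucoseSeries:
    """72-hour trace: daily meal excursions, circadian drift, AR(1) noise.

    Each meal adds a pulse with a near-exponential 2-hour rise — the
    postprandial regime the grey model targets — followed by an
    exponential return to baseline: for ``s`` samples since the meal,

        A * (exp(rise_rate*s) - 1) / (exp(rise_rate*rise_width) - 1)

    while ``s <= rise_width``, then ``A * exp(-(s - rise_width)/decay_tau)``.
    Meal times are 0-based sample offsets within a 288-sample day
    (defaults: 08:00, 12:30, 18:00).
    """
    meal_times = tuple(int(m) for m in meal_times)
    if len(meal_times) != len(meal_amplitudes):
        raise InvalidConfigError("meal_times and meal_amplitudes must align")
    if any(not 0 <= m < STEPS_PER_DAY for m in meal_times):
        raise InvalidConfigError(
            f"meal times must be sample offsets in [0, {STEPS_PER_DAY})"
        )
    if baseline <= 0 or rise_width < 1 or rise_rate <= 0 or decay_tau <= 0:
        raise InvalidConfigError(
            "baseline, rise_width, rise_rate and decay_tau must be positive"
        )
    t = np.arange(n, dtype=float)
    mean = np.full(n, float(baseline))
    mean += circadian_amplitude * np.sin(2.0 * np.pi * (t - 60.0) / STEPS_PER_DAY)
    n_days = int(np.ceil(n / STEPS_PER_DAY))
    norm = np.exp(rise_rate * rise_width) - 1.0
    for day in range(n_days):
        for m, amp in zip(meal_times, meal_amplitudes):
            s = t - (day * STEPS_PER_DAY + m)
            pulse = np.zeros(n)
            rising = (s > 0) & (s <= rise_width)
            pulse[rising] = amp * (np.exp(rise_rate * s[rising]) - 1.0) / norm
            decaying = s > rise_width
            pulse[decaying] = amp * np.exp(-(s[decaying] - rise_width) / decay_tau)
            mean += pulse
    rng = np.random.default_rng(seed)
    noise = _ar1_noise(n, noise_sd, noise_phi, rng)
    return GlucoseSeries(_clip(mean + noise), sample_interval=sample_interval)


def day72h_rise_stages(
    n: int = 864,
    meal_times: Sequence[int] = (96, 150, 216),
    rise_width: int = 24,
):
    """Labelled 1-based sample ranges of the rise phase of every meal in a
    :func:`generate_day72h` trace — the "rising segments" used for
    stage-restricted error summaries.

    A meal at 0-based offset ``m`` of day ``d`` rises over 0-based samples
    ``d*288 + m + 1 .. d*288 + m + rise_width``; 1-based ranges shift by
    one.
    """
    stages = {}
    n_days = int(np.ceil(n / STEPS_PER_DAY))
    for day in range(n_days):
        for k, m in enumerate(meal_times):
            t0 = day * STEPS_PER_DAY + int(m)
            start, stop = t0 + 2, t0 + rise_width + 1
            if start <= n:
                stages[f"day{day + 1}_meal{k + 1}_rise"] = (start, min(stop, n))
    return stages


def generate(config: SynthConfig) -> GlucoseSeries:
    """Dispatch on ``config.mode``."""
    if config.mode == "exact_grey":
        a, b, y0 = config.grey_params
        return generate_exact_grey(
            n=config.n_samples or 24,
            a=a,
            b=b,
            y0=y0,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
    mp = config.meal_params
    if config.mode == "postprandial":
        return generate_postprandial(
            n=config.n_samples or 24,
            baseline=mp.baseline,
            amplitude=mp.amplitude,
            rise_rate=mp.rise_rate,
            noise_sd=config.noise_sd,
            noise_phi=config.noise_phi,
            seed=config.seed,
        )
    return generate_day72h(
        n=config.n_samples or 864,
        baseline=mp.baseline,
        meal_times=mp.meal_times,
        noise_sd=config.noise_sd,
        noise_phi=config.noise_phi,
        seed=config.seed,
    )
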