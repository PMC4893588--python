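"""Grey GM(1,1) model core: transform, accumulation, fit, forecast.

The GM(1,1) ("grey model, one variable, first order") treats a short
positive time series as samples from the whitening differential equation

    dy1/dt + a*y1(t) = b,

where ``y1`` is the first-order accumulated (running-sum) series.  ``a``
is the *development coefficient* (negative ``a`` means growth) and ``b``
the *grey control* (constant forcing).  The parameters are estimated by
least squares on the grey difference equation

    y0(k) + a*z1(k) = b,        k = 2..n,

with background values ``z1(k) = (y1(k) + y1(k-1)) / 2``.  The time
response of the whitening equation, differenced back and inverse
transformed, yields fitted values and forecasts.

Two variants are provided through the ``domain`` flag:

* ``"log"`` — the improved, log-smoothed model: the grey machinery runs
  on ``y = ln(x)``, and predictions are exponentiated back to glucose
  units.  Logging flattens near-exponential postprandial excursions into
  near-linear sequences, which the homogeneous-exponential GM(1,1)
  tracks far better.  Forecasts are positive by construction.
* ``"identity"`` — the textbook GM(1,1) on raw glucose, kept for
  comparison.  Its forecasts are not sign-protected; non-positive
  predictions are flagged rather than raised.

All sample indices in this module are 1-based, matching the standard
grey-systems notation; the first sample is the exact initial condition
and is never fitted, so fitted values and residuals cover ``i = 2..n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .errors import InvalidInputError
from .series import MIN_FIT_LENGTH, ArrayLike, GlucoseSeries

Domain = Literal["log", "identity"]

#: |a| below this uses the a -> 0 limit (linear accumulated response).
DEGENERATE_A_TOL = 1e-10

#: Condition number of the 2x2 normal matrix above which a fit is flagged
#: as numerically degenerate.
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class TransformedSeries:
    """The working sequence y0: log-glucose (``domain="log"``) or raw
    glucose (``domain="identity"``)."""

    values: np.ndarray
    domain: Domain


@dataclass(frozen=True)
class AccumulatedSeries:
    """1-AGO running sums ``y1`` and background midpoints ``z1``.

    ``values[k-1]`` is ``y1(k)``; ``background[k-2]`` is ``z1(k)`` for
    ``k = 2..n``.
    """

    values: np.ndarray
    background: np.ndarray


@dataclass(frozen=True)
class GreyParameters:
    """Estimated development coefficient ``a`` and grey control ``b``."""

    a: float
    b: float


@dataclass
class GreyFit:
    """A fitted GM(1,1) model.

    Attributes
    ----------
    params : GreyParameters
    domain : {"log", "identity"}
    y0_initial : float
        The transformed first sample y0(1), the exact initial condition.
    n_fit : int
        Length of the fitting window.
    fitted_glucose : ndarray
        Fitted values in mmol/L for samples ``i = 2..n_fit``.
    residuals : ndarray
        ``x(i) - x_hat(i)`` in mmol/L, same indexing as ``fitted_glucose``.
    degenerate_a : bool
        True when |a| < tolerance and the linear limit form is in use.
    condition_number : float
        Condition number of the normal matrix (diagnostic only).
    """

    params: GreyParameters
    domain: Domain
    y0_initial: float
    n_fit: int
    fitted_glucose: np.ndarray
    residuals: np.ndarray
    degenerate_a: bool
    condition_number: float


@dataclass(frozen=True)
class ForecastResult:
    """Out-of-window predictions for samples ``n_fit+1 .. n_fit+h``."""

    predictions: np.ndarray
    horizon_steps: int
    horizon_minutes: float
    nonpositive: bool = False


def log_transform(series: GlucoseSeries) -> TransformedSeries:
    """Natural log of the glucose trace, ``y0(i) = ln x(i)``.

    Values in (0, 1) mmol/L log to negative numbers; that is valid
    arithmetic but physiologically implausible, so it draws a warning.
    """
    x = series.values
    if np.any(x < 1.0):
        warnings.warn(
            "glucose values below 1 mmol/L produce negative logs; "
            "check units (mg/dL input?)",
            stacklevel=2,
        )
    return TransformedSeries(values=np.log(x), domain="log")


def identity_transform(series: GlucoseSeries) -> TransformedSeries:
    """Pass-through transform for the plain (raw-glucose) GM(1,1)."""
    return TransformedSeries(values=series.values.copy(), domain="identity")


def ago_accumulate(ts: TransformedSeries) -> AccumulatedSeries:
    """First-order accumulated generating operation (1-AGO).

    Returns the running sums ``y1(k) = sum_{i<=k} y0(i)`` together with
    the background midpoints ``z1(k) = (y1(k) + y1(k-1)) / 2`` for
    ``k = 2..n``.  First-differencing ``values`` recovers the input
    exactly.
    """
    y0 = np.asarray(ts.values, dtype=float)
    if y0.size < 2:
        raise InvalidInputError("1-AGO needs at least 2 samples")
    y1 = np.cumsum(y0)
    z1 = 0.5 * (y1[1:] + y1[:-1])
    return AccumulatedSeries(values=y1, background=z1)


def fit_gm11(series: GlucoseSeries, domain: Domain = "log") -> GreyFit:
    """Fit a GM(1,1) model to a glucose window.

    Builds the least-squares system ``y0(k) = -a*z1(k) + b`` over
    ``k = 2..n`` in the transformed domain, solves the 2x2 normal
    equations, and evaluates fitted glucose values and residuals via the
    time response.

    Raises
    ------
    InvalidInputError
        If the window is shorter than 4 samples.
    """
    if domain not in ("log", "identity"):
        raise InvalidInputError(f"unknown domain {domain!r}")
    if len(series) < MIN_FIT_LENGTH:
        raise InvalidInputError(
            f"GM(1,1) fit needs at least {MIN_FIT_LENGTH} samples, got {len(series)}"
        )
    ts = log_transform(series) if domain == "log" else identity_transform(series)
    acc = ago_accumulate(ts)

    z = acc.background
    design = np.column_stack([-z, np.ones_like(z)])
    target = ts.values[1:]

    gram = design.T @ design
    cond = float(np.linalg.cond(gram))
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        # near-singular background: fall back to a rank-revealing solve
        sol, *_ = np.linalg.lstsq(design, target, rcond=None)
    else:
        sol = np.linalg.solve(gram, design.T @ target)
    a, b = float(sol[0]), float(sol[1])

    fit = GreyFit(
        params=GreyParameters(a=a, b=b),
        domain=domain,
        y0_initial=float(ts.values[0]),
        n_fit=len(series),
        fitted_glucose=np.empty(0),
        residuals=np.empty(0),
        degenerate_a=abs(a) < DEGENERATE_A_TOL,
        condition_number=cond,
    )
    idx = np.arange(2, len(series) + 1)
    y0_hat = restore_increments(fit, idx)
    fitted = np.exp(y0_hat) if domain == "log" else y0_hat
    fit.fitted_glucose = fitted
    fit.residuals = series.values[1:] - fitted
    return fit


def time_response(fit: GreyFit, i: Union[int, ArrayLike]) -> Union[float, np.ndarray]:
    """Accumulated-domain response ``y1_hat(i)``.

    Evaluates ``(y0(1) - b/a) * exp(-a*(i-1)) + b/a``; in the degenerate
    ``a -> 0`` limit the linear form ``y0(1) + b*(i-1)`` is used.
    ``i`` is 1-based and may be a scalar or an array; ``i = 1`` returns
    the initial condition exactly.
    """
    arr = np.asarray(i)
    if np.any(arr < 1):
        raise InvalidInputError("time response index must be >= 1")
    a, b = fit.params.a, fit.params.b
    if fit.degenerate_a:
        out = fit.y0_initial + b * (arr - 1)
    else:
        ba = b / a
        out = (fit.y0_initial - ba) * np.exp(-a * (arr - 1)) + ba
    return float(out) if np.isscalar(i) else np.asarray(out)


def restore_increments(
    fit: GreyFit,
    i: Union[int, ArrayLike],
    method: Literal["closed", "difference"] = "closed",
) -> Union[float, np.ndarray]:
    """Transformed-domain increment ``y0_hat(i) = y1_hat(i) - y1_hat(i-1)``.

    ``method="closed"`` evaluates the algebraically equivalent closed
    form ``(1 - e^a) * (y0(1) - b/a) * exp(-a*(i-1))``; the two routes
    agree to ~1e-12 and the differencing form is kept as a cross-check.
    In the degenerate ``a -> 0`` limit both reduce to the constant ``b``.
    """
    arr = np.asarray(i)
    if np.any(arr < 2):
        raise InvalidInputError("restored increments start at i = 2")
    a, b = fit.params.a, fit.params.b
    if fit.degenerate_a:
        out = np.broadcast_to(float(b), arr.shape).copy() if arr.ndim else b
        return float(b) if np.isscalar(i) else np.asarray(out, dtype=float)
    if method == "difference":
        out = time_response(fit, arr) - time_response(fit, arr - 1)
    elif method == "closed":
        out = (1.0 - np.exp(a)) * (fit.y0_initial - b / a) * np.exp(-a * (arr - 1))
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return float(out) if np.isscalar(i) else np.asarray(out)


def forecast(fit: GreyFit, h: int, sample_interval: float = 5.0) -> ForecastResult:
    """Predict ``h`` steps past the fitting window.

    For the log-domain model predictions are ``exp(y0_hat(i))`` and hence
    always positive.  The identity-domain model can emit non-positive
    values when inadequate for the data; that sets the ``nonpositive``
    flag and warns instead of raising.
    """
    if h < 1:
        raise InvalidInputError("forecast horizon must be >= 1 step")
    idx = np.arange(fit.n_fit + 1, fit.n_fit + h + 1)
    y0_hat = restore_increments(fit, idx)
    if fit.domain == "log":
        pred = np.exp(y0_hat)
        flag = False
    else:
        pred = np.asarray(y0_hat, dtype=float)
        flag = bool(np.any(pred <= 0))
        if flag:
            warnings.warn(
                "identity-domain GM(1,1) produced non-positive glucose "
                "predictions; the model is inadequate for this window",
                stacklevel=2,
            )
    return ForecastResult(
        predictions=pred,
        horizon_steps=h,
        horizon_minutes=h * sample_interval,
        nonpositive=flag,
    )
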