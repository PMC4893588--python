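"""Minimal autoregressive baseline forecaster.

A deliberately simple comparator for the grey model: ordinary least
squares of x(t) on an intercept and its last ``p`` lags, with iterated
one-step forecasting (predictions fed back as inputs).  No order
selection, no Yule-Walker/Burg refinements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import InvalidInputError
from .series import ArrayLike, GlucoseSeries


@dataclass(frozen=True)
class ARModel:
    """Least-squares AR(p) fit: x(t) = c + sum_j phi_j * x(t-j)."""

    order: int
    coefficients: np.ndarray  # phi_1 .. phi_p
    intercept: float
    fit_window: int


def _values(series: Union[GlucoseSeries, ArrayLike]) -> np.ndarray:
    if isinstance(series, GlucoseSeries):
        return series.values
    return np.asarray(series, dtype=float)


def fit_ar(series: Union[GlucoseSeries, ArrayLike], order: int = 3) -> ARModel:
    """OLS fit of an AR(p) with intercept.

    Needs at least ``2*order + 1`` samples so the design has more rows
    than parameters.
    """
    x = _values(series)
    if order < 1:
        raise InvalidInputError("AR order must be >= 1")
    if x.size < 2 * order + 1:
        raise InvalidInputError(
            f"AR({order}) fit needs at least {2 * order + 1} samples, got {x.size}"
        )
    # row t predicts x[t] from x[t-1] .. x[t-order]
    nrow = x.size - order
    design = np.ones((nrow, order + 1))
    for j in range(1, order + 1):
        design[:, j] = x[order - j : x.size - j]
    target = x[order:]
    sol, *_ = np.linalg.lstsq(design, target, rcond=None)
    return ARModel(
        order=order,
        coefficients=np.asarray(sol[1:], dtype=float),
        intercept=float(sol[0]),
        fit_window=int(x.size),
    )


def forecast_ar(
    model: ARModel, history: Union[GlucoseSeries, ArrayLike], h: int
) -> np.ndarray:
    """Iterated multi-step forecast: each prediction becomes an input."""
    x = _values(history)
    if h < 1:
        raise InvalidInputError("forecast horizon must be >= 1 step")
    if x.size < model.order:
        raise InvalidInputError(
            f"history of length {x.size} shorter than AR order {model.order}"
        )
    buf = list(x[-model.order :])
    out = np.empty(h)
    for k in range(h):
        lags = buf[::-1]  # most recent first, matching phi_1 .. phi_p
        out[k] = model.intercept + float(np.dot(model.coefficients, lags))
        buf.pop(0)
        buf.append(out[k])
    return out
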