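"""Forecast scoring: MSE, MAE and Clarke Error Grid Analysis.

The Clarke grid is the clinical "gold standard" for judging glucose
predictions: each (reference, predicted) pair lands in one of five
zones, from A (clinically benign deviation) to E (dangerously wrong
treatment decision).  The zone geometry follows the standard 1987
codification, evaluated in mg/dL with the conventional clinical
conversion 1 mmol/L = 18.0 mg/dL exactly; all boundary inequalities are
inclusive so classification is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .errors import InvalidInputError
from .series import ArrayLike

#: Conventional clinical conversion factor (exact, by design).
MMOL_TO_MGDL = 18.0

ZONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class ErrorMetrics:
    """Mean squared error ((mmol/L)^2) and mean absolute error (mmol/L)."""

    mse: float
    mae: float
    n: int

    @classmethod
    def from_pairs(cls, actual: ArrayLike, predicted: ArrayLike) -> "ErrorMetrics":
        a, p = _paired(actual, predicted)
        e = a - p
        return cls(mse=float(np.mean(e**2)), mae=float(np.mean(np.abs(e))), n=a.size)

    def to_dict(self) -> dict:
        return {"mse": self.mse, "mae": self.mae, "n": self.n}


@dataclass(frozen=True)
class EGAResult:
    """Per-pair Clarke zone labels and the zone percentage table."""

    zones: np.ndarray  # array of single-character labels
    percentages: Dict[str, float]
    units_used: str = "mg/dL"

    def to_dict(self) -> dict:
        return {
            "zones": self.zones.tolist(),
            "percentages": self.percentages,
            "units_used": self.units_used,
        }


def _paired(actual: ArrayLike, predicted: ArrayLike):
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 1:
        raise InvalidInputError(
            f"need equal-length non-empty 1-D sequences (got {a.shape} vs {p.shape})"
        )
    return a, p


def mse(actual: ArrayLike, predicted: ArrayLike) -> float:
    """Mean of squared residuals."""
    a, p = _paired(actual, predicted)
    return float(np.mean((a - p) ** 2))


def mae(actual: ArrayLike, predicted: ArrayLike) -> float:
    """Mean of absolute residuals."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def clarke_zone(ref_mgdl: float, pred_mgdl: float) -> str:
    """Clarke zone of a single (reference, predicted) pair in mg/dL.

    Rule table (precedence A, E, C, D, else B):

    * A: |pred - ref| <= 0.2*ref, or both below 70
    * E: (ref >= 180 and pred <= 70) or (ref <= 70 and pred >= 180)
    * C: (70 <= ref <= 290 and pred >= ref + 110) or
         (130 <= ref <= 180 and pred <= 1.4*ref - 182)
    * D: (ref >= 240 and 70 <= pred <= 180) or
         (ref <= 175/3 and 70 <= pred <= 180) or
         (175/3 <= ref <= 70 and pred >= 1.2*ref)
    """
    r, p = ref_mgdl, pred_mgdl
    if abs(p - r) <= 0.2 * r or (r < 70 and p < 70):
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= 1.4 * r - 182):
        return "C"
    if (
        (r >= 240 and 70 <= p <= 180)
        or (r <= 175 / 3 and 70 <= p <= 180)
        or (175 / 3 <= r <= 70 and p >= 1.2 * r)
    ):
        return "D"
    return "B"


def clarke_ega(reference: ArrayLike, predicted: ArrayLike) -> EGAResult:
    """Classify every (reference, predicted) pair, inputs in mmol/L.

    Values are converted to mg/dL before applying the rule table.  Every
    pair receives exactly one zone and the percentages sum to 100.
    """
    ref, pred = _paired(reference, predicted)
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise InvalidInputError("glucose values must be positive")
    r = ref * MMOL_TO_MGDL
    p = pred * MMOL_TO_MGDL
    labels = np.array([clarke_zone(ri, pi) for ri, pi in zip(r, p)])
    pct = {z: float(100.0 * np.mean(labels == z)) for z in ZONES}
    return EGAResult(zones=labels, percentages=pct)


def plot_ega(
    reference: ArrayLike,
    predicted: ArrayLike,
    path: Optional[str] = None,
    ax=None,
):
    """Scatter the pairs on the Clarke grid with zone boundary overlays.

    Cosmetic output only; returns the matplotlib Axes.  Saves to ``path``
    when given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ref, pred = _paired(reference, predicted)
    r = ref * MMOL_TO_MGDL
    p = pred * MMOL_TO_MGDL
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    lim = 400.0
    ax.plot([0, lim], [0, lim], "k:", lw=0.8)
    # classic zone boundary segments (mg/dL)
    segs = [
        ([0, lim], [0, 1.2 * lim]),
        ([0, lim], [0, 0.8 * lim]),
        ([0, 70], [70, 70]),
        ([70, 70], [0, 56]),
        ([70, 70], [84, lim]),
        ([0, 70], [180, 180]),
        ([180, lim], [70, 70]),
        ([180, 180], [0, 70]),
        ([240, 240], [70, 180]),
        ([240, lim], [180, 180]),
        ([130, 180], [0, 70]),
        ([70, 290], [180, lim]),
    ]
    for xs, ys in segs:
        ax.plot(xs, ys, "k-", lw=0.6, alpha=0.6)
    ax.scatter(r, p, s=12, c="tab:red", alpha=0.8, zorder=3)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("Reference glucose (mg/dL)")
    ax.set_ylabel("Predicted glucose (mg/dL)")
    ax.set_title("Clarke Error Grid")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
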