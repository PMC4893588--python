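"""Model-acceptance tests for a fitted GM(1,1).

Grey-systems practice gates a fitted model through three checks before
its forecasts are trusted:

1. **Relative error test** — pointwise arithmetic check.  The accuracy
   score ``p_deg = (1 - mean relative error) * 100`` must exceed 80%.
2. **Posterior deviation test** — statistical check on the residual
   distribution.  ``C = S2/S1`` is the ratio of residual to data
   standard deviation (population divisor); ``p`` is the fraction of
   residual deviations within ``0.6745 * S1``.  The (C, p) pair maps to
   the conventional four-level grade, taking the worse of the two
   indicator levels.
3. **Grey relational (correlation) test** — geometric similarity of the
   fitted and actual curves via deviation coefficients with resolution
   ratio ``rho`` (0.5 by default); the relational degree must exceed 0.6.

Residuals are always taken in the original glucose domain (mmol/L), over
the fitted points ``i = 2..n`` (the initial sample has no fitted value).
The "posterior probability" here is the grey-systems empirical fraction,
not a Bayesian posterior.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, UndefinedRatioError
from .series import ArrayLike


class Grade(enum.IntEnum):
    """Four-level accuracy grade; higher is better."""

    DISQUALIFIED = 0
    MARGINAL = 1
    QUALIFIED = 2
    SUPERIOR = 3

    def __str__(self) -> str:  # serialized form
        return self.name.lower()


#: (C upper bound, p lower bound) per grade, best first.
_GRADE_TABLE = (
    (Grade.SUPERIOR, 0.35, 0.95),
    (Grade.QUALIFIED, 0.50, 0.80),
    (Grade.MARGINAL, 0.65, 0.70),
)


@dataclass(frozen=True)
class RelativeErrorReport:
    per_point: np.ndarray  # epsilon(i), fractions
    mean_error: float
    accuracy: float  # p_deg, percent
    passed: bool

    def to_dict(self) -> dict:
        return {
            "per_point_percent": (self.per_point * 100).tolist(),
            "mean_error": self.mean_error,
            "accuracy_percent": self.accuracy,
            "passed": self.passed,
        }


@dataclass(frozen=True)
class PosteriorReport:
    s1: float
    s2: float
    c_ratio: float
    posterior_p: float
    grade: Grade

    def to_dict(self) -> dict:
        return {
            "s1": self.s1,
            "s2": self.s2,
            "c_ratio": self.c_ratio,
            "posterior_p": self.posterior_p,
            "grade": str(self.grade),
        }


@dataclass(frozen=True)
class RelationalReport:
    coefficients: np.ndarray
    degree: float
    rho: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "degree": self.degree,
            "rho": self.rho,
            "passed": self.passed,
        }


@dataclass(frozen=True)
class DiagnosticsReport:
    relative: RelativeErrorReport
    posterior: PosteriorReport
    relational: RelationalReport
    all_passed: bool

    def to_dict(self) -> dict:
        return {
            "relative": self.relative.to_dict(),
            "posterior": self.posterior.to_dict(),
            "relational": self.relational.to_dict(),
            "all_passed": self.all_passed,
        }


def _paired(actual: ArrayLike, fitted: ArrayLike, min_len: int = 1):
    a = np.asarray(actual, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if a.shape != f.shape or a.ndim != 1:
        raise InvalidInputError(
            f"actual and fitted must be equal-length 1-D sequences "
            f"(got {a.shape} vs {f.shape})"
        )
    if a.size < min_len:
        raise InvalidInputError(f"need at least {min_len} pairs, got {a.size}")
    return a, f


def relative_error_test(actual: ArrayLike, fitted: ArrayLike) -> RelativeErrorReport:
    """Pointwise relative errors eps(i) = |actual - fitted| / actual and
    the accuracy score p_deg = (1 - mean eps) * 100 (gate: > 80%)."""
    a, f = _paired(actual, fitted)
    if np.any(a <= 0):
        raise InvalidInputError("actual glucose must be positive")
    eps = np.abs(a - f) / a
    mean_err = float(np.mean(eps))
    accuracy = (1.0 - mean_err) * 100.0
    return RelativeErrorReport(
        per_point=eps,
        mean_error=mean_err,
        accuracy=accuracy,
        passed=bool(accuracy > 80.0),
    )


def grade_from_cp(c_ratio: float, posterior_p: float) -> Grade:
    """Grade from the (C, p) table, taking the worse of the two levels."""

    def level(ok) -> Grade:
        for grade, c_max, p_min in _GRADE_TABLE:
            if ok(c_max, p_min):
                return grade
        return Grade.DISQUALIFIED

    c_level = level(lambda c_max, _p: c_ratio < c_max)
    p_level = level(lambda _c, p_min: posterior_p > p_min)
    return min(c_level, p_level)


def posterior_deviation_test(actual: ArrayLike, fitted: ArrayLike) -> PosteriorReport:
    """Posterior variance ratio C = S2/S1 and posterior probability p.

    S1 and S2 are population standard deviations (divisor n) of the
    actual series and of the residuals; p is the fraction of centred
    residuals with magnitude below 0.6745 * S1.
    """
    a, f = _paired(actual, fitted, min_len=2)
    s1 = float(np.std(a))
    if s1 == 0.0:
        raise UndefinedRatioError(
            "posterior variance ratio undefined: actual series is constant (S1 = 0)"
        )
    e = a - f
    s2 = float(np.std(e))
    c_ratio = s2 / s1
    p = float(np.mean(np.abs(e - e.mean()) < 0.6745 * s1))
    return PosteriorReport(
        s1=s1, s2=s2, c_ratio=c_ratio, posterior_p=p, grade=grade_from_cp(c_ratio, p)
    )


def relational_test(
    actual: ArrayLike, fitted: ArrayLike, rho: float = 0.5
) -> RelationalReport:
    """Grey relational degree between the actual and fitted curves.

    With deviations ``d_i = |actual - fitted|`` the coefficients are
    ``xi_i = (d_min + rho*d_max) / (d_i + rho*d_max)``, each in
    ``[rho/(1+rho), 1]``, and the degree is their mean (gate: > 0.6).
    When every deviation is zero the relation is perfect by the
    continuity limit: all ``xi_i = 1``.
    """
    if not 0.0 <= rho <= 1.0:
        raise InvalidInputError("resolution ratio rho must lie in [0, 1]")
    a, f = _paired(actual, fitted)
    d = np.abs(a - f)
    d_max = float(d.max())
    if d_max == 0.0:
        xi = np.ones_like(d)
    else:
        d_min = float(d.min())
        xi = (d_min + rho * d_max) / (d + rho * d_max)
    degree = float(np.mean(xi))
    return RelationalReport(
        coefficients=xi, degree=degree, rho=rho, passed=bool(degree > 0.6)
    )


def run_diagnostics(
    actual: ArrayLike, fitted: ArrayLike, rho: float = 0.5
) -> DiagnosticsReport:
    """Run all three acceptance tests and combine the gates.

    The model passes overall when the relative-error accuracy exceeds
    80%, the posterior grade is at least qualified, and the relational
    degree exceeds 0.6.
    """
    relative = relative_error_test(actual, fitted)
    posterior = posterior_deviation_test(actual, fitted)
    relational = relational_test(actual, fitted, rho=rho)
    all_passed = bool(
        relative.passed and posterior.grade >= Grade.QUALIFIED and relational.passed
    )
    return DiagnosticsReport(
        relative=relative,
        posterior=posterior,
        relational=relational,
        all_passed=all_passed,
    )
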