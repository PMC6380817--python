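"""Fit diagnostics for grey models: relative error, post-test ratio C,
small-error probability P, and the joint accuracy grade.

Conventions: population (divide-by-n) standard deviations for both the
residual series Se and the original series Sx; absolute relative errors for
the average relative error (ARE).  The small-error constant defaults to
0.6745, the probable-error multiplier of the normal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidSeriesError, UndefinedDiagnosticError

__all__ = [
    "FitReport",
    "relative_errors",
    "average_relative_error",
    "post_test_ratio",
    "small_error_probability",
    "grade",
    "fit_report",
    "DEFAULT_SMALL_ERROR_CONSTANT",
    "DEFAULT_GRADE_THRESHOLDS",
]

DEFAULT_SMALL_ERROR_CONSTANT = 0.6745

#: (grade, max C, min P), best first; a fit gets the worse of its C- and
#: P-implied class, boundaries belonging to the better class.
DEFAULT_GRADE_THRESHOLDS: tuple[tuple[str, float, float], ...] = (
    ("good", 0.35, 0.95),
    ("qualified", 0.50, 0.80),
    ("barely qualified", 0.65, 0.70),
    ("unqualified", float("inf"), 0.0),
)


def _as_pair(actual: Sequence[float], fitted: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if a.shape != f.shape or a.ndim != 1 or a.size == 0:
        raise InvalidSeriesError("actual and fitted must be equal-length 1-D sequences")
    return a, f


def relative_errors(actual: Sequence[float], fitted: Sequence[float]) -> np.ndarray:
    """Per-point absolute relative errors |actual - fitted| / actual."""
    a, f = _as_pair(actual, fitted)
    if np.any(a == 0):
        raise InvalidSeriesError("relative error undefined for zero actual values")
    return np.abs(a - f) / np.abs(a)


def average_relative_error(actual: Sequence[float], fitted: Sequence[float]) -> float:
    return float(relative_errors(actual, fitted).mean())


def _sx(actual: np.ndarray) -> float:
    sx = float(np.std(actual))  # population sd
    if sx == 0:
        raise UndefinedDiagnosticError("original series is constant: Sx = 0, C undefined")
    return sx


def post_test_ratio(actual: Sequence[float], fitted: Sequence[float]) -> float:
    """Post-test ratio C = sd(residuals) / sd(original series)."""
    a, f = _as_pair(actual, fitted)
    if a.size < 2:
        raise InvalidSeriesError("post-test ratio requires length >= 2")
    return float(np.std(a - f) / _sx(a))


def small_error_probability(
    actual: Sequence[float],
    fitted: Sequence[float],
    c: float = DEFAULT_SMALL_ERROR_CONSTANT,
) -> float:
    """P = fraction of residual deviations from their mean below c·Sx."""
    a, f = _as_pair(actual, fitted)
    if a.size < 2:
        raise InvalidSeriesError("small-error probability requires length >= 2")
    eps = a - f
    return float(np.mean(np.abs(eps - eps.mean()) < c * _sx(a)))


def grade(
    c_value: float,
    p_value: float,
    thresholds: tuple[tuple[str, float, float], ...] = DEFAULT_GRADE_THRESHOLDS,
) -> str:
    """Joint accuracy grade: the worse of the C-implied and P-implied class."""
    if c_value < 0 or not 0 <= p_value <= 1:
        raise InvalidSeriesError("require C >= 0 and P in [0, 1]")
    c_rank = next(i for i, (_, cmax, _) in enumerate(thresholds) if c_value <= cmax)
    p_rank = next(i for i, (_, _, pmin) in enumerate(thresholds) if p_value >= pmin)
    return thresholds[max(c_rank, p_rank)][0]


@dataclass(frozen=True)
class FitReport:
    """Summary of fit quality over a window."""

    relative_errors: np.ndarray
    are: float
    c: float
    p: float
    grade: str
    residuals: np.ndarray
    n: int
    constant_used: float

    def to_dict(self) -> dict:
        return {
            "are": self.are,
            "c": self.c,
            "p": self.p,
            "grade": self.grade,
            "n": self.n,
            "constant_used": self.constant_used,
        }

    def summary_line(self) -> str:
        flag = "" if self.constant_used == DEFAULT_SMALL_ERROR_CONSTANT else (
            f" [non-default small-error constant {self.constant_used}]"
        )
        return (
            f"n={self.n} ARE={self.are:.4%} C={self.c:.4f} P={self.p:.4f} "
            f"grade={self.grade}{flag}"
        )


def fit_report(
    actual: Sequence[float],
    fitted: Sequence[float],
    c: float = DEFAULT_SMALL_ERROR_CONSTANT,
) -> FitReport:
    """Compute all diagnostics for an (actual, fitted) pair."""
    a, f = _as_pair(actual, fitted)
    rel = relative_errors(a, f)
    cv = post_test_ratio(a, f)
    pv = small_error_probability(a, f, c=c)
    return FitReport(
        relative_errors=rel,
        are=float(rel.mean()),
        c=cv,
        p=pv,
        grade=grade(cv, pv),
        residuals=a - f,
        n=int(a.size),
        constant_used=c,
    )
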