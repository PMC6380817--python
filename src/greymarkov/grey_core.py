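"""Basic GM(1,1) grey forecasting model.

The grey model of first order in one variable, GM(1,1), forecasts a short
positive time series x(0)(1..n) through its accumulated sum x(1) (the AGO
series).  The continuous whitenization equation

    dx(1)/dt + a*x(1) = u

has solution x̂(1)(k+1) = (x(0)(1) - u/a)·exp(-a·k) + u/a, and differencing
(inverse AGO) recovers fitted values on the original scale.  The developing
coefficient ``a`` sets the exponential rate (negative a: growth of the AGO
curve, i.e. a declining or growing original series depending on sign); the
control variable ``u`` is the constant grey input.  Parameters are estimated
by ordinary least squares on the grey difference equation

    x(0)(k) + a*z(1)(k) = u,   k = 2..n,

where z(1)(k) is the mean of adjacent AGO values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateFitError, FitQualityWarning, InvalidSeriesError

__all__ = [
    "ObservedSeries",
    "AGOSeries",
    "GM11Model",
    "accumulate",
    "inverse_accumulate",
    "adjacent_means",
    "estimate_params",
    "time_response",
    "fit_gm11",
    "forecast",
    "prediction_length_class",
]

#: |a| below this uses the analytic linear limit of the time response.
DEGENERATE_A = 1e-8

#: Prediction-length classes by |a|, most permissive first.  The thresholds
#: are the standard grey-literature ones; pass a custom mapping to
#: :func:`prediction_length_class` to override.
DEFAULT_LENGTH_CLASSES: tuple[tuple[float, str], ...] = (
    (0.3, "medium-long-term"),
    (0.5, "short-term"),
    (1.0, "caution"),
    (float("inf"), "unsuitable"),
)


@dataclass(frozen=True)
class ObservedSeries:
    """A positive annual incidence series with calendar-year labels.

    Parameters
    ----------
    labels : strictly increasing consecutive integer years.
    values : strictly positive rates (per 100,000 live births, or any
        positive scale — the model is scale-equivariant).
    """

    labels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise InvalidSeriesError("series must be a non-empty 1-D sequence")
        if labels.shape != values.shape:
            raise InvalidSeriesError("labels and values must have equal length")
        if not np.all(np.isfinite(values)):
            raise InvalidSeriesError("series contains non-finite values")
        if np.any(values <= 0):
            raise InvalidSeriesError("all series values must be strictly positive")
        if labels.size > 1 and not np.all(np.diff(labels) == 1):
            raise InvalidSeriesError("labels must increase in unit steps")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def window(self, start: int, stop: int) -> "ObservedSeries":
        """Sub-series for label range [start, stop] inclusive."""
        mask = (self.labels >= start) & (self.labels <= stop)
        if not mask.any():
            raise InvalidSeriesError(f"no observations in window {start}-{stop}")
        return ObservedSeries(self.labels[mask], self.values[mask])


@dataclass(frozen=True)
class AGOSeries:
    """Accumulated (cumulative-sum) series x(1) of an observed series."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def accumulate(series: ObservedSeries) -> AGOSeries:
    """Accumulated generating operation: x(1)(k) = sum_{i<=k} x(0)(i)."""
    return AGOSeries(np.cumsum(series.values))


def inverse_accumulate(ago: AGOSeries | np.ndarray) -> np.ndarray:
    """Inverse AGO (first difference, first element kept)."""
    values = ago.values if isinstance(ago, AGOSeries) else np.asarray(ago, float)
    if values.size == 0:
        raise InvalidSeriesError("cannot invert an empty accumulated series")
    return np.diff(values, prepend=0.0)


def adjacent_means(ago: AGOSeries | np.ndarray) -> np.ndarray:
    """Background values z(1)(k) = (x(1)(k) + x(1)(k-1)) / 2 for k = 2..n."""
    values = ago.values if isinstance(ago, AGOSeries) else np.asarray(ago, float)
    if values.size < 2:
        raise InvalidSeriesError("adjacent means require length >= 2")
    return 0.5 * (values[1:] + values[:-1])


def estimate_params(series: ObservedSeries) -> tuple[float, float]:
    """Least-squares estimate of (a, u) from the grey difference equation.

    Solves min_{a,u} sum_{k=2}^{n} (x(0)(k) + a*z(1)(k) - u)^2, i.e. OLS with
    design rows [-z(1)(k), 1] and response x(0)(k).
    """
    if series.n < 4:
        raise InvalidSeriesError("GM(1,1) fitting requires at least 4 observations")
    z = adjacent_means(accumulate(series))
    design = np.column_stack([-z, np.ones_like(z)])
    response = series.values[1:]
    solution, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
    if rank < 2:
        raise DegenerateFitError("singular normal equations: background values collinear")
    a, u = float(solution[0]), float(solution[1])
    return a, u


@dataclass(frozen=True)
class GM11Model:
    """A fitted GM(1,1) model over one calendar window.

    ``fitted`` reconstructs x̂(0) over the window (first value reproduced
    exactly by construction); ``residual_ratios`` are actual/fitted, the
    quantity on which Markov ratio states are defined.
    """

    a: float
    u: float
    x0_first: float
    window_labels: np.ndarray
    actual: np.ndarray
    fitted: np.ndarray = field(repr=False)
    residual_ratios: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return int(self.actual.size)

    def time_response(self, k: int | np.ndarray) -> float | np.ndarray:
        return time_response(self, k)

    def forecast(self, horizon: int) -> np.ndarray:
        return forecast(self, horizon)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "u": self.u,
            "x0_first": self.x0_first,
            "window_start": int(self.window_labels[0]),
            "window_end": int(self.window_labels[-1]),
            "n": self.n,
            "prediction_length_class": prediction_length_class(self.a),
        }


def time_response(model: GM11Model, k: int | np.ndarray) -> float | np.ndarray:
    """AGO-scale prediction x̂(1)(k+1) for 0-based step(s) k.

    For |a| below ``DEGENERATE_A`` the analytic limit x0 + u*k of the
    exponential form is used, avoiding division by a vanishing coefficient.
    """
    k = np.asarray(k, dtype=float)
    if abs(model.a) < DEGENERATE_A:
        out = model.x0_first + model.u * k
    else:
        ua = model.u / model.a
        out = (model.x0_first - ua) * np.exp(-model.a * k) + ua
    return float(out) if out.ndim == 0 else out


def fit_gm11(series: ObservedSeries) -> GM11Model:
    """Fit GM(1,1): estimate (a, u), reconstruct x̂(0) by inverse AGO.

    Warns :class:`FitQualityWarning` if any fitted value is non-positive
    (actual/fitted ratio states then become unstable).
    """
    a, u = estimate_params(series)
    shell = GM11Model(
        a=a,
        u=u,
        x0_first=float(series.values[0]),
        window_labels=series.labels.copy(),
        actual=series.values.copy(),
        fitted=np.empty(0),
        residual_ratios=np.empty(0),
    )
    x1_hat = time_response(shell, np.arange(series.n))
    fitted = np.concatenate([[series.values[0]], np.diff(x1_hat)])
    if np.any(fitted <= 0):
        warnings.warn(
            "non-positive fitted values: actual/fitted ratios are unstable",
            FitQualityWarning,
            stacklevel=2,
        )
    ratios = series.values / fitted
    return GM11Model(
        a=a,
        u=u,
        x0_first=shell.x0_first,
        window_labels=shell.window_labels,
        actual=shell.actual,
        fitted=fitted,
        residual_ratios=ratios,
    )


def forecast(model: GM11Model, horizon: int) -> np.ndarray:
    """Out-of-window forecasts x̂(0)(n+1 .. n+horizon) by differencing x̂(1)."""
    if horizon < 1:
        raise InvalidSeriesError("forecast horizon must be a positive integer")
    k = np.arange(model.n - 1, model.n + horizon)
    x1_hat = np.atleast_1d(time_response(model, k))
    return np.diff(x1_hat)


def prediction_length_class(
    a: float,
    thresholds: Sequence[tuple[float, str]] = DEFAULT_LENGTH_CLASSES,
) -> str:
    """Classify how far ahead the model may be trusted, from |a|.

    Defaults: |a| <= 0.3 medium-long-term; <= 0.5 short-term; <= 1 caution
    (apply a correction before trusting forecasts); > 1 unsuitable.
    """
    magnitude = abs(float(a))
    for bound, label in thresholds:
        if magnitude <= bound:
            return label
    return thresholds[-1][1]
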