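"""Metabolic (rolling-window) GM(1,1) updates.

A metabolic grey model drops the oldest observation from the fitting window,
appends the newest value — either an actual observation or the previous
model's own one-step forecast — and refits.  Chaining such updates keeps a
constant window size while the window slides forward in time, so the model
tracks the most recent trend.  Each refit is a full re-estimation; windows
are short, so there is no need for warm starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import InvalidSeriesError
from .grey_core import GM11Model, ObservedSeries, fit_gm11, forecast

__all__ = ["MetabolicStep", "MetabolicChain", "metabolic_step", "metabolic_chain"]

Source = Literal["actual", "forecast"]


@dataclass(frozen=True)
class MetabolicStep:
    appended_value: float
    source: Source
    model: GM11Model


@dataclass(frozen=True)
class MetabolicChain:
    """A base model plus successive one-step rolling refits."""

    base_model: GM11Model
    steps: tuple[MetabolicStep, ...]
    window_size: int

    @property
    def models(self) -> tuple[GM11Model, ...]:
        return (self.base_model,) + tuple(s.model for s in self.steps)

    @property
    def final_model(self) -> GM11Model:
        return self.models[-1]


def metabolic_step(model: GM11Model, new_value: float, source: Source = "forecast") -> GM11Model:
    """Refit on the window shifted by one: drop oldest, append ``new_value``."""
    if not np.isfinite(new_value) or new_value <= 0:
        raise InvalidSeriesError("appended value must be a positive finite number")
    labels = np.append(model.window_labels[1:], model.window_labels[-1] + 1)
    values = np.append(model.actual[1:], new_value)
    return fit_gm11(ObservedSeries(labels, values))


def metabolic_chain(
    series: ObservedSeries,
    window: int,
    n_steps: int,
    source: Source = "forecast",
) -> MetabolicChain:
    """Build the base model on the first ``window`` points, then roll forward.

    With ``source="forecast"`` (the default) each appended value is the
    previous model's one-step forecast, so the chain is self-seeding and
    needs no data beyond the initial window.  With ``source="actual"`` the
    observed continuation of ``series`` is consumed, which requires at least
    ``window + n_steps`` observations.
    """
    if window < 4:
        raise InvalidSeriesError("metabolic window must be at least 4")
    if n_steps < 0:
        raise InvalidSeriesError("number of metabolic steps must be non-negative")
    if series.n < window:
        raise InvalidSeriesError("series shorter than the requested window")
    if source == "actual" and series.n < window + n_steps:
        raise InvalidSeriesError(
            f"source='actual' needs {window + n_steps} observations, have {series.n}"
        )

    base = fit_gm11(ObservedSeries(series.labels[:window], series.values[:window]))
    steps: list[MetabolicStep] = []
    current = base
    for t in range(n_steps):
        if source == "forecast":
            new_value = float(forecast(current, 1)[0])
        else:
            new_value = float(series.values[window + t])
        current = metabolic_step(current, new_value, source)
        steps.append(MetabolicStep(new_value, source, current))
    return MetabolicChain(base_model=base, steps=tuple(steps), window_size=window)
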