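"""Seeded generator of declining incidence series with Markov-modulated noise.

Emulates the shape of a rural maternal-mortality series: a short, strictly
positive, monotone-declining exponential trend towards a floor, multiplied
by a fluctuation ratio driven by a hidden K-state Markov chain.  The ratio
axis is split into K equal-width intervals centred on 1; each year the chain
picks an interval and the ratio is drawn uniformly inside it.  Because the
noise lives on the actual/trend ratio scale — exactly the scale on which the
Markov correction operates — the hybrid model has a recoverable structure.

The generator returns the truth (trend and hidden states) alongside the
observations so recovery tests need no external oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidSeriesError
from .grey_core import ObservedSeries

__all__ = ["GeneratorConfig", "generate"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults: 13 years starting at 63.0 per 100,000,
    exponential decay 0.095/year towards a floor of 15.0, 2% ratio noise in
    3 hidden states with stickiness 0.5."""

    n: int = 13
    x0: float = 63.0
    floor: float = 15.0
    decay: float = 0.095
    noise_sd: float = 0.02
    n_states: int = 3
    state_stickiness: float = 0.5
    start_year: int = 2005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidSeriesError("series length must be positive")
        if not self.x0 > self.floor >= 0:
            raise InvalidSeriesError("require x0 > floor >= 0")
        if self.decay <= 0:
            raise InvalidSeriesError("decay must be positive")
        if self.noise_sd < 0:
            raise InvalidSeriesError("noise_sd must be non-negative")
        if self.n_states < 1:
            raise InvalidSeriesError("need at least one ratio state")
        if not 0 <= self.state_stickiness <= 1:
            raise InvalidSeriesError("state_stickiness must lie in [0, 1]")

    @property
    def ratio_boundaries(self) -> np.ndarray:
        """Equal-width state intervals on [1 - K*noise_sd, 1 + K*noise_sd]."""
        half = self.n_states * self.noise_sd
        return np.linspace(1.0 - half, 1.0 + half, self.n_states + 1)

    @property
    def transition_matrix(self) -> np.ndarray:
        """True hidden-chain transition matrix: stay with probability
        ``state_stickiness``, otherwise move uniformly to another state."""
        K = self.n_states
        if K == 1:
            return np.ones((1, 1))
        off = (1.0 - self.state_stickiness) / (K - 1)
        P = np.full((K, K), off)
        np.fill_diagonal(P, self.state_stickiness)
        return P


def generate(config: GeneratorConfig) -> tuple[ObservedSeries, np.ndarray, np.ndarray]:
    """Draw one series; returns (observed, true trend, hidden state sequence).

    trend(t) = (x0 - floor)·exp(-decay·t) + floor for t = 0..n-1;
    observed(t) = trend(t)·r(t) with r(t) uniform in the hidden state's
    ratio interval.  A fixed seed reproduces the series exactly; with
    noise_sd = 0 the observations equal the trend.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n)
    trend = (config.x0 - config.floor) * np.exp(-config.decay * t) + config.floor

    P = config.transition_matrix
    states = np.empty(config.n, dtype=int)
    states[0] = rng.integers(config.n_states)
    for i in range(1, config.n):
        states[i] = rng.choice(config.n_states, p=P[states[i - 1]])

    if config.noise_sd == 0:
        ratios = np.ones(config.n)
    else:
        b = config.ratio_boundaries
        ratios = rng.uniform(b[states], b[states + 1])

    observed = trend * ratios
    labels = config.start_year + t
    return ObservedSeries(labels, observed), trend, states
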