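"""Markov-chain correction of GM(1,1) output.

The grey model captures the smooth exponential trend; the Markov layer
models the fluctuation around it.  Per window year the actual/fitted ratio
y(k) = x(0)(k)/x̂(0)(k) is computed, the ratio axis is partitioned into K
contiguous states E1..EK, a one-step transition matrix is estimated from the
state sequence, a chi-square test checks that consecutive states are in fact
dependent (otherwise the correction has nothing to learn), the next state is
predicted by summing probability rows of the m-step matrices for the most
recent observations, and the grey forecast is multiplied by the predicted
state's interval midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegeneratePartitionError,
    InvalidSeriesError,
    StateRangeWarning,
    UndefinedTestError,
)
from .grey_core import GM11Model

__all__ = [
    "StatePartition",
    "TransitionModel",
    "StateForecast",
    "MarkovTestResult",
    "ratio_series",
    "partition_states",
    "assign_states",
    "estimate_transitions",
    "markov_property_test",
    "forecast_state",
    "revise_forecast",
    "hybrid_fitted",
]


@dataclass(frozen=True)
class StatePartition:
    """Ordered contiguous intervals on the actual/fitted ratio axis.

    ``boundaries`` has K+1 strictly increasing entries; state i (0-based)
    is [boundaries[i], boundaries[i+1]), lower-inclusive, with the last
    interval closed on both sides.
    """

    boundaries: np.ndarray
    method: Literal["equal_width", "custom"]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b.size < 3:
            raise InvalidSeriesError("a partition needs at least 2 states (3 boundaries)")
        if np.any(np.diff(b) <= 0):
            raise InvalidSeriesError("partition boundaries must be strictly increasing")

    @property
    def n_states(self) -> int:
        return self.boundaries.size - 1

    @property
    def intervals(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return [(float(b[i]), float(b[i + 1])) for i in range(self.n_states)]

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    @property
    def labels(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_states)]


@dataclass(frozen=True)
class TransitionModel:
    """One-step transition counts/probabilities and m-step extensions.

    Rows of ``P1`` with no observed transitions are left all-zero and listed
    in ``zero_rows``.  ``marginals`` are state frequencies over the whole
    sequence.  m-step matrices follow Chapman–Kolmogorov (matrix powers) by
    default; ``m_step_method="empirical"`` counts lag-m pairs directly.
    """

    counts: np.ndarray
    P1: np.ndarray
    marginals: np.ndarray
    states: np.ndarray
    zero_rows: tuple[int, ...] = ()
    m_step_method: Literal["power", "empirical"] = "power"

    @property
    def n_states(self) -> int:
        return self.P1.shape[0]

    def m_step(self, m: int) -> np.ndarray:
        """m-step transition matrix P(m)."""
        if m < 1:
            raise InvalidSeriesError("transfer step m must be >= 1")
        if self.m_step_method == "power":
            return np.linalg.matrix_power(self.P1, m)
        counts = _pair_counts(self.states, self.n_states, lag=m)
        return _normalise_rows(counts)[0]


class MarkovTestResult(NamedTuple):
    statistic: float
    df: int
    critical_value: float
    p_value: float
    markov_suitable: bool


class StateForecast(NamedTuple):
    sources: list[tuple[int, int, np.ndarray]]  # (state, transfer step m, row of P(m))
    summed: np.ndarray
    predicted_state: int
    tie: bool


def ratio_series(model: GM11Model) -> np.ndarray:
    """Actual/fitted ratio per window year, y(k) = x(0)(k)/x̂(0)(k)."""
    if np.any(model.fitted <= 0):
        raise InvalidSeriesError("ratio series undefined: non-positive fitted values")
    return model.actual / model.fitted


def partition_states(
    ratios: Sequence[float],
    n_states: int = 3,
    method: Literal["equal_width", "custom"] = "equal_width",
    custom_boundaries: Sequence[float] | None = None,
) -> StatePartition:
    """Partition the ratio axis into states.

    ``equal_width`` spans [min(ratios), max(ratios)] with ``n_states`` equal
    intervals.  ``custom`` uses supplied boundaries verbatim, which is how
    unequal, expert-chosen intervals are reproduced.
    """
    if method == "custom":
        if custom_boundaries is None:
            raise InvalidSeriesError("custom partition requires explicit boundaries")
        return StatePartition(np.asarray(custom_boundaries, float), "custom")
    if n_states < 2:
        raise InvalidSeriesError("at least 2 states are required")
    ratios = np.asarray(ratios, dtype=float)
    lo, hi = float(ratios.min()), float(ratios.max())
    if hi <= lo:
        raise DegeneratePartitionError("ratios are constant; partition has zero width")
    return StatePartition(np.linspace(lo, hi, n_states + 1), "equal_width")


def assign_states(ratios: Sequence[float], partition: StatePartition) -> np.ndarray:
    """Map each ratio to a 0-based state index.

    Intervals are lower-inclusive, upper-exclusive; the last interval is
    closed.  Ratios outside the partition (possible at forecast time) are
    clamped to the nearest state with a :class:`StateRangeWarning`.
    """
    ratios = np.asarray(ratios, dtype=float)
    b = partition.boundaries
    if np.any(ratios < b[0]) or np.any(ratios > b[-1]):
        warnings.warn(
            "ratio outside the state partition; clamped to the nearest state",
            StateRangeWarning,
            stacklevel=2,
        )
    idx = np.searchsorted(b, ratios, side="right") - 1
    return np.clip(idx, 0, partition.n_states - 1)


def _pair_counts(states: np.ndarray, n_states: int, lag: int = 1) -> np.ndarray:
    counts = np.zeros((n_states, n_states))
    if states.size > lag:
        np.add.at(counts, (states[:-lag], states[lag:]), 1.0)
    return counts


def _normalise_rows(counts: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    row_sums = counts.sum(axis=1)
    zero_rows = tuple(int(i) for i in np.flatnonzero(row_sums == 0))
    probs = np.divide(
        counts, row_sums[:, None], out=np.zeros_like(counts), where=row_sums[:, None] > 0
    )
    return probs, zero_rows


def estimate_transitions(
    states: Sequence[int],
    n_states: int | None = None,
    m_step_method: Literal["power", "empirical"] = "power",
) -> TransitionModel:
    """Estimate the one-step transition matrix from a state sequence.

    p_ij = f_ij / sum_j f_ij from consecutive-pair counts f_ij; marginals
    p_.j are the frequency of state j over the whole sequence.
    """
    states = np.asarray(states, dtype=int)
    if states.size < 2:
        raise InvalidSeriesError("transition estimation requires at least 2 states")
    K = int(n_states) if n_states is not None else int(states.max()) + 1
    if np.any(states < 0) or np.any(states >= K):
        raise InvalidSeriesError("state index outside [0, n_states)")
    counts = _pair_counts(states, K, lag=1)
    P1, zero_rows = _normalise_rows(counts)
    marginals = np.bincount(states, minlength=K) / states.size
    return TransitionModel(
        counts=counts,
        P1=P1,
        marginals=marginals,
        states=states,
        zero_rows=zero_rows,
        m_step_method=m_step_method,
    )


def markov_property_test(
    states: Sequence[int],
    alpha: float = 0.05,
    n_states: int | None = None,
) -> MarkovTestResult:
    """Chi-square (likelihood-ratio) test of the Markov property.

    Tests dependence of consecutive states: statistic
    2·|Σ_ij f_ij·ln(p_ij / p_.j)| over cells with f_ij > 0 and p_.j > 0,
    referred to chi-square with (K−1)² degrees of freedom.  The sum is
    non-negative by construction (row-wise maximum likelihood), so the
    absolute value is a guard, not a reflection.  Rejection means the
    sequence is dependent, i.e. suitable for Markov correction.
    """
    if not 0 < alpha < 1:
        raise InvalidSeriesError("alpha must be in (0, 1)")
    states = np.asarray(states, dtype=int)
    if np.unique(states).size < 2:
        raise UndefinedTestError("Markov-property test needs >= 2 distinct states")
    tm = estimate_transitions(states, n_states=n_states)
    K = tm.n_states
    marg = np.broadcast_to(tm.marginals, (K, K))
    valid = (tm.counts > 0) & (marg > 0)
    log_terms = np.zeros_like(tm.counts)
    log_terms[valid] = tm.counts[valid] * np.log(tm.P1[valid] / marg[valid])
    statistic = float(2.0 * abs(log_terms.sum()))
    df = (K - 1) ** 2
    critical = float(stats.chi2.ppf(1 - alpha, df))
    p_value = float(stats.chi2.sf(statistic, df))
    return MarkovTestResult(statistic, df, critical, p_value, statistic > critical)


def forecast_state(
    transitions: TransitionModel,
    recent: Sequence[tuple[int, int]],
    tie_tol: float = 1e-12,
) -> StateForecast:
    """Predict the next state from the most recent observations.

    ``recent`` is a list of (state, transfer step m) pairs — conventionally
    the last three observed states with m = 1, 2, 3 (most recent first).
    Row ``state`` of P(m) is taken per pair; the rows are summed
    element-wise and the predicted state is the argmax.  Ties break toward
    the higher-index (larger-ratio) state and are flagged.  An all-zero row
    (state never observed as a source) falls back to the marginals with a
    warning.
    """
    if not recent:
        raise InvalidSeriesError("at least one (state, step) source is required")
    sources: list[tuple[int, int, np.ndarray]] = []
    summed = np.zeros(transitions.n_states)
    for state, m in recent:
        if m < 1:
            raise InvalidSeriesError("transfer step m must be >= 1")
        row = transitions.m_step(m)[state]
        if row.sum() == 0:
            warnings.warn(
                f"state {state} has no observed outgoing transitions; "
                "using marginal probabilities",
                StateRangeWarning,
                stacklevel=2,
            )
            row = transitions.marginals.copy()
        sources.append((int(state), int(m), row))
        summed = summed + row
    best = summed.max()
    winners = np.flatnonzero(summed >= best - tie_tol)
    return StateForecast(
        sources=sources,
        summed=summed,
        predicted_state=int(winners.max()),
        tie=winners.size > 1,
    )


def revise_forecast(grey_forecast: float, interval: tuple[float, float]) -> float:
    """Revise a grey forecast by the predicted state's interval midpoint.

    Returns 0.5·(Q1 + Q2)·x̂, which always lies in [Q1·x̂, Q2·x̂].
    """
    q1, q2 = float(interval[0]), float(interval[1])
    if grey_forecast <= 0:
        raise InvalidSeriesError("grey forecast must be positive")
    if not q1 < q2:
        raise InvalidSeriesError("state interval must satisfy Q1 < Q2")
    return 0.5 * (q1 + q2) * grey_forecast


def hybrid_fitted(model: GM11Model, partition: StatePartition, states: Sequence[int] | None = None) -> np.ndarray:
    """In-sample hybrid fitted values.

    Each window year's grey fitted value is revised by the midpoint of its
    own assigned state's interval — the in-sample analogue of the forecast
    revision step.
    """
    if states is None:
        states = assign_states(ratio_series(model), partition)
    states = np.asarray(states, dtype=int)
    return model.fitted * partition.midpoints[states]
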