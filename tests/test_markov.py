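import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import greymarkov as gm
from greymarkov.exceptions import (
    DegeneratePartitionError,
    InvalidSeriesError,
    StateRangeWarning,
    UndefinedTestError,
)

from conftest import STUDY_BOUNDARIES

state_sequences = st.lists(st.integers(min_value=0, max_value=2), min_size=5, max_size=60)


def test_ratio_series_is_actual_over_fitted(declining_series):
    model = gm.fit_gm11(declining_series)
    assert np.allclose(gm.ratio_series(model), model.actual / model.fitted)
    pure_exp, _, _ = gm.generate(gm.GeneratorConfig(noise_sd=0.0, floor=0.0, seed=0))
    near_perfect = gm.fit_gm11(pure_exp)
    assert np.allclose(gm.ratio_series(near_perfect), 1.0, atol=1e-3)


def test_equal_width_partition():
    part = gm.partition_states([0.9, 1.0, 1.1], n_states=2)
    assert np.allclose(part.boundaries, [0.9, 1.0, 1.1])
    assert part.labels == ["E1", "E2"]


def test_custom_partition_reproduces_study_intervals(study_partition):
    assert study_partition.intervals == [
        (0.9491, 0.9919),
        (0.9919, 1.0133),
        (1.0133, 1.0561),
    ]


def test_constant_ratios_make_partition_degenerate():
    with pytest.raises(DegeneratePartitionError):
        gm.partition_states([1.0, 1.0, 1.0], n_states=3)


class TestAssignStates:
    def test_study_example_maps_to_top_state(self, study_partition):
        assert gm.assign_states([1.0347], study_partition)[0] == 2  # E3

    def test_boundary_is_lower_inclusive(self, study_partition):
        assert gm.assign_states([0.9919], study_partition)[0] == 1  # E2

    def test_last_interval_closed(self, study_partition):
        assert gm.assign_states([1.0561], study_partition)[0] == 2

    def test_unit_ratios_single_state(self, study_partition):
        states = gm.assign_states(np.ones(5), study_partition)
        assert np.all(states == states[0])

    def test_out_of_range_clamps_with_warning(self, study_partition):
        with pytest.warns(StateRangeWarning):
            states = gm.assign_states([0.5, 2.0], study_partition)
        assert list(states) == [0, 2]

    @given(st.lists(st.floats(min_value=0.8, max_value=1.2), min_size=2, max_size=30))
    def test_partition_totality(self, ratios):
        ratios = np.asarray(ratios)
        if ratios.max() <= ratios.min():
            return
        part = gm.partition_states(ratios, n_states=3)
        states = gm.assign_states(ratios, part)
        assert np.all((states >= 0) & (states < 3))


def test_alternating_sequence_transition_matrix():
    tm = gm.estimate_transitions([0, 1, 0, 1])
    assert np.allclose(tm.P1, [[0, 1], [1, 0]])
    assert np.allclose(tm.m_step(2), np.eye(2))
    assert np.allclose(tm.marginals, [0.5, 0.5])


@given(state_sequences)
def test_rows_stochastic_and_chapman_kolmogorov(states):
    states = np.asarray(states)
    tm = gm.estimate_transitions(states, n_states=3)
    row_sums = tm.P1.sum(axis=1)
    observed = tm.counts.sum(axis=1) > 0
    assert np.allclose(row_sums[observed], 1.0, atol=1e-12)
    assert np.all((tm.P1 >= 0) & (tm.P1 <= 1))
    assert np.allclose(tm.marginals.sum(), 1.0)
    # Chapman-Kolmogorov: P(a+b) = P(a) @ P(b)
    assert np.allclose(tm.m_step(5), tm.m_step(2) @ tm.m_step(3), atol=1e-12)


def test_zero_count_row_flagged_and_falls_back_to_marginals():
    tm = gm.estimate_transitions([0, 1, 1, 1], n_states=3)
    assert 2 in tm.zero_rows
    with pytest.warns(StateRangeWarning):
        fc = gm.forecast_state(tm, [(2, 1)])
    assert np.allclose(fc.summed, tm.marginals)


def test_empirical_m_step_counts_lagged_pairs():
    states = [0, 1, 0, 1, 0, 1]
    tm = gm.estimate_transitions(states, m_step_method="empirical")
    assert np.allclose(tm.m_step(2), np.eye(2))  # lag-2 pairs always repeat


class TestMarkovPropertyTest:
    def test_deterministic_cycle_is_suitable(self):
        states = np.tile([0, 1, 2], 10)
        result = gm.markov_property_test(states)
        assert result.df == 4
        assert result.statistic > 3 * result.critical_value
        assert result.p_value < 1e-10
        assert result.markov_suitable

    def test_statistic_matches_hand_formula(self):
        """2·Σ f_ij·ln(p_ij/p_.j), computed by an explicit double loop;
        cells where p_ij equals the marginal contribute log(1) = 0."""
        states = [0, 0, 1, 1, 0, 0, 1, 1, 0]
        counts = {(i, j): 0 for i in range(2) for j in range(2)}
        for i, j in zip(states, states[1:]):
            counts[i, j] += 1
        marg = [states.count(j) / len(states) for j in range(2)]
        expected = 0.0
        for i in range(2):
            row_total = counts[i, 0] + counts[i, 1]
            for j in range(2):
                if counts[i, j]:
                    expected += counts[i, j] * np.log(
                        counts[i, j] / row_total / marg[j]
                    )
        expected = 2 * abs(expected)
        result = gm.markov_property_test(states)
        assert result.statistic == pytest.approx(expected, abs=1e-12)
        assert not result.markov_suitable

    def test_statistic_bounded_for_independent_sequences(self):
        """Under independence the statistic stays O(1) as the sequence
        grows (it does not drift upward with n), the hallmark of a
        correctly centred likelihood-ratio form."""
        rng = np.random.default_rng(0)
        short = gm.markov_property_test(rng.integers(0, 3, 50), n_states=3)
        long = gm.markov_property_test(rng.integers(0, 3, 3000), n_states=3)
        assert long.statistic < 10 * short.critical_value

    def test_single_state_sequence_undefined(self):
        with pytest.raises(UndefinedTestError):
            gm.markov_property_test([1, 1, 1, 1])


class TestForecastState:
    def test_identity_matrix_predicts_source_state(self):
        tm = gm.estimate_transitions([0, 0, 1, 1, 2, 2], n_states=3)
        identity = gm.TransitionModel(
            counts=np.eye(3), P1=np.eye(3), marginals=np.full(3, 1 / 3),
            states=tm.states,
        )
        assert gm.forecast_state(identity, [(1, 1)]).predicted_state == 1

    def test_uniform_tie_breaks_to_higher_state(self):
        uniform = gm.TransitionModel(
            counts=np.ones((2, 2)), P1=np.full((2, 2), 0.5),
            marginals=np.array([0.5, 0.5]), states=np.array([0, 1]),
        )
        fc = gm.forecast_state(uniform, [(0, 1), (1, 2)])
        assert fc.tie
        assert fc.predicted_state == 1

    def test_summed_vector_matches_hand_computation(self):
        P1 = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.2, 0.2, 0.6]])
        tm = gm.TransitionModel(
            counts=P1 * 10, P1=P1, marginals=np.array([0.3, 0.4, 0.3]),
            states=np.zeros(2, dtype=int),
        )
        fc = gm.forecast_state(tm, [(2, 1), (1, 2), (0, 3)])
        expected = P1[2] + (P1 @ P1)[1] + (P1 @ P1 @ P1)[0]
        assert np.allclose(fc.summed, expected)
        assert fc.predicted_state == int(np.argmax(expected))

    def test_invalid_step_rejected(self):
        tm = gm.estimate_transitions([0, 1, 0, 1])
        with pytest.raises(InvalidSeriesError):
            gm.forecast_state(tm, [(0, 0)])


class TestReviseForecast:
    def test_study_worked_example(self):
        assert gm.revise_forecast(19.12, (1.0133, 1.0561)) == pytest.approx(19.78, abs=0.005)

    def test_symmetric_interval_about_one_is_identity(self):
        assert gm.revise_forecast(100.0, (0.9, 1.1)) == pytest.approx(100.0)

    @given(
        st.floats(min_value=0.1, max_value=100.0),
        st.floats(min_value=0.8, max_value=0.99),
        st.floats(min_value=1.0, max_value=1.2),
    )
    def test_revision_stays_within_interval_bounds(self, value, q1, q2):
        revised = gm.revise_forecast(value, (q1, q2))
        assert q1 * value <= revised <= q2 * value


def test_hybrid_fitted_uses_own_state_midpoint():
    series, _, _ = gm.generate(gm.GeneratorConfig(seed=11))
    model = gm.fit_gm11(gm.ObservedSeries(series.labels[:10], series.values[:10]))
    ratios = gm.ratio_series(model)
    part = gm.partition_states(ratios, n_states=3)
    states = gm.assign_states(ratios, part)
    hybrid = gm.hybrid_fitted(model, part)
    assert np.allclose(hybrid, model.fitted * part.midpoints[states])
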