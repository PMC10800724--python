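"""Prospect utility, value updating, softmax choice, and forward simulation."""

import decimal
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from insightrl.bandit import make_standard_schedule
from insightrl.model import (
    AgentState,
    ModelParameters,
    advantageous_accuracy,
    choice_probabilities,
    prospect_utility,
    replay,
    simulate_agent,
    tab_performance,
    traces_to_frame,
    update_q,
)

from conftest import sample_sane_params


def high_precision_power(base: float, exponent: float) -> float:
    """Independent closed-form oracle: base**exponent at 50-digit precision."""
    decimal.getcontext().prec = 50
    b = decimal.Decimal(base)
    e = decimal.Decimal(exponent)
    return float((e * b.ln()).exp())


class TestProspectUtility:
    def test_exponent_one_identities(self):
        p = ModelParameters(beta=1, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.5, lam=1)
        assert prospect_utility(10, p) == 10.0
        assert prospect_utility(-10, p) == -10.0

    def test_loss_aversion_scales_losses(self):
        p = ModelParameters(beta=1, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.5, lam=2)
        assert prospect_utility(-10, p) == -20.0

    def test_zero_reward_maps_to_zero(self, typical_params):
        assert prospect_utility(0, typical_params) == 0.0

    def test_matches_high_precision_closed_form_at_cohort_means(self):
        p = ModelParameters(beta=0.85, mu=0.48, nu=0.52, alpha_pos=0.42,
                            alpha_neg=0.59, lam=0.51)
        assert prospect_utility(10, p) == pytest.approx(
            high_precision_power(10, 0.48), rel=1e-12
        )
        assert prospect_utility(-10, p) == pytest.approx(
            -0.51 * high_precision_power(10, 0.52), rel=1e-12
        )

    def test_negative_shape_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(beta=1, mu=-0.1, nu=1, alpha_pos=0.5, alpha_neg=0.5, lam=1)
        with pytest.raises(ValueError):
            ModelParameters(beta=1, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.5, lam=-1)

    @given(r=st.floats(0.01, 1000), mu=st.floats(0.01, 2), lam=st.floats(0.01, 5))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_odd_symmetry_when_curvatures_match_and_lam_one(self, r, mu, lam):
        p_sym = ModelParameters(beta=1, mu=mu, nu=mu, alpha_pos=0.5, alpha_neg=0.5, lam=1)
        assert prospect_utility(-r, p_sym) == pytest.approx(-prospect_utility(r, p_sym), rel=1e-12)
        # losses strictly decreasing in lam
        p_lam = ModelParameters(beta=1, mu=mu, nu=mu, alpha_pos=0.5, alpha_neg=0.5, lam=lam)
        p_lam2 = ModelParameters(beta=1, mu=mu, nu=mu, alpha_pos=0.5, alpha_neg=0.5, lam=lam + 1)
        assert prospect_utility(-r, p_lam2) < prospect_utility(-r, p_lam)

    @given(r1=st.floats(0.01, 100), r2=st.floats(0.01, 100), mu=st.floats(0.05, 2))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_strictly_increasing_on_gains(self, r1, r2, mu):
        if r1 == r2:
            return
        lo, hi = sorted((r1, r2))
        p = ModelParameters(beta=1, mu=mu, nu=1, alpha_pos=0.5, alpha_neg=0.5, lam=1)
        assert prospect_utility(lo, p) < prospect_utility(hi, p)


class TestUpdateQ:
    def test_zero_delta_zero_phi_leaves_q_unchanged(self):
        p = ModelParameters(beta=1, mu=1, nu=1, alpha_pos=0.3, alpha_neg=0.7, lam=1, phi=0)
        state = AgentState({"right": 0.0, "left": 0.0})
        new, trace = update_q(state, "right", utility=0.0, params=p)
        assert new.q_values == {"right": 0.0, "left": 0.0}
        assert trace.delta == 0.0

    def test_positive_branch_hand_value(self):
        p = ModelParameters(beta=1, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.9, lam=1, phi=0)
        state = AgentState({"right": 0.0, "left": 3.0})
        new, trace = update_q(state, "right", utility=10.0, params=p)
        assert new.q_values["right"] == 5.0
        assert new.q_values["left"] == 3.0
        assert trace.delta == 10.0

    def test_negative_branch_with_phi_hand_value(self):
        # q_chosen = 2 + 0.25*(-12) + 1 = 0
        p = ModelParameters(beta=1, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.25, lam=1, phi=1)
        state = AgentState({"right": 2.0, "left": -1.0})
        new, trace = update_q(state, "right", utility=-10.0, params=p)
        assert new.q_values["right"] == 0.0
        assert new.q_values["left"] == -1.0
        assert trace.delta == -12.0

    def test_delta_equal_zero_takes_positive_branch(self):
        # with phi != 0 the branches differ only via alpha; delta=0 must use alpha_pos
        p = ModelParameters(beta=1, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.9, lam=1, phi=2)
        state = AgentState({"right": 0.0, "left": 0.0})
        new, trace = update_q(state, "right", utility=0.0, params=p)
        assert trace.delta == 0.0
        assert new.q_values["right"] == 2.0  # 0 + alpha*0 + phi

    def test_unknown_box_raises(self, typical_params):
        state = AgentState({"right": 0.0, "left": 0.0})
        with pytest.raises(KeyError):
            update_q(state, "top", 1.0, typical_params)

    def test_trace_delta_consistency(self, typical_params):
        state = AgentState({"right": 1.5, "left": -0.5})
        _, trace = update_q(state, "left", utility=3.0, params=typical_params)
        assert trace.delta == trace.utility - trace.q_before[1]


class TestChoiceProbabilities:
    def test_equal_values_give_half(self):
        state = AgentState({"right": 3.7, "left": 3.7})
        p = choice_probabilities(state, beta=4.2)
        assert p["right"] == pytest.approx(0.5, abs=1e-14)

    def test_beta_zero_is_uniform(self):
        state = AgentState({"right": 100.0, "left": -40.0})
        p = choice_probabilities(state, beta=0.0)
        assert p == {"right": 0.5, "left": 0.5}

    def test_unit_gap_closed_form(self):
        state = AgentState({"right": 1.0, "left": 0.0})
        p = choice_probabilities(state, beta=1.0)
        assert p["right"] == pytest.approx(math.e / (math.e + 1), rel=1e-14)
        assert p["right"] == pytest.approx(0.7310585786300049, rel=1e-12)

    def test_non_finite_values_raise(self):
        with pytest.raises(FloatingPointError):
            choice_probabilities(AgentState({"right": np.nan, "left": 0.0}), beta=1.0)

    @given(
        qr=st.floats(-1e6, 1e6),
        ql=st.floats(-1e6, 1e6),
        beta=st.floats(0.0, 50.0),
    )
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_softmax_sums_to_one_and_is_positive(self, qr, ql, beta):
        p = choice_probabilities(AgentState({"right": qr, "left": ql}), beta)
        assert p["right"] + p["left"] == pytest.approx(1.0, abs=1e-12)
        assert p["right"] >= 0.0 and p["left"] >= 0.0


class TestSimulation:
    def test_session_has_exactly_100_trials(self, typical_params, standard_schedule):
        record, traces = simulate_agent(typical_params, standard_schedule, seed=5)
        assert len(record) == 100
        assert len(traces) == 100

    def test_seeded_reproducibility(self, typical_params, standard_schedule):
        r1, _ = simulate_agent(typical_params, standard_schedule, seed=77)
        r2, _ = simulate_agent(typical_params, standard_schedule, seed=77)
        np.testing.assert_array_equal(r1.choices, r2.choices)
        np.testing.assert_array_equal(r1.rewards, r2.rewards)

    def test_beta_zero_agent_chooses_at_random(self, standard_schedule):
        p = ModelParameters(beta=0, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.5, lam=1)
        freqs = []
        for seed in range(200):
            rec, _ = simulate_agent(p, standard_schedule, seed=seed, collect_traces=False)
            freqs.append((rec.choices == 0).mean())
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.03)

    def test_exploitation_beats_random_choice(self, standard_schedule):
        greedy = ModelParameters(beta=10, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.5, lam=1)
        random_p = ModelParameters(beta=0, mu=1, nu=1, alpha_pos=0.5, alpha_neg=0.5, lam=1)
        acc = {"greedy": [], "random": []}
        for seed in range(800):
            for label, params in (("greedy", greedy), ("random", random_p)):
                rec, _ = simulate_agent(params, standard_schedule, seed=10_000 + seed,
                                        collect_traces=False)
                acc[label].append(advantageous_accuracy(rec, standard_schedule))
        assert np.mean(acc["greedy"]) > np.mean(acc["random"])

    def test_replay_reproduces_simulated_traces_exactly(self, standard_schedule):
        rng = np.random.default_rng(31)
        for _ in range(5):
            params = sample_sane_params(rng)
            record, traces = simulate_agent(params, standard_schedule, seed=int(rng.integers(1 << 30)))
            replayed = replay(record, params)
            for a, b in zip(traces, replayed):
                assert a == b

    def test_replay_matches_scalar_update_q_path(self, standard_schedule):
        rng = np.random.default_rng(13)
        params = sample_sane_params(rng)
        record, _ = simulate_agent(params, standard_schedule, seed=99)
        traces = replay(record, params)
        state = AgentState.initial()
        for trace, choice, reward in zip(traces, record.choices, record.rewards):
            utility = prospect_utility(reward, params)
            state, step = update_q(state, "right" if choice == 0 else "left", utility, params)
            assert step.q_after[0] == pytest.approx(trace.q_after[0], abs=1e-12)
            assert step.q_after[1] == pytest.approx(trace.q_after[1], abs=1e-12)
            assert step.choice_prob_right == pytest.approx(trace.choice_prob_right, abs=1e-12)

    def test_chosen_q_contracts_into_utility_range(self, standard_schedule):
        # with phi = 0 the chosen-box value never leaves [min U, max U] once inside
        rng = np.random.default_rng(5)
        for _ in range(5):
            base = sample_sane_params(rng)
            params = ModelParameters(**{**base.__dict__, "phi": 0.0})
            record, traces = simulate_agent(params, standard_schedule, seed=int(rng.integers(1 << 30)))
            u_lo = prospect_utility(-10, params)
            u_hi = prospect_utility(10, params)
            inside = {"right": False, "left": False}
            for trace, choice in zip(traces, record.choices):
                box = "right" if choice == 0 else "left"
                q = trace.q_after[choice]
                if inside[box]:
                    assert u_lo - 1e-9 <= q <= u_hi + 1e-9
                elif u_lo <= q <= u_hi:
                    inside[box] = True

    def test_label_symmetry(self, standard_schedule):
        rng = np.random.default_rng(21)
        params = sample_sane_params(rng)
        record, traces = simulate_agent(params, standard_schedule, seed=55)
        flipped = record.relabeled()
        assert tab_performance(flipped) == tab_performance(record)
        replayed = replay(flipped, params)
        for orig, flip in zip(traces, replayed):
            assert flip.choice_prob_right == pytest.approx(1.0 - orig.choice_prob_right, abs=1e-12)
            assert flip.q_after == (orig.q_after[1], orig.q_after[0])


class TestTabPerformance:
    def test_reward_sum_example(self):
        from insightrl.bandit import BehavioralRecord

        record = BehavioralRecord("x", np.array([0, 1, 0]), np.array([10.0, 10.0, -10.0]))
        assert tab_performance(record) == 10.0

    def test_bounds_and_cancellation(self):
        from insightrl.bandit import BehavioralRecord

        all_wins = BehavioralRecord("w", np.zeros(100, dtype=int), np.full(100, 10.0))
        assert tab_performance(all_wins) == 1000.0
        alternating = BehavioralRecord(
            "a", np.zeros(10, dtype=int), np.tile([10.0, -10.0], 5)
        )
        assert tab_performance(alternating) == 0.0

    def test_empty_record_rejected(self):
        from insightrl.bandit import BehavioralRecord

        with pytest.raises(ValueError):
            tab_performance(BehavioralRecord("e", np.array([], dtype=int), np.array([])))

    def test_traces_frame_columns(self, typical_params, standard_schedule):
        _, traces = simulate_agent(typical_params, standard_schedule, seed=2)
        frame = traces_to_frame(traces)
        assert list(frame.columns) == ["trial", "delta", "utility", "q_right", "q_left", "p_right"]
        assert len(frame) == 100
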