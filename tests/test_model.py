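import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pporl import (AgentState, ORLParams, SubjectData, TrialRecord,
                   play_probability, simulate_agent, subject_log_likelihood,
                   update_state)
from pporl.orl import ModelError, subject_arrays
from pporl._kernels import cohort_loglik_grad
from oracles import random_trial_sequence, reference_log_likelihood


def make_subject(trials, subject_id="t"):
    recs = tuple(TrialRecord(i + 1, d, c, o)
                 for i, (d, c, o) in enumerate(trials))
    return SubjectData(subject_id, recs)


class TestPlayProbability:
    def test_zero_value_is_even_odds(self):
        assert play_probability(0.0) == 0.5

    def test_saturation(self):
        assert play_probability(20.0) == pytest.approx(1.0, abs=1e-8)
        assert play_probability(-20.0) == pytest.approx(0.0, abs=1e-8)

    def test_reference_bias_value(self):
        # state-zero play probability at a response bias of 1.22
        assert play_probability(1.22) == pytest.approx(0.772, abs=5e-4)

    def test_nonfinite_value_rejected(self):
        with pytest.raises(ModelError):
            play_probability(float("nan"))

    def test_monotone_in_bias_and_deck_value(self):
        state = AgentState(ev=(0.5, 0.0, 0.0, 0.0), ef=(0.2, 0, 0, 0))
        probs = [play_probability(state.play_value(
            "A", ORLParams(0.2, 0.2, 1.0, bb))) for bb in (-1, 0, 1, 2)]
        assert probs == sorted(probs) and len(set(probs)) == 4
        base = ORLParams(0.2, 0.2, 1.0, 0.0)
        by_ev = [play_probability(
            AgentState(ev=(ev, 0, 0, 0), ef=(0, 0, 0, 0)).play_value("A", base))
            for ev in (-1.0, 0.0, 1.0, 2.0)]
        assert by_ev == sorted(by_ev) and len(set(by_ev)) == 4


class TestUpdateState:
    def test_pass_leaves_state_untouched_for_any_parameters(self):
        state = AgentState(ev=(1.0, -2.0, 0.3, 0.0), ef=(0.5, -0.5, 0.1, 0.0))
        for params in (ORLParams(0.1, 0.9, -3.0, 2.0),
                       ORLParams(0.9, 0.1, 3.0, -2.0)):
            assert update_state(state, "B", 0, None, params) == state

    def test_gain_updates_played_deck_ev_with_reward_rate(self):
        params = ORLParams(0.3, 0.09, 1.0, 0.0)
        new = update_state(AgentState(), "B", 1, 1.0, params)
        assert new.ev[1] == pytest.approx(0.3)
        assert new.ef[1] == pytest.approx(0.3)  # toward sgn(+1)

    def test_fictive_update_moves_other_decks_with_punishment_rate(self):
        params = ORLParams(0.3, 0.09, 1.0, 0.0)
        new = update_state(AgentState(), "B", 1, 1.0, params)
        for other in (0, 2, 3):  # decks A, C, D
            assert new.ef[other] == pytest.approx(0.09 * (-1.0 / 3.0))
        assert new.ev[0] == 0.0  # EV has no fictive update

    def test_loss_swaps_learning_rate_roles(self):
        params = ORLParams(0.3, 0.09, 1.0, 0.0)
        new = update_state(AgentState(), "A", 1, -2.0, params)
        assert new.ev[0] == pytest.approx(0.09 * -2.0)
        assert new.ef[0] == pytest.approx(0.09 * -1.0)
        assert new.ef[1] == pytest.approx(0.3 * (1.0 / 3.0))

    def test_zero_outcome_takes_gain_branch_with_zero_sign(self):
        params = ORLParams(0.5, 0.25, 1.0, 0.0)
        state = AgentState(ev=(0, 0, 1.0, 0), ef=(0.2, 0, 0.8, -0.4))
        new = update_state(state, "C", 1, 0.0, params)
        assert new.ev[2] == pytest.approx(0.5)   # decays toward x = 0
        assert new.ef[2] == pytest.approx(0.4)   # decays toward sgn(0) = 0
        assert new.ef[0] == pytest.approx(0.2 * 0.75)  # fictive target 0

    def test_outcome_on_pass_and_unknown_deck_rejected(self):
        params = ORLParams(0.3, 0.3, 0.0, 0.0)
        with pytest.raises(ModelError):
            update_state(AgentState(), "A", 0, 1.0, params)
        with pytest.raises(ModelError):
            update_state(AgentState(), "E", 1, 1.0, params)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_win_frequency_stays_in_unit_band(self, seed, a_rew, a_pun):
        rng = np.random.default_rng(seed)
        params = ORLParams(a_rew, a_pun, 1.0, 0.0)
        state = AgentState()
        for _ in range(60):
            deck = "ABCD"[rng.integers(4)]
            x = float(rng.choice([-11.5, -2.0, 0.0, 0.5, 1.0]))
            state = update_state(state, deck, 1, x, params)
            assert all(-1.0 <= f <= 1.0 for f in state.ef)

    def test_ev_stays_inside_hull_of_observed_outcomes(self, rng):
        params = ORLParams(0.7, 0.6, 0.0, 0.0)
        state = AgentState()
        seen = {d: [0.0] for d in "ABCD"}
        for _ in range(200):
            deck = "ABCD"[rng.integers(4)]
            x = float(rng.choice([-3.0, -0.25, 0.0, 0.5, 1.0]))
            seen[deck].append(x)
            state = update_state(state, deck, 1, x, params)
            j = "ABCD".index(deck)
            assert min(seen[deck]) - 1e-12 <= state.ev[j] <= max(seen[deck]) + 1e-12


class TestSubjectLogLikelihood:
    def test_single_trial_at_zero_state_is_log_half(self):
        params = ORLParams(0.3, 0.3, 1.5, 0.0)
        for choice, outcome in ((0, None), (1, 100.0)):
            subj = make_subject([("A", choice, outcome)])
            assert subject_log_likelihood(subj, params) == pytest.approx(
                math.log(0.5))

    def test_all_pass_subject_never_updates(self):
        params = ORLParams(0.9, 0.9, 5.0, 0.0)
        subj = make_subject([("ABCD"[i % 4], 0, None) for i in range(40)])
        assert subject_log_likelihood(subj, params) == pytest.approx(
            40 * math.log(0.5))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_independent_recursion(self, seed):
        rng = np.random.default_rng(seed)
        trials = random_trial_sequence(rng)
        a_rew, a_pun = rng.uniform(0.02, 0.98, 2)
        beta_f, beta_b = rng.normal(0, 2, 2)
        subj = make_subject([(d, c, o) for d, c, o in trials])
        ours = subject_log_likelihood(
            subj, ORLParams(a_rew, a_pun, beta_f, beta_b))
        ref = reference_log_likelihood(trials, a_rew, a_pun, beta_f, beta_b)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_kernel_agrees_with_stepwise_path(self, rng):
        trials = random_trial_sequence(rng)
        subj = make_subject([(d, c, o) for d, c, o in trials])
        params = ORLParams(0.35, 0.15, 2.5, 0.8)
        deck, choice, outcome = subject_arrays(subj)
        ll, _ = cohort_loglik_grad(deck[None], choice[None], outcome[None],
                                   params.as_array()[None])
        assert ll[0] == pytest.approx(
            subject_log_likelihood(subj, params), abs=1e-10)

    def test_outcome_sequence_mismatch_names_trial(self, task):
        _, _, sequences = task
        deck0 = sequences["B"].outcomes[0]
        subj = make_subject([("B", 1, deck0), ("B", 1, deck0 + 1.0)])
        params = ORLParams(0.3, 0.3, 0.0, 0.0)
        with pytest.raises(ModelError, match="trial 2"):
            subject_log_likelihood(subj, params, sequences)


class TestSimulateAgent:
    def test_extreme_bias_saturates_behaviour(self, task):
        _, schedule, sequences = task
        always = simulate_agent(ORLParams(0.2, 0.2, 0.0, 20.0),
                                schedule, sequences, seed=0)
        assert all(rec.choice == 1 for rec in always.trials)
        never = simulate_agent(ORLParams(0.2, 0.2, 0.0, -20.0),
                               schedule, sequences, seed=0)
        assert all(rec.choice == 0 for rec in never.trials)
        # an all-pass agent assigns its own data near-certain probability
        ll = subject_log_likelihood(never, ORLParams(0.2, 0.2, 0.0, -20.0))
        assert ll / never.n_trials == pytest.approx(0.0, abs=1e-8)

    def test_seed_reproducibility(self, task, mid_params):
        _, schedule, sequences = task
        a = simulate_agent(mid_params, schedule, sequences, seed=42)
        b = simulate_agent(mid_params, schedule, sequences, seed=42)
        assert a == b

    def test_timeouts_are_passes(self, task, mid_params):
        _, schedule, sequences = task
        subj = simulate_agent(mid_params, schedule, sequences, seed=5,
                              timeout_prob=0.5)
        touts = [rec for rec in subj.trials if rec.timeout]
        assert touts and all(rec.choice == 0 for rec in touts)

    def test_high_punishment_rate_depresses_deck_b_after_big_loss(self, task):
        _, schedule, sequences = task
        # deck-B presentation positions 11-20 within the schedule
        b_positions = [t for t, d in enumerate(schedule.presented_deck)
                       if d == "B"][10:20]

        def mean_b_play(a_pun, n=100):
            rates = []
            for s in range(n):
                subj = simulate_agent(ORLParams(0.2, a_pun, 1.0, 1.0),
                                      schedule, sequences, seed=s)
                rates.append(np.mean([subj.trials[t].choice
                                      for t in b_positions]))
            return float(np.mean(rates))

        assert mean_b_play(0.9) < mean_b_play(0.05) - 0.15
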