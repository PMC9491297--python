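"""Single-trial model algebra: worked examples, invariants, and the
equivalence of the compiled engine with the reference operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grlkit import engine
from grlkit.models import (LEFT, RIGHT, AgentState, BeliefState, Params,
                           MODEL_REGISTRY, consistent_hypothesis,
                           expected_reward, get_model,
                           hysteresis_closed_form, hysteresis_update,
                           model_based_q, hmm_posterior_update,
                           hmm_propagate_prior, outcome_update,
                           policy_probabilities, reward_sensitivity,
                           spe_update, state_index, svpe_update)

TOL = 1e-10


class TestPolicy:
    def test_symmetric_values_give_even_odds(self):
        st_ = AgentState()
        p = policy_probabilities(np.array([0.4, 0.4]), st_, Params(tau=0.5))
        assert p == pytest.approx([0.5, 0.5], abs=TOL)

    def test_logistic_evaluation(self):
        # Q(L)=0.75, Q(R)=0.25, tau=0.5 -> P(L) = 1/(1+e^-1)
        st_ = AgentState()
        p = policy_probabilities(np.array([0.75, 0.25]), st_, Params(tau=0.5))
        assert p[LEFT] == pytest.approx(1 / (1 + math.exp(-1)), abs=TOL)

    def test_high_temperature_limit(self):
        st_ = AgentState()
        p = policy_probabilities(np.array([1.0, 0.0]), st_, Params(tau=1e8))
        assert p == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            policy_probabilities(np.zeros(2), AgentState(), Params(tau=0.0))

    def test_shift_invariance(self):
        st_ = AgentState()
        st_.beta_hist[:] = [0.3, -0.2]
        base = policy_probabilities(np.array([0.2, 0.9]), st_,
                                    Params(tau=0.7, beta_R=0.4))
        shifted = policy_probabilities(np.array([0.2, 0.9]) + 50.0, st_,
                                       Params(tau=0.7, beta_R=0.4))
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_dual_systems_mixing(self):
        st_ = AgentState()
        st_.Q[0] = [1.0, 0.0]
        q_mb = np.array([0.0, 1.0])
        p_mf = policy_probabilities(st_.Q[0], st_, Params(tau=0.5, w_MB=0.0),
                                    q_mb=q_mb)
        p_mb = policy_probabilities(st_.Q[0], st_, Params(tau=0.5, w_MB=1.0),
                                    q_mb=q_mb)
        p_mix = policy_probabilities(st_.Q[0], st_, Params(tau=0.5, w_MB=0.5),
                                     q_mb=q_mb)
        assert p_mf[LEFT] > 0.5 > p_mb[LEFT]
        assert p_mix[LEFT] == pytest.approx(0.5, abs=TOL)


class TestStateValueUpdate:
    def test_moves_toward_best_action_value(self):
        st_ = AgentState()
        st_.Q[2] = [0.6, 0.2]
        dv = svpe_update(st_, 2, Params(alpha=0.5))
        assert dv == pytest.approx(0.6, abs=TOL)
        assert st_.V0 == pytest.approx(0.3, abs=TOL)

    def test_matched_prediction_is_silent(self):
        st_ = AgentState()
        st_.V0 = 0.5
        st_.Q[0] = [0.5, 0.1]
        assert svpe_update(st_, 0, Params(alpha=0.9)) == pytest.approx(0.0)
        assert st_.V0 == pytest.approx(0.5)


class TestOutcomeUpdate:
    def test_generalized_update_with_clamp(self):
        # representative fitted parameters; first rewarded trial from Q = 0
        p = Params(alpha=0.318, g_A=-0.710, g_S=-0.808, g_SA=-0.710)
        st_ = AgentState()
        s = state_index(1, "A")
        dq = outcome_update(st_, s, LEFT, 1, p)
        assert dq == pytest.approx(1.0, abs=TOL)
        assert st_.Q[s, LEFT] == pytest.approx(0.318, abs=TOL)
        assert st_.Q[s, RIGHT] == 0.0          # clamped from -0.2258
        s_c = state_index(1, "B")
        assert st_.Q[s_c, LEFT] == 0.0         # clamped from -0.2569
        assert st_.Q[s_c, RIGHT] == pytest.approx(0.808 * 0.710 * 0.318,
                                                  abs=TOL)

    def test_without_generalization_reduces_to_plain_q_learning(self):
        p = Params(alpha=0.4, lambda_elig=0.0)
        st_ = AgentState()
        outcome_update(st_, 0, LEFT, 1, p)
        assert st_.Q[0, LEFT] == pytest.approx(0.4)
        assert np.all(st_.Q.ravel()[1:] == 0.0)

    def test_fully_learned_value_is_stable(self):
        st_ = AgentState()
        st_.Q[0, LEFT] = 1.0
        dq = outcome_update(st_, 0, LEFT, 1, Params(alpha=0.5, g_A=-1.0,
                                                    g_S=-1.0, g_SA=-1.0))
        assert dq == 0.0
        assert st_.Q[0, LEFT] == 1.0

    def test_eligibility_trace_relays_to_preparatory_state(self):
        st_ = AgentState()
        dq = outcome_update(st_, 0, LEFT, 1,
                            Params(alpha=0.4, lambda_elig=0.5))
        assert st_.V0 == pytest.approx(0.5 * 0.4 * 1.0)

    def test_invalid_reward_rejected(self):
        with pytest.raises(ValueError):
            outcome_update(AgentState(), 0, LEFT, 2, Params(alpha=0.5))

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 1),
                              st.integers(0, 1)), min_size=1, max_size=200),
           st.floats(0.05, 1.0), st.floats(-1.0, 0.0), st.floats(-1.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_values_stay_in_unit_interval(self, seq, alpha, g_a, g_s):
        p = Params(alpha=alpha, g_A=g_a, g_S=g_s, g_SA=g_a)
        st_ = AgentState()
        for s, a, r in seq:
            svpe_update(st_, s, p)
            outcome_update(st_, s, a, r, p)
        assert np.all(st_.Q >= 0.0) and np.all(st_.Q <= 1.0)
        assert 0.0 <= st_.V0 <= 1.0

    def test_deterministic_convergence_to_unity(self):
        # one action always rewarded, no generalization: Q -> 1 monotonically
        p = Params(alpha=0.3)
        st_ = AgentState()
        prev = 0.0
        for _ in range(60):
            outcome_update(st_, 0, LEFT, 1, p)
            assert st_.Q[0, LEFT] > prev or st_.Q[0, LEFT] == 1.0
            prev = st_.Q[0, LEFT]
        assert st_.Q[0, LEFT] == pytest.approx(1.0, abs=1e-4)

    def test_full_discriminative_generalization_pattern(self):
        # single rewarded observation with g_A = g_S = -1: only the congruent
        # complementary pair rises; incongruent pairs are driven to zero
        p = Params(alpha=0.5, g_A=-1.0, g_S=-1.0, g_SA=-1.0)
        st_ = AgentState()
        st_.Q[:] = 0.2
        outcome_update(st_, 0, LEFT, 1, p)
        assert st_.Q[0, LEFT] > 0.2
        assert st_.Q[1, RIGHT] > 0.2
        assert st_.Q[0, RIGHT] == 0.0
        assert st_.Q[1, LEFT] == 0.0
        assert np.all(st_.Q[2:] == 0.2)  # other category untouched


class TestHysteresis:
    def test_three_action_history(self):
        p = Params(beta_0=0.2, lambda_beta=0.5)
        st_ = AgentState()
        for a in (LEFT, LEFT, RIGHT):
            hysteresis_update(st_, a, p)
        assert st_.beta_hist[LEFT] == pytest.approx(0.15, abs=TOL)
        assert st_.beta_hist[RIGHT] == pytest.approx(0.2, abs=TOL)

    def test_zero_decay_is_one_back(self):
        p = Params(beta_0=0.4, lambda_beta=0.0)
        st_ = AgentState()
        for a in (RIGHT, RIGHT, LEFT):
            hysteresis_update(st_, a, p)
        assert st_.beta_hist[LEFT] == pytest.approx(0.4)
        assert st_.beta_hist[RIGHT] == 0.0

    def test_zero_magnitude_is_inert(self):
        st_ = AgentState()
        for a in (LEFT, RIGHT, LEFT):
            hysteresis_update(st_, a, Params(beta_0=0.0, lambda_beta=0.9))
        assert np.all(st_.beta_hist == 0.0)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=400),
           st.floats(-1.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_recursion_equals_closed_form(self, actions, beta_0, lam):
        p = Params(beta_0=beta_0, lambda_beta=lam)
        st_ = AgentState()
        for a in actions:
            hysteresis_update(st_, a, p)
        assert st_.beta_hist == pytest.approx(
            hysteresis_closed_form(actions, p), abs=1e-9)


class TestMetastateLearners:
    @pytest.mark.parametrize("state,action,reward,expect", [
        ("A", LEFT, 1, 0), ("A", LEFT, 0, 1),
        ("A", RIGHT, 1, 1), ("A", RIGHT, 0, 0),
        ("B", LEFT, 1, 1), ("B", LEFT, 0, 0),
        ("B", RIGHT, 1, 0), ("B", RIGHT, 0, 1),
    ])
    def test_consistent_hypothesis_case_table(self, state, action, reward,
                                              expect):
        h_hat, h_alt = consistent_hypothesis(state, action, reward)
        assert h_hat == expect
        assert h_alt == 1 - h_hat

    def test_spe_update_from_uniform(self):
        b = BeliefState()
        delta = spe_update(b, 1, 0, Params(alpha_SPE=0.4))
        assert delta == pytest.approx(0.5, abs=TOL)
        assert b.P[0] == pytest.approx([0.7, 0.3], abs=TOL)
        b.check()

    def test_spe_zero_rate_is_inert(self):
        b = BeliefState()
        b.P[0] = [0.6, 0.4]
        spe_update(b, 1, 0, Params(alpha_SPE=0.0))
        assert b.P[0] == pytest.approx([0.6, 0.4])

    def test_spe_certain_belief_is_stable(self):
        b = BeliefState()
        b.P[1] = [1.0, 0.0]
        delta = spe_update(b, 2, 0, Params(alpha_SPE=0.7))
        assert delta == pytest.approx(0.0, abs=TOL)
        assert b.P[1] == pytest.approx([1.0, 0.0])

    def test_hmm_prior_propagation(self):
        b = BeliefState()
        b.P[0] = [0.8, 0.2]
        prior = hmm_propagate_prior(b, 1, Params(theta_1=0.1))
        assert prior == pytest.approx([0.74, 0.26], abs=TOL)

    def test_hmm_zero_reversal_keeps_posterior(self):
        b = BeliefState()
        b.P[0] = [0.9, 0.1]
        assert hmm_propagate_prior(b, 1, Params(theta_1=0.0)) \
            == pytest.approx([0.9, 0.1])

    def test_hmm_full_mixing(self):
        b = BeliefState()
        b.P[0] = [0.95, 0.05]
        assert hmm_propagate_prior(b, 1, Params(theta_1=0.5)) \
            == pytest.approx([0.5, 0.5])

    def test_hmm_bayes_update(self):
        b = BeliefState()
        post = hmm_posterior_update(b, 1, "A", LEFT, 1, Params(theta_0=0.8))
        assert post == pytest.approx([0.8, 0.2], abs=TOL)

    def test_hmm_uninformative_likelihood(self):
        b = BeliefState()
        b.P[0] = [0.3, 0.7]
        post = hmm_posterior_update(b, 1, "A", LEFT, 1, Params(theta_0=0.5))
        assert post == pytest.approx([0.3, 0.7], abs=TOL)

    def test_hmm_certain_prior_stays_certain(self):
        b = BeliefState()
        b.P[0] = [1.0, 0.0]
        post = hmm_posterior_update(b, 1, "A", LEFT, 1, Params(theta_0=0.9))
        assert post[0] == pytest.approx(1.0, abs=1e-9)

    @given(st.lists(st.tuples(st.sampled_from(["A", "B"]),
                              st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=100),
           st.floats(0.5, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_beliefs_stay_normalized(self, obs, th0, th1, a_spe):
        p = Params(theta_0=th0, theta_1=th1, alpha_SPE=a_spe)
        hmm = BeliefState()
        spe = BeliefState()
        for s, a, r in obs:
            hmm_propagate_prior(hmm, 1, p)
            hmm_posterior_update(hmm, 1, s, a, r, p)
            h_hat, _ = consistent_hypothesis(s, a, r)
            spe_update(spe, 1, h_hat, p)
            hmm.check()
            spe.check()

    def test_model_based_q_mapping(self):
        b = BeliefState()
        b.P[0] = [0.7, 0.3]
        assert model_based_q(b, 1, "A", LEFT) == pytest.approx(0.7)
        assert model_based_q(b, 1, "B", RIGHT) == pytest.approx(0.7)
        assert model_based_q(b, 1, "A", RIGHT) == pytest.approx(0.3)
        b.P[1] = [0.5, 0.5]
        assert model_based_q(b, 2, "B", LEFT) == pytest.approx(0.5)

    def test_expected_reward(self):
        b = BeliefState()
        b.P[0] = [1.0, 0.0]
        assert expected_reward(b, 1, "A", LEFT, Params(theta_0=0.8)) \
            == pytest.approx(0.8, abs=TOL)
        b.P[0] = [0.5, 0.5]
        assert expected_reward(b, 1, "A", LEFT, Params(theta_0=0.8)) \
            == pytest.approx(0.5, abs=TOL)
        assert expected_reward(b, 1, "B", LEFT, Params(theta_0=0.5)) \
            == pytest.approx(0.5, abs=TOL)


class TestRewardSensitivity:
    def test_maximal_generalization(self):
        p = Params(alpha=0.5, g_A=-1.0, g_S=-1.0, tau=1.0)
        assert reward_sensitivity(p) == pytest.approx(math.log(2), abs=TOL)

    def test_matched_rate_and_temperature(self):
        p = Params(alpha=0.37, tau=0.37)
        assert reward_sensitivity(p) == pytest.approx(0.0, abs=TOL)

    def test_zero_learning_rate_sentinel(self):
        assert reward_sensitivity(Params(alpha=0.0, tau=1.0)) == -math.inf


class TestRegistry:
    def test_degrees_of_freedom(self):
        expected = {"A0|S0": 5, "A-|S0": 5, "AX|S0": 6, "A0|S+": 5,
                    "A0|S-": 5, "A0|SY": 6, "A-|S+": 5, "A-|S-": 5,
                    "AW|SW": 6, "AX|SY": 7, "AX|SY|Z": 8, "SPE": 5,
                    "SPE+RL": 7, "HMM0": 5, "HMM": 6, "HMM0+RL": 7,
                    "HMM+RL": 8, "hysteresis": 4, "intercept": 1, "chance": 0}
        assert {m: MODEL_REGISTRY[m].df for m in expected} == expected

    def test_unknown_label_lists_valid_models(self):
        with pytest.raises(KeyError, match="AX\\|SY"):
            get_model("nonsense")

    def test_fixed_interaction_weights(self):
        # in fixed-generalization models the interaction coefficient
        # g_S * g_SA equals g_S * g_A
        p = get_model("A-|S+").build_params(
            {"alpha": 0.5, "tau": 1.0, "beta_0": 0.0, "lambda_beta": 0.0,
             "beta_R": 0.0})
        assert p.g_SA == -1.0
        p = get_model("AW|SW").build_params(
            {"alpha": 0.5, "g_S": 0.6, "tau": 1.0, "beta_0": 0.0,
             "lambda_beta": 0.0, "beta_R": 0.0})
        assert p.g_A == 0.0 and p.g_SA == 0.0
        p = get_model("AW|SW").build_params(
            {"alpha": 0.5, "g_S": -0.6, "tau": 1.0, "beta_0": 0.0,
             "lambda_beta": 0.0, "beta_R": 0.0})
        assert p.g_A == pytest.approx(-0.6) and p.g_SA == pytest.approx(-0.6)


class TestEngineEquivalence:
    """The compiled kernel must reproduce the reference single-trial ops."""

    def _reference_nll(self, record, spec, params):
        """Pure-Python replay built directly on the models module."""
        tr = record.trials.reset_index(drop=True)
        st_ = AgentState()
        beliefs = BeliefState()
        nll = 0.0
        prev_run = None
        for _, row in tr.iterrows():
            if row["run"] != prev_run:
                st_.reset_run()
                beliefs.reset_run()
                prev_run = row["run"]
            s = state_index(row["category"], row["state"])
            svpe_update(st_, s, params)
            if spec.mb_system == "HMM":
                hmm_propagate_prior(beliefs, row["category"], params)
            q_mb = None
            if spec.mb_system is not None:
                from grlkit.models import model_based_q_pair
                q_mb = model_based_q_pair(beliefs, row["category"],
                                          row["state"])
            probs = policy_probabilities(st_.Q[s], st_, params, q_mb=q_mb)
            if row["missed"]:
                continue
            a = 0 if row["chosen_action"] == "left" else 1
            nll -= math.log(max(probs[a], 1e-12))
            r = int(row["reward"])
            hysteresis_update(st_, a, params)
            outcome_update(st_, s, a, r, params)
            if spec.mb_system == "SPE":
                h_hat, _ = consistent_hypothesis(row["state"], a, r)
                spe_update(beliefs, row["category"], h_hat, params)
            elif spec.mb_system == "HMM":
                hmm_posterior_update(beliefs, row["category"], row["state"],
                                     a, r, params)
        return nll

    @pytest.mark.parametrize("model_id,values", [
        ("AX|SY", {"alpha": 0.5, "g_A": -0.6, "g_S": -0.4, "tau": 0.4,
                   "beta_0": -0.1, "lambda_beta": 0.5, "beta_R": 0.2}),
        ("SPE", {"alpha_SPE": 0.4, "tau": 0.4, "beta_0": 0.1,
                 "lambda_beta": 0.3, "beta_R": -0.1}),
        ("HMM", {"theta_0": 0.8, "theta_1": 0.1, "tau": 0.4, "beta_0": 0.0,
                 "lambda_beta": 0.0, "beta_R": 0.0}),
        ("HMM0+RL", {"alpha": 0.4, "theta_0": 0.75, "w_MB": 0.6, "tau": 0.5,
                     "beta_0": 0.05, "lambda_beta": 0.4, "beta_R": 0.0}),
    ])
    def test_kernel_matches_reference(self, grl_record, model_id, values):
        spec = get_model(model_id)
        params = spec.build_params(values)
        arrays = engine.encode_session_arrays(grl_record.trials)
        chosen, reward = engine.encode_choices(grl_record.trials)
        fast = engine.replay_nll(arrays, chosen, reward, spec, params)
        slow = self._reference_nll(grl_record, spec, params)
        assert fast == pytest.approx(slow, abs=1e-8)


class TestNestingEquivalences:
    """Degenerate parameter settings must reproduce nested models exactly."""

    def _nll(self, record, model_id, values):
        spec = get_model(model_id)
        params = spec.build_params(values)
        arrays = engine.encode_session_arrays(record.trials)
        chosen, reward = engine.encode_choices(record.trials)
        return engine.replay_nll(arrays, chosen, reward, spec, params)

    @pytest.mark.parametrize("seed", range(20))
    def test_nested_models_bit_for_bit(self, seed, default_session):
        from grlkit.simulate import run_agent, sample_params
        rng = np.random.default_rng(seed)
        rec = run_agent(default_session, "AX|SY",
                        sample_params("AX|SY", rng), seed=rng)
        policy = {"tau": float(rng.uniform(0.2, 1.0)),
                  "beta_0": float(rng.uniform(-0.3, 0.3)),
                  "lambda_beta": float(rng.uniform(0, 1)),
                  "beta_R": float(rng.uniform(-0.3, 0.3))}
        alpha = float(rng.uniform(0.1, 0.9))
        # AX|SY at g_A = g_S = 0 is plain RL
        assert self._nll(rec, "AX|SY",
                         {"alpha": alpha, "g_A": 0.0, "g_S": 0.0, **policy}) \
            == self._nll(rec, "A0|S0", {"alpha": alpha, **policy})
        # AX|SY|Z at g_SA = g_A is the 7-parameter model
        g_a, g_s = float(rng.uniform(-1, 0)), float(rng.uniform(-1, 1))
        assert self._nll(rec, "AX|SY|Z",
                         {"alpha": alpha, "g_A": g_a, "g_S": g_s,
                          "g_SA": g_a, **policy}) \
            == self._nll(rec, "AX|SY",
                         {"alpha": alpha, "g_A": g_a, "g_S": g_s, **policy})
        # HMM at theta_1 = 0 is HMM0
        th0 = float(rng.uniform(0.55, 0.95))
        assert self._nll(rec, "HMM", {"theta_0": th0, "theta_1": 0.0,
                                      **policy}) \
            == self._nll(rec, "HMM0", {"theta_0": th0, **policy})
        # dual systems at w = 0 / w = 1 are the pure components
        a_spe = float(rng.uniform(0.1, 0.9))
        assert self._nll(rec, "SPE+RL",
                         {"alpha": alpha, "alpha_SPE": a_spe, "w_MB": 0.0,
                          **policy}) \
            == self._nll(rec, "A0|S0", {"alpha": alpha, **policy})
        assert self._nll(rec, "SPE+RL",
                         {"alpha": alpha, "alpha_SPE": a_spe, "w_MB": 1.0,
                          **policy}) \
            == self._nll(rec, "SPE", {"alpha_SPE": a_spe, **policy})
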