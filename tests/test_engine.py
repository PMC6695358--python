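"""Unit and property tests for the discrete active-inference engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oculopharm.engine import (GenerativeModel, Precisions, action_marginal,
                               apply_precision, expected_free_energy_batch,
                               infer_states, infer_states_batch,
                               policy_posterior, sample_action, softmax,
                               update_precision)

from conftest import brute_force_marginals, single_factor_toy

positive_cols = arrays(float, (3, 4),
                       elements=st.floats(1e-3, 1.0)).map(
    lambda x: x / x.sum(axis=0, keepdims=True))


class TestApplyPrecision:
    def test_identity_at_one(self):
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        np.testing.assert_allclose(apply_precision(A, 1.0), A, atol=1e-12)

    def test_zero_precision_flattens(self):
        A = np.array([[0.9, 0.2], [0.1, 0.8]])
        np.testing.assert_allclose(apply_precision(A, 0.0), 0.5, atol=1e-12)

    def test_hand_oracle_square(self):
        # squaring [0.8, 0.2] and renormalising: 0.64/0.68, 0.04/0.68
        out = apply_precision(np.array([[0.8], [0.2]]), 2.0)
        np.testing.assert_allclose(out[:, 0], [0.941, 0.059], atol=1e-3)

    def test_infinite_limit_one_hot(self):
        A = np.array([[0.6, 0.1], [0.3, 0.2], [0.1, 0.7]])
        out = apply_precision(A, 200.0)
        np.testing.assert_allclose(out, np.array([[1, 0], [0, 0], [0, 1]]),
                                   atol=1e-9)

    def test_negative_precision_rejected(self):
        with pytest.raises(ValueError):
            apply_precision(np.array([[1.0], [0.0]]), -0.5)

    @given(positive_cols, st.floats(0.0, 8.0))
    def test_columns_stay_normalised(self, A, prec):
        out = apply_precision(A, prec)
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-9)
        assert (out >= 0).all()


class TestInferStates:
    def test_noiseless_identification(self):
        """Deterministic A and B: one consistent state sequence, one-hot post."""
        A = np.eye(3)
        B = np.zeros((3, 3, 1))
        B[:, :, 0] = np.roll(np.eye(3), 1, axis=0)  # cyclic advance
        model = GenerativeModel(A=[A], B=[B], C=[np.zeros(3)],
                                D=[np.full(3, 1 / 3)],
                                policies=np.zeros((1, 2), int), T=3)
        beliefs, F, conv = infer_states(model, [(0,), (1,), (2,)], [0, 0])
        assert conv
        np.testing.assert_allclose(beliefs[0], np.eye(3), atol=1e-9)

    def test_zero_likelihood_precision_prior_only(self):
        toy = single_factor_toy()
        prec = Precisions(zeta=0.0, omega=1.0)
        res = infer_states_batch(toy, [(0,), (1,)], prec)
        # flattened likelihood carries no information: beliefs follow D and B
        q = res.beliefs[0][0]
        np.testing.assert_allclose(q[0], toy.D[0], atol=1e-6)
        np.testing.assert_allclose(q[1], toy.B[0][:, :, 0] @ toy.D[0], atol=1e-6)

    def test_two_state_exact_bayes(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        B = np.eye(2)[:, :, None]
        model = GenerativeModel(A=[A], B=[B], C=[np.zeros(2)],
                                D=[np.array([0.5, 0.5])],
                                policies=np.zeros((1, 1), int), T=2)
        beliefs, _, _ = infer_states(model, [(0,)], [0])
        np.testing.assert_allclose(beliefs[0][0], [0.9, 0.1], atol=1e-9)

    @pytest.mark.parametrize("outcomes", [[(0,)], [(0,), (2,)], [(1,), (1,), (0,)]])
    @pytest.mark.parametrize("policy", [[0, 0], [0, 1], [1, 1]])
    def test_matches_brute_force_single_factor(self, outcomes, policy):
        toy = single_factor_toy()
        beliefs, _, _ = infer_states(toy, outcomes, policy)
        exact, _ = brute_force_marginals(toy, outcomes, policy)
        np.testing.assert_allclose(beliefs[0], exact[0], atol=1e-3)

    def test_matches_brute_force_two_factors(self):
        """Two factors with per-factor likelihoods: the exact posterior
        factorises, so the structured approximation must recover it."""
        A0 = np.array([[0.8, 0.3], [0.2, 0.7]])[:, :, None] * np.ones((1, 1, 3))
        A1 = np.zeros((3, 2, 3))
        A1[:] = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6]])[:, None, :]
        B0 = np.zeros((2, 2, 2))
        B0[:, :, 0] = np.array([[0.9, 0.2], [0.1, 0.8]])
        B0[:, :, 1] = np.array([[0.1, 0.7], [0.9, 0.3]])
        B1 = np.array([[0.7, 0.2, 0.1], [0.2, 0.7, 0.2], [0.1, 0.1, 0.7]])[:, :, None]
        model = GenerativeModel(A=[A0, A1], B=[B0, B1],
                                C=[np.zeros(2), np.zeros(3)],
                                D=[np.array([0.6, 0.4]), np.full(3, 1 / 3)],
                                policies=np.array([[0, 1], [1, 0]]), T=3)
        outcomes = [(0, 2), (1, 1)]
        for pi, policy in enumerate(model.policies):
            res = infer_states_batch(model, outcomes)
            exact, _ = brute_force_marginals(model, outcomes, policy)
            for f in range(2):
                np.testing.assert_allclose(res.beliefs[f][pi], exact[f], atol=1e-3)

    def test_free_energy_non_increasing(self, task_model):
        prec = Precisions()
        res = infer_states_batch(task_model, [(1, 0, 0, 0), (4, 1, 0, 0)],
                                 prec, track_F=True)
        diffs = np.diff(res.F_trace, axis=0)
        assert (diffs <= 1e-6).all()

    def test_beliefs_normalised(self, task_model):
        res = infer_states_batch(task_model, [(0, 0, 0, 0)], Precisions())
        for q in res.beliefs:
            np.testing.assert_allclose(q.sum(axis=2), 1.0, atol=1e-9)


class TestExpectedFreeEnergy:
    def _simple_model(self, A, C):
        B = np.eye(A.shape[1])[:, :, None]
        return GenerativeModel(A=[A], B=[B], C=[C],
                               D=[np.full(A.shape[1], 1 / A.shape[1])],
                               policies=np.zeros((1, 1), int), T=2)

    def test_zero_when_preferences_match(self):
        model = self._simple_model(np.eye(2), np.zeros(2))
        beliefs = [np.full((1, 2, 2), 0.5)]
        G = expected_free_energy_batch(model, beliefs, 0)
        np.testing.assert_allclose(G, np.log(2) * 0 + (np.log(2) - np.log(2)), atol=1e-9)
        # predicted outcomes [0.5, 0.5] equal softmax(C) = [0.5, 0.5]; A
        # deterministic, so risk = ambiguity = 0
        assert abs(G[0]) < 1e-9

    def test_kl_hand_oracle(self):
        # deterministic A, predicted one-hot vs flat preferences: G = ln 2
        model = self._simple_model(np.eye(2), np.zeros(2))
        beliefs = [np.zeros((1, 2, 2))]
        beliefs[0][:, :, 0] = 1.0
        G = expected_free_energy_batch(model, beliefs, 0)
        np.testing.assert_allclose(G[0], np.log(2), atol=1e-6)

    def test_ambiguity_hand_oracle(self):
        # uniform A column: ambiguity contributes ln 2 per step, risk 0
        A = np.full((2, 2), 0.5)
        model = self._simple_model(A, np.zeros(2))
        beliefs = [np.full((1, 2, 2), 0.5)]
        G = expected_free_energy_batch(model, beliefs, 0)
        np.testing.assert_allclose(G[0], np.log(2), atol=1e-9)


class TestPolicyPosterior:
    def test_gamma_to_zero_uniform(self):
        G = np.array([0.0, 3.0, 7.0])
        post, prior = policy_posterior(np.zeros(3), G, 1e-12)
        np.testing.assert_allclose(prior, 1 / 3, atol=1e-9)
        np.testing.assert_allclose(post, 1 / 3, atol=1e-9)

    def test_softmax_hand_oracle(self):
        post, _ = policy_posterior(np.zeros(2), np.array([0.0, 1.0]), 1.0)
        np.testing.assert_allclose(post, [0.731, 0.269], atol=1e-3)

    def test_zero_temperature_one_hot(self):
        post, _ = policy_posterior(np.zeros(3), np.array([1.0, 0.0, 2.0]), 1e4)
        np.testing.assert_allclose(post, [0, 1, 0], atol=1e-6)

    def test_gamma_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior(np.zeros(2), np.zeros(2), 0.0)

    @given(arrays(float, 4, elements=st.floats(-5, 5)),
           arrays(float, 4, elements=st.floats(-5, 5)),
           st.floats(-10, 10), st.floats(0.05, 5.0))
    def test_shift_invariance(self, F, G, shift, gamma):
        p1, q1 = policy_posterior(F, G, gamma)
        p2, q2 = policy_posterior(F + shift, G + shift, gamma)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        np.testing.assert_allclose(q1, q2, atol=1e-9)


class TestUpdatePrecision:
    def test_no_belief_shift_flat_trace(self):
        G = np.array([1.0, 1.0, 1.0])  # equal G: posterior = prior for flat F
        pu = update_precision(2.0, G, np.zeros(3))
        np.testing.assert_allclose(pu.gamma_trace, 0.5, atol=1e-9)
        assert pu.beta == pytest.approx(2.0)

    def test_commitment_to_good_policy_raises_gamma(self):
        # F concentrates the posterior on the lowest-G policy: dopamine burst
        G = np.array([0.0, 2.0, 2.0])
        F = np.array([0.0, 10.0, 10.0])
        pu = update_precision(1.0, G, F)
        assert pu.beta < 1.0
        assert pu.gamma_trace[-1] > 1.0
        assert np.all(np.diff(pu.gamma_trace) >= -1e-12)

    def test_shift_to_bad_policy_dips_gamma(self):
        G = np.array([0.0, 2.0])
        F = np.array([10.0, 0.0])   # observations favour the high-G policy
        pu = update_precision(1.0, G, F)
        assert pu.beta > 1.0
        assert pu.gamma_trace[-1] < 1.0

    def test_positivity_clip(self):
        # a beta prior below the floor relaxes onto the clip, flagged
        pu = update_precision(0.01, np.array([0.0, 5.0]), np.array([0.0, 30.0]))
        assert pu.beta == pytest.approx(1.0 / 64.0)
        assert pu.clipped

    def test_beta_prior_must_be_positive(self):
        with pytest.raises(ValueError):
            update_precision(0.0, np.zeros(2), np.zeros(2))


class TestActionSampling:
    def test_one_hot_posterior_deterministic(self):
        policies = np.array([[0, 0], [1, 1], [1, 0]])
        pi = np.array([0.0, 1.0, 0.0])
        rng = np.random.default_rng(0)
        assert sample_action(pi, policies, 0, 2, rng) == 1

    def test_counting_marginal(self):
        policies = np.array([[0], [0], [1]])
        marg = action_marginal(np.full(3, 1 / 3), policies, 0, 2)
        np.testing.assert_allclose(marg, [2 / 3, 1 / 3], atol=1e-12)

    def test_seed_determinism(self):
        policies = np.array([[0, 1], [1, 0], [1, 1], [0, 0]])
        pi = softmax(np.array([0.3, 0.1, 0.5, 0.2]))
        seq1 = [sample_action(pi, policies, 0, 2, np.random.default_rng(7))
                for _ in range(5)]
        seq2 = [sample_action(pi, policies, 0, 2, np.random.default_rng(7))
                for _ in range(5)]
        assert seq1 == seq2


def test_model_json_round_trip(task_model):
    clone = GenerativeModel.from_json(task_model.to_json())
    for a, b in zip(task_model.A, clone.A):
        np.testing.assert_allclose(a, b, atol=1e-12)
    for a, b in zip(task_model.B, clone.B):
        np.testing.assert_allclose(a, b, atol=1e-12)
    np.testing.assert_array_equal(task_model.policies, clone.policies)
    assert clone.factor_names == task_model.factor_names
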