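"""Variational/expected free energy: bounds, decompositions, policy posterior."""

import itertools
import math

import numpy as np
import pytest

from imotiv import (BeliefState, Categorical, GenerativeModel, InferenceError,
                    Policy, action_marginal, efe_breakdown, entropy,
                    enumerate_policies, generalized_free_energy,
                    make_random_model, perceptual_posterior, policy_posterior,
                    rollout_policy, variational_free_energy)


def brute_rollout_final(gm, q0, policy):
    """Exhaustive sum over all state paths — the explicit path-sum oracle."""
    n = gm.n_states
    depth = len(policy)
    out = np.zeros(n)
    for path in itertools.product(range(n), repeat=depth + 1):
        p = q0.probs[path[0]]
        for t, u in enumerate(policy):
            p *= gm.transitions[u][path[t + 1], path[t]]
        out[path[-1]] += p
    return out


class TestVariationalFreeEnergy:
    def test_exact_posterior_attains_the_bound(self, random_model):
        gm = random_model(seed=10)
        post = perceptual_posterior(gm, BeliefState(gm.state_prior), 0)
        res = variational_free_energy(gm, post, 0)
        assert res.divergence == pytest.approx(0.0, abs=1e-12)
        assert res.total == pytest.approx(res.surprise, abs=1e-10)

    def test_two_routes_agree_and_bound_holds(self, random_model, rng):
        for seed in range(20):
            gm = random_model(seed=seed)
            for o in range(gm.n_obs):
                for _ in range(5):
                    q = BeliefState(Categorical(rng.dirichlet(np.ones(4))))
                    r = variational_free_energy(gm, q, o)
                    assert r.total == pytest.approx(r.surprise + r.divergence,
                                                    abs=1e-10)
                    assert r.total >= r.surprise - 1e-12

    def test_uniform_everything_is_tight(self):
        n = 3
        gm = GenerativeModel(
            likelihood=np.full((n, n), 1 / n),
            transitions=np.full((2, n, n), 1 / n),
            state_prior=Categorical.uniform(n),
            preference=Categorical.uniform(n))
        r = variational_free_energy(gm, BeliefState(Categorical.uniform(n)), 0)
        assert r.total == pytest.approx(r.surprise, abs=1e-12)

    def test_impossible_observation_reports_infinity(self):
        A = np.array([[1.0, 1.0], [0.0, 0.0]])
        gm = GenerativeModel(A, np.full((2, 2, 2), 0.5),
                             Categorical.uniform(2), Categorical.uniform(2))
        r = variational_free_energy(
            gm, BeliefState(Categorical.uniform(2)), 1)
        assert math.isinf(r.surprise) and not math.isnan(r.total)
        with pytest.raises(InferenceError):
            perceptual_posterior(gm, BeliefState(Categorical.uniform(2)), 1)


class TestPerceptualPosterior:
    def test_identity_likelihood_gives_point_mass(self):
        gm = GenerativeModel(np.eye(3), np.full((2, 3, 3), 1 / 3),
                             Categorical.uniform(3), Categorical.uniform(3))
        post = perceptual_posterior(gm, BeliefState(gm.state_prior), 2)
        assert np.allclose(post.probs, [0, 0, 1])

    def test_uninformative_likelihood_returns_prior(self, rng):
        prior = Categorical(rng.dirichlet(np.ones(4)))
        gm = GenerativeModel(np.full((3, 4), 1 / 3), np.full((2, 4, 4), 0.25),
                             prior, Categorical.uniform(3))
        post = perceptual_posterior(gm, BeliefState(prior), 1)
        assert np.allclose(post.probs, prior.probs, atol=1e-12)

    def test_matches_bruteforce_bayes(self, random_model):
        for seed in range(20):
            gm = random_model(seed=seed)
            o = seed % gm.n_obs
            post = perceptual_posterior(gm, BeliefState(gm.state_prior), o)
            w = np.array([gm.likelihood[o, s] * gm.state_prior.probs[s]
                          for s in range(gm.n_states)])
            assert np.allclose(post.probs, w / w.sum(), atol=1e-12)


class TestRollout:
    def test_deterministic_cycle_returns_to_start(self):
        perm = np.roll(np.eye(3), 1, axis=0)        # s -> s+1 mod 3
        B = np.stack([perm, np.eye(3)])
        gm = GenerativeModel(np.eye(3), B, Categorical.delta(0, 3),
                             Categorical.uniform(3))
        roll = rollout_policy(gm, BeliefState.delta(0, 3), Policy((0, 0, 0)))
        assert np.allclose(roll.q_states[-1].probs, [1, 0, 0])

    def test_uniform_transitions_mix_in_one_step(self, rng):
        n = 4
        gm = GenerativeModel(np.eye(n), np.full((2, n, n), 1 / n),
                             Categorical.delta(0, n), Categorical.uniform(n))
        roll = rollout_policy(gm, BeliefState.delta(0, n), Policy((0, 1)))
        for t in (1, 2):
            assert np.allclose(roll.q_states[t].probs, 1 / n)

    def test_matches_exhaustive_path_sum(self, random_model):
        for seed in range(10):
            gm = random_model(seed=seed)
            q0 = BeliefState(gm.state_prior)
            pol = Policy((0, 1, 0))
            roll = rollout_policy(gm, q0, pol)
            oracle = brute_rollout_final(gm, q0, pol)
            assert np.allclose(roll.q_states[-1].probs, oracle, atol=1e-12)

    def test_obs_prediction_consistent_with_states(self, random_model):
        gm = random_model(seed=3)
        roll = rollout_policy(gm, BeliefState(gm.state_prior), Policy((1, 0)))
        for qs, qo in zip(roll.q_states, roll.q_obs):
            assert np.allclose(qo.probs, gm.likelihood @ qs.probs, atol=1e-12)


class TestEFEBreakdown:
    def test_identity_chain_on_seeded_models(self, random_model):
        """risk+ambiguity = energy−H(s) = −E[log P(o)]−IG, per timestep."""
        for seed in range(30):
            gm = random_model(seed=seed)
            q0 = BeliefState(gm.state_prior)
            for depth in (1, 2, 3):
                for pol in enumerate_policies(gm.n_controls, depth):
                    bd = efe_breakdown(gm, q0, pol)
                    a = bd.risk + bd.ambiguity
                    b = bd.energy - bd.state_entropy
                    c = -bd.expected_log_preference - bd.information_gain
                    assert np.allclose(a, b, atol=1e-10)
                    assert np.allclose(a, c, atol=1e-10)
                    assert np.all(bd.risk >= -1e-12)
                    assert np.all(bd.ambiguity >= -1e-12)
                    assert np.all(bd.information_gain >= -1e-12)

    def test_identity_likelihood_has_zero_ambiguity(self):
        gm = make_random_model(3, 3, 2, seed=4)
        gm = GenerativeModel(np.eye(3), gm.transitions, gm.state_prior,
                             gm.preference)
        bd = efe_breakdown(gm, BeliefState(gm.state_prior), Policy((0, 1)))
        assert np.allclose(bd.ambiguity, 0.0, atol=1e-12)

    def test_uniform_preference_reduces_to_negative_information_gain(
            self, random_model):
        """With flat preferences, G = depth·log|O| − total information gain."""
        for seed in range(10):
            gm = random_model(seed=seed)
            gm = GenerativeModel(gm.likelihood, gm.transitions,
                                 gm.state_prior, Categorical.uniform(gm.n_obs))
            q0 = BeliefState(gm.state_prior)
            depth = 2
            for pol in enumerate_policies(gm.n_controls, depth):
                bd = efe_breakdown(gm, q0, pol)
                assert bd.g_total == pytest.approx(
                    depth * np.log(gm.n_obs) - bd.total_information_gain,
                    abs=1e-10)

    def test_uniform_preference_ranking_matches_information_gain(
            self, random_model):
        gm = random_model(n_states=5, n_obs=4, seed=17)
        gm = GenerativeModel(gm.likelihood, gm.transitions, gm.state_prior,
                             Categorical.uniform(gm.n_obs))
        q0 = BeliefState(gm.state_prior)
        pols = enumerate_policies(gm.n_controls, 3)
        G = [efe_breakdown(gm, q0, p).g_total for p in pols]
        IG = [efe_breakdown(gm, q0, p).total_information_gain for p in pols]
        assert list(np.argsort(G)) == list(np.argsort(-np.asarray(IG)))

    def test_zero_preference_reachable_observation_flags_infinite_risk(self):
        gm = make_random_model(3, 3, 2, seed=5)
        pref = np.array([0.5, 0.5, 0.0])
        gm = GenerativeModel(gm.likelihood, gm.transitions, gm.state_prior,
                             Categorical(pref))
        bd = efe_breakdown(gm, BeliefState(gm.state_prior), Policy((0,)))
        assert bd.infinite_risk_timesteps == (0,)
        assert math.isinf(bd.g_total)


class TestPolicyPosterior:
    def test_equal_efe_gives_uniform(self):
        q = policy_posterior(np.array([1.3, 1.3, 1.3]))
        assert np.allclose(q.probs, 1 / 3)

    def test_hand_computed_softmax(self):
        q = policy_posterior(np.array([0.0, np.log(2)]))
        assert np.allclose(q.probs, [2 / 3, 1 / 3], atol=1e-12)

    def test_shift_invariance(self, rng):
        G = rng.normal(size=6)
        assert np.allclose(policy_posterior(G).probs,
                           policy_posterior(G + 5.0).probs, atol=1e-12)

    def test_infinite_efe_gets_zero_probability(self):
        q = policy_posterior(np.array([0.0, np.inf]))
        assert np.allclose(q.probs, [1.0, 0.0])

    def test_all_infinite_is_an_error(self):
        with pytest.raises(InferenceError, match="no viable|infinite"):
            policy_posterior(np.array([np.inf, np.inf]))


class TestActionMarginal:
    def test_uniform_over_two_first_controls(self):
        pols = [Policy((0, 1)), Policy((1, 0))]
        q = action_marginal(Categorical.uniform(2), pols, 2)
        assert np.allclose(q.probs, [0.5, 0.5])

    def test_shared_first_control_gives_point_mass(self):
        pols = [Policy((2, 0)), Policy((2, 1))]
        q = action_marginal(Categorical.uniform(2), pols, 3)
        assert np.allclose(q.probs, [0, 0, 1])

    def test_matches_bruteforce_grouping(self, rng):
        pols = enumerate_policies(2, 3)
        q_pi = Categorical(rng.dirichlet(np.ones(len(pols))))
        got = action_marginal(q_pi, pols, 2)
        oracle = np.zeros(2)
        for prob, pol in zip(q_pi.probs, pols):   # explicit indicator sum
            oracle[pol.controls[0]] += prob
        assert np.allclose(got.probs, oracle, atol=1e-12)


class TestGeneralizedFreeEnergy:
    def test_uniform_beliefs_constant_efe(self):
        G = np.full(4, 1.7)
        val = generalized_free_energy(Categorical.uniform(4), G)
        assert val == pytest.approx(1.7 - np.log(4), abs=1e-12)

    def test_log_partition_identity_at_softmax(self, rng):
        G = rng.normal(size=5)
        q = policy_posterior(G)
        val = generalized_free_energy(q, G)
        assert val == pytest.approx(-np.log(np.exp(-G).sum()), abs=1e-10)

    def test_softmax_is_the_minimizer(self, rng):
        """No random policy distribution beats softmax(−G)."""
        G = rng.normal(size=4)
        best = generalized_free_energy(policy_posterior(G), G)
        for _ in range(1000):
            q = Categorical(rng.dirichlet(np.ones(4)))
            assert generalized_free_energy(q, G) >= best - 1e-12
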