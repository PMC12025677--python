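"""Variational and expected free energy for discrete generative models.

The planning objects follow the standard discrete active-inference recipe:
a belief over hidden states is rolled forward under an open-loop policy using
the transition model, observations are predicted through the likelihood, and
the expected free energy (EFE) of the policy decomposes per timestep as

    G_t = risk + ambiguity
        = −E[log P(o)] − information gain
        = energy − state entropy          (Helmholtz form)

Risk is the KL divergence from the predicted observation distribution to the
preference distribution P(o); ambiguity is the expected entropy of the
likelihood; the information gain uses the *exact* Bayes inversion of the
rollout predictive, which makes the three decompositions agree to machine
precision — the test suite asserts the full identity chain rather than
assuming it.

The policy posterior is the softmax of negative EFE (temperature fixed at 1),
and is exactly the minimizer of the generalized free energy
``E_q[G] − H(q)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .exceptions import InferenceError
from .genmodel import GenerativeModel, Policy
from .infotheory import Categorical, JointDistribution, entropy, mutual_information

__all__ = [
    "BeliefState", "VFEResult", "PolicyRollout", "EFEBreakdown",
    "variational_free_energy", "perceptual_posterior", "rollout_policy",
    "efe_breakdown", "policy_posterior", "action_marginal", "sample_action",
    "generalized_free_energy",
]


@dataclass(frozen=True)
class BeliefState:
    """A variational belief Q(s) over hidden states."""

    q_states: Categorical

    @classmethod
    def from_probs(cls, probs) -> "BeliefState":
        return cls(Categorical(np.asarray(probs, dtype=float)))

    @classmethod
    def delta(cls, state: int, n_states: int) -> "BeliefState":
        return cls(Categorical.delta(state, n_states))

    @property
    def probs(self) -> np.ndarray:
        return self.q_states.probs


@dataclass(frozen=True)
class VFEResult:
    """Variational free energy and both of its algebraic splits (nats).

    ``total = energy − entropy = surprise + divergence`` up to numerics;
    ``total ≥ surprise`` always, with equality iff the belief is the exact
    posterior.  Impossible observations yield explicit ``inf``, never NaN.
    """

    total: float
    energy: float
    entropy: float
    surprise: float
    divergence: float


def _neg_log(x: np.ndarray) -> np.ndarray:
    """Elementwise −log with −log 0 = +inf (no NaN)."""
    with np.errstate(divide="ignore"):
        return -np.log(x)


def variational_free_energy(
    gm: GenerativeModel, q: BeliefState, o: int
) -> VFEResult:
    """Variational free energy of a belief given an observation.

    ``F = E_q[−log P(s, o)] − H(q)`` with ``P(s, o) = P(o|s) P(s0)``; the
    equivalent decomposition ``F = −log P(o) + KL(q || P(s|o))`` is returned
    alongside.  ``F`` upper-bounds the surprise ``−log P(o)``.
    """
    qs = q.probs
    joint = gm.likelihood[o, :] * gm.state_prior.probs     # P(s, o) over s
    p_o = float(joint.sum())

    nll = _neg_log(joint)
    # 0 * inf := 0 — a belief putting no mass on an impossible state is fine
    terms = np.where(qs > 0, qs * nll, 0.0)
    energy = float(terms.sum())
    h_q = entropy(q.q_states)
    total = energy - h_q

    if p_o > 0:
        surprise = -float(np.log(p_o))
        post = joint / p_o
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(qs > 0, qs / np.where(post > 0, post, 1.0), 1.0)
            div_terms = np.where((qs > 0) & (post == 0), np.inf,
                                 xlogy(qs, ratio))
        divergence = float(div_terms.sum())
    else:
        surprise = np.inf
        divergence = np.inf
    return VFEResult(total=total, energy=energy, entropy=h_q,
                     surprise=surprise, divergence=divergence)


def perceptual_posterior(
    gm: GenerativeModel, prior: BeliefState, o: int
) -> BeliefState:
    """Exact Bayesian state posterior given an observation.

    This is the unconstrained global minimizer of the free energy functional:
    evaluating :func:`variational_free_energy` at the output gives
    ``−log P(o)`` exactly (zero divergence).
    """
    w = gm.likelihood[o, :] * prior.probs
    z = float(w.sum())
    if z <= 0:
        raise InferenceError(
            f"observation {o} has zero marginal likelihood under the prior")
    return BeliefState(Categorical(w / z))


@dataclass(frozen=True)
class PolicyRollout:
    """Forward-predicted beliefs Q(s_t | π) and observations Q(o_t | π).

    Index 0 is the initial belief; index t the belief after applying the
    first t controls of the policy.
    """

    q_states: tuple
    q_obs: tuple
    policy: Policy

    @property
    def depth(self) -> int:
        return len(self.q_states) - 1


def rollout_policy(
    gm: GenerativeModel, q0: BeliefState, policy: Policy
) -> PolicyRollout:
    """Roll the generative model forward under an open-loop policy.

    ``Q(s_t|π)`` is obtained by chaining the control-indexed transition
    matrices from ``Q(s_0)``; ``Q(o_t|π)`` by pushing each state belief
    through the likelihood.  Equivalent to the explicit sum over all state
    paths, at matrix-product cost.
    """
    qs = [np.asarray(q0.probs, dtype=float)]
    for u in policy:
        qs.append(gm.transitions[u] @ qs[-1])
    q_states = tuple(Categorical(v) for v in qs)
    q_obs = tuple(Categorical(gm.likelihood @ v) for v in qs)
    return PolicyRollout(q_states=q_states, q_obs=q_obs, policy=policy)


@dataclass(frozen=True)
class EFEBreakdown:
    """Per-timestep expected-free-energy terms for one policy (nats).

    Arrays are indexed by future timestep t = 1 … depth.  ``g_total`` is the
    policy's total EFE, the sum over timesteps of risk + ambiguity.  Any
    timestep whose predicted observations hit a zero-preference outcome
    carries infinite risk (flagged in ``infinite_risk_timesteps``).
    """

    risk: np.ndarray
    ambiguity: np.ndarray
    expected_log_preference: np.ndarray
    information_gain: np.ndarray
    energy: np.ndarray
    state_entropy: np.ndarray
    policy: Policy = None
    rollout: PolicyRollout = field(default=None, repr=False)

    @property
    def g_total(self) -> float:
        return float(np.sum(self.risk + self.ambiguity))

    @property
    def total_information_gain(self) -> float:
        return float(np.sum(self.information_gain))

    @property
    def infinite_risk_timesteps(self) -> tuple:
        return tuple(int(t) for t in np.flatnonzero(~np.isfinite(self.risk)))


def efe_breakdown(
    gm: GenerativeModel, q0: BeliefState, policy: Policy
) -> EFEBreakdown:
    """Expected free energy of a policy in all three printed decompositions.

    For each future timestep the predicted joint ``Q(o_t, s_t | π) =
    P(o|s) Q(s_t|π)`` is formed and

    * ``risk``      = KL(Q(o_t|π) || P(o)),
    * ``ambiguity`` = E_{Q(s_t|π)} H[P(o|s)],
    * ``expected_log_preference`` = E_{Q(o_t|π)} log P(o),
    * ``information_gain`` = I(s_t; o_t) under the predicted joint (the
      exact-posterior epistemic value),
    * ``energy``    = E[−log(P(o) Q(s_t|o_t, π))] with the exact Bayes
      inversion of the rollout predictive,
    * ``state_entropy`` = H(Q(s_t|π)).

    With uniform preferences the total reduces, up to the constant
    ``depth · log n_obs``, to minus the total information gain.
    """
    roll = rollout_policy(gm, q0, policy)
    A = gm.likelihood
    pref = gm.preference.probs
    h_cols = -xlogy(A, A).sum(axis=0)          # H[P(o|s)] per state
    T = roll.depth
    risk = np.empty(T)
    ambiguity = np.empty(T)
    elp = np.empty(T)
    info = np.empty(T)
    energy = np.empty(T)
    s_ent = np.empty(T)
    for t in range(1, T + 1):
        qs = roll.q_states[t].probs
        J = A * qs[None, :]                    # Q(o, s | π)
        qo = J.sum(axis=1)
        # risk: explicit inf when a reachable observation has zero preference
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.where(qo > 0,
                          np.log(np.where(qo > 0, qo, 1.0))
                          - np.log(np.where(pref > 0, pref, 1.0)), 0.0)
            lr = np.where((qo > 0) & (pref == 0), np.inf, lr)
        risk[t - 1] = float(np.where(qo > 0, qo * lr, 0.0).sum())
        ambiguity[t - 1] = float(h_cols @ qs)
        with np.errstate(divide="ignore"):
            lp = np.log(np.where(pref > 0, pref, 1.0))
            lp = np.where(pref > 0, lp, -np.inf)
        elp[t - 1] = float(np.where(qo > 0, qo * lp, 0.0).sum())
        info[t - 1] = mutual_information(JointDistribution(J))
        # Helmholtz energy against the biased generative P(o) Q(s|o, π)
        with np.errstate(divide="ignore", invalid="ignore"):
            q_s_given_o = np.where(qo[:, None] > 0, J / np.where(
                qo[:, None] > 0, qo[:, None], 1.0), 0.0)
            gen = pref[:, None] * q_s_given_o
            lg = np.where(J > 0, -np.log(np.where(gen > 0, gen, 1.0)), 0.0)
            lg = np.where((J > 0) & (gen == 0), np.inf, lg)
        energy[t - 1] = float(np.where(J > 0, J * lg, 0.0).sum())
        s_ent[t - 1] = entropy(roll.q_states[t])
    return EFEBreakdown(risk=risk, ambiguity=ambiguity,
                        expected_log_preference=elp, information_gain=info,
                        energy=energy, state_entropy=s_ent,
                        policy=policy, rollout=roll)


def policy_posterior(G: np.ndarray) -> Categorical:
    """Policy posterior Q(π) = softmax(−G), temperature 1.

    Policies with infinite EFE receive exactly zero probability.  All-infinite
    input is an error: no viable policy exists.
    """
    G = np.asarray(G, dtype=float)
    finite = np.isfinite(G)
    if not finite.any():
        raise InferenceError("every policy has infinite expected free energy")
    w = np.zeros_like(G)
    shift = G[finite].min()
    w[finite] = np.exp(-(G[finite] - shift))
    return Categorical(w / w.sum())


def action_marginal(
    q_pi: Categorical, policies: list, n_controls: int
) -> Categorical:
    """Marginal over first controls: Q(u_0) = Σ_π 1[π starts with u_0] Q(π)."""
    if len(q_pi) != len(policies):
        raise ValueError("q_pi and policies lengths differ")
    out = np.zeros(n_controls)
    for prob, pol in zip(q_pi.probs, policies):
        out[pol.controls[0]] += prob
    total = out.sum()
    if total > 0:
        out = out / total
    return Categorical(out)


def sample_action(q_u: Categorical, seed: int | np.random.Generator) -> int:
    """Sample a control from the action marginal (explicitly seeded)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return int(rng.choice(len(q_u), p=q_u.probs))


def generalized_free_energy(q_pi: Categorical, G: np.ndarray) -> float:
    """Generalized free energy ``E_q[G] − H(q)`` over policies (nats).

    Exactly minimized by :func:`policy_posterior`, where it equals the
    negative log-partition ``−log Σ_π exp(−G_π)``.  Zero-probability policies
    contribute nothing even when their EFE is infinite.
    """
    G = np.asarray(G, dtype=float)
    q = q_pi.probs
    if q.shape != G.shape:
        raise ValueError("shape mismatch between q_pi and G")
    expected = float(np.where(q > 0, q * G, 0.0).sum())
    return expected - entropy(q_pi)
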