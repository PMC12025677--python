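"""n-step empowerment and its free-energy-style decomposition audit.

Empowerment of a state (or belief) is the channel capacity of the conditional
distribution linking open-loop action sequences to a future observation: each
action sequence is one input symbol of a channel whose output is the
observation (or latent state) at the final step.  The channel is built
exactly by chaining the model's transition matrices and the likelihood;
capacity is computed by Blahut–Arimoto.

The audit operation computes, from the exact joint over (policy, final state,
final observation), every entropy/energy term that appears in the
free-energy-style rewritings of the policy→observation mutual information,
and reports the *residual* of each rewriting rather than asserting it — the
only identity asserted in tests is the standard chain rule
``H(o_T|π) = ambiguity + I(s_T; o_T | π)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .active_inference import BeliefState
from .genmodel import (POLICY_ENUMERATION_CAP, GenerativeModel, MDPSpec,
                       enumerate_policies)
from .infotheory import (CapacityResult, Categorical, Channel,
                         JointDistribution, channel_capacity, entropy,
                         mutual_information)
from .exceptions import ConfigurationError

__all__ = [
    "EmpowermentQuery", "EmpowermentAudit", "action_observation_channel",
    "empowerment_at", "empowerment_map", "empowerment_free_energy_audit",
]


@dataclass(frozen=True)
class EmpowermentQuery:
    """What to compute empowerment of.

    ``start`` is a state index (point-mass belief) or a :class:`BeliefState`;
    ``depth`` the number of action steps; ``use_observations`` selects the
    channel to the final observation (default) versus the final latent state.
    """

    start: int | BeliefState
    depth: int
    use_observations: bool = True

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigurationError("depth must be at least 1")

    def start_belief(self, n_states: int) -> np.ndarray:
        if isinstance(self.start, BeliefState):
            return self.start.probs
        b = np.zeros(n_states)
        b[int(self.start)] = 1.0
        return b


def action_observation_channel(
    gm: GenerativeModel,
    query: EmpowermentQuery,
    cap: int = POLICY_ENUMERATION_CAP,
) -> Channel:
    """The channel from depth-step action sequences to the final observation.

    One row per action sequence, in lexicographic order; the row for a
    sequence is the start belief pushed through the chained transitions and
    (if ``use_observations``) the likelihood.
    """
    policies = enumerate_policies(gm.n_controls, query.depth, cap=cap)
    q0 = query.start_belief(gm.n_states)
    rows = np.empty((len(policies),
                     gm.n_obs if query.use_observations else gm.n_states))
    for i, pol in enumerate(policies):
        q = q0
        for u in pol:
            q = gm.transitions[u] @ q
        rows[i] = gm.likelihood @ q if query.use_observations else q
    return Channel(rows)


def empowerment_at(
    gm: GenerativeModel,
    query: EmpowermentQuery,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> CapacityResult:
    """Empowerment (nats): capacity of the action→observation channel."""
    ch = action_observation_channel(gm, query)
    return channel_capacity(ch, tol=tol, max_iter=max_iter)


def empowerment_map(
    mdp: MDPSpec | None,
    gm: GenerativeModel,
    depth: int,
    tol: float = 1e-9,
    use_observations: bool = True,
) -> np.ndarray:
    """Per-state empowerment: capacity from a point-mass belief on each state.

    Absorbing states score 0 (all channel rows coincide).  The MDP spec, if
    given, is only used for a consistency check on the state count.
    """
    if mdp is not None and mdp.n_states != gm.n_states:
        raise ConfigurationError("MDP and generative model disagree on n_states")
    out = np.empty(gm.n_states)
    for s in range(gm.n_states):
        res = empowerment_at(
            gm, EmpowermentQuery(start=s, depth=depth,
                                 use_observations=use_observations), tol=tol)
        out[s] = res.capacity
    return out


@dataclass(frozen=True)
class EmpowermentAudit:
    """All terms of the free-energy-style rewritings of I(π; o_T), in nats.

    ``residuals`` maps the name of each printed rewriting to the difference
    (left minus right) between the mutual information (or its negation, for
    the free-energy forms) and the combination of terms the rewriting claims;
    ``residuals['chain_rule']`` is the standard identity
    ``H(o_T|π) − ambiguity_T − I(s_T;o_T|π)`` and should vanish numerically.
    """

    mutual_information: float          # I(π; o_T)
    policy_entropy: float              # H(π)
    obs_entropy: float                 # H(o_T)
    conditional_obs_entropy: float     # H(o_T | π)
    final_obs_energy: float            # E[−log P(o_T | s_T)]
    conditional_state_entropy: float   # H(s_T | π)
    ambiguity_T: float                 # E_{Q(s_T)} H[P(o|s_T)]
    state_information_gain: float      # I(π; s_T)
    state_obs_information: float       # I(s_T; o_T | π)
    residuals: dict = field(default_factory=dict)


def empowerment_free_energy_audit(
    gm: GenerativeModel,
    q0: BeliefState,
    depth: int,
    policy_dist: Categorical | None = None,
    cap: int = POLICY_ENUMERATION_CAP,
) -> EmpowermentAudit:
    """Numerically audit the free-energy rewritings of the empowerment MI.

    Builds the exact joint Q(π, s_T, o_T) from a policy distribution (uniform
    over enumerated sequences by default), the chained transitions, and the
    likelihood, then evaluates every term of the printed decompositions.

    The audited rewritings (residuals keyed by name, left minus right):

    * ``eq_mi_policy_entropy``   I(π;o_T) vs H(π) − H(o_T|π)
    * ``eq_mi_obs_entropy``      I(π;o_T) vs H(o_T) − H(o_T|π) (standard)
    * ``eq_fe_double_negative``  −I(π;o_T) vs −H(π) − H(o_T|π)
    * ``eq_fe_helmholtz``        −I(π;o_T) vs E[−log P(o_T|s_T)]
      + H(s_T|π) − H(π)
    * ``eq_fe_state_infogain``   −I(π;o_T) vs ambiguity_T − I(π;s_T)
    * ``chain_rule``             H(o_T|π) vs ambiguity_T + I(s_T;o_T|π)
    """
    policies = enumerate_policies(gm.n_controls, depth, cap=cap)
    n_pi = len(policies)
    q_pi = policy_dist if policy_dist is not None else Categorical.uniform(n_pi)
    if len(q_pi) != n_pi:
        raise ConfigurationError("policy_dist length != number of policies")

    # Q(s_T | π), one row per policy
    S = np.empty((n_pi, gm.n_states))
    for i, pol in enumerate(policies):
        q = np.asarray(q0.probs, dtype=float)
        for u in pol:
            q = gm.transitions[u] @ q
        S[i] = q
    A = gm.likelihood                                     # (o, s)
    joint = q_pi.probs[:, None, None] * S[:, :, None] \
        * A.T[None, :, :]                                 # (π, s, o)

    j_pi_o = joint.sum(axis=1)                            # (π, o)
    j_pi_s = joint.sum(axis=2)                            # (π, s)
    p_s = j_pi_s.sum(axis=0)
    p_o = j_pi_o.sum(axis=0)

    I_pi_o = mutual_information(JointDistribution(j_pi_o))
    I_pi_s = mutual_information(JointDistribution(j_pi_s))
    H_pi = entropy(q_pi)
    H_o = entropy(Categorical(p_o))
    # H(o_T | π) and H(s_T | π), direct conditional sums
    H_o_given_pi = 0.0
    H_s_given_pi = 0.0
    I_s_o_given_pi = 0.0
    for i in range(n_pi):
        w = q_pi.probs[i]
        if w == 0:
            continue
        H_o_given_pi += w * entropy(Categorical(j_pi_o[i] / w))
        H_s_given_pi += w * entropy(Categorical(j_pi_s[i] / w))
        I_s_o_given_pi += w * mutual_information(
            JointDistribution(joint[i] / w))
    h_cols = -xlogy(A, A).sum(axis=0)                     # H[P(o|s)] per s
    ambiguity_T = float(h_cols @ p_s)
    # E[−log P(o_T|s_T)] over the joint
    with np.errstate(divide="ignore", invalid="ignore"):
        nll = np.where(A.T[None, :, :] > 0,
                       -np.log(np.where(A.T[None, :, :] > 0,
                                        A.T[None, :, :], 1.0)), 0.0)
    final_obs_energy = float((joint * nll).sum())

    residuals = {
        "eq_mi_policy_entropy": I_pi_o - (H_pi - H_o_given_pi),
        "eq_mi_obs_entropy": I_pi_o - (H_o - H_o_given_pi),
        "eq_fe_double_negative": (-I_pi_o) - (-H_pi - H_o_given_pi),
        "eq_fe_helmholtz":
            (-I_pi_o) - (final_obs_energy + H_s_given_pi - H_pi),
        "eq_fe_state_infogain": (-I_pi_o) - (ambiguity_T - I_pi_s),
        "chain_rule": H_o_given_pi - (ambiguity_T + I_s_o_given_pi),
    }
    return EmpowermentAudit(
        mutual_information=I_pi_o,
        policy_entropy=H_pi,
        obs_entropy=H_o,
        conditional_obs_entropy=H_o_given_pi,
        final_obs_energy=final_obs_energy,
        conditional_state_entropy=H_s_given_pi,
        ambiguity_T=ambiguity_T,
        state_information_gain=I_pi_s,
        state_obs_information=I_s_o_given_pi,
        residuals=residuals,
    )
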