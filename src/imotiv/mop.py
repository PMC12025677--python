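"""Maximum-occupancy reward, value, and entropy-regularized optimal policies.

The occupancy objective rewards visiting improbable action–state paths: a
trajectory τ scores

    R(τ) = −Σ_t γ^t [ α log π(a_t|s_t) + β log P(s_{t+1}|s_t, a_t) ]

so its expectation under the policy and dynamics is the discounted sum of
α-weighted action entropies and β-weighted transition entropies.  α ≥ 0
weights action-path occupancy; β may be negative, which penalizes stochastic
transitions and steers the agent toward *controllable* states — a practical
approximation to empowerment-seeking.

The optimizing policy is found by soft value iteration: because the α-weighted
action-entropy term makes the per-state inner maximization analytic, the
Bellman backup has the closed Boltzmann form

    Q(s,a) = β H(S'|s,a) + γ E[V(s')],   V(s) = α log Σ_a exp(Q(s,a)/α),

with π*(a|s) ∝ exp(Q(s,a)/α).  The backup is a γ-contraction, so iteration
converges to machine precision for γ < 1.

Absorbing states are deterministic self-loops with a single effective action:
they contribute zero entropy for the rest of time, hence value exactly 0, and
their (ignored) policy row is pinned to the first action.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax, xlogy

from .exceptions import ConfigurationError, ImotivError
from .genmodel import MDPSpec
from .infotheory import NORM_ATOL

__all__ = [
    "MOPParams", "StatePolicy", "Trajectory", "SimulationResult",
    "mop_reward", "mop_value", "mop_optimize", "simulate",
]

_MAX_SWEEPS = 1_000_000


@dataclass(frozen=True)
class MOPParams:
    """Occupancy weights: α on action entropy, β on state entropy, γ discount."""

    alpha: float = 1.0
    beta: float = 0.0
    gamma: float = 0.99

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigurationError("alpha must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ConfigurationError("alpha = 0 requires beta != 0")
        if not (0.0 <= self.gamma < 1.0):
            raise ConfigurationError("gamma must lie in [0, 1)")


@dataclass(frozen=True)
class StatePolicy:
    """A stationary stochastic policy π(a | s), one row per state."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ConfigurationError("StatePolicy.matrix must be 2-D")
        if np.any(m < 0) or np.any(
                np.abs(m.sum(axis=1) - 1.0) > NORM_ATOL * max(1, m.shape[1])):
            raise ConfigurationError("policy rows must be stochastic")
        object.__setattr__(self, "matrix", m)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_actions(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def uniform(cls, n_states: int, n_actions: int) -> "StatePolicy":
        return cls(np.full((n_states, n_actions), 1.0 / n_actions))

    def row_entropies(self) -> np.ndarray:
        return -xlogy(self.matrix, self.matrix).sum(axis=1)


@dataclass(frozen=True)
class Trajectory:
    """A realized (state, action) path; |actions| = |states| − 1."""

    states: np.ndarray
    actions: np.ndarray
    reward: float | None = None

    def __post_init__(self):
        s = np.asarray(self.states, dtype=int)
        a = np.asarray(self.actions, dtype=int)
        if a.size != s.size - 1:
            raise ConfigurationError(
                f"|actions| = {a.size} must equal |states| - 1 = {s.size - 1}")
        object.__setattr__(self, "states", s)
        object.__setattr__(self, "actions", a)

    def __len__(self) -> int:
        return self.actions.size


def _transition_entropies(mdp: MDPSpec) -> np.ndarray:
    """H(S' | s, a) for every (state, action)."""
    T = mdp.transitions
    return -xlogy(T, T).sum(axis=2)


def mop_reward(
    traj: Trajectory, policy: StatePolicy, mdp: MDPSpec, params: MOPParams
) -> float:
    """Discounted occupancy reward of a realized trajectory (nats).

    ``−Σ_t γ^t [α log π(a_t|s_t) + β log P(s_{t+1}|s_t,a_t)]`` with t starting
    at 0.  A term with zero weight (α = 0 or β = 0) is skipped entirely, so
    only probabilities that actually enter the sum must be positive.
    """
    total = 0.0
    g = 1.0
    for t in range(len(traj)):
        s, a, s2 = int(traj.states[t]), int(traj.actions[t]), int(traj.states[t + 1])
        term = 0.0
        if params.alpha != 0:
            p = policy.matrix[s, a]
            if p <= 0:
                raise ImotivError(
                    f"step {t}: action {a} has zero policy probability in state {s}")
            term += params.alpha * np.log(p)
        if params.beta != 0:
            p = mdp.transitions[s, a, s2]
            if p <= 0:
                raise ImotivError(
                    f"step {t}: transition ({s},{a})->{s2} has zero probability")
            term += params.beta * np.log(p)
        total -= g * term
        g *= params.gamma
    return float(total)


def _stopping_threshold(tol: float, gamma: float) -> float:
    # sup-norm change d guarantees distance to fixed point <= d * gamma/(1-gamma)
    return tol * (1.0 - gamma) / max(gamma, 1e-12)


def mop_value(
    mdp: MDPSpec,
    params: MOPParams,
    policy: StatePolicy,
    tol: float = 1e-10,
    return_trace: bool = False,
):
    """Evaluate a policy's occupancy value V^π(s) by fixed-point iteration.

    Iterates ``V ← r + γ Π T V`` where the per-state reward is
    ``r(s) = α H[π(·|s)] + β Σ_a π(a|s) H(S'|s,a)``, until the iterate is
    within ``tol`` of the fixed point (contraction bound).  Absorbing states
    are pinned to 0: with their single effective action they generate no path
    entropy ever.

    Returns ``V`` (and the sup-norm change per sweep when ``return_trace``).
    """
    absorbing = np.array(sorted(mdp.absorbing), dtype=int)
    h_trans = _transition_entropies(mdp)
    pi = policy.matrix
    r = params.alpha * policy.row_entropies() \
        + params.beta * (pi * h_trans).sum(axis=1)
    # P_pi[s, s'] = sum_a pi(a|s) P(s'|s,a)
    P_pi = np.einsum("sa,sat->st", pi, mdp.transitions)
    if absorbing.size:
        r[absorbing] = 0.0
    V = np.zeros(mdp.n_states)
    thresh = _stopping_threshold(tol, params.gamma)
    trace = []
    for _ in range(_MAX_SWEEPS):
        V_new = r + params.gamma * (P_pi @ V)
        if absorbing.size:
            V_new[absorbing] = 0.0
        diff = float(np.max(np.abs(V_new - V)))
        trace.append(diff)
        V = V_new
        if diff < thresh:
            break
    else:
        raise ImotivError("policy evaluation failed to converge "
                          f"within {_MAX_SWEEPS} sweeps")
    if return_trace:
        return V, np.asarray(trace)
    return V


def mop_optimize(
    mdp: MDPSpec,
    params: MOPParams,
    tol: float = 1e-10,
    return_trace: bool = False,
):
    """Soft value iteration for the occupancy-maximizing policy.

    Requires ``α > 0`` (the closed-form Boltzmann improvement uses α as the
    soft-max temperature); for α = 0 use plain value iteration, which is out
    of scope here.  Returns ``(StatePolicy, V)``; re-evaluating the returned
    policy with :func:`mop_value` reproduces ``V`` to within the tolerance.
    """
    if params.alpha <= 0:
        raise ConfigurationError(
            "mop_optimize requires alpha > 0; with alpha = 0 the "
            "soft-max improvement degenerates — use plain value iteration")
    absorbing = np.array(sorted(mdp.absorbing), dtype=int)
    h_trans = _transition_entropies(mdp)
    V = np.zeros(mdp.n_states)
    thresh = _stopping_threshold(tol, params.gamma)
    trace = []
    for _ in range(_MAX_SWEEPS):
        Q = params.beta * h_trans + params.gamma * (mdp.transitions @ V)
        V_new = params.alpha * logsumexp(Q / params.alpha, axis=1)
        if absorbing.size:
            V_new[absorbing] = 0.0
        diff = float(np.max(np.abs(V_new - V)))
        trace.append(diff)
        V = V_new
        if diff < thresh:
            break
    else:
        raise ImotivError("soft value iteration failed to converge "
                          f"within {_MAX_SWEEPS} sweeps")
    Q = params.beta * h_trans + params.gamma * (mdp.transitions @ V)
    pi = softmax(Q / params.alpha, axis=1)
    if absorbing.size:
        pi[absorbing] = 0.0
        pi[absorbing, 0] = 1.0
    result = (StatePolicy(pi), V)
    if return_trace:
        return result + (np.asarray(trace),)
    return result


@dataclass(frozen=True)
class SimulationResult:
    """A sampled trajectory with its occupancy statistics."""

    trajectory: Trajectory
    visit_distribution: np.ndarray   # empirical state-visit frequencies
    visit_entropy: float             # entropy of that distribution (nats)
    reward: float | None = None      # discounted occupancy reward, if params given


def simulate(
    mdp: MDPSpec,
    policy: StatePolicy,
    steps: int,
    seed: int,
    start: int,
    params: MOPParams | None = None,
) -> SimulationResult:
    """Sample an action–state path by alternating policy and dynamics draws.

    Fully determined by ``seed``.  The visit distribution counts all
    ``steps + 1`` visited states (including the start).  When ``params`` is
    given, the trajectory's discounted occupancy reward is computed too.
    """
    if not (0 <= start < mdp.n_states):
        raise ConfigurationError(f"start state {start} out of range")
    rng = np.random.default_rng(seed)
    pol_cum = np.cumsum(policy.matrix, axis=1)
    trans_cum = np.cumsum(mdp.transitions, axis=2)
    u = rng.random((steps, 2))
    states = np.empty(steps + 1, dtype=int)
    actions = np.empty(steps, dtype=int)
    s = int(start)
    states[0] = s
    for t in range(steps):
        a = int(np.searchsorted(pol_cum[s], u[t, 0], side="right"))
        a = min(a, mdp.n_actions - 1)
        s2 = int(np.searchsorted(trans_cum[s, a], u[t, 1], side="right"))
        s2 = min(s2, mdp.n_states - 1)
        actions[t] = a
        states[t + 1] = s2
        s = s2
    traj = Trajectory(states=states, actions=actions)
    counts = np.bincount(states, minlength=mdp.n_states).astype(float)
    visit = counts / counts.sum()
    visit_entropy = float(-xlogy(visit, visit).sum())
    reward = None
    if params is not None:
        reward = mop_reward(traj, policy, mdp, params)
        traj = Trajectory(states=states, actions=actions, reward=reward)
    return SimulationResult(trajectory=traj, visit_distribution=visit,
                            visit_entropy=visit_entropy, reward=reward)
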