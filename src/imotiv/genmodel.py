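"""Discrete generative models, MDPs, and the fixture generators.

Matrix orientation conventions (enforced by :func:`validate_model`):

* ``likelihood`` — observations × states; each **column** is P(o | s).
* ``transitions`` — one matrix per control, next-state × current-state;
  ``transitions[u][s_next, s_cur]`` = P(s_next | s_cur, u), so each column is
  a distribution over next states.
* :class:`MDPSpec` transitions — state × action × next-state;
  ``T[s, a, :]`` is a distribution (the usual reinforcement-learning layout).

The two layouts coexist deliberately: the generative-model form composes by
left matrix multiplication (``q' = B[u] @ q``), the MDP form indexes naturally
by (state, action).  Converters are provided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, EnumerationCapError
from .infotheory import NORM_ATOL, Categorical

#: default cap on exhaustive policy enumeration (n_controls ** depth)
POLICY_ENUMERATION_CAP = 100_000


@dataclass(frozen=True)
class Policy:
    """An open-loop policy: an ordered sequence of control indices."""

    controls: tuple

    def __post_init__(self):
        object.__setattr__(self, "controls", tuple(int(u) for u in self.controls))

    def __len__(self) -> int:
        return len(self.controls)

    def __iter__(self):
        return iter(self.controls)


@dataclass(frozen=True)
class GenerativeModel:
    """A discrete POMDP generative model.

    Fields
    ------
    likelihood
        P(o | s), observations × states (column-stochastic).
    transitions
        Array (n_controls, n_states, n_states); ``transitions[u]`` maps a
        belief over current states to a belief over next states
        (column-stochastic per control).
    state_prior
        P(s0).
    preference
        State-independent preferred distribution P(o) over observations.
        Zero-preference observations are legal but make risk infinite for
        policies that can reach them (flagged, never floored).
    horizon
        Optional default planning depth.
    """

    likelihood: np.ndarray
    transitions: np.ndarray
    state_prior: Categorical
    preference: Categorical
    horizon: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "likelihood",
                           np.asarray(self.likelihood, dtype=float))
        object.__setattr__(self, "transitions",
                           np.asarray(self.transitions, dtype=float))

    @property
    def n_obs(self) -> int:
        return self.likelihood.shape[0]

    @property
    def n_states(self) -> int:
        return self.likelihood.shape[1]

    @property
    def n_controls(self) -> int:
        return self.transitions.shape[0]


@dataclass(frozen=True)
class MDPSpec:
    """A fully observed MDP with optional absorbing states.

    ``transitions[s, a, :]`` is the next-state distribution; absorbing states
    self-loop under every action.  ``labels`` optionally carries grid
    coordinates for gridworld fixtures.
    """

    n_states: int
    n_actions: int
    transitions: np.ndarray
    absorbing: frozenset = frozenset()
    labels: tuple | None = None

    def __post_init__(self):
        T = np.asarray(self.transitions, dtype=float)
        if T.shape != (self.n_states, self.n_actions, self.n_states):
            raise ConfigurationError(
                f"transitions shape {T.shape} != "
                f"({self.n_states}, {self.n_actions}, {self.n_states})"
            )
        object.__setattr__(self, "transitions", T)
        object.__setattr__(self, "absorbing", frozenset(int(s) for s in self.absorbing))
        for s in self.absorbing:
            if not (0 <= s < self.n_states):
                raise ConfigurationError(f"absorbing state {s} out of range")


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_model`."""

    severity: str          # "error" or "warning"
    location: str          # e.g. "transitions[u=1][:, s=3]"
    message: str


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(v.severity == "error" for v in self.violations)

    @property
    def errors(self) -> list:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def warnings(self) -> list:
        return [v for v in self.violations if v.severity == "warning"]

    def __bool__(self) -> bool:
        return self.ok


def _check_stochastic_vector(p: np.ndarray, location: str, out: list) -> None:
    neg = np.flatnonzero(p < 0)
    if neg.size:
        out.append(Violation("error", location,
                             f"negative entries at {neg.tolist()}"))
    s = float(p.sum())
    if abs(s - 1.0) > NORM_ATOL * max(1.0, p.size):
        out.append(Violation("error", location, f"sums to {s!r}, expected 1"))


def validate_model(gm: GenerativeModel) -> ValidationReport:
    """Check every stochasticity and support invariant of a generative model.

    Returns a report listing each violation with its index; the report is
    empty iff the model is valid.  A preference distribution with zero entries
    produces a warning (risk may be infinite), not an error.
    """
    report = ValidationReport()
    v = report.violations
    A, B = gm.likelihood, gm.transitions
    if B.ndim != 3 or B.shape[1] != B.shape[2] or B.shape[1] != A.shape[1]:
        v.append(Violation("error", "transitions",
                           f"shape {B.shape} inconsistent with likelihood {A.shape}"))
        return report
    for s in range(gm.n_states):
        _check_stochastic_vector(A[:, s], f"likelihood[:, s={s}]", v)
    for u in range(gm.n_controls):
        for s in range(gm.n_states):
            _check_stochastic_vector(B[u][:, s], f"transitions[u={u}][:, s={s}]", v)
    _check_stochastic_vector(gm.state_prior.probs, "state_prior", v)
    _check_stochastic_vector(gm.preference.probs, "preference", v)
    if len(gm.preference) != gm.n_obs:
        v.append(Violation("error", "preference",
                           f"length {len(gm.preference)} != n_obs {gm.n_obs}"))
    if len(gm.state_prior) != gm.n_states:
        v.append(Violation("error", "state_prior",
                           f"length {len(gm.state_prior)} != n_states {gm.n_states}"))
    zeros = np.flatnonzero(gm.preference.probs == 0)
    if zeros.size:
        v.append(Violation(
            "warning", "preference",
            f"zero preference for observations {zeros.tolist()}; "
            "risk is infinite for policies reaching them"))
    return report


def validate_mdp(mdp: MDPSpec) -> ValidationReport:
    """Check row-stochasticity and the absorbing-state self-loop contract."""
    report = ValidationReport()
    v = report.violations
    for s in range(mdp.n_states):
        for a in range(mdp.n_actions):
            _check_stochastic_vector(mdp.transitions[s, a],
                                     f"transitions[s={s}, a={a}]", v)
    for s in mdp.absorbing:
        for a in range(mdp.n_actions):
            if abs(mdp.transitions[s, a, s] - 1.0) > NORM_ATOL:
                v.append(Violation(
                    "error", f"transitions[s={s}, a={a}]",
                    "absorbing state must self-loop with probability 1"))
    return report


def mdp_to_transition_tensor(mdp: MDPSpec) -> np.ndarray:
    """Convert MDP (s, a, s') transitions to generative (u, s', s) layout."""
    return np.ascontiguousarray(mdp.transitions.transpose(1, 2, 0))


# gridworld actions, in index order
GRID_ACTIONS = ("up", "down", "left", "right", "stay")
_MOVES = {"up": (-1, 0), "down": (1, 0), "left": (0, -1), "right": (0, 1),
          "stay": (0, 0)}


def make_gridworld(
    width: int,
    height: int,
    absorbing_cells: list | tuple = (),
    slip: float = 0.0,
    observation_noise: float = 0.0,
) -> tuple[MDPSpec, GenerativeModel]:
    """Build a rectangular gridworld with 5 actions (up/down/left/right/stay).

    States are flat indices ``s = row * width + col``.  A move into a wall
    leaves the agent in place.  With probability ``slip`` the intended action
    is replaced by a uniformly random cardinal move (wall-clamped), so row
    sums are exactly one.  Absorbing cells self-loop under every action.

    The observation model is the identity corrupted by ``observation_noise``:
    the true cell keeps ``1 − noise`` and the rest is spread uniformly over
    the other cells.  The preference distribution defaults to uniform, so
    expected free energy is purely epistemic out of the box.
    """
    n = width * height
    if n < 2:
        raise ConfigurationError("grid must have at least 2 cells")
    if not (0.0 <= slip <= 1.0) or not (0.0 <= observation_noise <= 1.0):
        raise ConfigurationError("slip and observation_noise must be in [0, 1]")
    absorbing = []
    for c in absorbing_cells:
        c = int(c)
        if not (0 <= c < n):
            raise ConfigurationError(f"absorbing cell {c} outside the {width}x{height} grid")
        absorbing.append(c)

    def step(s: int, action: str) -> int:
        r, c = divmod(s, width)
        dr, dc = _MOVES[action]
        r2, c2 = r + dr, c + dc
        if 0 <= r2 < height and 0 <= c2 < width:
            return r2 * width + c2
        return s

    T = np.zeros((n, 5, n))
    cardinal = GRID_ACTIONS[:4]
    for s in range(n):
        if s in absorbing:
            T[s, :, s] = 1.0
            continue
        for a, name in enumerate(GRID_ACTIONS):
            T[s, a, step(s, name)] += 1.0 - slip
            for other in cardinal:
                T[s, a, step(s, other)] += slip / 4.0

    mdp = MDPSpec(
        n_states=n, n_actions=5, transitions=T,
        absorbing=frozenset(absorbing),
        labels=tuple(divmod(s, width) for s in range(n)),
    )

    if observation_noise > 0 and n > 1:
        A = np.full((n, n), observation_noise / (n - 1))
        np.fill_diagonal(A, 1.0 - observation_noise)
    else:
        A = np.eye(n)
    gm = GenerativeModel(
        likelihood=A,
        transitions=mdp_to_transition_tensor(mdp),
        state_prior=Categorical.uniform(n),
        preference=Categorical.uniform(n),
    )
    return mdp, gm


def make_random_model(
    n_states: int,
    n_obs: int,
    n_controls: int,
    concentration: float = 1.0,
    seed: int = 0,
) -> GenerativeModel:
    """Sample a random generative model with symmetric-Dirichlet conditionals.

    Every conditional distribution (each likelihood column, each transition
    column, the prior, the preference) is an independent draw from
    ``Dirichlet(concentration, ..., concentration)``.  Reproducible under
    ``seed``.  Large concentrations give near-uniform conditionals.
    """
    if min(n_states, n_obs, n_controls) < 2:
        raise ConfigurationError("all cardinalities must be at least 2")
    if concentration <= 0:
        raise ConfigurationError("concentration must be positive")
    rng = np.random.default_rng(seed)
    A = rng.dirichlet(np.full(n_obs, concentration), size=n_states).T
    B = np.empty((n_controls, n_states, n_states))
    for u in range(n_controls):
        B[u] = rng.dirichlet(np.full(n_states, concentration), size=n_states).T
    prior = Categorical(rng.dirichlet(np.full(n_states, concentration)))
    pref = Categorical(rng.dirichlet(np.full(n_obs, concentration)))
    return GenerativeModel(likelihood=A, transitions=B,
                           state_prior=prior, preference=pref)


def enumerate_policies(
    n_controls: int, depth: int, cap: int = POLICY_ENUMERATION_CAP
) -> list:
    """All control sequences of the given depth, in lexicographic order.

    Raises
    ------
    EnumerationCapError
        If ``n_controls ** depth`` exceeds ``cap`` — reduce the depth.
    """
    count = n_controls ** depth
    if count > cap:
        raise EnumerationCapError(
            f"{n_controls}^{depth} = {count} policies exceeds the cap of "
            f"{cap}; reduce the planning depth")
    return [Policy(seq) for seq in itertools.product(range(n_controls),
                                                     repeat=depth)]


def gridworld_edges(mdp: MDPSpec) -> list:
    """Positive-probability (state, action, next_state, prob) tuples.

    A plain edge list for visual inspection or export; action indices follow
    :data:`GRID_ACTIONS`.
    """
    edges = []
    for s in range(mdp.n_states):
        for a in range(mdp.n_actions):
            for s2 in np.flatnonzero(mdp.transitions[s, a] > 0):
                edges.append((s, a, int(s2), float(mdp.transitions[s, a, s2])))
    return edges
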