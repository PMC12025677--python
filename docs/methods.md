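# Methods

This note documents the models implemented by `imotiv`, the numerical choices
behind them, and the limits of what the test suite demonstrates.

## Scope and conventions

All computations are exact operations on finite categorical distributions.
Quantities are in **nats** throughout; `nats_to_bits` converts for reporting.
The convention `0·log 0 = 0` (and `0·log(0/0) = 0`) is implemented by explicit
masking, never by flooring probabilities with an epsilon: flooring would make
closed-form cases (deterministic channels, point-mass beliefs) inexact and
would silently distort policy rankings when genuine infinities arise.
Infinities are therefore propagated explicitly — an observation with zero
marginal likelihood yields infinite surprise, a zero-preference observation
yields infinite risk, and both are flagged, never NaN.

Matrix orientations are fixed once and enforced by validation: likelihoods are
observations × states (column-stochastic), generative-model transitions are
next-state × current-state per control (so beliefs update by left
multiplication), and MDP transitions are state × action × next-state (the
reinforcement-learning layout). Two layouts coexist because each composes
naturally in its own setting; converters are provided.

## Empowerment

The empowerment of a start state (or belief) at depth *d* is the capacity of
the channel whose inputs are the `n_controls^d` open-loop action sequences
(lexicographic order) and whose outputs are the final observation — or the
final latent state, selectable per query; the two coincide exactly under an
identity likelihood. Rows are built by chaining transition matrices, which
equals the explicit sum over state paths at matrix-product cost.

Capacity is computed by **Blahut–Arimoto** iteration. The stopping rule uses
the classical sandwich `Σ_i p_i D_i ≤ C ≤ max_i D_i` with
`D_i = KL(row_i ‖ pW)`: iteration ends when the gap is below `tol`
(default 1e-9 nats) or at `max_iter` (default 10 000), in which case the
result is returned with `converged=False` and a logged warning. The
lower-bound sequence is monotone non-decreasing and is recorded on the result
for auditing. The reported capacity is the lower bound achieved by the
returned input distribution, so the result is always self-consistent: the
mutual information of (input distribution, channel) *is* the reported number.

An independent cross-check, `grid_search_capacity`, enumerates every input
distribution on a simplex lattice (default spacing 1e-3) for channels with up
to 4 rows; it shares no code path with the solver. Unreachable output columns
are retained rather than pruned so that indices remain stable across modules.

### The free-energy rewriting audit

The mutual information between a policy distribution and the final
observation can be rearranged into free-energy-like forms (an "energy" of the
final observation, a policy entropy, a conditional state entropy, a state
information gain). Some published rearrangements of this kind contain sign
and variable inconsistencies, so the audit operation deliberately **computes
every term from the exact joint Q(π, s_T, o_T) and reports the residual of
each rearrangement instead of asserting it**. The only identities the test
suite asserts to be zero are the standard ones: `I(π;o_T) = H(o_T) −
H(o_T|π)` and the chain rule `H(o_T|π) = ambiguity_T + I(s_T; o_T|π)` (which
holds because the observation is conditionally independent of the policy
given the final state). The default policy distribution for the audit is
uniform over enumerated sequences — the capacity-achieving distribution is a
separate, solver-dependent object and would make residuals depend on solver
tolerance.

## Active inference

Perception is exact: the discrete Bayes posterior is the unconstrained global
minimizer of the variational free energy `F = E_q[−log P(s,o)] − H(q)`, and
evaluating F at it returns `−log P(o)` to machine precision. Both algebraic
splits of F (energy − entropy, and surprise + divergence) are computed
through independent routes and reconciled in tests.

Planning uses open-loop policies (control sequences) up to a depth that is
deliberately decoupled from any model horizon, with an enumeration cap
(default 10^5) that fails loudly: exhaustive enumeration is exponential and
should never be silent. For each policy the belief is rolled forward through
the transition model and observations are predicted through the likelihood.

The per-timestep EFE is computed in three decompositions at once — risk +
ambiguity, −expected-log-preference − information gain, and Helmholtz
energy − state entropy — with the information gain taken from the **exact
Bayes inversion of the rollout predictive**. With the exact inversion the
three decompositions are identical rather than approximately equal, which
turns the usual "≈" into an identity the suite asserts at 1e-10. The
Helmholtz energy is evaluated against the biased generative
`P(o)·Q(s|o,π)`, the construction under which the identity chain is exact.
Where a transcription ambiguity exists in the sign convention of the
expected-utility term, the implementation follows the standard convention
(risk + ambiguity = −E[log P(o)] − information gain) and verifies it
numerically; both sign readings can be recovered from the reported terms.

The policy posterior is `softmax(−G)` with temperature fixed at 1 — the
temperature/precision and habit-prior machinery of fuller treatments is
explicitly out of scope. The generalized free energy `E_q[G] − H(q)` is
provided with the log-partition identity and the minimizer property tested
against random distributions and a simplex grid. Action selection marginalizes
policy probability over first controls; sampling takes an explicit seed, and
every test and experiment uses the deterministic marginal. MAP ties break to
the lowest index.

With a **uniform preference distribution** the EFE reduces, up to the
constant `log |O|` per step, to the negative information gain — the purely
epistemic regime. This is the default preference in all fixtures.

## Maximum occupancy

The occupancy reward of a realized trajectory is
`R(τ) = −Σ_t γ^t [α log π(a_t|s_t) + β log P(s_{t+1}|s_t,a_t)]`, with γ^t
indexed from t = 0; its expectation is the discounted sum of α-weighted
action entropies and β-weighted transition entropies. A term whose weight is
zero is skipped entirely, so zero-probability events only matter where they
actually enter the sum. Negative β penalizes noisy transitions and is a
practical approximation to empowerment's controllability preference; the
suite checks the monotone trend (mass shifts toward the deterministic action
as β decreases through {0, −0.5, −1}).

The objective defines a value function but no algorithm; here the optimizer
is **soft value iteration**, chosen because the α-weighted action-entropy
term makes the per-state inner maximization analytic:

    Q(s,a) = β H(S'|s,a) + γ E[V(s')],   V(s) = α log Σ_a exp(Q(s,a)/α),

with `π*(a|s) ∝ exp(Q(s,a)/α)`. α is thus the soft-max temperature, which is
consistent with its role as the weight on `H(A|s)` in the value expansion.
Evaluating the returned policy reproduces the returned V exactly in exact
arithmetic, and within twice the tolerance numerically (asserted). α = 0 is
refused with a pointer to plain value iteration, which is out of scope.

Infinite-horizon sums are truncated by the contraction tolerance, not a step
count: iteration stops when the sup-norm change is below `tol·(1−γ)/γ`, which
bounds the distance to the fixed point by `tol` (default 1e-10 nats). The
soft-Bellman operator is a γ-contraction and the suite asserts the per-sweep
decay rate directly (ignoring sweeps within ~1e-8 of convergence, where
float cancellation dominates the ratio).

**Absorbing states** are deterministic self-loops with a single effective
action: they generate zero action and state entropy forever, so their value
is pinned to 0 and their (never-consulted) policy row to the first action.
This is the discrete device for "death" — no thermodynamic reinterpretation
of the dissolution of the agent is attempted.

Defaults are α = 1, β = 0, γ = 0.99, the configuration used in the
comparative experiments this package operationalizes.

## Synthetic environments

`make_gridworld` builds width × height grids with 5 actions
(up/down/left/right/stay). "Stay" is included deliberately so an interior
cell has 5 distinct one-step outcomes, making log 5 an exact depth-1
empowerment ground truth (corners give log 3, edges log 4). Wall moves clamp
in place. With probability `slip` the intended move is replaced by a
uniformly random cardinal move (wall-clamped), keeping rows exactly
stochastic. The observation model is the identity corrupted by
`observation_noise` spread uniformly over the other cells; preference and
state prior default to uniform.

`make_random_model` draws every conditional from a symmetric Dirichlet with a
given concentration, seeded; its outputs always validate, and large
concentrations approach uniform conditionals (checked statistically). The
number of observations may differ from the number of states, and tests cover
both. These fixtures emulate the *structure* of the models used in discrete
intrinsic-motivation studies — small state spaces, exactly known dynamics,
full-support conditionals. They do not emulate learned or misspecified
models, large sparse state spaces, or nonstationary environments, so passing
tests demonstrate correctness of the objectives' computation, not performance
of the objectives on realistic tasks.

## The comparison experiment

`run_comparison` runs four agents on one environment: uniform-random,
empowerment-greedy, active inference, and MOP-optimal. Design choices:

- **Empowerment-greedy** is one-step lookahead on the expected next-state
  value of a precomputed depth-d empowerment map (d = 2 by default), ties to
  the lowest action index. The positional description of
  empowerment-seeking fixes no algorithm; greedy lookahead is the simplest
  deterministic operationalization.
- **Active inference** replans every step from the exact current belief.
  With noiseless observations that belief is a point mass on the current
  state, so the replanned action marginal is a function of the state and is
  tabulated once — an exact implementation of receding-horizon replanning,
  not an approximation. Note a structural consequence: with deterministic
  dynamics, flat preferences and exact observation, *every* policy predicts
  zero-entropy observations, the epistemic term is identical across policies,
  and the softmax (at temperature 1) is uniform — the agent behaves like the
  random baseline. This is a property of the objective in this degenerate
  regime, reported as-is.
- **MOP** uses the soft-value-iteration optimal policy.

The default comparison environment uses deterministic dynamics (slip = 0) so
that the avoidance statistic isolates each policy's own behavior rather than
slip noise. All randomness flows through one seed per run; identical seeds
and configuration give byte-identical reports (asserted). Statistics
reported per (agent, seed): empirical state-visit entropy, fraction of steps
in absorbing states, mean per-step action entropy.

With a 5×5 grid, one absorbing cell and 10 000 steps, the random walker is
absorbed early in essentially every seed (absorbing frequency ≈ 1) while the
MOP and empowerment agents' absorbing frequency is 0 — the emergent
"survival instinct" of entropy- and control-seeking agents, obtained with no
reward signal. The acceptance suite asserts the ordering in ≥ 9 of 10 seeds.

## Problem sizes and tolerances

Identity audits use 4-state/3-observation/2-control Dirichlet models (100
seeds, depths 1–3) — large enough to be non-degenerate, small enough that
exhaustive path-sum oracles remain exact. Identity assertions are at 1e-10;
solver cross-checks at the grid resolution (2e-3 nats for capacity); the
Monte-Carlo check of policy evaluation uses 3 000 episodes of 175 steps
(γ^175 < 1e-8 at γ = 0.9) and a 3-standard-error band. The comparison runs
10 seeds × 10 000 steps.

## Known limitations

- Exhaustive policy enumeration limits planning depth (the cap errors out at
  10^5 sequences); no amortized or sampled policy search is provided.
- Empowerment is exact but exponential in depth; the multi-interval
  generalizations and continuous state spaces are out of scope.
- No learning anywhere: models are given, not estimated; preferences are
  fixed; there is no precision/temperature updating and no habit prior.
- The generalized-free-energy treatment is limited to the policy-level
  functional; a full latent-future-observation model is not implemented.
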