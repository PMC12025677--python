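# imotiv

**Intrinsic-motivation objectives for discrete agents: empowerment, expected
free energy, and maximum occupancy in one exact framework.**

Intrinsically motivated agents act without external reward: they are driven by
structural features of the agent–environment loop itself. Three formal accounts
dominate the literature, and this package implements all three on finite
discrete models, exactly, together with numerical audits of the algebraic
identities that connect them:

- **Empowerment** — the channel capacity of the conditional distribution
  linking an agent's action sequences to a future observation,
  `E = max_{P(A)} I(A_{t:T}; O_T)`, computed by Blahut–Arimoto iteration.
  High empowerment means many distinct, controllable outcomes are reachable.
- **Active inference** — policies are scored by expected free energy (EFE),
  `G_π = Σ_t [ risk + ambiguity ]`, where risk is
  `KL(Q(o_t|π) ‖ P(o))` against a preference distribution and ambiguity is the
  expected likelihood entropy. The policy posterior is `Q(π) = softmax(−G)`,
  which is exactly the minimizer of the generalized free energy
  `E_Q[G] − H(Q)`.
- **Maximum occupancy (MOP)** — agents maximize discounted action- and
  state-path entropy, `V(s) = E[ Σ_t γ^t (α H(A|s_t) + β H(S'|s_t,a_t)) ]`,
  solved by entropy-regularized (soft) value iteration with a closed-form
  Boltzmann policy.

Everything runs on small discrete models (POMDP-style generative models and
gridworld MDPs) built by the package's own generators; all quantities are in
nats; no external data is needed. The intended users are researchers who want
exact, auditable reference implementations of these objectives rather than
deep-RL approximations.

## Worked example

A 3×3 gridworld whose center cell is absorbing ("death": it self-loops under
every action and generates zero path entropy forever):

```python
import numpy as np
from imotiv import (make_gridworld, empowerment_map, mop_optimize,
                    MOPParams, run_comparison)

mdp, gm = make_gridworld(3, 3, absorbing_cells=[4])

print(np.round(empowerment_map(mdp, gm, depth=1).reshape(3, 3), 4))
# [[1.0986 1.3863 1.0986]
#  [1.3863 0.     1.3863]
#  [1.0986 1.3863 1.0986]]
```

Corners reach 3 distinct cells in one step (two moves + stay), so their
empowerment is log 3 ≈ 1.0986 nats; edge cells reach 4 (log 4 ≈ 1.3863); the
absorbing center has no control at all, hence 0.

```python
policy, V = mop_optimize(mdp, MOPParams(alpha=1.0, beta=0.0, gamma=0.95))
print(np.round(policy.matrix[1], 4))
# [0.2209 0.     0.2791 0.2791 0.2209]
```

The occupancy-optimal policy in the cell above the center assigns probability
0 to the "down" action that would enter the absorbing cell, and spreads the
rest nearly uniformly — survival emerges from entropy maximization alone, with
no reward anywhere in the model.

```python
rep = run_comparison(mdp, gm, steps=2000, seeds=[1, 2, 3])
print(rep.summary().round(4))
#                   visit_entropy  absorbing_frequency  mean_action_entropy
# active_inference         0.0188               0.9975               1.6094
# empowerment              0.0043               0.0000               0.0000
# mop                      2.0432               0.0000               1.5160
# uniform                  0.0188               0.9975               1.6094
```

The uniform-random walker ends up dead 99.8% of the time; the occupancy and
empowerment agents never enter the absorbing cell. (With fully deterministic
dynamics and a flat preference distribution, every policy predicts the same
zero observation entropy, so the purely epistemic active-inference agent is
indifferent and behaves like the random baseline — see `docs/methods.md`.)

A command-line interface mirrors the library:

```bash
imotiv make-env --type gridworld --width 4 --height 4 --absorbing 5 -o env.yaml
imotiv empowerment --model env.yaml --depth 2 --map -o emp.csv
imotiv mop --env env.yaml --alpha 1 --beta 0 --gamma 0.99 -o policy.csv
imotiv compare --env env.yaml --steps 10000 --seeds 1..10 --out report.csv
```

## Layout

| module | contents |
|---|---|
| `imotiv.infotheory` | entropy, KL, mutual information (five routes), channel capacity (Blahut–Arimoto + exhaustive grid cross-check) |
| `imotiv.genmodel` | generative models, MDPs, validation, gridworld and random-model generators, policy enumeration |
| `imotiv.active_inference` | variational free energy, exact posteriors, policy rollouts, EFE breakdowns, policy posterior, generalized free energy |
| `imotiv.empowerment` | action→observation channels, empowerment maps, free-energy decomposition audit |
| `imotiv.mop` | occupancy reward, policy evaluation, soft value iteration, trajectory simulation |
| `imotiv.harness` | four-agent comparison experiment, reports |
| `imotiv.io` / `imotiv.cli` | YAML serialization and the `imotiv` command |
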