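# anticipation-rl

Reinforcement-learning models of **RPE-boosted anticipatory utility**, for
studying *observing behavior* — the preference of humans, monkeys and birds
for targets that yield advance information about upcoming rewards, even
when that information changes nothing about the rewards themselves.

## The model

Waiting for a known future reward is itself valuable (savouring); waiting
for a known aversive outcome is itself costly (dread).  For a cue at t = 0
predicting an outcome of magnitude R at t = T, anticipation is worth
a(t) = R·e^(−ν(T−t)), growing toward delivery at rate ν.  Discounting both
the anticipation stream and the outcome at rate γ, the cue's value is

    Q = η·A + B
    A = R/(ν−γ)·(e^(−γT) − e^(−νT))      (integrated discounted anticipation)
    B = R·e^(−γT)                          (discounted outcome)

with η weighting anticipation against consumption.  The central hypothesis:
**η is boosted by the magnitude of the reward prediction error (RPE) the
cue evokes**, η = η₀ + c·|δpe| (or a saturating tanh / step variant).
Cues that resolve uncertainty carry RPEs, so they intensify savouring and
dread — which is why informative targets can be worth choosing, and why the
preference grows with the delay T and can reverse again at very long
delays.  Because the RPE depends on the cue's value and vice versa, the
equilibrium RPE solves a self-consistency equation; under the linear ansatz
a finite solution exists only while (1−q)·c·A < 1.

The package implements, as separately testable layers:

- `core_valuation` — closed-form A, B, Q, boosting ansatzes, softmax choice;
- `fixed_point` — self-consistent RPEs, existence/stability diagnostics,
  the boosted cue value Q = (η₀A + B)/(1 − (1−q)cA);
- `task_models` — the macaque 100%/50%/0%-information choice task (coupled
  cue/target/RPE system) and the generalized pigeon observing task with
  preference phase diagrams over (reward probability, γT);
- `trial_model` — a trial-by-trial learning model of the human
  advance-information task (delta-rule value learning, softmax choice) and
  a six-model comparison zoo from plain Q-learning to the full boosted
  model with savouring ν₊, dread ν₋ and a free-signed no-reward value R₋;
- `synthetic_data` — cohort generator for the blocked (2.5/7.5/20/40 s) and
  randomized (1–40 s) experimental designs with known ground truth;
- `inference` — hierarchical Bayesian random-effects fitting
  (Laplace-approximate EM), trial balancing, and integrated-BIC model
  comparison;
- `cli` — an `anticipation-rl` command with `simulate`, `fit`, `compare`,
  `phase` and `recover` subcommands.

## Worked example

```python
import numpy as np
from anticipation_rl import (
    AnticipationParams, BoostSpec, PigeonTask, InfoTask,
    pigeon_delta_q, monkey_values, monkey_preferences,
    FITTED_GROUP_MEANS, make_model, builtin_design, simulate_subject,
)

# 1. pigeon observing task: 50%-rewarded informative target vs certain target
params = AnticipationParams(R=1.0, nu=0.5, gamma=1.0, eta0=3.0,
                            boost=BoostSpec("linear", c=3.0))
for gT in (0.1, 1.0, 5.0):
    dq = pigeon_delta_q(PigeonTask(p_info=0.5, p_noinfo=1.0, T=gT), params)
    print(f"gamma*T = {gT:3.1f}: Q_info - Q_certain = {dq:+.3f}")

# 2. macaque information-choice task
vals = monkey_values(InfoTask(), AnticipationParams(
    R=0.88, nu=0.5, gamma=0.1, eta0=1.0,
    boost=BoostSpec("linear", c=1.0), sigma=0.08))
prefs = monkey_preferences(vals, sigma=0.08)
print({k: round(v, 3) for k, v in vals.q_target.items()})
print(f"P(100% over 50%) = {prefs[(100, 50)]:.3f}")

# 3. simulate a human subject at the fitted group means
spec = make_model("boosted_full")
subject = spec.params_from_values(dict(FITTED_GROUP_MEANS))
ds = simulate_subject(subject, builtin_design("exp1"), seed=42)
by_delay = {}
for r in ds.records:
    by_delay.setdefault(r.delay_s, []).append(r.choice == "info")
for T, ch in sorted(by_delay.items()):
    print(f"delay {T:4.1f} s: chose info on {np.mean(ch):.2f} of {len(ch)} trials")
```

prints

```
gamma*T = 0.1: Q_info - Q_certain = -0.496
gamma*T = 1.0: Q_info - Q_certain = +1.368
gamma*T = 5.0: Q_info - Q_certain = -0.162
{100: 2.1, 0: 1.055, 50: 1.577}
P(100% over 50%) = 0.999
delay  2.5 s: chose info on 0.51 of 90 trials
delay  7.5 s: chose info on 0.64 of 36 trials
delay 20.0 s: chose info on 0.89 of 18 trials
delay 40.0 s: chose info on 0.89 of 18 trials
```

Reading the numbers: at a short scaled delay the certain target is worth
more (ΔQ < 0), at an intermediate delay boosted savouring makes the
informative target win (ΔQ > 0), and at a very long delay discounting
reverses the preference once more.  In the macaque task the boosted model
orders the targets by informativeness, Q₁₀₀ > Q₅₀ > Q₀, with near-saturated
pairwise preferences at the task's low softmax temperature.  The simulated
human subject is indifferent at 2.5 s and strongly prefers the informative
target at 20–40 s, because savouring (ν₊ ≈ 0.08 s⁻¹) outlasts dread
(ν₋ ≈ 0.41 s⁻¹) at long delays.

The same pipeline is available from the shell:

```sh
anticipation-rl simulate --design exp1 --n 14 --seed 1 --out runs/sim
anticipation-rl fit --model boosted_full --data runs/sim/trials.csv --out runs/fit
anticipation-rl phase --pb 0.5:1.0:11 --gt 0.05:5:100 --out runs/phase
```

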