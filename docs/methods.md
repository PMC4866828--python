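# Methods

## Valuation with anticipatory utility

A predictive cue at t = 0 announces an outcome of magnitude R (utility
units, sign free) delivered at t = T seconds.  Anticipation while waiting
is worth a(t) = R·e^(−ν(T−t)): ν (s⁻¹) sets how sharply anticipation ramps
toward delivery — small ν means anticipation accrues early, large ν means
it spikes just before the outcome.  Both the anticipation stream and the
outcome are discounted exponentially at γ (s⁻¹).  The cue's value is
Q = η·A + B with

    A = ∫₀ᵀ e^(−γt)·a(t) dt = R/(ν−γ)·(e^(−γT) − e^(−νT)),    B = R·e^(−γT).

`integrated_anticipation` validates against adaptive quadrature to 1e−8
relative over wide random parameter ranges.  At ν = γ the closed form has a
removable singularity; we switch to the analytic limit R·T·e^(−γT) when
|ν−γ| < 1e−9·max(ν,γ), and the switch is continuous to better than 1e−6.

For R > 0 and η > γ, Q(T) is an inverted U: dQ/dT at T = 0 is R(η−γ), the
maximum is interior and exceeds Q(0) = R, and Q → 0 as T → ∞ for γ > 0.

## RPE boosting and the self-consistency problem

The anticipation weight η is not constant but responds to the magnitude of
the reward prediction error the cue evokes:

- linear: η = η₀ + c·|δpe|
- saturating: η = η₀ + c₁·tanh(c₂·|δpe|)
- step: η = η₀ + c·θ(|δpe|), θ(x) = 1 for x > 0 and 0 for x ≤ 0

The absolute value matters: surprising news of a *bad* outcome intensifies
dread just as surprising good news intensifies savouring.  Floating-point
RPEs below 1e−12 in magnitude count as zero, so a fully predicted cue is
never boosted.

Because the boosted value feeds back into the RPE, the equilibrium RPE
solves δ = slope·f(|δ|) + intercept.  Closed forms: linear with positive
intercept gives δ = β/(1−α) when α < 1 and *no finite solution* otherwise
(unbounded boosting); the negative branch is δ = β/(1+α).  The tanh
equation always has a solution; we bisect on the branch matching the sign
of the unboosted solution, growing the bracket geometrically from
[0, |β|+|α|+1] and halving until the midpoint collides with an endpoint
(full float resolution), giving residuals at machine precision.  Bisection
is used deliberately: the equation is monotone-bounded on its branch and
bisection cannot be thrown by the tanh saturation.  Nonexistence is
reported as a result (`exists=False` with a stability margin), not an
exception, so parameter sweeps can mask invalid cells; `boosted_cue_value`
raises `NoSolutionError` carrying the margin because a single diverging
valuation has no meaningful return value.

For a cue that follows the choice with probability p, the linear-ansatz
equilibrium is Q = (η₀A + B)/(1 − (1−p)·c·A), valid while (1−p)·c·A < 1.
The brute-force sweep in `stability_boundary_sweep` confirms the boundary
at unit product to grid resolution, cross-checking the closed form against
damped iteration (classified by the empirical contraction ratio of the
iteration increments, which is exact for this linear map).

## Macaque information-choice task

Three targets lead to reward-size predictive cues with probability 1.0,
0.5, 0.0; rewards R_big = 0.88, R_small = 0.04 after T = 2.25 s, with
ν = 0.5 s⁻¹, γ = 0.1 s⁻¹ and softmax temperature σ = 0.08.  Cue values,
target values and context-dependent RPEs form a coupled system (a cue's
RPE depends on which target preceded it), solved by damped fixed-point
iteration on the RPEs (damping 0.5, tolerance 1e−10, cap 10⁴ iterations).
With no boosting the three targets are exactly equivalued; with boosting
the solution orders them Q₁₀₀ > Q₅₀ > Q₀ across the stable region of the
(η₀, c) plane.

The linear ansatz's stable region at these task parameters is bounded:
the self-amplification gain of the coupled system is roughly 0.65·c
(A_big ≈ 1.04 at these settings), so gains c ≳ 1.6 have no stable
equilibrium and the solver reports nonexistence rather than a value.
Sweeps (`monkey_param_sweep`) mask such cells as NaN.

## Generalized pigeon observing task

An informative target yields a certainly-rewarded cue with probability p_I
(else a never-rewarded cue); an uninformative target is rewarded with
probability p_N.  With unit-reward factors a, b (A, B at R = 1),

    ΔQ = Q_info − Q_noinfo = (η₀a + b)·( p_I·R_I/(1 − (1−p_I)·c·A_I) − p_N·R_N ),

where A_I = R_I·a.  The value of "no outcome" is 0 in these tasks.  At the
standard ratios ν/γ = 0.5, η₀/γ = 3, c/γ = 3, R = 1 the model produces the
signature double reversal against a certain target (certain → info →
certain as γT grows) and unconditional info preference at matched reward
probabilities.  Phase diagrams are computed on the dimensionless γT axis
and report a stability mask alongside ΔQ.

In the 20%-informative vs 50%-uninformative configuration (equal reward
sizes) the preference for the informative target requires boosting.  The
saturating ansatz reproduces this only when its amplitude is large enough:
positivity needs roughly c₁ > 4.5 + 1.5·b/a at these ratios, because the
tanh boost is capped at η₀ + c₁ while the linear boost grows without bound
near its stability boundary.  Tests therefore verify the flip with the
linear ansatz on its stable region and with a tanh amplitude of c₁/γ = 8
(c₂ = 3) on the full delay range; with a weak amplitude (c₁/γ = 1) the flip
is algebraically impossible, which is a genuine difference between the
ansatzes, not a numerical artifact.

## Trial-by-trial model of the human task

Subjects choose between an informative target (followed by a reward- or
no-reward-predictive cue) and an uninformative one (outcome only), with
reward probability 0.5 and delay T set by the design.  The experienced
value of a trial is V = η_S·A_i + B_i with i = + (reward, magnitude R₊) or
− (no reward, magnitude R₋, sign free), separate anticipation rates ν₊
(savouring) and ν₋ (dread), and a shared discount rate γ.  Informative
cues evoke an RPE and are boosted, η_S = η₀ + c; the uninformative path is
weighted by η₀ alone.  The chosen target's learned value follows the delta
rule Q ← Q + α(V − Q); choices are softmax in (q_info − q_noinfo)/σ.  Both
targets start at Q = 0 and are not reset between blocks (target identities
persist).  Only the products cR₊/σ and cR₋/σ are identified, so c = σ = 1
during fitting, and η₀ is fixed at 0 in the boosted variants (it cancels
from the expected value difference).  The asymmetric-boosting variant
(η_S = η₀ + c₊θ(δpe) + c₋θ(−δpe)) is likelihood-equivalent to the full
model — the asymmetry is absorbed into the fitted magnitudes of R₊ and R₋
— and is exposed under its own name for interpretation only.

The model zoo: q_learning (3 parameters), q_learning_discount (5, with
separate γ₊, γ₋ entering as B_i = R_i·e^(−γᵢT) and no anticipation),
anticipation_no_boost (7, c = 0 with η₀ free), boosted_no_rminus (4),
boosted_no_discount (5), boosted_full (6).

Because choices are observed, each target's Q trajectory is a fixed
exponentially weighted average of its own trials' V values; the session
log-likelihood is evaluated with a linear filter rather than a Python
loop.  The filtered route is held to the explicit per-trial recursion to
1e−9 (values and finite-difference gradients) in tests.

A structural consequence worth noting: in the randomized design the
current trial's announced delay does not enter the choice probability
(only the learned target values do), so the model predicts
delay-*independent* choice fractions within a randomized session.  Its
delay dependence lives in the value functions — the asymptotic preference
σ(c(A₊(T)+A₋(T))/2) is higher at 20–40 s than at ≤ 7.5 s and the positive/
negative value functions are mirrored inverted U's — and in blocked
designs, where the learned values track the block's delay.

## Synthetic cohorts

The generator reproduces the study conditions: the blocked design
(2.5/7.5/20/40 s with 90/36/18/18 trials, fixed order; the control variant
reorders the blocks and repeats 2.5 s), the randomized design (25 trials,
5 per delay in {1, 5, 10, 20, 40} s), reward probability 0.5 throughout.
Subject parameters are drawn from a diagonal Gaussian on the transformed
scale (logit α; log ν₊, ν₋, γ; identity R₊, R₋), centred at the fitted
group means (α = 0.17, R₊ = 0.85, R₋ = −0.84, γ = 0.041 s⁻¹,
ν₊ = 0.082 s⁻¹, ν₋ = 0.41 s⁻¹) with a default 10% coefficient of variation
of the transformed means.  One seeded generator per session drives, in
order, the block shuffle, the choice draw and the outcome draw, making
cohorts bit-reproducible; cohort member seeds derive from the population
seed.

What the generator does *not* emulate: reaction times and response
penalties, the adaptation to abrupt delay changes seen in the control
experiment, image-specific reward magnitudes, and any cross-trial
anticipation.  Passing recovery tests therefore show that the estimation
machinery is consistent for data generated by the model itself, not that
the model captures every feature of real behavior.

## Hierarchical fitting and model comparison

Transformed per-subject parameters are modelled as draws from a diagonal
Gaussian (μ, Σ).  Approximate EM: the E-step computes each subject's MAP
under the current prior by L-BFGS-B (numerical gradients; bounds keep the
exp/logit maps finite) with 5 restarts on the first iteration and a single
warm-started run afterwards, and a Laplace covariance from a central
finite-difference Hessian (step 1e−4) whose eigenvalues are floored at
1e−8 before inversion.  The M-step sets μ to the mean of the MAPs and the
diagonal of Σ to mean(mᵢ² + Σᵢ,kk) − μ², floored at 1e−6.  Convergence:
max |Δμ| < 1e−4 (or the configured tolerance) within the iteration cap.  A
Laplace log-evidence surrogate is tracked per iteration and is
non-decreasing up to approximation error.

The posterior SD of the group mean is computed from the total Fisher
information Σᵢ Σ⁻¹(Σ − Σᵢ)Σ⁻¹ (exact when subject likelihoods are
Gaussian): subjects whose posteriors fill the prior contribute nothing,
well-determined subjects contribute Σ⁻¹, recovering sqrt(Σ/N) in the
sharp limit.  The full matrices are essential — γ, ν₊ and R₊ lie on a
likelihood ridge, and diagonal-only information overstates the precision
of γ several-fold.  Numerically indefinite contributions (finite-
difference Hessians can violate Σᵢ ⪯ Σ) are clipped to their PSD part.

Model comparison uses the integrated BIC,
iBIC = −2·log p(D|θ) + |M|·log|D|, with the marginal likelihood per
subject approximated by a log-space Monte-Carlo average over K = 10⁴ prior
draws (seeded; convergence in K verified at these scales), |M| = twice the
free-parameter count (a mean and a variance per parameter) and |D| the
total number of choices.  Trial balancing (`balance_trials`) subsamples to
the minimum per-delay count (90/36/18/18 → 4×18) and is optional, off by
default for recovery runs.

At the study scale — 14 subjects × 162 trials — γ = 0.041 s⁻¹ is weakly
identified: the sampling spread of the recovered group mean is roughly 45%
of its value, and the ~9-point log-marginal evidence that discounting
contributes is of the same order as the ~15-point iBIC penalty for its two
prior parameters, so the full model and its no-discount reduction are
genuinely close competitors at this scale.  The acceptance tests assert
recovery within 3 posterior SDs (using the Fisher SE above) and run the
model-recovery contest at fixed seeds with reduced EM/Monte-Carlo settings
(≤ 25 EM iterations, K = 3000) chosen to keep the whole suite at desk
scale.

## Problem sizes used by tests and the acceptance script

Quadrature and fixed-point oracles use 1000 and 500 random draws; the
no-boost null simulates ~10⁶ trials; the recovery and model-comparison
runs use 14 subjects × 162 trials (the blocked design); the stability
sweep uses a gain grid of resolution 1e−4 over (0, 8].  All runs are
single-CPU and seeded.
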