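"""Forward predictions for two classic observing-behavior paradigms.

Macaque information-choice task: three targets lead to reward-size
predictive cues with probability 1.0 (100% info), 0.5 or 0.0.  Because the
RPE evoked by a cue depends on which target preceded it, cue values, target
values and RPEs form a coupled system that is solved here by damped
fixed-point iteration.

Pigeon observing task (generalized): an informative target yields, with
probability ``p_info``, a cue that certainly predicts reward after delay T
(otherwise a never-rewarded cue); an uninformative target is rewarded with
probability ``p_noinfo`` without predictive cueing.  The value difference
has a closed form under the linear boosting ansatz and is solved
numerically for the tanh ansatz, including the phase diagram of preference
over (reward probability, scaled delay).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from .core_valuation import (
    AnticipationParams,
    BoostSpec,
    boost_weight,
    choice_probability,
    discounted_reward,
    integrated_anticipation,
)
from .fixed_point import (
    NoSolutionError,
    SelfConsistencyProblem,
    solve_selfconsistent,
)

__all__ = [
    "InfoTask",
    "PigeonTask",
    "TaskValues",
    "monkey_values",
    "monkey_preferences",
    "monkey_param_sweep",
    "pigeon_delta_q",
    "phase_diagram",
]

TARGETS = (100, 50, 0)
CUES = ("big", "small", "random")

#: which targets each cue can follow, with the conditional probability of
#: the (cue | target) transition used to average cue values over targets
_CUE_CONTEXTS: Dict[str, Tuple[int, ...]] = {
    "big": (100, 50),
    "small": (100, 50),
    "random": (50, 0),
}


@dataclass(frozen=True)
class InfoTask:
    """Macaque information-choice task configuration."""

    r_big: float = 0.88
    r_small: float = 0.04
    T: float = 2.25
    info_probs: Mapping[int, float] = field(
        default_factory=lambda: {100: 1.0, 50: 0.5, 0: 0.0}
    )

    def __post_init__(self) -> None:
        if not self.r_big > self.r_small >= 0:
            raise ValueError("require r_big > r_small >= 0")


@dataclass(frozen=True)
class PigeonTask:
    """Generalized pigeon observing task.

    p_info    probability the informative target's rewarded cue appears
    p_noinfo  reward probability of the uninformative target
    r_info, r_noinfo  reward magnitudes of the two targets
    T         cue-to-reward delay (s)
    """

    p_info: float = 0.5
    p_noinfo: float = 1.0
    r_info: float = 1.0
    r_noinfo: float = 1.0
    T: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.p_info, self.p_noinfo):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.p_info == 0.0:
            raise ValueError("p_info must be positive")


@dataclass
class TaskValues:
    """Solved equilibrium of the macaque task."""

    q_target: Dict[int, float]
    q_cue: Dict[str, float]
    v_cue: Dict[Tuple[str, int], float]
    rpe: Dict[Tuple[str, int], float]
    n_iterations: int
    converged: bool


def _cue_outcome_terms(task: InfoTask, params: AnticipationParams):
    """(A, B) per reward size for the task's delay."""
    out = {}
    for name, r in (("big", task.r_big), ("small", task.r_small)):
        out[name] = (
            integrated_anticipation(r, params.nu, params.gamma, task.T),
            discounted_reward(r, params.gamma, task.T),
        )
    return out


def monkey_values(
    task: InfoTask,
    params: AnticipationParams,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> TaskValues:
    """Solve the coupled target/cue/RPE system of the macaque task.

    The system: target values are probability-weighted means of cue values;
    a cue's value is the mean of its (context-dependent) boosted values over
    the targets it can follow; the RPE of a cue in a context is the cue's
    value minus the preceding target's value; the boosted value weights the
    anticipation terms by ``boost_weight(eta0, boost, rpe)``.
    """
    ab = _cue_outcome_terms(task, params)
    contexts = [(cue, tgt) for cue in CUES for tgt in _CUE_CONTEXTS[cue]]
    rpe = {ctx: 0.0 for ctx in contexts}

    v_cue: Dict[Tuple[str, int], float] = {}
    q_cue: Dict[str, float] = {}
    q_target: Dict[int, float] = {}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for (cue, tgt) in contexts:
            eta = boost_weight(params.eta0, params.boost, rpe[(cue, tgt)])
            if cue == "random":
                a_big, b_big = ab["big"]
                a_small, b_small = ab["small"]
                v = 0.5 * ((eta * a_big + b_big) + (eta * a_small + b_small))
            else:
                a, b = ab[cue]
                v = eta * a + b
            v_cue[(cue, tgt)] = v
        for cue in CUES:
            ctx = _CUE_CONTEXTS[cue]
            q_cue[cue] = sum(v_cue[(cue, tgt)] for tgt in ctx) / len(ctx)
        q_target[100] = 0.5 * (q_cue["big"] + q_cue["small"])
        q_target[0] = q_cue["random"]
        q_target[50] = 0.25 * (q_cue["big"] + q_cue["small"]) + 0.5 * q_cue["random"]

        new_rpe = {
            (cue, tgt): q_cue[cue] - q_target[tgt] for (cue, tgt) in contexts
        }
        if not all(abs(v) < 1e100 for v in new_rpe.values()):
            raise NoSolutionError(
                "macaque task iteration diverged: the boosting gain admits "
                "no stable self-consistent solution at these parameters"
            )
        delta = max(abs(new_rpe[ctx] - rpe[ctx]) for ctx in contexts)
        rpe = {
            ctx: (1.0 - damping) * rpe[ctx] + damping * new_rpe[ctx]
            for ctx in contexts
        }
        if delta < tol:
            rpe = new_rpe
            converged = True
            break
    if not converged:
        raise NoSolutionError(
            f"macaque task iteration did not converge in {max_iter} steps "
            f"(last change {delta:.3g}); boosting may be unstable"
        )
    return TaskValues(
        q_target=q_target,
        q_cue=q_cue,
        v_cue=v_cue,
        rpe=rpe,
        n_iterations=it,
        converged=converged,
    )


def monkey_preferences(values: TaskValues, sigma: float) -> Dict[Tuple[int, int], float]:
    """Pairwise choice probabilities P(X% over Y%) from solved target values."""
    return {
        (x, y): choice_probability(values.q_target[x], values.q_target[y], sigma)
        for x, y in itertools.permutations(TARGETS, 2)
    }


def monkey_param_sweep(
    task: InfoTask,
    eta0_grid: np.ndarray,
    c_grid: np.ndarray,
    targets: Mapping[Tuple[int, int], float],
    nu: float = 0.5,
    gamma: float = 0.1,
    sigma: float = 0.08,
    boost_kind: str = "linear",
) -> np.ndarray:
    """Squared-error surface of predicted vs observed pairwise preferences.

    Returns an array of shape (len(eta0_grid), len(c_grid)); cells where the
    coupled system has no stable solution are NaN.
    """
    err = np.full((len(eta0_grid), len(c_grid)), np.nan)
    for i, eta0 in enumerate(eta0_grid):
        for j, c in enumerate(c_grid):
            if boost_kind == "tanh":
                boost = BoostSpec(kind="tanh", c1=float(c), c2=1.0)
            else:
                boost = BoostSpec(kind=boost_kind, c=float(c))
            params = AnticipationParams(
                R=task.r_big, nu=nu, gamma=gamma, eta0=float(eta0),
                boost=boost, sigma=sigma,
            )
            try:
                vals = monkey_values(task, params)
            except NoSolutionError:
                continue
            prefs = monkey_preferences(vals, sigma)
            err[i, j] = sum(
                (prefs[pair] - obs) ** 2 for pair, obs in targets.items()
            )
    return err


def pigeon_delta_q(task: PigeonTask, params: AnticipationParams) -> float:
    """Value difference Q_info - Q_noinfo in the generalized observing task.

    Under the linear ansatz,

        dQ = (eta0*a + b) * ( p_I*R_I / (1 - (1-p_I)*c*A_I) - p_N*R_N )

    with a, b the unit-reward anticipation and discount factors and
    A_I = R_I * a.  Other ansatzes are solved through the self-consistency
    equation for the RPE at the rewarded cue.  Raises NoSolutionError if
    the linear boost diverges.
    """
    a = integrated_anticipation(1.0, params.nu, params.gamma, task.T)
    b = discounted_reward(1.0, params.gamma, task.T)
    base_unit = params.eta0 * a + b
    q_noinfo = task.p_noinfo * task.r_noinfo * base_unit

    p_i = task.p_info
    a_i = task.r_info * a
    b_i = task.r_info * b
    base_i = params.eta0 * a_i + b_i
    qmiss = 1.0 - p_i
    boost = params.boost
    problem = SelfConsistencyProblem(
        slope=qmiss * boost.gain * a_i, intercept=qmiss * base_i, boost=boost
    )
    res = solve_selfconsistent(problem)
    if not res.exists:
        raise NoSolutionError(
            "informative branch diverges: (1-p_info)*c*A_I = "
            f"{qmiss * boost.gain * a_i:.6g} >= 1",
            margin=res.stability_margin,
        )
    if qmiss == 0.0:
        q_splus = base_i
    else:
        q_splus = res.delta_pe / qmiss
    q_info = p_i * q_splus
    return q_info - q_noinfo


def phase_diagram(
    pB_grid: np.ndarray,
    gammaT_grid: np.ndarray,
    params: AnticipationParams,
    p_info: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Preference map over (p_noinfo, gamma*T) for the observing task.

    Returns (delta_q, mask): delta_q[i, j] is Q_info - Q_noinfo at
    p_noinfo = pB_grid[i] and T = gammaT_grid[j] / gamma; mask is True where
    the linear fixed point has no stable solution (delta_q is NaN there).
    """
    if params.gamma <= 0:
        raise ValueError("phase diagram requires gamma > 0 for the gamma*T axis")
    dq = np.full((len(pB_grid), len(gammaT_grid)), np.nan)
    mask = np.zeros_like(dq, dtype=bool)
    for j, gt in enumerate(gammaT_grid):
        T = float(gt) / params.gamma
        for i, pb in enumerate(pB_grid):
            task = PigeonTask(p_info=p_info, p_noinfo=float(pb), T=T)
            try:
                dq[i, j] = pigeon_delta_q(task, params)
            except NoSolutionError:
                mask[i, j] = True
    return dq, mask
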