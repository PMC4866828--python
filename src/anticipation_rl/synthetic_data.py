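"""Synthetic cohorts for the advance-information choice experiments.

Generates populations of simulated subjects whose choices come from the
trial-by-trial boosted-anticipation model run forward under one of the
built-in experimental designs:

* ``exp1``          — four fixed-order delay blocks, 2.5/7.5/20/40 s with
                      90/36/18/18 trials (block length compensates delay so
                      subjects spend similar time per condition);
* ``exp1_control``  — the re-ordered control with a repeated 2.5 s block;
* ``exp2``          — 25 trials, delays {1, 5, 10, 20, 40} s randomized
                      trial-by-trial, 5 trials per condition.

Reward probability is 0.5 throughout.  Ground-truth parameters are known,
so the output is directly usable for parameter- and model-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .trial_model import (
    ModelSpec,
    QState,
    SubjectDataset,
    TrialModelParams,
    TrialRecord,
    _path_terms,
    q_update,
    trial_choice_prob,
)

__all__ = [
    "ExperimentDesign",
    "PopulationSpec",
    "builtin_design",
    "sample_population",
    "simulate_subject",
    "simulate_cohort",
    "FITTED_GROUP_MEANS",
]

#: Fitted group-mean parameters of the full boosted model for the human
#: cohort (learning rate, outcome values with c = sigma = 1, shared discount
#: rate and the two anticipation rates; savouring is slower than dread).
FITTED_GROUP_MEANS: Dict[str, float] = {
    "alpha": 0.17,
    "r_plus": 0.85,
    "r_minus": -0.84,
    "gamma": 0.041,
    "nu_plus": 0.082,
    "nu_minus": 0.41,
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure of one experiment."""

    name: str
    blocks: Tuple[Tuple[int, float, int], ...]  # (block_index, delay_s, n_trials)
    randomized: bool = False
    p_reward: float = 0.5

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("design needs at least one block")
        for _, delay, n in self.blocks:
            if n <= 0:
                raise ValueError("n_trials must be positive")
            if delay < 0:
                raise ValueError("delay must be non-negative")
        if not 0.0 <= self.p_reward <= 1.0:
            raise ValueError("p_reward must be a probability")

    @property
    def n_trials(self) -> int:
        return sum(n for _, _, n in self.blocks)

    def trial_sequence(self, rng: np.random.Generator) -> List[Tuple[int, float]]:
        """Ordered (block_index, delay_s) per trial; shuffled if randomized."""
        seq = [
            (b, delay) for b, delay, n in self.blocks for _ in range(n)
        ]
        if self.randomized:
            perm = rng.permutation(len(seq))
            seq = [seq[i] for i in perm]
        return seq


_BUILTINS: Dict[str, ExperimentDesign] = {
    "exp1": ExperimentDesign(
        name="exp1",
        blocks=((0, 2.5, 90), (1, 7.5, 36), (2, 20.0, 18), (3, 40.0, 18)),
    ),
    "exp1_control": ExperimentDesign(
        name="exp1_control",
        blocks=(
            (0, 2.5, 90),
            (1, 40.0, 18),
            (2, 20.0, 18),
            (3, 7.5, 36),
            (4, 2.5, 36),
        ),
    ),
    "exp2": ExperimentDesign(
        name="exp2",
        blocks=tuple((i, d, 5) for i, d in enumerate((1.0, 5.0, 10.0, 20.0, 40.0))),
        randomized=True,
    ),
}


def builtin_design(name: str) -> ExperimentDesign:
    """One of the built-in designs: 'exp1', 'exp1_control' or 'exp2'."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown design {name!r}; choose from {sorted(_BUILTINS)}"
        ) from None


@dataclass(frozen=True)
class PopulationSpec:
    """Group-level Gaussian over transformed parameters.

    ``mu`` and ``var`` are keyed by the model's free-parameter names and live
    on the transformed scale (logit for alpha, log for rates, identity for
    outcome values), matching the hierarchical fit.
    """

    spec: ModelSpec
    mu: Dict[str, float]
    var: Dict[str, float]
    n_subjects: int
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(self.spec.free_names) - set(self.mu)
        if missing:
            raise ValueError(f"population mean missing parameters: {missing}")
        for k, v in self.var.items():
            if v < 0:
                raise ValueError(f"negative variance for {k}")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    @staticmethod
    def from_natural_means(
        spec: ModelSpec,
        means: Dict[str, float],
        n_subjects: int,
        cv: float = 0.1,
        seed: int = 0,
    ) -> "PopulationSpec":
        """Population centred at natural-scale ``means`` with between-subject
        spread of ``cv`` (coefficient of variation of the transformed mean)."""
        mu = {k: spec.transform(k, means[k]) for k in spec.free_names}
        var = {k: (cv * abs(m)) ** 2 for k, m in mu.items()}
        return PopulationSpec(
            spec=spec, mu=mu, var=var, n_subjects=n_subjects, seed=seed
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.spec.name,
                "mu": self.mu,
                "var": self.var,
                "n_subjects": self.n_subjects,
                "seed": self.seed,
            },
            indent=2,
        )


def sample_population(pop: PopulationSpec) -> List[TrialModelParams]:
    """Draw per-subject natural-scale parameters from the group Gaussian."""
    rng = np.random.default_rng(pop.seed)
    spec = pop.spec
    out = []
    for _ in range(pop.n_subjects):
        vals = {}
        for name in spec.free_names:
            h = pop.mu[name] + np.sqrt(pop.var[name]) * rng.standard_normal()
            vals[name] = spec.untransform(name, float(h))
        out.append(spec.params_from_values(vals))
    return out


def simulate_subject(
    params: TrialModelParams,
    design: ExperimentDesign,
    seed: int,
    subject_id: str = "s0",
) -> SubjectDataset:
    """Run the learning model forward through one session.

    A single seeded generator drives, in order per trial: the block shuffle
    (randomized designs, once at session start), the softmax choice draw and
    the cue/outcome draw, making sessions bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    seq = design.trial_sequence(rng)
    u = rng.random((len(seq), 2))  # [:, 0] choice draw, [:, 1] outcome draw

    # experienced value per (path, delay), precomputed once per session
    v_table: Dict[Tuple[bool, bool, float], float] = {}
    for delay in {d for _, d in seq}:
        t = _path_terms(params, delay)
        v_table[(True, True, delay)] = (
            (params.eta0 + params.gain_plus) * t["a_plus"] + t["b_plus"]
        )
        v_table[(True, False, delay)] = (
            (params.eta0 + params.gain_minus) * t["a_minus"] + t["b_minus"]
        )
        v_table[(False, True, delay)] = params.eta0 * t["a_plus"] + t["b_plus"]
        v_table[(False, False, delay)] = params.eta0 * t["a_minus"] + t["b_minus"]

    state = QState()
    records: List[TrialRecord] = []
    for t, (block, delay) in enumerate(seq):
        p_info = trial_choice_prob(state, params.sigma)
        is_info = u[t, 0] < p_info
        choice = "info" if is_info else "noinfo"
        rewarded = bool(u[t, 1] < design.p_reward)
        if is_info:
            cue = "reward_cue" if rewarded else "noreward_cue"
        else:
            cue = "none"
        outcome = "reward" if rewarded else "noreward"
        v = v_table[(bool(is_info), rewarded, delay)]
        state = q_update(state, choice, v, params.alpha)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                trial_index=t,
                block_index=block,
                delay_s=delay,
                choice=choice,
                cue=cue,
                outcome=outcome,
            )
        )
    return SubjectDataset(subject_id=subject_id, records=records)


def simulate_cohort(
    pop: PopulationSpec,
    design: ExperimentDesign,
) -> Tuple[List[SubjectDataset], List[TrialModelParams]]:
    """Sample a population and simulate every subject; seeds derive from
    ``pop.seed`` so the whole cohort is reproducible."""
    members = sample_population(pop)
    rng = np.random.default_rng(pop.seed + 1)
    seeds = rng.integers(0, 2**31 - 1, size=len(members))
    datasets = [
        simulate_subject(p, design, int(s), subject_id=f"s{i:03d}")
        for i, (p, s) in enumerate(zip(members, seeds))
    ]
    return datasets, members
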