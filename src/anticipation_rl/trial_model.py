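"""Trial-by-trial learning model of the human advance-information task.

On each trial the subject chooses between an informative target (followed
by a cue that announces reward or no-reward) and an uninformative one
(followed by the outcome alone after the same delay).  The chosen target's
learned value is updated by a delta rule toward the trial's experienced
value

    V = eta_S * A_i + B_i,        i = + (reward) or - (no-reward),

where A_i and B_i are the integrated anticipation and discounted outcome of
magnitude R_i, and eta_S is the anticipation weight of the path taken: the
informative cues evoke an RPE and are boosted (eta0 + c), the uninformative
path is not (eta0).  Choices are softmax in the learned value difference.

``make_model`` builds the nested family of restrictions used for model
comparison, from plain Q-learning (no anticipation, no discounting) to the
full boosted model with savouring (nu+), dread (nu-) and a free-signed
no-reward value R-.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit

from .core_valuation import discounted_reward, integrated_anticipation

__all__ = [
    "TrialModelParams",
    "ModelSpec",
    "TrialRecord",
    "SubjectDataset",
    "QState",
    "MODEL_NAMES",
    "outcome_value",
    "q_update",
    "trial_choice_prob",
    "session_loglik",
    "make_model",
    "read_trials",
    "write_trials",
    "datasets_to_frame",
]

CSV_COLUMNS = [
    "subject_id",
    "trial_index",
    "block_index",
    "delay_s",
    "choice",
    "cue",
    "outcome",
]

CHOICES = ("info", "noinfo")
CUES = ("reward_cue", "noreward_cue", "none")
OUTCOMES = ("reward", "noreward")


@dataclass(frozen=True)
class TrialModelParams:
    """Natural-scale parameters of the trial-by-trial model.

    alpha       learning rate in [0, 1]
    r_plus      value of the reward outcome (with c*sigma = 1, this is c*R+/sigma)
    r_minus     value of the no-reward outcome; its sign is free
    nu_plus     savouring (positive anticipation) rate, 1/s; 0 disables
    nu_minus    dread (negative anticipation) rate, 1/s; 0 disables
    gamma_plus  discount rate applied to the reward path, 1/s
    gamma_minus discount rate applied to the no-reward path, 1/s
    eta0        baseline anticipation weight (0 in the boosted models)
    c           boosting gain, fixed to 1 for fitting (absorbed into R+-)
    sigma       softmax temperature, fixed to 1 for fitting
    c_plus/c_minus  optional asymmetric gains for positive/negative RPEs
    """

    alpha: float
    r_plus: float
    r_minus: float = 0.0
    nu_plus: float = 0.0
    nu_minus: float = 0.0
    gamma_plus: float = 0.0
    gamma_minus: float = 0.0
    eta0: float = 0.0
    c: float = 1.0
    sigma: float = 1.0
    c_plus: Optional[float] = None
    c_minus: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("learning rate alpha must be in [0, 1]")
        for name in ("nu_plus", "nu_minus", "gamma_plus", "gamma_minus", "eta0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def gamma(self) -> float:
        return self.gamma_plus

    @property
    def gain_plus(self) -> float:
        return self.c if self.c_plus is None else self.c_plus

    @property
    def gain_minus(self) -> float:
        return self.c if self.c_minus is None else self.c_minus


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    trial_index: int
    block_index: int
    delay_s: float
    choice: str
    cue: str
    outcome: str

    def validate(self) -> List[str]:
        errs = []
        if self.choice not in CHOICES:
            errs.append(f"bad choice {self.choice!r}")
        if self.cue not in CUES:
            errs.append(f"bad cue {self.cue!r}")
        if self.outcome not in OUTCOMES:
            errs.append(f"bad outcome {self.outcome!r}")
        if self.choice == "info" and self.cue == "none":
            errs.append("informative choice must show a predictive cue")
        if self.choice == "noinfo" and self.cue != "none":
            errs.append("uninformative choice carries no predictive cue")
        if self.cue == "reward_cue" and self.outcome != "reward":
            errs.append("reward cue must be followed by reward")
        if self.cue == "noreward_cue" and self.outcome != "noreward":
            errs.append("no-reward cue must be followed by no-reward")
        if self.delay_s < 0:
            errs.append("negative delay")
        return errs


@dataclass
class SubjectDataset:
    """One subject's ordered session of trials."""

    subject_id: str
    records: List[TrialRecord]

    _arrays: Optional[tuple] = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        problems = []
        for rec in self.records:
            for msg in rec.validate():
                problems.append(f"trial {rec.trial_index}: {msg}")
        idx = [r.trial_index for r in self.records]
        if idx != sorted(idx):
            problems.append("records not ordered by trial_index")
        if problems:
            raise ValueError(
                f"invalid dataset for subject {self.subject_id}: "
                + "; ".join(problems)
            )

    @property
    def n_trials(self) -> int:
        return len(self.records)

    def arrays(self):
        """(is_info, is_reward, delay_idx, unique_delays) as numpy arrays."""
        if self._arrays is None:
            is_info = np.array(
                [r.choice == "info" for r in self.records], dtype=bool
            )
            is_reward = np.array(
                [r.outcome == "reward" for r in self.records], dtype=bool
            )
            delays = np.array([r.delay_s for r in self.records], dtype=float)
            uniq, inv = np.unique(delays, return_inverse=True)
            self._arrays = (is_info, is_reward, inv, uniq)
        return self._arrays


@dataclass(frozen=True)
class QState:
    q_info: float = 0.0
    q_noinfo: float = 0.0


# ---------------------------------------------------------------------------
# model zoo

_LOGIT_PARAMS = {"alpha"}
_LOG_PARAMS = {"nu_plus", "nu_minus", "gamma", "gamma_plus", "gamma_minus", "eta0"}

MODEL_NAMES = (
    "q_learning",
    "q_learning_discount",
    "anticipation_no_boost",
    "boosted_no_rminus",
    "boosted_no_discount",
    "boosted_full",
    "boosted_asymmetric",
)

_MODEL_DEFS: Dict[str, Tuple[Tuple[str, ...], Dict[str, float]]] = {
    # name: (free parameter names, fixed natural-scale values)
    "q_learning": (
        ("alpha", "r_plus", "r_minus"),
        {"nu_plus": 0.0, "nu_minus": 0.0, "gamma_plus": 0.0, "gamma_minus": 0.0},
    ),
    "q_learning_discount": (
        ("alpha", "r_plus", "r_minus", "gamma_plus", "gamma_minus"),
        {"nu_plus": 0.0, "nu_minus": 0.0},
    ),
    "anticipation_no_boost": (
        ("alpha", "r_plus", "r_minus", "gamma", "nu_plus", "nu_minus", "eta0"),
        {"c": 0.0},
    ),
    "boosted_no_rminus": (
        ("alpha", "r_plus", "gamma", "nu_plus"),
        {"r_minus": 0.0, "nu_minus": 0.0},
    ),
    "boosted_no_discount": (
        ("alpha", "r_plus", "r_minus", "nu_plus", "nu_minus"),
        {"gamma_plus": 0.0, "gamma_minus": 0.0},
    ),
    "boosted_full": (
        ("alpha", "r_plus", "r_minus", "gamma", "nu_plus", "nu_minus"),
        {},
    ),
    # Asymmetric boosting c+ != c- is absorbed into the fitted magnitudes of
    # R+ and R- (only the products c+R+ and c-R- enter the likelihood), so
    # the asymmetric variant shares the boosted_full parameterization and is
    # distinguished only by interpretation.
    "boosted_asymmetric": (
        ("alpha", "r_plus", "r_minus", "gamma", "nu_plus", "nu_minus"),
        {},
    ),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named restriction of the trial-by-trial model family."""

    name: str
    free_names: Tuple[str, ...]
    fixed: Dict[str, float]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    # -- natural <-> transformed maps -------------------------------------
    def transform(self, name: str, value: float) -> float:
        if name in _LOGIT_PARAMS:
            return float(logit(value))
        if name in _LOG_PARAMS:
            return math.log(value)
        return float(value)

    def untransform(self, name: str, value: float) -> float:
        if name in _LOGIT_PARAMS:
            return float(expit(value))
        if name in _LOG_PARAMS:
            return math.exp(value)
        return float(value)

    def params_from_values(self, values: Dict[str, float]) -> TrialModelParams:
        """Build TrialModelParams from natural-scale free values + restrictions."""
        merged = dict(self.fixed)
        merged.update(values)
        if "gamma" in merged:
            g = merged.pop("gamma")
            merged.setdefault("gamma_plus", g)
            merged.setdefault("gamma_minus", g)
        merged.setdefault("eta0", 0.0)
        merged.setdefault("c", 1.0)
        merged.setdefault("sigma", 1.0)
        merged.setdefault("r_minus", 0.0)
        merged.setdefault("nu_plus", 0.0)
        merged.setdefault("nu_minus", 0.0)
        merged.setdefault("gamma_plus", 0.0)
        merged.setdefault("gamma_minus", 0.0)
        return TrialModelParams(**merged)

    def natural_from_vector(self, x: Sequence[float]) -> TrialModelParams:
        if len(x) != self.n_free:
            raise ValueError(
                f"{self.name}: expected {self.n_free} parameters, got {len(x)}"
            )
        vals = {
            name: self.untransform(name, xi)
            for name, xi in zip(self.free_names, x)
        }
        return self.params_from_values(vals)

    def vector_from_natural(self, params: TrialModelParams) -> np.ndarray:
        out = []
        for name in self.free_names:
            v = params.gamma if name == "gamma" else getattr(params, name)
            out.append(self.transform(name, v))
        return np.asarray(out, dtype=float)


def make_model(name: str) -> ModelSpec:
    """Look up one of the named model restrictions (see ``MODEL_NAMES``)."""
    try:
        free, fixed = _MODEL_DEFS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {MODEL_NAMES}"
        ) from None
    return ModelSpec(name=name, free_names=free, fixed=dict(fixed))


# ---------------------------------------------------------------------------
# single-trial operations

def _path_terms(params: TrialModelParams, T: float) -> Dict[str, float]:
    """A and B for the reward (+) and no-reward (-) outcomes at delay T."""
    a_plus = (
        integrated_anticipation(params.r_plus, params.nu_plus, params.gamma_plus, T)
        if params.nu_plus > 0
        else 0.0
    )
    a_minus = (
        integrated_anticipation(params.r_minus, params.nu_minus, params.gamma_minus, T)
        if params.nu_minus > 0
        else 0.0
    )
    return {
        "a_plus": a_plus,
        "b_plus": discounted_reward(params.r_plus, params.gamma_plus, T),
        "a_minus": a_minus,
        "b_minus": discounted_reward(params.r_minus, params.gamma_minus, T),
    }


def outcome_value(
    params: TrialModelParams,
    event: Tuple[str, str, str],
    T: float,
) -> float:
    """Experienced value V of one trial's path.

    ``event`` is (choice, cue, outcome).  Informative cues evoke an RPE, so
    their anticipation weight is boosted (eta0 + c, or eta0 + c+/- for the
    asymmetric variant); the uninformative path is weighted by eta0 alone.
    """
    choice, cue, outcome = event
    rec = TrialRecord("", 0, 0, T, choice, cue, outcome)
    errs = rec.validate()
    if errs:
        raise ValueError("invalid event: " + "; ".join(errs))
    t = _path_terms(params, T)
    if outcome == "reward":
        eta = params.eta0 + (params.gain_plus if choice == "info" else 0.0)
        return eta * t["a_plus"] + t["b_plus"]
    eta = params.eta0 + (params.gain_minus if choice == "info" else 0.0)
    return eta * t["a_minus"] + t["b_minus"]


def q_update(state: QState, choice: str, V: float, alpha: float) -> QState:
    """Delta-rule update of the chosen target: Q <- Q + alpha*(V - Q)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if choice == "info":
        return QState(state.q_info + alpha * (V - state.q_info), state.q_noinfo)
    if choice == "noinfo":
        return QState(state.q_info, state.q_noinfo + alpha * (V - state.q_noinfo))
    raise ValueError(f"bad choice {choice!r}")


def trial_choice_prob(state: QState, sigma: float) -> float:
    """P(choose info) = logistic((q_info - q_noinfo)/sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(expit((state.q_info - state.q_noinfo) / sigma))


# ---------------------------------------------------------------------------
# session likelihood

def _trial_values(
    params: TrialModelParams, dataset: SubjectDataset
) -> Tuple[np.ndarray, np.ndarray]:
    """(v_trial, is_info): experienced value per trial, vectorized by delay."""
    is_info, is_reward, delay_idx, uniq = dataset.arrays()
    n_d = len(uniq)
    # path index: 0 info/reward, 1 info/noreward, 2 noinfo/reward, 3 noinfo/noreward
    v_table = np.empty((4, n_d))
    for k, T in enumerate(uniq):
        t = _path_terms(params, float(T))
        v_table[0, k] = (params.eta0 + params.gain_plus) * t["a_plus"] + t["b_plus"]
        v_table[1, k] = (params.eta0 + params.gain_minus) * t["a_minus"] + t["b_minus"]
        v_table[2, k] = params.eta0 * t["a_plus"] + t["b_plus"]
        v_table[3, k] = params.eta0 * t["a_minus"] + t["b_minus"]
    path = np.where(is_info, 0, 2) + np.where(is_reward, 0, 1)
    return v_table[path, delay_idx], is_info


def session_loglik(
    dataset: SubjectDataset,
    params: TrialModelParams,
    spec: Optional[ModelSpec] = None,
    delay_weights: Optional[Dict[float, float]] = None,
) -> float:
    """Total log-likelihood of one subject's observed choices.

    Both targets start at Q = 0; the chosen target's Q is updated each trial
    by the delta rule.  Because the choice sequence is observed, each
    target's Q trajectory is a fixed exponentially weighted average of the
    experienced values on its own trials, evaluated here with a linear
    filter rather than an explicit loop.  ``spec`` is accepted for interface
    symmetry; restrictions are already baked into ``params``.

    ``delay_weights`` optionally reweights each trial's log-probability by
    its delay condition (learning itself is untouched) — an alternative to
    subsampling for giving every delay condition equal influence.
    """
    if dataset.n_trials == 0:
        return 0.0
    v_trial, is_info = _trial_values(params, dataset)
    a = params.alpha
    n = dataset.n_trials

    for mask in (is_info, ~is_info):
        vm = v_trial[mask]
        if vm.size:
            # Q after m-th own trial: Q_m = (1-a)*Q_{m-1} + a*V_m, Q_0 = 0
            q_post = lfilter([a], [1.0, -(1.0 - a)], vm)
            ext = np.concatenate(([0.0], q_post))
            count_before = np.cumsum(mask) - mask
            q_series = ext[count_before]
        else:
            q_series = np.zeros(n)
        if mask is is_info:
            q_info_pre = q_series
        else:
            q_noinfo_pre = q_series

    z = (q_info_pre - q_noinfo_pre) / params.sigma
    # log P(info) = -log(1+exp(-z)); log P(noinfo) = -log(1+exp(z))
    ll = -np.logaddexp(0.0, np.where(is_info, -z, z))
    if delay_weights is not None:
        _, _, delay_idx, uniq = dataset.arrays()
        w = np.array([delay_weights.get(float(d), 1.0) for d in uniq])
        ll = ll * w[delay_idx]
    return float(ll.sum())


# ---------------------------------------------------------------------------
# CSV interchange

def datasets_to_frame(datasets: Sequence[SubjectDataset]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "trial_index": r.trial_index,
            "block_index": r.block_index,
            "delay_s": r.delay_s,
            "choice": r.choice,
            "cue": r.cue,
            "outcome": r.outcome,
        }
        for ds in datasets
        for r in ds.records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_trials(datasets: Sequence[SubjectDataset], path) -> None:
    datasets_to_frame(datasets).to_csv(path, index=False)


def read_trials(path) -> List[SubjectDataset]:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials CSV missing columns: {missing}")
    out: List[SubjectDataset] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial_index")
        records = [
            TrialRecord(
                subject_id=str(row.subject_id),
                trial_index=int(row.trial_index),
                block_index=int(row.block_index),
                delay_s=float(row.delay_s),
                choice=str(row.choice),
                cue=str(row.cue),
                outcome=str(row.outcome),
            )
            for row in grp.itertuples(index=False)
        ]
        ds = SubjectDataset(subject_id=str(sid), records=records)
        ds.validate()
        out.append(ds)
    return out
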