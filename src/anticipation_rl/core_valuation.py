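"""Closed-form valuation of reward-predictive cues under anticipatory utility.

A cue presented at t=0 predicts a reward of magnitude ``R`` delivered at
t=T.  While waiting, the agent enjoys (or suffers) anticipation worth
``a(t) = R * exp(-nu * (T - t))``: the anticipation ramps up toward the
moment of delivery at rate ``nu``.  Both the anticipation stream and the
reward itself are discounted exponentially at rate ``gamma``, so the cue is
worth

    Q = eta * A + B,
    A = R / (nu - gamma) * (exp(-gamma*T) - exp(-nu*T)),
    B = R * exp(-gamma*T),

where ``eta`` weights anticipation relative to consumption.  The central
hypothesis implemented here is that ``eta`` is not constant: it is boosted
by the magnitude of the reward prediction error (RPE) evoked by the cue,
``eta = eta0 + f(|delta_pe|)`` for one of several boosting ansatzes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "BoostSpec",
    "AnticipationParams",
    "CueValue",
    "integrated_anticipation",
    "discounted_reward",
    "boost_weight",
    "cue_value",
    "choice_probability",
]

#: |nu - gamma| below this fraction of max(nu, gamma) switches A to the
#: analytic nu == gamma limit R*T*exp(-gamma*T) (removable singularity).
NU_GAMMA_TOL = 1e-9

#: RPEs smaller than this in magnitude are treated as exactly zero, so a
#: fully predicted cue is never boosted by floating-point dust.
RPE_ZERO_TOL = 1e-12

BoostKind = Literal["linear", "tanh", "step", "none"]


@dataclass(frozen=True)
class BoostSpec:
    """How the anticipation weight responds to the RPE at the cue.

    kind='linear' : eta = eta0 + c * |delta_pe|
    kind='tanh'   : eta = eta0 + c1 * tanh(c2 * |delta_pe|)
    kind='step'   : eta = eta0 + c * theta(|delta_pe|), theta(x)=1 for x>0
    kind='none'   : eta = eta0 (no boosting; conventional anticipation RL)
    """

    kind: BoostKind = "linear"
    c: float = 0.0
    c1: float = 0.0
    c2: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "tanh", "step", "none"):
            raise ValueError(f"unknown boost kind: {self.kind!r}")
        if self.c < 0 or self.c1 < 0:
            raise ValueError("boost gains c, c1 must be non-negative")
        if self.c2 <= 0:
            raise ValueError("tanh slope c2 must be positive")

    @property
    def gain(self) -> float:
        """Effective gain (0 for kind='none')."""
        if self.kind == "none":
            return 0.0
        return self.c1 if self.kind == "tanh" else self.c

    @staticmethod
    def none() -> "BoostSpec":
        return BoostSpec(kind="none")


@dataclass(frozen=True)
class AnticipationParams:
    """Parameters of the anticipatory-utility valuation.

    R      reward magnitude (utility units)
    nu     anticipation growth rate (1/s)
    gamma  temporal discount rate (1/s)
    eta0   baseline anticipation weight (dimensionless)
    boost  RPE-boosting ansatz for the anticipation weight
    sigma  softmax temperature (utility units)
    """

    R: float
    nu: float
    gamma: float
    eta0: float
    boost: BoostSpec = field(default_factory=BoostSpec.none)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("anticipation rate nu must be positive")
        if self.gamma < 0:
            raise ValueError("discount rate gamma must be non-negative")
        if self.sigma <= 0:
            raise ValueError("softmax temperature sigma must be positive")
        if self.eta0 < 0:
            raise ValueError("baseline anticipation weight eta0 must be >= 0")

    def to_json(self) -> str:
        b = self.boost
        return json.dumps(
            {
                "R": self.R,
                "nu": self.nu,
                "gamma": self.gamma,
                "eta0": self.eta0,
                "sigma": self.sigma,
                "boost": {"kind": b.kind, "c": b.c, "c1": b.c1, "c2": b.c2},
            }
        )

    @staticmethod
    def from_json(text: str) -> "AnticipationParams":
        d = json.loads(text)
        bd = d.get("boost", {"kind": "none"})
        boost = BoostSpec(
            kind=bd.get("kind", "none"),
            c=bd.get("c", 0.0),
            c1=bd.get("c1", 0.0),
            c2=bd.get("c2", 1.0),
        )
        return AnticipationParams(
            R=d["R"],
            nu=d["nu"],
            gamma=d["gamma"],
            eta0=d["eta0"],
            sigma=d.get("sigma", 1.0),
            boost=boost,
        )


@dataclass(frozen=True)
class CueValue:
    """Value decomposition of one predictive cue: Q = eta*A + B."""

    A: float
    B: float
    eta: float

    @property
    def Q(self) -> float:
        return self.eta * self.A + self.B


def integrated_anticipation(R: float, nu: float, gamma: float, T: float) -> float:
    """Discounted anticipation integrated from cue onset to reward delivery.

    A = int_0^T exp(-gamma*t) * R * exp(-nu*(T-t)) dt
      = R/(nu-gamma) * (exp(-gamma*T) - exp(-nu*T)),

    with the continuous limit R*T*exp(-gamma*T) when nu == gamma.
    """
    if T < 0:
        raise ValueError("delay T must be non-negative")
    if nu <= 0:
        raise ValueError("anticipation rate nu must be positive")
    if gamma < 0:
        raise ValueError("discount rate gamma must be non-negative")
    if abs(nu - gamma) < NU_GAMMA_TOL * max(nu, gamma):
        return R * T * math.exp(-gamma * T)
    return R / (nu - gamma) * (math.exp(-gamma * T) - math.exp(-nu * T))


def discounted_reward(R: float, gamma: float, T: float) -> float:
    """Exponentially discounted value of the reward itself: B = R*exp(-gamma*T)."""
    if T < 0:
        raise ValueError("delay T must be non-negative")
    if gamma < 0:
        raise ValueError("discount rate gamma must be non-negative")
    return R * math.exp(-gamma * T)


def boost_weight(eta0: float, boost: BoostSpec, delta_pe: float) -> float:
    """Realized anticipation weight for a cue that evoked RPE ``delta_pe``.

    Boosting always acts on the absolute value of the RPE: surprising news
    of *either* sign intensifies the anticipation (savouring or dread) of
    the outcome it announces.
    """
    x = abs(delta_pe)
    if x < RPE_ZERO_TOL:
        x = 0.0
    if boost.kind == "none":
        return eta0
    if boost.kind == "linear":
        return eta0 + boost.c * x
    if boost.kind == "tanh":
        return eta0 + boost.c1 * math.tanh(boost.c2 * x)
    if boost.kind == "step":
        return eta0 + (boost.c if x > 0 else 0.0)
    raise ValueError(f"unknown boost kind: {boost.kind!r}")


def cue_value(params: AnticipationParams, T: float, eta: float) -> CueValue:
    """Assemble the cue value Q = eta*A + B at a realized anticipation weight."""
    A = integrated_anticipation(params.R, params.nu, params.gamma, T)
    B = discounted_reward(params.R, params.gamma, T)
    return CueValue(A=A, B=B, eta=eta)


def choice_probability(q_x: float, q_y: float, sigma: float) -> float:
    """Softmax (logistic) probability of choosing x over y at temperature sigma."""
    if sigma <= 0:
        raise ValueError("softmax temperature sigma must be positive")
    z = (q_x - q_y) / sigma
    # saturate rather than overflow
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)
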