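"""Self-consistent reward-prediction errors under RPE-boosted anticipation.

Because the RPE at a predictive cue boosts the cue's value, and the cue's
value in turn determines the RPE, the equilibrium RPE solves a fixed-point
equation.  With a boosting ansatz ``f`` the equation takes the form

    delta = slope * f(|delta|) + intercept

where slope and intercept are set by the task (reward probabilities,
anticipation and discounting).  The linear ansatz admits a closed-form
solution that ceases to exist when slope >= 1 with a positive intercept
(unbounded boosting); the tanh ansatz always has a solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_valuation import AnticipationParams, BoostSpec, CueValue, RPE_ZERO_TOL

__all__ = [
    "SelfConsistencyProblem",
    "FixedPointResult",
    "NoSolutionError",
    "solve_selfconsistent",
    "boosted_cue_value",
    "stability_boundary_sweep",
]

_BISECT_TOL = 1e-12


class NoSolutionError(RuntimeError):
    """The self-consistency equation has no finite solution (boost diverges)."""

    def __init__(self, message: str, margin: float = float("nan")):
        super().__init__(message)
        #: stability margin 1 - slope; <= 0 means divergence
        self.margin = margin


@dataclass(frozen=True)
class SelfConsistencyProblem:
    """delta = slope * f(|delta|) + intercept, with f set by ``boost.kind``.

    For kind='linear' and 'step' the slope multiplies |delta| resp.
    theta(|delta|) directly; for kind='tanh' the equation reads
    delta = slope * tanh(c2 * |delta|) + intercept.
    """

    slope: float
    intercept: float
    boost: BoostSpec


@dataclass(frozen=True)
class FixedPointResult:
    delta_pe: float
    exists: bool
    stability_margin: float

    def residual(self, problem: SelfConsistencyProblem) -> float:
        """Defect of the fixed-point equation at the returned solution."""
        d = self.delta_pe
        k = problem.boost.kind
        if k in ("linear", "none"):
            rhs = problem.slope * abs(d) + problem.intercept
        elif k == "tanh":
            rhs = problem.slope * math.tanh(problem.boost.c2 * abs(d)) + problem.intercept
        elif k == "step":
            rhs = problem.slope * (1.0 if abs(d) > RPE_ZERO_TOL else 0.0) + problem.intercept
        else:  # pragma: no cover
            raise ValueError(f"unknown boost kind {k!r}")
        return d - rhs


def _solve_linear(alpha: float, beta: float) -> FixedPointResult:
    # delta > 0 branch: delta = alpha*delta + beta  -> beta/(1-alpha)
    # delta < 0 branch: delta = -alpha*delta + beta -> beta/(1+alpha)
    if abs(beta) < RPE_ZERO_TOL:
        return FixedPointResult(0.0, True, 1.0 - alpha)
    if beta > 0:
        if alpha >= 1.0:
            return FixedPointResult(math.nan, False, 1.0 - alpha)
        return FixedPointResult(beta / (1.0 - alpha), True, 1.0 - alpha)
    return FixedPointResult(beta / (1.0 + alpha), True, 1.0 + alpha)


def _solve_tanh(alpha: float, c2: float, beta: float) -> FixedPointResult:
    # Root of g(d) = d - alpha*tanh(c2*|d|) - beta on the branch whose sign
    # matches the unboosted solution (sign of beta).  g is continuous with
    # g(d) -> +/- inf, so a bracket always exists; bisection is safe.
    if abs(beta) < RPE_ZERO_TOL and alpha * c2 <= 1.0:
        return FixedPointResult(0.0, True, 1.0 - alpha * c2)

    sign = 1.0 if beta >= 0 else -1.0

    def g(d: float) -> float:
        return d - alpha * math.tanh(c2 * abs(d)) - beta

    lo, hi = 0.0, abs(beta) + abs(alpha) + 1.0
    # grow the bracket geometrically until the sign changes
    while g(sign * hi) * g(sign * lo) > 0:
        lo = hi
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - g is eventually dominated by d
            raise NoSolutionError("tanh fixed point: bracket growth failed")
    a, b = sign * lo, sign * hi
    fa = g(a)
    # bisect to full float resolution (midpoint collides with an endpoint)
    while True:
        m = 0.5 * (a + b)
        if m == a or m == b:
            break
        fm = g(m)
        if fm == 0.0:
            a = b = m
            break
        if fa * fm < 0:
            b = m
        else:
            a, fa = m, fm
    d = 0.5 * (a + b)
    # local stability: derivative of rhs at the solution
    margin = 1.0 - alpha * c2 / math.cosh(c2 * abs(d)) ** 2
    return FixedPointResult(d, True, margin)


def _solve_step(alpha: float, beta: float) -> FixedPointResult:
    cand = alpha + beta
    if abs(cand) > RPE_ZERO_TOL:
        return FixedPointResult(cand, True, 1.0)
    return FixedPointResult(beta, abs(beta) < RPE_ZERO_TOL, 1.0)


def solve_selfconsistent(problem: SelfConsistencyProblem) -> FixedPointResult:
    """Solve the self-consistency equation for the boosting ansatz in ``problem``.

    ``exists=False`` (linear ansatz, slope >= 1 with positive intercept) is a
    result, not an exception: callers decide whether divergence is an error.
    """
    kind = problem.boost.kind
    if kind in ("linear", "none"):
        a = 0.0 if kind == "none" else problem.slope
        return _solve_linear(a, problem.intercept)
    if kind == "tanh":
        return _solve_tanh(problem.slope, problem.boost.c2, problem.intercept)
    if kind == "step":
        return _solve_step(problem.slope, problem.intercept)
    raise ValueError(f"unknown boost kind: {kind!r}")


def boosted_cue_value(p_cue: float, params: AnticipationParams, T: float) -> CueValue:
    """Equilibrium value of a reward-predictive cue that follows the chosen
    target with probability ``p_cue``.

    The RPE at the cue is delta = Q_cue - p_cue*Q_cue = (1-p_cue)*Q_cue, and
    Q_cue = (eta0 + boost(|delta|))*A + B, closing the loop.  For the linear
    ansatz the solution is

        Q_cue = (eta0*A + B) / (1 - (1-p_cue)*c*A)

    valid only while (1-p_cue)*c*A < 1; violation raises NoSolutionError
    carrying the stability margin.
    """
    if not (0.0 < p_cue <= 1.0):
        raise ValueError("p_cue must be in (0, 1]")
    from .core_valuation import discounted_reward, integrated_anticipation

    A = integrated_anticipation(params.R, params.nu, params.gamma, T)
    B = discounted_reward(params.R, params.gamma, T)
    q = 1.0 - p_cue
    boost = params.boost
    base = params.eta0 * A + B
    problem = SelfConsistencyProblem(
        slope=q * boost.gain * A, intercept=q * base, boost=boost
    )
    res = solve_selfconsistent(problem)
    if not res.exists:
        raise NoSolutionError(
            "boosted cue value diverges: (1-p_cue)*c*A = "
            f"{q * boost.gain * A:.6g} >= 1",
            margin=res.stability_margin,
        )
    if q == 0.0:
        # fully predicted cue: no RPE, no boosting
        return CueValue(A=A, B=B, eta=params.eta0)
    from .core_valuation import boost_weight

    eta = boost_weight(params.eta0, boost, res.delta_pe)
    return CueValue(A=A, B=B, eta=eta)


def stability_boundary_sweep(
    q: float = 0.5,
    v_anticipation: float = 0.5,
    v_reward: float = 0.4,
    eta0: float = 1.0,
    resolution: float = 1e-4,
    c_max: float = 8.0,
    damping: float = 0.5,
    n_iter: int = 200,
):
    """Brute-force location of the linear-ansatz existence boundary.

    Sweeps the boost gain ``c`` on a grid and, for each value, decides
    whether the fixed-point equation

        delta = (1 - q) * ((eta0 + c*delta) * V_A + V_R)

    has a finite positive solution, both by the closed form (slope < 1) and
    by damped iteration (the per-step contraction ratio of the increments).
    Returns a dict with the largest existing gain and the product
    (1 - q) * c * V_A at the boundary from both routes — theoretically this
    product equals 1 where the solution ceases to exist.
    """
    import numpy as np

    cs = np.arange(resolution, c_max + resolution / 2, resolution)
    slope = (1.0 - q) * cs * v_anticipation
    beta = (1.0 - q) * (eta0 * v_anticipation + v_reward)
    if beta <= 0:
        raise ValueError("sweep assumes a positive intercept")
    exists_closed = slope < 1.0

    # damped iteration: delta <- (1-d)*delta + d*(slope*delta + beta);
    # increments contract iff the solution exists, so the empirical
    # step-ratio classifies each cell
    delta = np.full_like(cs, 1.0)
    prev_inc = None
    ratio = np.full_like(cs, np.nan)
    for _ in range(n_iter):
        new = (1.0 - damping) * delta + damping * (slope * delta + beta)
        inc = new - delta
        if prev_inc is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.abs(inc) / np.abs(prev_inc)
            ratio = np.where(np.isfinite(r), r, ratio)
        prev_inc = inc
        delta = new
    exists_iter = ratio < 1.0 - 1e-12
    # converged cells have increments at rounding level; classify as existing
    exists_iter |= np.abs(prev_inc) < 1e-12

    def boundary(mask):
        idx = np.flatnonzero(mask)
        if len(idx) == 0 or mask.all():
            raise ValueError("boundary not bracketed by the sweep grid")
        last = idx[-1]
        return float(cs[last]), float((1.0 - q) * cs[last] * v_anticipation)

    c_closed, prod_closed = boundary(exists_closed)
    c_iter, prod_iter = boundary(exists_iter)
    return {
        "c_last_closed_form": c_closed,
        "c_last_iterative": c_iter,
        "boundary_product_closed_form": prod_closed,
        "boundary_product_iterative": prod_iter,
        "resolution": resolution,
    }
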