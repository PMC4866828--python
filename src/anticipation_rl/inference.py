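"""Hierarchical Bayesian (random-effects) fitting of the trial-by-trial model.

Per-subject parameters, suitably transformed (logit for the learning rate,
log for rates, identity for outcome values), are modelled as draws from a
diagonal Gaussian whose mean and variance are estimated by approximate
Expectation-Maximization:

* E-step — per subject, a Laplace approximation around the MAP estimate
  under the current group prior (multi-start quasi-Newton optimization;
  covariance from the numerically differentiated Hessian);
* M-step — moment updates of the group mean and variance that account for
  per-subject posterior uncertainty.

Model comparison uses the integrated BIC: -2 times the group-prior-
marginalized data log-likelihood (a Monte-Carlo average over prior draws)
plus a complexity penalty counting the prior's fitted parameters (one mean
and one variance per free model parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .trial_model import ModelSpec, SubjectDataset, TrialRecord, session_loglik

__all__ = [
    "GroupPrior",
    "SubjectPosterior",
    "FitSettings",
    "FitResult",
    "IbicScore",
    "subject_map",
    "condition_weights",
    "em_fit",
    "balance_trials",
    "ibic",
    "compare_models",
]


@dataclass(frozen=True)
class GroupPrior:
    """Diagonal Gaussian over transformed parameters."""

    names: tuple
    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if len(self.mu) != len(self.names) or len(self.var) != len(self.names):
            raise ValueError("prior dimension mismatch")
        if np.any(self.var < 0):
            raise ValueError("prior variances must be non-negative")

    def logpdf(self, h: np.ndarray) -> float:
        v = self.var
        return float(
            -0.5 * np.sum((h - self.mu) ** 2 / v)
            - 0.5 * np.sum(np.log(2.0 * np.pi * v))
        )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.mu + np.sqrt(self.var) * rng.standard_normal(
            (size, len(self.mu))
        )

    def as_dict(self) -> Dict[str, Dict[str, float]]:
        return {
            n: {"mu": float(m), "var": float(v)}
            for n, m, v in zip(self.names, self.mu, self.var)
        }


@dataclass(frozen=True)
class SubjectPosterior:
    """Laplace approximation N(m, cov) of one subject's posterior."""

    m: np.ndarray
    cov: np.ndarray
    logpost: float


@dataclass(frozen=True)
class IbicScore:
    score: float
    log_marginal: float
    penalty: float
    n_prior_params: int
    n_datapoints: int
    K: int


@dataclass(frozen=True)
class FitSettings:
    """Numerical settings of the EM fit; defaults favour robustness."""

    max_em_iter: int = 200
    em_tol: float = 1e-4
    n_restarts: int = 5
    hessian_step: float = 1e-4
    var_floor: float = 1e-6
    eig_floor: float = 1e-8
    ibic_K: int = 10_000
    seed: int = 0
    #: weight each trial's log-likelihood by min-count/count of its delay
    #: condition during fitting — the reweighting alternative to subsampling
    weight_by_condition: bool = False


@dataclass
class FitResult:
    spec: ModelSpec
    prior: GroupPrior
    posteriors: List[SubjectPosterior]
    n_em_iterations: int
    converged: bool
    evidence_trace: List[float]
    ibic: Optional[IbicScore] = None

    def group_means_natural(self) -> Dict[str, float]:
        return {
            n: self.spec.untransform(n, float(m))
            for n, m in zip(self.prior.names, self.prior.mu)
        }

    def group_sd_transformed(self) -> Dict[str, float]:
        return {
            n: float(np.sqrt(v))
            for n, v in zip(self.prior.names, self.prior.var)
        }

    def posterior_group_sd(self) -> Dict[str, float]:
        """Posterior standard deviation of the group mean (transformed scale).

        Under the Laplace approximation each subject's Fisher information
        about the group mean mu is Sigma^-1 (Sigma - Sigma_i) Sigma^-1 (the
        exact result when the subject likelihood is Gaussian): a subject
        whose posterior is as wide as the prior carries no information,
        while sharp posteriors contribute the familiar Sigma^-1, recovering
        sqrt(Sigma/N) when every subject is well determined.  The full
        matrices matter — correlated (ridge-like) parameters have marginal
        uncertainties far larger than their conditional curvatures — so the
        SD is taken from the diagonal of the inverse total information.
        """
        prec = np.diag(1.0 / self.prior.var)
        sigma = np.diag(self.prior.var)
        d = len(self.prior.var)
        info = np.zeros((d, d))
        for p in self.posteriors:
            contrib = prec @ (sigma - p.cov) @ prec
            contrib = 0.5 * (contrib + contrib.T)
            # Sigma_i <= Sigma holds exactly, so negative directions are
            # finite-difference noise: clip the contribution to its PSD part
            w, V = np.linalg.eigh(contrib)
            info += (V * np.maximum(w, 0.0)) @ V.T
        w, V = np.linalg.eigh(info)
        w = np.maximum(w, 1e-8 * max(w.max(), 1.0))
        cov_mu = (V / w) @ V.T
        return {
            name: float(np.sqrt(cov_mu[i, i]))
            for i, name in enumerate(self.prior.names)
        }


# transformed-scale optimizer bounds: wide enough to be unconstraining for
# plausible behaviour, tight enough to keep exp() finite
_LOG_BOUND = (-20.0, 6.0)
_GEN_BOUND = (-30.0, 30.0)


def _bounds(spec: ModelSpec):
    from .trial_model import _LOG_PARAMS

    return [
        _LOG_BOUND if name in _LOG_PARAMS else _GEN_BOUND
        for name in spec.free_names
    ]


def condition_weights(dataset: SubjectDataset) -> Dict[float, float]:
    """Per-delay weights min_count/count, equalizing condition influence."""
    counts: Dict[float, int] = {}
    for rec in dataset.records:
        counts[rec.delay_s] = counts.get(rec.delay_s, 0) + 1
    n_min = min(counts.values())
    return {d: n_min / n for d, n in counts.items()}


def _neg_log_post(h, dataset, prior, spec, weights=None):
    try:
        params = spec.natural_from_vector(h)
    except (ValueError, OverflowError):
        return 1e12
    ll = session_loglik(dataset, params, spec, delay_weights=weights)
    lp = prior.logpdf(np.asarray(h))
    val = -(ll + lp)
    if not np.isfinite(val):
        return 1e12
    return val


def _numerical_hessian(f, x: np.ndarray, step: float) -> np.ndarray:
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def _repaired_inverse(H: np.ndarray, eig_floor: float) -> np.ndarray:
    """Inverse of H with eigenvalues floored so the result is a valid
    covariance even when the numerical Hessian is indefinite."""
    Hs = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(Hs)
    w = np.maximum(w, eig_floor)
    return (V / w) @ V.T


def subject_map(
    dataset: SubjectDataset,
    prior: GroupPrior,
    spec: ModelSpec,
    settings: FitSettings = FitSettings(),
    rng: Optional[np.random.Generator] = None,
    warm_start: Optional[np.ndarray] = None,
) -> SubjectPosterior:
    """MAP estimate and Laplace covariance of one subject's parameters."""
    if dataset.n_trials == 0:
        raise ValueError("cannot fit an empty dataset")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    d = len(prior.mu)
    sd = np.sqrt(np.maximum(prior.var, settings.var_floor))
    starts = [prior.mu.copy()]
    if warm_start is not None:
        starts.insert(0, np.asarray(warm_start, dtype=float))
    while len(starts) < max(settings.n_restarts, 1):
        starts.append(prior.mu + sd * rng.standard_normal(d))

    weights = condition_weights(dataset) if settings.weight_by_condition else None
    bounds = _bounds(spec)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _neg_log_post,
            x0,
            args=(dataset, prior, spec, weights),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"subject {dataset.subject_id}: MAP optimization failed on all "
            f"{len(starts)} restarts"
        )
    m = np.asarray(best.x, dtype=float)
    H = _numerical_hessian(
        lambda h: _neg_log_post(h, dataset, prior, spec, weights),
        m, settings.hessian_step,
    )
    cov = _repaired_inverse(H, settings.eig_floor)
    return SubjectPosterior(m=m, cov=cov, logpost=-float(best.fun))


_DEFAULT_INIT_NATURAL = {
    "alpha": 0.3,
    "r_plus": 0.5,
    "r_minus": -0.1,
    "nu_plus": 0.1,
    "nu_minus": 0.1,
    "gamma": 0.05,
    "gamma_plus": 0.05,
    "gamma_minus": 0.05,
    "eta0": 0.5,
}


def default_prior(spec: ModelSpec) -> GroupPrior:
    """Broad starting prior for EM; means at unremarkable natural values."""
    mu = np.array(
        [spec.transform(n, _DEFAULT_INIT_NATURAL[n]) for n in spec.free_names]
    )
    var = np.ones(len(mu))
    return GroupPrior(names=tuple(spec.free_names), mu=mu, var=var)


def em_fit(
    datasets: Sequence[SubjectDataset],
    spec: ModelSpec,
    settings: FitSettings = FitSettings(),
    init_prior: Optional[GroupPrior] = None,
) -> FitResult:
    """Fit the group prior by Laplace-approximate EM.

    Alternates per-subject MAP (E) with moment updates of the group mean and
    diagonal variance (M) until the mean moves by less than ``em_tol``.
    Later iterations warm-start each subject at its previous MAP with a
    single restart, which keeps the cost of the many small corrective
    iterations low.
    """
    if len(datasets) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    rng = np.random.default_rng(settings.seed)
    prior = init_prior if init_prior is not None else default_prior(spec)
    posteriors: List[Optional[SubjectPosterior]] = [None] * len(datasets)
    evidence_trace: List[float] = []
    converged = False
    it = 0
    for it in range(1, settings.max_em_iter + 1):
        iter_settings = settings if it == 1 else replace(settings, n_restarts=1)
        new_post = []
        for k, ds in enumerate(datasets):
            warm = posteriors[k].m if posteriors[k] is not None else None
            new_post.append(
                subject_map(ds, prior, spec, iter_settings, rng, warm_start=warm)
            )
        posteriors = new_post

        # Laplace log-evidence surrogate, for monitoring monotonicity
        ev = sum(
            p.logpost + 0.5 * np.linalg.slogdet(2.0 * np.pi * p.cov)[1]
            for p in posteriors
        )
        evidence_trace.append(float(ev))

        M = np.stack([p.m for p in posteriors])
        S = np.stack([np.diag(p.cov) for p in posteriors])
        mu_new = M.mean(axis=0)
        var_new = (M**2 + S).mean(axis=0) - mu_new**2
        var_new = np.maximum(var_new, settings.var_floor)
        delta = float(np.max(np.abs(mu_new - prior.mu)))
        prior = GroupPrior(names=prior.names, mu=mu_new, var=var_new)
        if delta < settings.em_tol:
            converged = True
            break
    return FitResult(
        spec=spec,
        prior=prior,
        posteriors=list(posteriors),
        n_em_iterations=it,
        converged=converged,
        evidence_trace=evidence_trace,
    )


def balance_trials(dataset: SubjectDataset, seed: int) -> SubjectDataset:
    """Equalize trial counts across delay conditions by random subsampling.

    Keeps min-count trials per delay (without replacement), preserving the
    original trial order, so every condition contributes equally to the fit.
    """
    rng = np.random.default_rng(seed)
    by_delay: Dict[float, List[TrialRecord]] = {}
    for rec in dataset.records:
        by_delay.setdefault(rec.delay_s, []).append(rec)
    n_min = min(len(v) for v in by_delay.values())
    keep = []
    for delay in sorted(by_delay):
        recs = by_delay[delay]
        idx = rng.choice(len(recs), size=n_min, replace=False)
        keep.extend(recs[i] for i in sorted(idx))
    keep.sort(key=lambda r: r.trial_index)
    return SubjectDataset(subject_id=dataset.subject_id, records=keep)


def ibic(
    datasets: Sequence[SubjectDataset],
    spec: ModelSpec,
    prior: GroupPrior,
    K: int = 10_000,
    seed: int = 0,
) -> IbicScore:
    """Integrated BIC of a fitted group prior.

    The per-subject marginal likelihood is a Monte-Carlo average of the
    session likelihood over ``K`` prior draws (computed in log space); the
    penalty counts one mean and one variance per free parameter against the
    total number of choices.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    draws = prior.sample(rng, K)
    params_list = [spec.natural_from_vector(h) for h in draws]
    log_marg = 0.0
    for ds in datasets:
        lls = np.array([session_loglik(ds, p, spec) for p in params_list])
        log_marg += float(logsumexp(lls) - np.log(K))
    n_prior = 2 * spec.n_free
    n_data = sum(ds.n_trials for ds in datasets)
    penalty = n_prior * np.log(n_data)
    return IbicScore(
        score=float(-2.0 * log_marg + penalty),
        log_marginal=float(log_marg),
        penalty=float(penalty),
        n_prior_params=n_prior,
        n_datapoints=n_data,
        K=K,
    )


def compare_models(
    datasets: Sequence[SubjectDataset],
    specs: Sequence[ModelSpec],
    settings: FitSettings = FitSettings(),
) -> pd.DataFrame:
    """Fit every model and rank by iBIC (lower is better)."""
    rows = []
    for spec in specs:
        fit = em_fit(datasets, spec, settings)
        score = ibic(
            datasets, spec, fit.prior, K=settings.ibic_K, seed=settings.seed
        )
        fit.ibic = score
        rows.append(
            {
                "model": spec.name,
                "n_params": spec.n_free,
                "ibic": score.score,
                "log_marginal": score.log_marginal,
                "penalty": score.penalty,
                "converged": fit.converged,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("ibic").reset_index(drop=True)
    )
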