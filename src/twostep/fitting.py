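"""Hierarchical empirical-Bayes fitting and iBIC model comparison.

Free parameters are optimised in an unconstrained space: logit for the
unit-interval parameters (α₁, α₂, λ, ω), log for the inverse temperatures
(β₁, β₂) and identity for ρ.  Each subject gets a MAP estimate under a
Gaussian prior on the transformed parameters; expectation–maximization
alternates these MAP fits (with Laplace covariances) against updates of the
prior mean and variance, so the prior is learned from the whole cohort.
Model evidence is the Monte-Carlo marginal likelihood under the fitted
prior, penalised by the number of prior hyperparameters times the log of
the total number of observed choices (integrated BIC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .agents import PARAM_NAMES, ModelSpec, Parameters
from .task import SessionData, TaskConfig

__all__ = [
    "transform",
    "inverse_transform",
    "GroupPrior",
    "FitResult",
    "EMResult",
    "map_fit_subject",
    "em_fit_group",
    "ibic_penalty",
    "integrated_bic",
    "IBICResult",
    "ModelComparison",
    "compare_models",
    "default_prior",
    "fits_to_frame",
]

logger = logging.getLogger(__name__)

_LOGIT_PARAMS = frozenset({"alpha1", "alpha2", "lam", "omega"})
_LOG_PARAMS = frozenset({"beta1", "beta2"})

VAR_FLOOR = 1e-6  # smallest admissible prior variance in transformed space


def _to_unconstrained(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        if not 0 < value < 1:
            raise ValueError(f"{name}={value} is on/outside (0, 1); logit undefined")
        return float(logit(value))
    if name in _LOG_PARAMS:
        if value <= 0:
            raise ValueError(f"{name}={value} must be > 0; log undefined")
        return float(np.log(value))
    return float(value)


def _from_unconstrained(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        return float(expit(value))
    if name in _LOG_PARAMS:
        return float(np.exp(value))
    return float(value)


def transform(
    natural: Parameters, names: Sequence[str] = PARAM_NAMES
) -> np.ndarray:
    """Map natural-space parameters to the unconstrained fitting space."""
    return np.array(
        [_to_unconstrained(n, getattr(natural, n)) for n in names], dtype=float
    )


def inverse_transform(
    vec: np.ndarray,
    names: Sequence[str] = PARAM_NAMES,
    base: Parameters | None = None,
) -> Parameters:
    """Map an unconstrained vector back to natural space.

    Parameters absent from ``names`` keep their value in ``base`` (defaults).
    """
    values = dict(zip(names, vec))
    kwargs = {n: _from_unconstrained(n, float(values[n])) for n in names}
    out = (base or Parameters()).replace(**kwargs)
    return out


@dataclass(frozen=True)
class GroupPrior:
    """Gaussian prior (mean, variance) per free transformed parameter."""

    names: tuple[str, ...]
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.mean) == len(self.var)):
            raise ValueError("names, mean and var must have equal length")
        if np.any(np.asarray(self.var) <= 0):
            raise ValueError("prior variances must be strictly positive")

    @property
    def n_hyper(self) -> int:
        return 2 * len(self.names)

    def neg_log_pdf(self, theta: np.ndarray) -> float:
        q = 0.5 * np.sum((theta - self.mean) ** 2 / self.var)
        norm = 0.5 * np.sum(np.log(2 * np.pi * self.var))
        return float(q + norm)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.var), size=(n, len(self.names)))


def default_prior(spec: ModelSpec, sd: float = 2.5) -> GroupPrior:
    """Diffuse starting prior: logit/ρ coordinates centred at 0, log-β at log 5."""
    names = spec.free_names
    mean = np.array([np.log(5.0) if n in _LOG_PARAMS else 0.0 for n in names])
    return GroupPrior(names=names, mean=mean, var=np.full(len(names), sd**2))


@dataclass
class FitResult:
    """Per-subject MAP fit: estimate, curvature, and convergence diagnostics."""

    subject_id: str
    model: str
    names: tuple[str, ...]
    theta: np.ndarray  # transformed-space MAP
    params: Parameters  # natural space, spec fixings applied
    neg_log_lik: float  # likelihood-only at the MAP
    neg_log_post: float  # penalised objective at the MAP (no prior normalisation)
    hessian: np.ndarray  # of the penalised objective, transformed space
    cov: np.ndarray  # Laplace covariance (pseudo-)inverse of the Hessian
    converged: bool
    n_restarts: int


class EMResult(NamedTuple):
    prior: GroupPrior
    fits: list[FitResult]
    history: pd.DataFrame


def _numerical_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return 0.5 * (H + H.T)


def _laplace_cov(hessian: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hessian)
    if not np.all(np.isfinite(cov)):
        cov = np.linalg.pinv(hessian)
    return 0.5 * (cov + cov.T)


def _make_objective(
    session: SessionData, prior: GroupPrior, spec: ModelSpec, config: TaskConfig
):
    from . import _kernels

    names = prior.names
    idx = [PARAM_NAMES.index(n) for n in names]
    base = spec.apply(Parameters()).as_vector()
    mean, var = prior.mean, prior.var
    a1, s2 = session.first_choice, session.second_state
    a2, r = session.second_choice, session.reward
    p_common = config.p_common
    is_logit = np.array([n in _LOGIT_PARAMS for n in names])
    is_log = np.array([n in _LOG_PARAMS for n in names])

    def natural(theta: np.ndarray) -> np.ndarray:
        # cap the log-β coordinates: e^30 is already an effectively greedy policy
        vals = np.where(
            is_logit, expit(theta), np.where(is_log, np.exp(np.minimum(theta, 30.0)), theta)
        )
        full = base.copy()
        full[idx] = vals
        return full

    def nll(theta: np.ndarray) -> float:
        return float(_kernels.session_nll(natural(theta), p_common, a1, s2, a2, r))

    def objective(theta: np.ndarray) -> float:
        val = nll(theta) + 0.5 * np.sum((theta - mean) ** 2 / var)
        return val if np.isfinite(val) else 1e12

    return objective, nll, natural


def map_fit_subject(
    session: SessionData,
    prior: GroupPrior,
    spec: ModelSpec,
    config: TaskConfig | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> FitResult:
    """MAP estimate of one subject's parameters under a Gaussian prior.

    Minimises −LL(θ) − log N(θ; prior) over the transformed space from
    ``n_restarts`` starts (prior mean, optional warm start, jittered draws);
    the best optimum is returned with a finite-difference Hessian.  If no
    restart converges the best point found is still returned, flagged.
    """
    config = config or TaskConfig(n_trials=session.n_trials)
    objective, nll, natural = _make_objective(session, prior, spec, config)
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if start is not None:
        starts.append(np.asarray(start, float))
    starts.append(prior.mean.copy())
    while len(starts) < n_restarts:
        starts.append(prior.mean + rng.normal(0, 1, len(prior.names)) * np.sqrt(prior.var))
    best = None
    converged = False
    for x0 in starts[:n_restarts] if n_restarts > 0 else starts[:1]:
        res = minimize(objective, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    theta = np.asarray(best.x, float)
    hessian = _numerical_hessian(objective, theta)
    params = inverse_transform(theta, prior.names)
    return FitResult(
        subject_id=session.subject_id,
        model=spec.name,
        names=prior.names,
        theta=theta,
        params=spec.apply(params),
        neg_log_lik=nll(theta),
        neg_log_post=float(best.fun),
        hessian=hessian,
        cov=_laplace_cov(hessian),
        converged=converged,
        n_restarts=len(starts),
    )


def _laplace_neg_log_marginal(fit: FitResult, prior: GroupPrior) -> float:
    d = len(prior.names)
    eigs = np.clip(np.linalg.eigvalsh(fit.hessian), 1e-8, None)
    return float(
        fit.neg_log_post
        + 0.5 * np.sum(np.log(2 * np.pi * prior.var))  # prior normalisation
        - 0.5 * d * np.log(2 * np.pi)
        + 0.5 * np.sum(np.log(eigs))
    )


def em_fit_group(
    sessions: Sequence[SessionData],
    spec: ModelSpec,
    config: TaskConfig | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
    n_restarts: int = 5,
    seed: int = 0,
    var_floor: float = VAR_FLOOR,
) -> EMResult:
    """Empirical-Bayes EM over a cohort.

    E-step: per-subject MAP fit (warm-started from the previous iteration)
    plus Laplace covariance under the current prior.  M-step: prior means are
    the average MAP estimates; prior variances add the average Laplace
    variance to the between-subject spread and are floored at ``var_floor``.
    Stops when the largest absolute change in prior means drops below
    ``tol``.
    """
    if len(sessions) < 1:
        raise ValueError("EM requires at least 1 session")
    if len(sessions) == 1:
        logger.warning("single-session cohort: prior variance is Laplace-only")
    config = config or TaskConfig(n_trials=sessions[0].n_trials)
    prior = default_prior(spec)
    d = len(prior.names)
    warm: list[np.ndarray | None] = [None] * len(sessions)
    rng = np.random.default_rng(seed)
    history = []
    fits: list[FitResult] = []
    for iteration in range(max_iter):
        sub_seeds = rng.integers(0, 2**31 - 1, size=len(sessions))
        fits = [
            map_fit_subject(
                s,
                prior,
                spec,
                config,
                n_restarts=n_restarts,
                seed=int(sub_seeds[i]),
                start=warm[i],
            )
            for i, s in enumerate(sessions)
        ]
        warm = [f.theta for f in fits]
        # Laplace evidence under the prior the E-step was run with
        neg_log_marg = sum(_laplace_neg_log_marginal(f, prior) for f in fits)
        thetas = np.array([f.theta for f in fits])
        covs = np.array([np.clip(np.diag(f.cov), 0, None) for f in fits])
        new_mean = thetas.mean(axis=0)
        new_var = (thetas**2 + covs).mean(axis=0) - new_mean**2
        if np.any(new_var <= var_floor):
            logger.debug("EM iteration %d: flooring %d variance(s)", iteration, int(np.sum(new_var <= var_floor)))
        new_var = np.maximum(new_var, var_floor)
        delta = float(np.max(np.abs(new_mean - prior.mean)))
        prior = GroupPrior(names=prior.names, mean=new_mean, var=new_var)
        history.append(
            {
                "iteration": iteration,
                "max_delta_mean": delta,
                "laplace_neg_log_marginal": neg_log_marg,
                **{f"mean_{n}": new_mean[k] for k, n in enumerate(prior.names)},
                **{f"var_{n}": new_var[k] for k, n in enumerate(prior.names)},
            }
        )
        logger.info(
            "EM[%s] iter %d: max|Δmean|=%.2e, Laplace -log p=%.2f",
            spec.name,
            iteration,
            delta,
            neg_log_marg,
        )
        if delta < tol:
            break
    return EMResult(prior=prior, fits=fits, history=pd.DataFrame(history))


def ibic_penalty(n_free: int, total_choices: int) -> float:
    """iBIC complexity penalty: hyperparameter count × log(total observations).

    Each free parameter contributes a prior mean and a prior variance, and
    every trial contributes two observed choices (both stages).
    """
    return 2 * n_free * np.log(total_choices)


@dataclass
class IBICResult:
    """Monte-Carlo iBIC for one model: evidence, penalty, per-subject pieces."""

    model: str
    ibic: float
    log_marginals: np.ndarray  # per-subject log p̂(session | prior)
    penalty: float
    n_obs: int
    n_mc_samples: int


def integrated_bic(
    prior: GroupPrior,
    sessions: Sequence[SessionData],
    spec: ModelSpec,
    config: TaskConfig | None = None,
    n_mc_samples: int = 2000,
    seed: int = 0,
    method: str = "mc",
    fits: Sequence[FitResult] | None = None,
) -> IBICResult:
    """Integrated BIC under a fitted group prior.

    The per-subject marginal likelihood is estimated by averaging the session
    likelihood over ``n_mc_samples`` prior draws (log-sum-exp guarded); one
    fixed draw set is shared across subjects.  ``method="laplace"`` uses the
    Laplace approximation from supplied ``fits`` instead.
    """
    config = config or TaskConfig(n_trials=sessions[0].n_trials)
    n_obs = int(sum(2 * s.n_trials for s in sessions))
    penalty = ibic_penalty(len(prior.names), n_obs)
    if method == "laplace":
        if fits is None:
            raise ValueError("laplace method requires per-subject fits")
        log_marg = np.array([-_laplace_neg_log_marginal(f, prior) for f in fits])
    elif method == "mc":
        from . import _kernels

        rng = np.random.default_rng(seed)
        thetas = prior.sample(rng, n_mc_samples)
        idx = [PARAM_NAMES.index(n) for n in prior.names]
        base = spec.apply(Parameters()).as_vector()
        naturals = np.tile(base, (n_mc_samples, 1))
        for k, name in enumerate(prior.names):
            naturals[:, idx[k]] = [_from_unconstrained(name, t) for t in thetas[:, k]]
        log_marg = np.empty(len(sessions))
        for i, s in enumerate(sessions):
            ll = np.array(
                [
                    -_kernels.session_nll(
                        naturals[m],
                        config.p_common,
                        s.first_choice,
                        s.second_state,
                        s.second_choice,
                        s.reward,
                    )
                    for m in range(n_mc_samples)
                ]
            )
            log_marg[i] = logsumexp(ll) - np.log(n_mc_samples)
    else:
        raise ValueError(f"unknown method {method!r}")
    ibic = float(-2 * log_marg.sum() + penalty)
    return IBICResult(
        model=spec.name,
        ibic=ibic,
        log_marginals=log_marg,
        penalty=float(penalty),
        n_obs=n_obs,
        n_mc_samples=n_mc_samples,
    )


@dataclass
class ModelComparison:
    """iBIC scores per model, overall and per group; lower wins."""

    table: pd.DataFrame  # index: model name; columns: 'all' + group labels
    winner: str
    em_results: dict[str, EMResult] = field(default_factory=dict)

    def relative(self) -> pd.DataFrame:
        """Differences with regard to the winning model (winner row = 0)."""
        return self.table - self.table.loc[self.winner]


def compare_models(
    sessions: Sequence[SessionData],
    specs: Sequence[ModelSpec],
    config: TaskConfig | None = None,
    groups: Sequence[str] | None = None,
    n_mc_samples: int = 2000,
    seed: int = 0,
    **em_kwargs,
) -> ModelComparison:
    """Fit every model variant by EM and rank them by iBIC.

    Per-group columns recompute the iBIC restricted to that group's sessions
    (group-specific observation counts in the penalty), mirroring a
    model-comparison table split by cohort group.
    """
    config = config or TaskConfig(n_trials=sessions[0].n_trials)
    if groups is None:
        groups = [s.group or "all" for s in sessions]
    groups = np.asarray([str(g) for g in groups])
    labels = list(dict.fromkeys(groups))
    rows = {}
    em_results = {}
    for spec in specs:
        em = em_fit_group(sessions, spec, config, seed=seed, **em_kwargs)
        em_results[spec.name] = em
        res = integrated_bic(
            em.prior, sessions, spec, config, n_mc_samples=n_mc_samples, seed=seed
        )
        row = {"all": res.ibic}
        for g in labels:
            mask = groups == g
            n_obs_g = int(sum(2 * s.n_trials for s, m in zip(sessions, mask) if m))
            row[g] = float(
                -2 * res.log_marginals[mask].sum()
                + ibic_penalty(len(em.prior.names), n_obs_g)
            )
        rows[spec.name] = row
    table = pd.DataFrame(rows).T
    winner = table["all"].idxmin()
    return ModelComparison(table=table, winner=str(winner), em_results=em_results)


def fits_to_frame(fits: Sequence[FitResult], sessions: Sequence[SessionData] | None = None) -> pd.DataFrame:
    """Tabulate per-subject fits (natural-space estimates + −LL)."""
    meta = {}
    if sessions is not None:
        meta = {s.subject_id: (s.group, s.bmi) for s in sessions}
    rows = []
    for f in fits:
        group, bmi = meta.get(f.subject_id, (None, None))
        rows.append(
            {
                "subject_id": f.subject_id,
                "group": group,
                "bmi": bmi,
                "omega": f.params.omega,
                "alpha1": f.params.alpha1,
                "alpha2": f.params.alpha2,
                "beta1": f.params.beta1,
                "beta2": f.params.beta2,
                "lambda": f.params.lam,
                "rho": f.params.rho,
                "negLL": f.neg_log_lik,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
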