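"""Hierarchical Bayesian model fitting and comparison.

Subjects are fit per model by MAP optimization under a Gaussian group
prior in the unconstrained parameter space, with the model evidence
approximated by Laplace's method.  An outer loop alternates:

1. per-subject Laplace fits under the current group priors,
2. per-subject model responsibilities (posterior model probabilities
   under a uniform model prior, proportional to the Laplace evidences),
3. re-estimation of each model's group mean and variance with subjects
   weighted by their responsibility for that model,

so that subjects poorly described by a model do not pull on its group
distribution.  Summing responsibilities over subjects gives each model's
frequency; group-level model selection uses the protected exceedance
probability — the probability that a model is the most frequent in the
population, discounted by the Bayes omnibus risk that all models are
equally frequent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from .models import ModelSpec, RatedRound, log_likelihood_grad


@dataclass
class SubjectData:
    """One subject's observations as the fitter consumes them."""

    subject_id: str
    rounds: list[RatedRound]
    ratings: np.ndarray
    T: int


def subject_data_from_session(session, rating_kind: str = "slider") -> SubjectData:
    return SubjectData(
        subject_id=session.subject_id,
        rounds=session.rated_rounds(),
        ratings=session.ratings(rating_kind),
        T=len(session.rounds),
    )


@dataclass(frozen=True)
class FitConfig:
    prior_mean: float = 0.0
    prior_var: float = 6.25
    n_restarts: int = 5
    opt_tol: float = 1e-6
    max_iter: int = 50
    group_tol: float = 1e-4
    ridge: float = 1e-6
    hess_step: float = 1e-4
    pxp_samples: int = 100_000
    var_floor: float = 1e-4


@dataclass
class SubjectFit:
    mode: np.ndarray
    cov: np.ndarray
    log_evidence: float
    success: bool


@dataclass
class FitResult:
    """Everything the comparison produces."""

    specs: list[ModelSpec]
    subject_ids: list[str]
    group_means: dict[str, np.ndarray]  # keyed by canonical model name
    group_vars: dict[str, np.ndarray]
    subject_fits: dict[str, list[SubjectFit]]
    responsibilities: np.ndarray  # (n_subjects, n_models)
    evidences: np.ndarray  # (n_subjects, n_models) log Laplace evidences
    frequencies: np.ndarray
    exceedance: np.ndarray
    pxp: np.ndarray
    bor: float
    n_iterations: int

    def responsibility(self, spec: ModelSpec) -> np.ndarray:
        return self.responsibilities[:, self._index(spec)]

    def _index(self, spec: ModelSpec) -> int:
        return [s.canonical_name for s in self.specs].index(spec.canonical_name)


# ---- Laplace machinery ----

def map_laplace(
    fun_grad,
    starts: list[np.ndarray],
    ridge: float = 1e-6,
    hess_step: float = 1e-4,
    opt_tol: float = 1e-6,
) -> SubjectFit:
    """Multi-start MAP with a Laplace evidence approximation.

    ``fun_grad(x) -> (negative log joint, gradient)``.  The evidence is
    log joint at the mode + (d/2) log 2*pi - 0.5 logdet(H), with H the
    (ridge-regularized, eigenvalue-floored) Hessian of the negative log
    joint obtained by central differences of the analytic gradient.
    """
    best = None
    for x0 in starts:
        try:
            res = minimize(
                fun_grad, np.asarray(x0, float), jac=True, method="L-BFGS-B",
                options={"ftol": opt_tol, "gtol": 1e-7, "maxiter": 500},
            )
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        d = len(starts[0])
        return SubjectFit(
            mode=np.asarray(starts[0], float), cov=np.eye(d),
            log_evidence=-np.inf, success=False,
        )
    mode = best.x
    d = len(mode)
    hess = np.empty((d, d))
    for j in range(d):
        e = np.zeros(d)
        e[j] = hess_step
        _, gp = fun_grad(mode + e)
        _, gm = fun_grad(mode - e)
        hess[j] = (gp - gm) / (2 * hess_step)
    hess = 0.5 * (hess + hess.T) + ridge * np.eye(d)
    w, v = np.linalg.eigh(hess)
    w = np.maximum(w, 1e-8)  # floor to keep the Gaussian proper
    cov = (v / w) @ v.T
    logdet_h = float(np.sum(np.log(w)))
    log_evidence = -best.fun + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet_h
    return SubjectFit(mode=mode, cov=cov, log_evidence=float(log_evidence),
                      success=True)


def fit_subject_laplace(
    spec: ModelSpec,
    data: SubjectData,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    rng: np.random.Generator,
    config: FitConfig = FitConfig(),
    warm_start: np.ndarray | None = None,
    n_restarts: int | None = None,
) -> SubjectFit:
    """MAP + Laplace evidence for one (subject, model) pair."""
    prior_mean = np.asarray(prior_mean, float)
    prior_var = np.asarray(prior_var, float)

    def fun_grad(x):
        ll, g = log_likelihood_grad(spec, x, data.rounds, data.ratings, T=data.T)
        dev = x - prior_mean
        lp = -0.5 * float(np.sum(dev**2 / prior_var + np.log(2 * np.pi * prior_var)))
        gp = -dev / prior_var
        return -(ll + lp), -(g + gp)

    k = config.n_restarts if n_restarts is None else n_restarts
    starts = [prior_mean]
    if warm_start is not None:
        starts.insert(0, warm_start)
    while len(starts) < max(k, 1):
        starts.append(prior_mean + np.sqrt(prior_var) * rng.standard_normal(len(prior_mean)))
    return map_laplace(
        fun_grad, starts, ridge=config.ridge,
        hess_step=config.hess_step, opt_tol=config.opt_tol,
    )


# ---- hierarchical loop ----

def fit_hierarchical(
    specs: list[ModelSpec],
    cohort: list[SubjectData],
    config: FitConfig = FitConfig(),
    rng: np.random.Generator | None = None,
    verbose: bool = False,
) -> FitResult:
    """Fit a model set to a cohort with the iterative hierarchical scheme."""
    if len(cohort) < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    if len(specs) == 0:
        raise ValueError("at least one model is required")
    if rng is None:
        rng = np.random.default_rng()
    n_s, n_m = len(cohort), len(specs)
    names = [s.canonical_name for s in specs]
    means = {nm: np.full(sp.n_params, config.prior_mean, float)
             for nm, sp in zip(names, specs)}
    variances = {nm: np.full(sp.n_params, config.prior_var, float)
                 for nm, sp in zip(names, specs)}
    fits: dict[str, list[SubjectFit | None]] = {nm: [None] * n_s for nm in names}
    resp = np.full((n_s, n_m), 1.0 / n_m)
    evid = np.zeros((n_s, n_m))

    n_iter = 0
    for it in range(config.max_iter):
        n_iter = it + 1
        for mi, (nm, sp) in enumerate(zip(names, specs)):
            for si, data in enumerate(cohort):
                prev = fits[nm][si]
                fit = fit_subject_laplace(
                    sp, data, means[nm], variances[nm], rng, config,
                    warm_start=prev.mode if prev and prev.success else None,
                    n_restarts=config.n_restarts if it == 0 else 2,
                )
                fits[nm][si] = fit
                evid[si, mi] = fit.log_evidence
        # responsibilities under a uniform model prior
        ok = np.isfinite(evid)
        for si in range(n_s):
            row = np.where(ok[si], evid[si], -np.inf)
            if not np.any(np.isfinite(row)):
                warnings.warn(f"all model fits failed for subject {si}")
                resp[si] = 1.0 / n_m
            else:
                resp[si] = np.exp(row - logsumexp(row))
        # group update
        max_change = 0.0
        for mi, nm in enumerate(names):
            w = resp[:, mi].copy()
            w[~ok[:, mi]] = 0.0
            sw = float(np.sum(w))
            if sw <= 0:
                warnings.warn(f"model {nm} has no contributing subjects")
                continue
            thetas = np.array([fits[nm][si].mode for si in range(n_s)])
            pvars = np.array([np.diag(fits[nm][si].cov) for si in range(n_s)])
            mu = (w @ thetas) / sw
            dev2 = (thetas - mu) ** 2 + pvars
            # one pseudo-observation at the initial prior variance keeps the
            # group variance proper when few subjects load on a model
            var = (w @ dev2 + config.prior_var) / (sw + 1.0)
            var = np.maximum(var, config.var_floor)
            max_change = max(
                max_change,
                float(np.max(np.abs(mu - means[nm]) / (1.0 + np.abs(means[nm])))),
            )
            means[nm], variances[nm] = mu, var
        if verbose:
            print(f"  hbi iteration {n_iter}: max group-mean change {max_change:.2e}")
        if max_change < config.group_tol and it > 0:
            break

    freq = resp.sum(axis=0)
    ep, pxp, bor = protected_exceedance(evid, rng=rng, n_samples=config.pxp_samples)
    return FitResult(
        specs=list(specs),
        subject_ids=[d.subject_id for d in cohort],
        group_means=means,
        group_vars=variances,
        subject_fits={nm: fits[nm] for nm in names},
        responsibilities=resp,
        evidences=evid,
        frequencies=freq,
        exceedance=ep,
        pxp=pxp,
        bor=bor,
        n_iterations=n_iter,
    )


# ---- group-level model selection ----

def _dirichlet_vb(log_evid: np.ndarray, alpha0: float = 1.0, max_iter: int = 200):
    """Variational random-effects model comparison on a log-evidence matrix."""
    n, k = log_evid.shape
    alpha = np.full(k, alpha0)
    g = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        log_u = log_evid + digamma(alpha) - digamma(alpha.sum())
        g_new = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g_new.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < 1e-8:
            alpha, g = alpha_new, g_new
            break
        alpha, g = alpha_new, g_new
    return alpha, g


def _dirichlet_kl(alpha: np.ndarray, alpha0: float) -> float:
    a0 = np.full_like(alpha, alpha0)
    return float(
        gammaln(alpha.sum()) - np.sum(gammaln(alpha))
        - gammaln(a0.sum()) + np.sum(gammaln(a0))
        + np.sum((alpha - a0) * (digamma(alpha) - digamma(alpha.sum())))
    )


def protected_exceedance(
    log_evid: np.ndarray,
    rng: np.random.Generator | None = None,
    n_samples: int = 100_000,
    alpha0: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """(exceedance, protected exceedance, Bayes omnibus risk).

    Exceedance probabilities are Monte-Carlo argmax frequencies under the
    Dirichlet posterior over model probabilities; the protected version
    blends them with the null in which all models are equally frequent:
    PXP = (1 - BOR) * EP + BOR / K.
    """
    log_evid = np.asarray(log_evid, float)
    if log_evid.ndim != 2:
        raise ValueError("expected an (n_subjects, n_models) matrix")
    n, k = log_evid.shape
    if k == 1:
        return np.ones(1), np.ones(1), 1.0
    if rng is None:
        rng = np.random.default_rng()
    # guard against -inf rows (failed fits): treat as totally uninformative
    rows_ok = np.all(np.isfinite(log_evid), axis=1)
    le = log_evid[rows_ok] if np.any(rows_ok) else np.zeros((1, k))

    alpha, g = _dirichlet_vb(le, alpha0=alpha0)
    draws = rng.dirichlet(alpha, size=n_samples)
    ep = np.bincount(np.argmax(draws, axis=1), minlength=k) / n_samples

    log_u = le + digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    f1 = float(np.sum(g * log_u) + entropy - _dirichlet_kl(alpha, alpha0))
    f0 = float(np.sum(logsumexp(le, axis=1) - np.log(k)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / k
    return ep, pxp, bor
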