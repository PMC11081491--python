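"""Cross-model posteriors over cost magnitudes.

Group-level parameter estimates live inside single models, but different
subjects are best described by different models.  To compare cost
magnitudes across the whole comparison set, each subject's posterior over
a cost is a responsibility-weighted mixture of that subject's per-model
Laplace posteriors; models that omit the cost contribute the across-model
group prior for it (a frequency-weighted mixture of the group-level
Gaussians of the models that do contain it).  Averaging subject mixtures
gives the cohort posterior; restricting the combination to a subject
group (e.g. a questionnaire tertile) and multiplying their densities
gives group posteriors.

Within-model posteriors are treated as axis-aligned Gaussians, so the 4D
joint over (update, interference, maintenance, fa) factorizes per mixture
component and is evaluated marginal-by-marginal on a per-cost grid that is
never materialized densely.  The hierarchical SEM divides the marginal SD
by the square root of the summed responsibilities of the models containing
that cost — the effective number of subjects whose data the cost explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .hbi import FitResult
from .models import ModelSpec

#: the four cost magnitudes compared across models
DEFAULT_COSTS = ("update", "interference", "maintenance", "fa")

DEFAULT_N_GRID = 81
DEFAULT_SPAN_SD = 4.0


@dataclass
class CostPosterior:
    """Marginal posteriors over cost magnitudes on per-cost grids."""

    costs: tuple[str, ...]
    grids: dict[str, np.ndarray]
    marginals: dict[str, np.ndarray]  # probability masses, each sums to 1
    means: dict[str, float]
    sds: dict[str, float]
    sems: dict[str, float]
    effective_n: dict[str, float]
    subject_density: dict[str, np.ndarray] | None = None  # (n_subjects, n_grid)

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cost": list(self.costs),
                "mean": [self.means[c] for c in self.costs],
                "sd": [self.sds[c] for c in self.costs],
                "hierarchical_sem": [self.sems[c] for c in self.costs],
                "effective_n": [self.effective_n[c] for c in self.costs],
            }
        )


def _cost_index(spec: ModelSpec, cost: str) -> int | None:
    name = f"c_{cost}"
    return spec.param_names.index(name) if name in spec.param_names else None


def _included_models(fit: FitResult, threshold: float) -> list[int]:
    return [i for i, f in enumerate(fit.frequencies) if f >= threshold]


def _across_model_prior(
    fit: FitResult, cost: str, included: list[int]
) -> list[tuple[float, float, float]]:
    """(weight, mean, sd) components of the across-model group prior for a
    cost, frequency-weighted over the models that contain it."""
    for pool in (included, range(len(fit.specs))):
        comps = []
        for i in pool:
            spec = fit.specs[i]
            j = _cost_index(spec, cost)
            if j is None:
                continue
            nm = spec.canonical_name
            comps.append(
                (
                    float(fit.frequencies[i]),
                    float(fit.group_means[nm][j]),
                    float(np.sqrt(fit.group_vars[nm][j])),
                )
            )
        if comps:
            total = sum(w for w, _, _ in comps)
            if total > 0:
                return [(w / total, m, s) for w, m, s in comps]
    return [(1.0, 0.0, 2.5)]  # base fitting prior: no model carries the cost


def _grid_for(fit, cost, included, n_grid, span_sd) -> np.ndarray:
    """Per-cost grid spanning every mixture component's mean +/- span_sd SD."""
    lows, highs = [], []
    for w, m, s in _across_model_prior(fit, cost, included):
        lows.append(m - span_sd * s)
        highs.append(m + span_sd * s)
    for i in included:
        spec = fit.specs[i]
        j = _cost_index(spec, cost)
        if j is None:
            continue
        for sf in fit.subject_fits[spec.canonical_name]:
            if sf is None or not sf.success:
                continue
            sd = float(np.sqrt(max(sf.cov[j, j], 1e-12)))
            lows.append(sf.mode[j] - span_sd * sd)
            highs.append(sf.mode[j] + span_sd * sd)
    return np.linspace(min(lows), max(highs), n_grid)


def mixture_posterior(
    fit: FitResult,
    threshold: float = 1.0,
    costs: tuple[str, ...] = DEFAULT_COSTS,
    n_grid: int = DEFAULT_N_GRID,
    span_sd: float = DEFAULT_SPAN_SD,
    subject_indices: list[int] | None = None,
) -> CostPosterior:
    """Cohort posterior over cost magnitudes, mixing subjects and models.

    Only models with frequency >= ``threshold`` enter the mixture; per
    subject, responsibilities are renormalized over the included models.
    """
    included = _included_models(fit, threshold)
    if not included:
        raise ValueError(
            f"no model reaches the frequency threshold {threshold}"
        )
    n_s = len(fit.subject_ids)
    subjects = subject_indices if subject_indices is not None else list(range(n_s))
    grids, marginals, means, sds, sems, eff_n = {}, {}, {}, {}, {}, {}
    subject_density: dict[str, np.ndarray] = {}

    for cost in costs:
        grid = _grid_for(fit, cost, included, n_grid, span_sd)
        prior = _across_model_prior(fit, cost, included)
        prior_pdf = np.zeros_like(grid)
        for w, m, s in prior:
            prior_pdf += w * norm.pdf(grid, m, s)
        dens = np.zeros((len(subjects), len(grid)))
        for row, si in enumerate(subjects):
            weights = fit.responsibilities[si, included]
            total = float(weights.sum())
            weights = (
                weights / total if total > 0 else np.full(len(included), 1.0 / len(included))
            )
            for w, i in zip(weights, included):
                spec = fit.specs[i]
                j = _cost_index(spec, cost)
                if j is None:
                    dens[row] += w * prior_pdf
                    continue
                sf = fit.subject_fits[spec.canonical_name][si]
                if sf is None or not sf.success:
                    dens[row] += w * prior_pdf
                    continue
                sd = float(np.sqrt(max(sf.cov[j, j], 1e-12)))
                dens[row] += w * norm.pdf(grid, sf.mode[j], sd)
        pooled = dens.mean(axis=0)
        mass = pooled / pooled.sum()
        mu = float(mass @ grid)
        sd = float(np.sqrt(mass @ (grid - mu) ** 2))
        grids[cost], marginals[cost] = grid, mass
        means[cost], sds[cost] = mu, sd
        # hierarchical SEM: responsibilities summed over models containing
        # the cost (unrenormalized, so they conserve across models)
        neff = 0.0
        for i in included:
            if _cost_index(fit.specs[i], cost) is not None:
                neff += float(fit.responsibilities[np.asarray(subjects), i].sum())
        eff_n[cost] = neff
        sems[cost] = sd / np.sqrt(neff) if neff > 0 else float("nan")
        subject_density[cost] = dens
    return CostPosterior(
        costs=tuple(costs), grids=grids, marginals=marginals, means=means,
        sds=sds, sems=sems, effective_n=eff_n, subject_density=subject_density,
    )


def hierarchical_sem(fit: FitResult, cost: str, threshold: float = 1.0) -> float:
    """Marginal SD over sqrt(summed responsibility of models containing
    the cost)."""
    return mixture_posterior(fit, threshold=threshold, costs=(cost,)).sems[cost]


def group_posterior(
    fit: FitResult,
    labels: dict[str, str],
    threshold: float = 1.0,
    costs: tuple[str, ...] = DEFAULT_COSTS,
    n_grid: int = DEFAULT_N_GRID,
) -> dict[str, CostPosterior]:
    """Per-group posterior: the product over the group's subjects of their
    mixture densities, computed per cost axis in log space and renormalized
    on the grid.  Empty groups are skipped with a warning."""
    import warnings

    missing = [s for s in fit.subject_ids if s not in labels]
    if missing:
        raise ValueError(f"grouping does not cover subjects: {missing[:5]}")
    base = mixture_posterior(fit, threshold=threshold, costs=costs, n_grid=n_grid)
    groups = sorted(set(labels.values()))
    out: dict[str, CostPosterior] = {}
    for g in groups:
        idx = [i for i, s in enumerate(fit.subject_ids) if labels[s] == g]
        if not idx:
            warnings.warn(f"group {g!r} is empty; skipped")
            continue
        marginals, means, sds, sems, eff_n = {}, {}, {}, {}, {}
        for cost in costs:
            dens = base.subject_density[cost][idx]
            with np.errstate(divide="ignore"):
                log_prod = np.sum(np.log(dens), axis=0)
            mass = np.exp(log_prod - logsumexp(log_prod))
            grid = base.grids[cost]
            mu = float(mass @ grid)
            sd = float(np.sqrt(mass @ (grid - mu) ** 2))
            marginals[cost], means[cost], sds[cost] = mass, mu, sd
            neff = 0.0
            for i in _included_models(fit, threshold):
                if _cost_index(fit.specs[i], cost) is not None:
                    neff += float(fit.responsibilities[idx, i].sum())
            eff_n[cost] = neff
            sems[cost] = sd / np.sqrt(neff) if neff > 0 else float("nan")
        out[g] = CostPosterior(
            costs=tuple(costs), grids=base.grids, marginals=marginals,
            means=means, sds=sds, sems=sems, effective_n=eff_n,
        )
    return out


def posterior_overlap(a: CostPosterior, b: CostPosterior, cost: str) -> float:
    """Overlap coefficient (shared mass) between two marginal posteriors
    evaluated on the same grid."""
    if not np.allclose(a.grids[cost], b.grids[cost]):
        raise ValueError("posteriors must share a grid for overlap")
    return float(np.minimum(a.marginals[cost], b.marginals[cost]).sum())
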