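"""Generative models of fair-wage ratings.

A round's total cost is the sum of its component tallies scaled by fitted
cost magnitudes,

    cost_r(k) = sum_j components_j^r * c_j(t),

and the mean rating for task k evolves by a delta rule driven by the cost
experienced on the last completed round of that task,

    m_{r+1}(k) = m_r(k) + alpha * (cost_r(k) - m_r(k)),

with the realized rating adding independent Gaussian noise of SD sigma.
Four mechanism classes share this skeleton:

* ``alpha``             — constant costs, fitted learning rate, one init
                          per rated task;
* ``delta``             — alpha fixed at 1, costs drift linearly with the
                          global round number t (c_j(t) = c_j*(1+d_j*t/T)),
                          a single shared init;
* ``alpha_delta_linear``— learning rate and linear cost drift jointly;
* ``alpha_delta_exp``   — learning rate with power-law drift c_j*t^d_j.

Crossing the six cost components' non-empty subsets with the ``alpha`` and
``delta`` classes gives the canonical 126-model comparison space.

Fitting happens in an unconstrained space: alpha through a logistic
sigmoid, sigma through an exponential; inits, costs and drift rates are
unbounded.  The Gaussian likelihood is not truncated to the 1-5 slider.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .process_model import COST_NAMES, CostComponents
from .tasks import RATED_TASKS, TaskKind

MECHANISMS = ("alpha", "delta", "alpha_delta_linear", "alpha_delta_exp")
DEFAULT_MECHANISMS = ("alpha", "delta")

_RATED_NAMES = tuple(t.value for t in RATED_TASKS)


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


def logit(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


@dataclass(frozen=True, order=True)
class ModelSpec:
    """A model identity: which costs it tracks and how ratings update."""

    mech: str
    cost_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mech not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mech!r}")
        if len(self.cost_set) == 0:
            raise ValueError("cost_set must be non-empty")
        ordered = tuple(c for c in COST_NAMES if c in self.cost_set)
        if ordered != self.cost_set:
            object.__setattr__(self, "cost_set", ordered)
        for c in self.cost_set:
            if c not in COST_NAMES:
                raise ValueError(f"unknown cost component {c!r}")

    @property
    def canonical_name(self) -> str:
        return f"{self.mech}:{'+'.join(self.cost_set)}"

    @classmethod
    def parse(cls, name: str) -> "ModelSpec":
        mech, _, costs = name.partition(":")
        if not costs:
            raise ValueError(f"malformed model name {name!r}")
        return cls(mech=mech, cost_set=tuple(costs.split("+")))

    # ---- parameter layout (unconstrained fitting space) ----

    @property
    def has_alpha(self) -> bool:
        return self.mech != "delta"

    @property
    def has_deltas(self) -> bool:
        return self.mech != "alpha"

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["sigma"]
        if self.has_alpha:
            names.append("alpha")
            names += [f"init_{k}" for k in _RATED_NAMES]
        else:
            names.append("init")
        names += [f"c_{c}" for c in self.cost_set]
        if self.has_deltas:
            names += [f"d_{c}" for c in self.cost_set]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def enumerate_model_space(
    classes: tuple[str, ...] = DEFAULT_MECHANISMS,
) -> list[ModelSpec]:
    """All non-empty cost subsets crossed with the requested mechanism
    classes, in deterministic canonical order (63 per class)."""
    if len(classes) == 0:
        raise ValueError("at least one mechanism class is required")
    for cl in classes:
        if cl not in MECHANISMS:
            raise ValueError(f"unknown mechanism class {cl!r}")
    specs = []
    for mech in [m for m in MECHANISMS if m in classes]:
        for r in range(1, len(COST_NAMES) + 1):
            for subset in itertools.combinations(COST_NAMES, r):
                specs.append(ModelSpec(mech=mech, cost_set=subset))
    return specs


@dataclass(frozen=True)
class ParamSet:
    """Natural-space parameters for one model."""

    spec: ModelSpec
    sigma: float
    costs: dict[str, float]
    alpha: float | None = None
    inits: dict[str, float] | None = None  # per rated task (alpha classes)
    init: float | None = None  # shared init (delta class)
    deltas: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.spec.has_alpha:
            if self.alpha is None or not (0.0 <= self.alpha <= 1.0):
                raise ValueError("alpha must lie in [0, 1]")
            if self.inits is None or set(self.inits) != set(_RATED_NAMES):
                raise ValueError("alpha classes need one init per rated task")
        elif self.init is None:
            raise ValueError("delta class needs a shared init")
        if set(self.costs) != set(self.spec.cost_set):
            raise ValueError("costs must match the spec's cost set")
        if self.spec.has_deltas and (
            self.deltas is None or set(self.deltas) != set(self.spec.cost_set)
        ):
            raise ValueError("delta-bearing classes need one drift per cost")

    def init_for(self, task: TaskKind) -> float:
        if self.spec.has_alpha:
            return self.inits[task.value]
        return self.init

    @property
    def effective_alpha(self) -> float:
        return 1.0 if self.spec.mech == "delta" else self.alpha

    def to_vector(self) -> np.ndarray:
        """Map to the unconstrained fitting space (log sigma, logit alpha)."""
        vec = [np.log(self.sigma)]
        if self.spec.has_alpha:
            a = min(max(self.alpha, 1e-9), 1 - 1e-9)
            vec.append(float(logit(a)))
            vec += [self.inits[k] for k in _RATED_NAMES]
        else:
            vec.append(self.init)
        vec += [self.costs[c] for c in self.spec.cost_set]
        if self.spec.has_deltas:
            vec += [self.deltas[c] for c in self.spec.cost_set]
        return np.asarray(vec, dtype=float)

    @classmethod
    def from_vector(cls, spec: ModelSpec, vec: np.ndarray) -> "ParamSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (spec.n_params,):
            raise ValueError(
                f"expected {spec.n_params} parameters for {spec.canonical_name}"
            )
        i = 0
        sigma = float(np.exp(vec[i]))
        i += 1
        alpha = inits = init = None
        if spec.has_alpha:
            alpha = float(sigmoid(vec[i]))
            i += 1
            inits = {k: float(vec[i + j]) for j, k in enumerate(_RATED_NAMES)}
            i += len(_RATED_NAMES)
        else:
            init = float(vec[i])
            i += 1
        costs = {c: float(vec[i + j]) for j, c in enumerate(spec.cost_set)}
        i += len(spec.cost_set)
        deltas = None
        if spec.has_deltas:
            deltas = {c: float(vec[i + j]) for j, c in enumerate(spec.cost_set)}
        return cls(
            spec=spec, sigma=sigma, alpha=alpha, inits=inits, init=init,
            costs=costs, deltas=deltas,
        )


@dataclass(frozen=True)
class RatedRound:
    """One round of the task schedule as the rating model sees it.

    ``t`` is the 1-based global round number (counted over all 32 rounds
    regardless of auction outcome); ``comps`` is present only when the
    rated task was actually completed — only then does the rating update.
    """

    task: TaskKind
    t: int
    completed: bool
    comps: CostComponents | None = None

    def __post_init__(self) -> None:
        if self.task not in RATED_TASKS:
            raise ValueError(f"{self.task} is not a rated task")
        if self.completed and self.comps is None:
            raise ValueError("completed rounds need cost components")


def _time_factor(mech: str, delta: float, t: int, T: int) -> float:
    if mech == "alpha":
        return 1.0
    if mech in ("delta", "alpha_delta_linear"):
        return 1.0 + delta * t / T
    return float(t) ** delta  # alpha_delta_exp


def round_cost(
    spec: ModelSpec, params: ParamSet, comps: CostComponents, t: int, T: int
) -> float:
    """Total cost of one round: component tallies times (possibly
    time-varying) cost magnitudes."""
    if not (1 <= t <= T):
        raise ValueError("global round index t must lie in 1..T")
    total = 0.0
    for c in spec.cost_set:
        d = params.deltas[c] if spec.has_deltas else 0.0
        total += comps[c] * params.costs[c] * _time_factor(spec.mech, d, t, T)
    return total


def predict_ratings(
    spec: ModelSpec,
    params: ParamSet,
    rounds: list[RatedRound],
    T: int | None = None,
) -> np.ndarray:
    """Noise-free mean rating emitted at each round of the schedule.

    The mean for a task starts at its init and moves toward the cost of
    each completed round of that task by the learning rate; skipped
    (auction-lost) rounds leave it unchanged.
    """
    if T is None:
        T = len(rounds)
    alpha = params.effective_alpha
    state = {k: params.init_for(k) for k in RATED_TASKS}
    means = np.empty(len(rounds))
    for i, rnd in enumerate(rounds):
        means[i] = state[rnd.task]
        if rnd.completed:
            cost = round_cost(spec, params, rnd.comps, rnd.t, T)
            state[rnd.task] += alpha * (cost - state[rnd.task])
    return means


def simulate_ratings(
    spec: ModelSpec,
    params: ParamSet,
    rounds: list[RatedRound],
    rng: np.random.Generator,
    T: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(means, realized) ratings; realized adds N(0, sigma^2) noise and is
    deliberately left unclipped (the slider clamp happens at the
    experiment layer, not in the generative model)."""
    means = predict_ratings(spec, params, rounds, T=T)
    noisy = means + rng.normal(0.0, params.sigma, size=means.shape)
    return means, noisy


def _trajectory_with_grad(
    spec: ModelSpec, vec: np.ndarray, rounds: list[RatedRound], T: int
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-mode means and Jacobian d(mean)/d(unconstrained params)."""
    d = spec.n_params
    params = ParamSet.from_vector(spec, vec)
    alpha = params.effective_alpha
    if spec.has_alpha:
        a_idx = 1
        init_idx = {k: 2 + j for j, k in enumerate(_RATED_NAMES)}
        base = 2 + len(_RATED_NAMES)
    else:
        a_idx = None
        init_idx = {k: 1 for k in _RATED_NAMES}
        base = 2
    c_idx = {c: base + j for j, c in enumerate(spec.cost_set)}
    d_idx = (
        {c: base + len(spec.cost_set) + j for j, c in enumerate(spec.cost_set)}
        if spec.has_deltas
        else {}
    )
    dalpha_da = alpha * (1.0 - alpha) if spec.has_alpha else 0.0

    state = {k: params.init_for(k) for k in RATED_TASKS}
    grad_state = {k: np.zeros(d) for k in RATED_TASKS}
    for k in RATED_TASKS:
        grad_state[k][init_idx[k.value]] = 1.0

    means = np.empty(len(rounds))
    jac = np.empty((len(rounds), d))
    for i, rnd in enumerate(rounds):
        means[i] = state[rnd.task]
        jac[i] = grad_state[rnd.task]
        if not rnd.completed:
            continue
        t = rnd.t
        cost = 0.0
        dcost = np.zeros(d)
        for c in spec.cost_set:
            dl = params.deltas[c] if spec.has_deltas else 0.0
            f = _time_factor(spec.mech, dl, t, T)
            comp = rnd.comps[c]
            cost += comp * params.costs[c] * f
            dcost[c_idx[c]] += comp * f
            if spec.has_deltas:
                if spec.mech in ("delta", "alpha_delta_linear"):
                    df = t / T
                else:
                    df = f * np.log(t)
                dcost[d_idx[c]] += comp * params.costs[c] * df
        m = state[rnd.task]
        g = grad_state[rnd.task]
        new_g = g + alpha * (dcost - g)
        if a_idx is not None:
            new_g = new_g.copy()
            new_g[a_idx] += dalpha_da * (cost - m)
        state[rnd.task] = m + alpha * (cost - m)
        grad_state[rnd.task] = new_g
    return means, jac


def log_likelihood(
    spec: ModelSpec,
    vec: np.ndarray,
    rounds: list[RatedRound],
    ratings: np.ndarray,
    T: int | None = None,
) -> float:
    """Gaussian log-likelihood of observed ratings, parameters given in
    the unconstrained fitting space."""
    ll, _ = log_likelihood_grad(spec, vec, rounds, ratings, T=T)
    return ll


def log_likelihood_grad(
    spec: ModelSpec,
    vec: np.ndarray,
    rounds: list[RatedRound],
    ratings: np.ndarray,
    T: int | None = None,
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its analytic gradient in unconstrained space."""
    ratings = np.asarray(ratings, dtype=float)
    if len(ratings) != len(rounds):
        raise ValueError("one observed rating per round is required")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("observed ratings must be finite")
    if T is None:
        T = len(rounds)
    vec = np.asarray(vec, dtype=float).copy()
    # keep sigma = exp(s) representable; the optimum never sits at the clamp
    vec[0] = float(np.clip(vec[0], -20.0, 20.0))
    means, jac = _trajectory_with_grad(spec, vec, rounds, T)
    sigma = float(np.exp(vec[0]))
    resid = ratings - means
    n = len(ratings)
    ll = -n * (np.log(sigma) + 0.5 * np.log(2 * np.pi)) - float(
        np.sum(resid**2)
    ) / (2 * sigma**2)
    grad = (resid / sigma**2) @ jac
    grad[0] += -n + float(np.sum(resid**2)) / sigma**2  # d/d(log sigma)
    return float(ll), grad
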