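"""Synthetic cohorts for the wage-for-work paradigm.

Each simulated subject plays 32 rounds.  Before a round they are shown one
of three rated tasks (1-back, 3-detect, 2-back; the schedule offers each
10-11 times in random order) and state a fair wage on a 1-5 slider.  An
inverted Becker-DeGroot-Marschak auction then draws a uniform computer
offer on [1, 5]: an offer at or above the stated wage means the subject
completes the rated task for the offer; otherwise they complete the
default 1-detect task for 1 point.  This mechanism makes truthful wage
reporting the payoff-maximizing policy for a risk-neutral agent.

Agents generate ratings from one of the generative rating models
(:mod:`wagework.models`): the model's mean rating plus Gaussian noise,
clamped to the slider bounds at this (and only this) layer.  Round
performance is sampled from per-task hit and false-alarm probabilities and
an RT distribution calibrated to the behavioral profile of the paradigm's
four tasks; responses slower than the 1.5 s stimulus count as misses.
Only completed rounds of a rated task feed back into the agent's rating
state, reproducing the selection artifact by which high-raters complete
fewer rated rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import ModelSpec, ParamSet, RatedRound, round_cost
from .process_model import decompose_round
from .tasks import (
    DEFAULT_LURE_RANGE,
    DEFAULT_N_TRIALS,
    DEFAULT_TARGET_RANGE,
    RATED_TASKS,
    STIMULUS_MS,
    RoundResult,
    TaskKind,
    TrialSequence,
    generate_sequence,
    score_responses,
)

#: per-task (hit probability, false-alarm probability) emulating the
#: paradigm's canonical accuracy ordering (1-detect ~98%, 1-back ~89%,
#: 3-detect ~94%, 2-back ~80% weighted accuracy)
DEFAULT_HIT_FA = {
    TaskKind.detect1: (0.98, 0.005),
    TaskKind.back1: (0.85, 0.05),
    TaskKind.detect3: (0.92, 0.02),
    TaskKind.back2: (0.70, 0.10),
}

#: per-task (mean, SD) response time in ms (canonical ordering: the 2-back
#: slowest at ~720 ms, the detections fastest)
DEFAULT_RT = {
    TaskKind.detect1: (550.0, 150.0),
    TaskKind.back1: (611.0, 180.0),
    TaskKind.detect3: (530.0, 150.0),
    TaskKind.back2: (720.0, 220.0),
}

NFC_N_ITEMS, NFC_SCALE_MAX = 18, 5
NFC_REVERSE = (3, 4, 5, 7, 8, 9, 12, 16, 17)  # 0-based reverse-coded items
SAPS_N_ITEMS, SAPS_SCALE_MAX = 8, 7
SAPS_REVERSE: tuple[int, ...] = ()


@dataclass(frozen=True)
class ExperimentConfig:
    """Paradigm constants."""

    n_rounds: int = 32
    n_trials: int = DEFAULT_N_TRIALS
    target_range: tuple[int, int] = DEFAULT_TARGET_RANGE
    lure_range: tuple[int, int] = DEFAULT_LURE_RANGE
    rating_bounds: tuple[float, float] = (1.0, 5.0)
    offer_bounds: tuple[float, float] = (1.0, 5.0)
    discrete_offers: bool = False
    offer_step: float = 0.1
    default_points: float = 1.0
    stimulus_ms: float = STIMULUS_MS
    isi_ms: float = 300.0
    exclusion_enabled: bool = True
    exclusion_every: int = 8
    exclusion_threshold: float = 0.60


@dataclass(frozen=True)
class AgentProfile:
    """Everything needed to simulate one subject."""

    spec: ModelSpec
    params: ParamSet
    hit_fa: dict[TaskKind, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HIT_FA)
    )
    rt: dict[TaskKind, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RT)
    )
    nfc_latent: float = 3.4
    saps_latent: float = 4.4
    screener_correct_prob: float = 0.95


@dataclass
class SimRound:
    """One round of a simulated session."""

    round_index: int  # 1-based global round number t
    rated_task: TaskKind
    rating_mean: float  # model mean before clamping/noise
    rating_raw: float  # mean + noise, as the generative model emits it
    rating: float  # realized, slider-clamped rating
    offer: float
    won: bool
    completed_task: TaskKind
    sequence: TrialSequence | None
    result: RoundResult | None
    points: float


@dataclass
class SessionData:
    """One subject's full synthetic record."""

    subject_id: str
    rounds: list[SimRound]
    nfc_items: list[int | None]
    saps_items: list[int | None]
    screener_pass: bool
    difficulty: dict[str, float]
    excluded: bool = False
    profile: AgentProfile | None = None

    def rated_rounds(self) -> list[RatedRound]:
        """Schedule view consumed by the rating models: every round emits a
        rating; only auction-won rounds carry components and update."""
        out = []
        for rnd in self.rounds:
            comps = (
                decompose_round(rnd.sequence, rnd.result)
                if rnd.won and rnd.sequence is not None
                else None
            )
            out.append(
                RatedRound(
                    task=rnd.rated_task,
                    t=rnd.round_index,
                    completed=rnd.won and comps is not None,
                    comps=comps,
                )
            )
        return out

    def ratings(self, kind: str = "slider") -> np.ndarray:
        """Observed ratings: ``slider`` (clamped to the 1-5 scale, what the
        experiment records) or ``raw`` (the generative model's unclipped
        emission behind the same noise draw and auction outcomes)."""
        if kind == "slider":
            return np.array([rnd.rating for rnd in self.rounds])
        if kind == "raw":
            return np.array([rnd.rating_raw for rnd in self.rounds])
        raise ValueError(f"unknown rating kind {kind!r}")


def run_auction(
    rating: float,
    offer: float,
    bounds: tuple[float, float] = (1.0, 5.0),
    default_points: float = 1.0,
) -> tuple[bool, float]:
    """(won, points): the rated task is completed for the offer when the
    offer is at or above the stated wage, else the default task for the
    fixed default wage.  Ties go to the rated task."""
    lo, hi = bounds
    if not (lo <= rating <= hi) or not (lo <= offer <= hi):
        raise ValueError(f"rating/offer must lie in [{lo}, {hi}]")
    if offer >= rating:
        return True, float(offer)
    return False, float(default_points)


def make_schedule(
    n_rounds: int,
    tasks: tuple[TaskKind, ...] = RATED_TASKS,
    rng: np.random.Generator | None = None,
) -> list[TaskKind]:
    """Random task order with per-task counts as balanced as possible
    (10/11/11 for 32 rounds over 3 tasks)."""
    if rng is None:
        rng = np.random.default_rng()
    k = len(tasks)
    if n_rounds < k:
        raise ValueError("need at least one round per task")
    base, extra = divmod(n_rounds, k)
    counts = [base] * k
    for i in rng.choice(k, size=extra, replace=False):
        counts[i] += 1
    schedule = [t for t, c in zip(tasks, counts) for _ in range(c)]
    rng.shuffle(schedule)
    return schedule


def simulate_round_performance(
    task: TaskKind,
    profile: AgentProfile,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> tuple[TrialSequence, RoundResult]:
    """Generate a sequence and sample responses/RTs for one round."""
    seq = generate_sequence(
        task,
        n_trials=config.n_trials,
        target_range=config.target_range,
        lure_range=config.lure_range,
        rng=rng,
    )
    p_hit, p_fa = profile.hit_fa[task]
    mu, sd = profile.rt[task]
    responded, rts = [], []
    for is_tgt in seq.is_target:
        p = p_hit if is_tgt else p_fa
        r = bool(rng.random() < p)
        responded.append(r)
        # RTs below 150 ms are not humanly plausible; late ones are scored
        # as non-responses downstream
        rts.append(max(150.0, rng.normal(mu, sd)) if r else np.nan)
    return seq, score_responses(seq, responded, rts, deadline_ms=config.stimulus_ms)


def _questionnaire_items(
    latent: float,
    n_items: int,
    scale_max: int,
    reverse: tuple[int, ...],
    rng: np.random.Generator,
    missing_prob: float = 0.01,
) -> list[int | None]:
    items: list[int | None] = []
    for i in range(n_items):
        if rng.random() < missing_prob:
            items.append(None)
            continue
        v = int(np.clip(round(rng.normal(latent, 1.0)), 1, scale_max))
        if i in reverse:
            v = scale_max + 1 - v
        items.append(v)
    return items


def simulate_subject(
    profile: AgentProfile,
    config: ExperimentConfig = ExperimentConfig(),
    rng: np.random.Generator | None = None,
    subject_id: str = "s000",
) -> SessionData:
    """Play one agent through the full 32-round session."""
    if rng is None:
        rng = np.random.default_rng()
    spec, params = profile.spec, profile.params
    T = config.n_rounds
    lo, hi = config.rating_bounds
    schedule = make_schedule(T, RATED_TASKS, rng)
    state = {k: params.init_for(k) for k in RATED_TASKS}
    alpha = params.effective_alpha

    rounds: list[SimRound] = []
    excluded = False
    accs: list[float] = []
    for t, task in enumerate(schedule, start=1):
        mean = state[task]
        rating_raw = float(mean + rng.normal(0.0, params.sigma))
        rating = float(np.clip(rating_raw, lo, hi))
        if config.discrete_offers:
            n_steps = int(round((hi - lo) / config.offer_step))
            offer = lo + config.offer_step * rng.integers(n_steps + 1)
        else:
            offer = rng.uniform(lo, hi)
        won, points = run_auction(
            rating, offer, bounds=config.rating_bounds,
            default_points=config.default_points,
        )
        completed = task if won else TaskKind.detect1
        seq, result = simulate_round_performance(completed, profile, config, rng)
        if won:
            comps = decompose_round(seq, result)
            state[task] = mean + alpha * (round_cost(spec, params, comps, t, T) - mean)
        rounds.append(
            SimRound(
                round_index=t, rated_task=task, rating_mean=mean,
                rating_raw=rating_raw, rating=rating, offer=float(offer), won=won,
                completed_task=completed, sequence=seq, result=result,
                points=points,
            )
        )
        accs.append(result.weighted_accuracy)
        if (
            config.exclusion_enabled
            and t % config.exclusion_every == 0
            and float(np.nanmean(accs)) < config.exclusion_threshold
        ):
            excluded = True
            break

    difficulty = {}
    for task in (TaskKind.detect1,) + RATED_TASKS:
        base = 1.5 if task is TaskKind.detect1 else state[task]
        difficulty[task.value] = float(np.clip(base + rng.normal(0.0, 0.5), lo, hi))

    return SessionData(
        subject_id=subject_id,
        rounds=rounds,
        nfc_items=_questionnaire_items(
            profile.nfc_latent, NFC_N_ITEMS, NFC_SCALE_MAX, NFC_REVERSE, rng
        ),
        saps_items=_questionnaire_items(
            profile.saps_latent, SAPS_N_ITEMS, SAPS_SCALE_MAX, SAPS_REVERSE, rng
        ),
        screener_pass=bool(rng.random() < profile.screener_correct_prob),
        difficulty=difficulty,
        excluded=excluded,
        profile=profile,
    )


# ---- parameter sampling for cohorts ----

#: declared simulation ranges for generate-and-recover draws
PARAM_RANGES = {
    "sigma": (0.1, 1.5),
    "alpha": (0.05, 0.95),
    "init": (1.0, 5.0),
    "cost": (-1.0, 1.0),
    "delta": (-1.0, 1.0),
}


def sample_params(
    spec: ModelSpec,
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> ParamSet:
    """Draw one subject's generative parameters uniformly within the
    declared ranges."""
    rg = dict(PARAM_RANGES)
    if ranges:
        rg.update(ranges)
    u = lambda key: float(rng.uniform(*rg[key]))  # noqa: E731
    costs = {c: u("cost") for c in spec.cost_set}
    deltas = {c: u("delta") for c in spec.cost_set} if spec.has_deltas else None
    if spec.has_alpha:
        return ParamSet(
            spec=spec, sigma=u("sigma"), alpha=u("alpha"),
            inits={k.value: u("init") for k in RATED_TASKS},
            costs=costs, deltas=deltas,
        )
    return ParamSet(spec=spec, sigma=u("sigma"), init=u("init"),
                    costs=costs, deltas=deltas)


def simulate_cohort(
    n_subjects: int,
    spec: ModelSpec,
    rng: np.random.Generator | None = None,
    config: ExperimentConfig = ExperimentConfig(),
    param_sampler=None,
    nfc_sd: float = 0.9,
    saps_sd: float = 1.3,
) -> tuple[list[SessionData], pd.DataFrame]:
    """Simulate a cohort from one generative model.

    Returns the sessions together with the ground-truth parameter table
    (natural scale, one row per subject) used to score recovery.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    sessions, truth_rows = [], []
    for i in range(n_subjects):
        params = (
            param_sampler(spec, rng) if param_sampler else sample_params(spec, rng)
        )
        profile = AgentProfile(
            spec=spec,
            params=params,
            nfc_latent=float(np.clip(rng.normal(3.4, nfc_sd), 1, 5)),
            saps_latent=float(np.clip(rng.normal(4.4, saps_sd), 1, 7)),
        )
        sid = f"s{i:03d}"
        sessions.append(simulate_subject(profile, config, rng, subject_id=sid))
        row = {"subject_id": sid, "sigma": params.sigma}
        if spec.has_alpha:
            row["alpha"] = params.alpha
            row.update({f"init_{k}": v for k, v in params.inits.items()})
        else:
            row["init"] = params.init
        row.update({f"c_{c}": v for c, v in params.costs.items()})
        if spec.has_deltas:
            row.update({f"d_{c}": v for c, v in params.deltas.items()})
        truth_rows.append(row)
    return sessions, pd.DataFrame(truth_rows)


# ---- tabular export ----

def round_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Round-level table: one row per (subject, round)."""
    rows = []
    for s in sessions:
        for rnd in s.rounds:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "round": rnd.round_index,
                    "rated_task": rnd.rated_task.value,
                    "rating": rnd.rating,
                    "offer": rnd.offer,
                    "outcome": "rated" if rnd.won else "default",
                    "completed_task": rnd.completed_task.value,
                    "points": rnd.points,
                    "weighted_accuracy": (
                        rnd.result.weighted_accuracy if rnd.result else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def trial_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Trial-level table (1-based trial index within round)."""
    rows = []
    for s in sessions:
        for rnd in s.rounds:
            if rnd.sequence is None:
                continue
            for j in range(rnd.sequence.n_trials):
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "round": rnd.round_index,
                        "trial": j + 1,
                        "task": rnd.completed_task.value,
                        "letter": rnd.sequence.letters[j],
                        "is_target": int(rnd.sequence.is_target[j]),
                        "is_lure": int(rnd.sequence.is_lure[j]),
                        "responded": int(rnd.result.responded[j]),
                        "rt_ms": rnd.result.rt_ms[j],
                    }
                )
    return pd.DataFrame(rows)


def subject_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Subject-level table: questionnaire items and difficulty ratings."""
    rows = []
    for s in sessions:
        row = {
            "subject_id": s.subject_id,
            "screener_pass": int(s.screener_pass),
            "excluded": int(s.excluded),
        }
        row.update({f"nfc_{i+1:02d}": v for i, v in enumerate(s.nfc_items)})
        row.update({f"saps_{i+1:02d}": v for i, v in enumerate(s.saps_items)})
        row.update({f"difficulty_{k}": v for k, v in s.difficulty.items()})
        rows.append(row)
    return pd.DataFrame(rows)
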