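"""Model-agnostic statistics: questionnaires, splits, and behavior.

Covers the descriptive layer of the paradigm: normalized questionnaire
scoring with screener-based exclusion, tertile splits on those scores,
the regression-trimming model-selection procedure relating self-report
scores (linear and quadratic NFC/SAPS terms) to task measures, and
task-level behavioral summaries with ANOVAs, post-hoc t-tests, half-split
comparisons, and the offer-matching (Spearman) check.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr, spearmanr, ttest_rel
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .simulate import SessionData
from .tasks import RATED_TASKS, TaskKind

TERTILE_LABELS = ("low", "mid", "high")


@dataclass
class QuestionnaireScore:
    instrument: str
    items: list[int | None]
    reverse_mask: tuple[int, ...]
    scale_max: int
    score: float
    n_answered: int
    screener_pass: bool

    @property
    def excluded(self) -> bool:
        return not self.screener_pass or self.n_answered == 0


def score_questionnaire(
    items: list[int | None],
    reverse_mask: tuple[int, ...],
    scale_max: int,
    screener_pass: bool = True,
    instrument: str = "questionnaire",
) -> QuestionnaireScore:
    """Normalized score: reverse masked items (scale_max + 1 - response),
    sum the answered items, divide by the number answered so missing
    responses do not drag the score down.  Screener failures flag the
    score as excluded rather than dropping it."""
    values = []
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if not (1 <= v <= scale_max):
            raise ValueError(f"item {i} response {v} outside 1..{scale_max}")
        values.append(scale_max + 1 - v if i in reverse_mask else v)
    n = len(values)
    score = float(np.sum(values) / n) if n else float("nan")
    if n == 0:
        warnings.warn(f"{instrument}: all items missing, score undefined")
    return QuestionnaireScore(
        instrument=instrument, items=list(items), reverse_mask=tuple(reverse_mask),
        scale_max=scale_max, score=score, n_answered=n,
        screener_pass=screener_pass,
    )


def tertile_split(scores: pd.Series | np.ndarray) -> pd.Series:
    """Low/mid/high labels at the 1/3 and 2/3 empirical quantiles.

    All subjects sharing a score receive the same label, so heavy ties
    produce unequal group sizes.
    """
    s = pd.Series(scores, dtype=float)
    valid = s.dropna()
    if len(valid) < 3:
        raise ValueError("tertile split needs at least 3 scored subjects")
    if valid.nunique() < 3:
        warnings.warn("fewer than 3 distinct scores: degenerate tertile split")
    q1, q2 = np.quantile(valid, [1 / 3, 2 / 3])
    labels = pd.Series(index=s.index, dtype=object)
    labels[s < q1] = "low"
    labels[(s >= q1) & (s < q2)] = "mid"
    labels[s >= q2] = "high"
    labels[s.isna()] = None
    return labels


@dataclass
class TrimmedModel:
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    model_pvalue: float
    mse: float
    significant: bool
    results: object = None


def trimmed_regression(
    outcome: np.ndarray | pd.Series,
    nfc: np.ndarray | pd.Series,
    saps: np.ndarray | pd.Series,
    alpha_level: float = 0.05,
    criterion: str = "omnibus",
) -> TrimmedModel:
    """Exhaustive trim over the four self-report terms.

    Candidate predictors are {NFC, NFC^2, SAPS, SAPS^2}; the intercept is
    always included.  All 15 non-empty subsets are fit by OLS on complete
    cases; subsets significant at ``alpha_level`` (omnibus F-test by
    default, every per-term t-test with ``criterion='per_term'``) are
    retained and the one with the lowest mean squared error is selected.
    With no significant subset the intercept-only model is returned,
    flagged non-significant.
    """
    df = pd.DataFrame(
        {"y": np.asarray(outcome, float), "nfc": np.asarray(nfc, float),
         "saps": np.asarray(saps, float)}
    ).dropna()
    df["nfc2"] = df["nfc"] ** 2
    df["saps2"] = df["saps"] ** 2
    terms = ("nfc", "nfc2", "saps", "saps2")
    best = None
    for r in range(1, len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            X = sm.add_constant(df[list(subset)])
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                warnings.warn(f"collinear subset {subset} skipped")
                continue
            res = sm.OLS(df["y"], X).fit()
            if criterion == "per_term":
                pvals = res.pvalues.drop("const")
                sig = bool((pvals < alpha_level).all())
                p_model = float(pvals.max())
            else:
                p_model = float(res.f_pvalue)
                sig = p_model < alpha_level
            if not sig:
                continue
            mse = float(np.mean(res.resid**2))
            if best is None or mse < best[0]:
                best = (mse, subset, res, p_model)
    if best is None:
        res = sm.OLS(df["y"], np.ones((len(df), 1))).fit()
        return TrimmedModel(
            terms=(), coefficients={"const": float(res.params.iloc[0])},
            model_pvalue=float("nan"), mse=float(np.mean(res.resid**2)),
            significant=False, results=res,
        )
    mse, subset, res, p_model = best
    return TrimmedModel(
        terms=subset, coefficients={k: float(v) for k, v in res.params.items()},
        model_pvalue=p_model, mse=mse, significant=True, results=res,
    )


# ---- behavioral summaries ----

def _round_frame(sessions: list[SessionData]) -> pd.DataFrame:
    rows = []
    iter_count: dict[tuple[str, str], int] = {}
    for s in sessions:
        for rnd in s.rounds:
            key = (s.subject_id, rnd.completed_task.value)
            iter_count[key] = iter_count.get(key, 0) + 1
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "round": rnd.round_index,
                    "rated_task": rnd.rated_task.value,
                    "completed_task": rnd.completed_task.value,
                    "iteration": iter_count[key],
                    "rating": rnd.rating,
                    "offer": rnd.offer,
                    "accuracy": rnd.result.weighted_accuracy if rnd.result else np.nan,
                    "rt": (
                        float(np.nanmean(rnd.result.rt_ms)) if rnd.result and
                        np.any(np.isfinite(rnd.result.rt_ms)) else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def _rating_iterations(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["rating_iteration"] = out.groupby(["subject_id", "rated_task"]).cumcount() + 1
    return out


@dataclass
class BehavioralSummary:
    table1: pd.DataFrame
    anova: dict[str, pd.DataFrame]
    posthoc: pd.DataFrame
    halves: pd.DataFrame
    offer_matching: dict[str, float]
    rounds: pd.DataFrame = field(repr=False, default=None)


def _two_way_anova(df: pd.DataFrame, value: str, task_col: str, iter_col: str):
    data = df.dropna(subset=[value]).rename(columns={value: "y"})
    if data[task_col].nunique() < 2 or data[iter_col].nunique() < 2:
        return None
    model = ols(f"y ~ C({task_col}) + C({iter_col})", data=data).fit()
    return anova_lm(model, typ=2)


def _paired_posthoc(per_subject: pd.DataFrame, value: str, holm: bool) -> pd.DataFrame:
    tasks = sorted(per_subject["task"].unique())
    wide = per_subject.pivot(index="subject_id", columns="task", values=value)
    rows = []
    for a, b in itertools.combinations(tasks, 2):
        sub = wide[[a, b]].dropna()
        if len(sub) < 3:
            continue
        t, p = ttest_rel(sub[a], sub[b])
        rows.append({"measure": value, "task_a": a, "task_b": b,
                     "t": float(t), "p": float(p), "n": len(sub)})
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out


def behavioral_summaries(
    sessions: list[SessionData], holm: bool = False
) -> BehavioralSummary:
    """Task-level summary table plus the standard test battery."""
    if len(sessions) < 2:
        raise ValueError("behavioral summaries need at least 2 subjects")
    df = _round_frame(sessions)

    per_subject_acc = (
        df.groupby(["subject_id", "completed_task"])
        .agg(accuracy=("accuracy", "mean"), rt=("rt", "mean"))
        .reset_index()
        .rename(columns={"completed_task": "task"})
    )
    per_subject_rating = (
        df.groupby(["subject_id", "rated_task"])["rating"].mean().reset_index()
        .rename(columns={"rated_task": "task"})
    )
    diff_rows = [
        {"subject_id": s.subject_id, "task": k, "difficulty": v}
        for s in sessions for k, v in s.difficulty.items()
    ]
    per_subject_diff = pd.DataFrame(diff_rows)

    order = [t.value for t in (TaskKind.detect1,) + RATED_TASKS]
    table1 = pd.DataFrame(index=["accuracy", "rt_ms", "difficulty", "fair_wage"],
                          columns=order, dtype=float)
    for task in order:
        acc = per_subject_acc[per_subject_acc["task"] == task]
        table1.loc["accuracy", task] = acc["accuracy"].mean() * 100
        table1.loc["rt_ms", task] = acc["rt"].mean()
        table1.loc["difficulty", task] = per_subject_diff[
            per_subject_diff["task"] == task
        ]["difficulty"].mean()
        rat = per_subject_rating[per_subject_rating["task"] == task]
        table1.loc["fair_wage", task] = rat["rating"].mean() if len(rat) else np.nan

    anova = {}
    acc_tab = _two_way_anova(df, "accuracy", "completed_task", "iteration")
    if acc_tab is not None:
        anova["accuracy"] = acc_tab
    ratings = _rating_iterations(df)
    rat_tab = _two_way_anova(ratings, "rating", "rated_task", "rating_iteration")
    if rat_tab is not None:
        anova["rating"] = rat_tab

    posthoc = pd.concat(
        [
            _paired_posthoc(per_subject_acc, "accuracy", holm),
            _paired_posthoc(per_subject_acc.dropna(subset=["rt"]), "rt", holm),
            _paired_posthoc(per_subject_rating, "rating", holm),
            _paired_posthoc(per_subject_diff, "difficulty", holm),
        ],
        ignore_index=True,
    )

    # first vs second half of each subject's completions, per task measure
    half_rows = []
    for (task, measure, col, frame) in [
        (t, m, c, f)
        for t in [k.value for k in RATED_TASKS]
        for m, c, f in [("rating", "rating", ratings), ("accuracy", "accuracy", df)]
    ]:
        key = "rated_task" if measure == "rating" else "completed_task"
        sub = frame[frame[key] == task].dropna(subset=[col])
        firsts, seconds = [], []
        for _, g in sub.groupby("subject_id"):
            if len(g) < 2:
                continue
            half = len(g) // 2
            firsts.append(g[col].iloc[:half].mean())
            seconds.append(g[col].iloc[half:].mean())
        if len(firsts) >= 3:
            t_stat, p = ttest_rel(firsts, seconds)
            half_rows.append({"task": task, "measure": measure,
                              "t": float(t_stat), "p": float(p), "n": len(firsts)})
    halves = pd.DataFrame(half_rows)

    # offer matching: rating on round t vs the offer on round t-1
    pooled_x, pooled_y, n_sig = [], [], 0
    for sid, g in df.sort_values("round").groupby("subject_id"):
        x = g["offer"].to_numpy()[:-1]
        y = g["rating"].to_numpy()[1:]
        if len(x) >= 5:
            rho, p = spearmanr(x, y)
            if np.isfinite(p) and p < 0.05:
                n_sig += 1
        pooled_x.append(x)
        pooled_y.append(y)
    rho, p = spearmanr(np.concatenate(pooled_x), np.concatenate(pooled_y))
    offer_matching = {"rho": float(rho), "p": float(p),
                      "n_subjects_significant": int(n_sig)}

    return BehavioralSummary(
        table1=table1, anova=anova, posthoc=posthoc, halves=halves,
        offer_matching=offer_matching, rounds=df,
    )


def accuracy_wage_correlations(sessions: list[SessionData]) -> pd.DataFrame:
    """Across-subject Pearson correlation of mean accuracy and mean fair
    wage, per rated task."""
    df = _round_frame(sessions)
    rows = []
    for task in [t.value for t in RATED_TASKS]:
        acc = (
            df[df["completed_task"] == task]
            .groupby("subject_id")["accuracy"].mean()
        )
        wage = (
            df[df["rated_task"] == task].groupby("subject_id")["rating"].mean()
        )
        joined = pd.concat([acc, wage], axis=1, keys=["acc", "wage"]).dropna()
        if len(joined) < 3:
            continue
        r, p = pearsonr(joined["acc"], joined["wage"])
        rows.append({"task": task, "r": float(r), "p": float(p), "n": len(joined)})
    return pd.DataFrame(rows)
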