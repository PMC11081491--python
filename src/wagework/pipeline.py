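"""File-format layer and the end-to-end pipeline.

Stages write plain comma-separated tables with headers (trial-, round-
and subject-level files) plus structured-text reports, and every later
stage can be re-run alone from those files.  ``pipeline_run`` chains
simulate -> decompose -> fit -> posterior -> validate -> stats -> report
deterministically under the config seed.
"""

from __future__ import annotations

import datetime
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import posterior as posterior_mod
from .config import RunConfig, substream
from .hbi import FitResult, fit_hierarchical, subject_data_from_session
from .models import ModelSpec, ParamSet, sigmoid
from .process_model import decompose_session
from .simulate import (
    SessionData,
    SimRound,
    round_table,
    simulate_cohort,
    subject_table,
    trial_table,
)
from .stats import behavioral_summaries, score_questionnaire, tertile_split
from .tasks import TaskKind, TrialSequence, score_responses
from .validation import simulation_fidelity
from .simulate import NFC_REVERSE, NFC_SCALE_MAX


class MissingInputError(FileNotFoundError):
    """A pipeline stage was asked to run without its input files."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"stage '{stage}' needs {path.name} — run the earlier stages first "
            f"(looked in {path.parent})"
        )
    return path


def save_cohort(sessions: list[SessionData], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial_table(sessions).to_csv(out / "trials.csv", index=False)
    round_table(sessions).to_csv(out / "rounds.csv", index=False)
    subject_table(sessions).to_csv(out / "subjects.csv", index=False)


def load_cohort(data_dir: str | Path, stage: str = "load") -> list[SessionData]:
    """Rebuild sessions from the tabular files (generative profiles and
    pre-noise rating means are not recoverable from disk)."""
    data = Path(data_dir)
    trials = pd.read_csv(_require(data / "trials.csv", stage))
    rounds = pd.read_csv(_require(data / "rounds.csv", stage))
    subjects = pd.read_csv(_require(data / "subjects.csv", stage))
    sessions = []
    for sid, sub_rounds in rounds.groupby("subject_id", sort=False):
        sub_trials = trials[trials["subject_id"] == sid]
        sim_rounds = []
        for _, row in sub_rounds.sort_values("round").iterrows():
            tr = sub_trials[sub_trials["round"] == row["round"]].sort_values("trial")
            seq = result = None
            if len(tr):
                seq = TrialSequence(
                    task=TaskKind(row["completed_task"]),
                    letters=tuple(tr["letter"]),
                    is_target=tuple(bool(v) for v in tr["is_target"]),
                    is_lure=tuple(bool(v) for v in tr["is_lure"]),
                )
                result = score_responses(
                    seq, [bool(v) for v in tr["responded"]],
                    tr["rt_ms"].to_numpy(float),
                )
            sim_rounds.append(
                SimRound(
                    round_index=int(row["round"]),
                    rated_task=TaskKind(row["rated_task"]),
                    rating_mean=float("nan"),
                    rating_raw=float(row["rating"]),  # pre-clamp value not on disk
                    rating=float(row["rating"]),
                    offer=float(row["offer"]),
                    won=row["outcome"] == "rated",
                    completed_task=TaskKind(row["completed_task"]),
                    sequence=seq,
                    result=result,
                    points=float(row["points"]),
                )
            )
        srow = subjects[subjects["subject_id"] == sid].iloc[0]
        nfc = [None if pd.isna(srow[f"nfc_{i+1:02d}"]) else int(srow[f"nfc_{i+1:02d}"])
               for i in range(sum(c.startswith("nfc_") for c in subjects.columns))]
        saps = [None if pd.isna(srow[f"saps_{i+1:02d}"]) else int(srow[f"saps_{i+1:02d}"])
                for i in range(sum(c.startswith("saps_") for c in subjects.columns))]
        difficulty = {
            c.removeprefix("difficulty_"): float(srow[c])
            for c in subjects.columns if c.startswith("difficulty_")
        }
        sessions.append(
            SessionData(
                subject_id=sid, rounds=sim_rounds, nfc_items=nfc,
                saps_items=saps, screener_pass=bool(srow["screener_pass"]),
                difficulty=difficulty, excluded=bool(srow["excluded"]),
            )
        )
    return sessions


def _reported_params(spec: ModelSpec, vec: np.ndarray) -> dict[str, float]:
    """Group means mapped through the reporting transforms."""
    out = {}
    for name, v in zip(spec.param_names, vec):
        if name == "sigma":
            out[name] = float(np.exp(v))
        elif name == "alpha":
            out[name] = float(sigmoid(v))
        else:
            out[name] = float(v)
    return out


def write_fit_report(fit: FitResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# hierarchical fit report", ""]
    lines.append("## model comparison")
    for i, spec in enumerate(fit.specs):
        lines.append(
            f"  {spec.canonical_name}: frequency={fit.frequencies[i]:.3f} "
            f"pxp={fit.pxp[i]:.4f} exceedance={fit.exceedance[i]:.4f}"
        )
    lines.append(f"  bayes_omnibus_risk={fit.bor:.4f}")
    lines.append(f"  iterations={fit.n_iterations}")
    lines.append("")
    lines.append("## group parameters (reporting scale)")
    for spec in fit.specs:
        nm = spec.canonical_name
        rep = _reported_params(spec, fit.group_means[nm])
        lines.append(f"  {nm}:")
        for k, v in rep.items():
            lines.append(f"    {k} = {v:.4f}")
    (out / "fit_report.txt").write_text("\n".join(lines) + "\n")

    rows = []
    for mi, spec in enumerate(fit.specs):
        nm = spec.canonical_name
        for si, sid in enumerate(fit.subject_ids):
            sf = fit.subject_fits[nm][si]
            row = {"subject_id": sid, "model": nm,
                   "responsibility": fit.responsibilities[si, mi]}
            if sf is not None and sf.success:
                p = ParamSet.from_vector(spec, sf.mode)
                row["sigma"] = p.sigma
                if spec.has_alpha:
                    row["alpha"] = p.alpha
                    row.update({f"init_{k}": v for k, v in p.inits.items()})
                else:
                    row["init"] = p.init
                row.update({f"c_{c}": v for c, v in p.costs.items()})
                if spec.has_deltas:
                    row.update({f"d_{c}": v for c, v in p.deltas.items()})
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "subject_fits.csv", index=False)


def write_posterior_report(post, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    post.summary().to_csv(out / "posterior_summary.csv", index=False)
    rows = []
    for cost in post.costs:
        for v, d in zip(post.grids[cost], post.marginals[cost]):
            rows.append({"cost": cost, "value": v, "mass": d})
    pd.DataFrame(rows).to_csv(out / "posterior_marginals.csv", index=False)


def pipeline_run(config: RunConfig, verbose: bool = False) -> Path:
    """Run the full pipeline; returns the artifacts directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] seed={config.seed} {msg}"
        log_lines.append(line)
        if verbose:
            print(line)

    try:
        config.save(out / "config.yaml")

        # simulate
        spec = ModelSpec.parse(config.generating_model)
        sessions, truth = simulate_cohort(
            config.n_subjects, spec, substream(config.seed, "simulate"),
            config=config.experiment,
        )
        save_cohort(sessions, out)
        truth.to_csv(out / "ground_truth.csv", index=False)
        log("simulate", f"{len(sessions)} subjects from {spec.canonical_name}")

        # decompose
        comps = pd.concat([decompose_session(s) for s in sessions],
                          ignore_index=True)
        comps.to_csv(out / "components.csv", index=False)
        log("decompose", f"{len(comps)} round records")

        # fit
        specs = [ModelSpec.parse(m) for m in config.models]
        cohort = [subject_data_from_session(s) for s in sessions]
        fit = fit_hierarchical(
            specs, cohort, config.fitter, substream(config.seed, "fit"),
            verbose=verbose,
        )
        write_fit_report(fit, out)
        log("fit", f"{len(specs)} models, {fit.n_iterations} iterations, "
            f"pxp_max={fit.pxp.max():.3f}")

        # posterior
        threshold = min(1.0, float(fit.frequencies.max()))
        post = posterior_mod.mixture_posterior(fit, threshold=threshold)
        write_posterior_report(post, out)
        log("posterior", f"threshold={threshold:.2f} "
            + " ".join(f"{c}={post.means[c]:+.3f}" for c in post.costs))

        # validate (simulation fidelity of the fitted models)
        r2 = simulation_fidelity(
            fit, cohort, n_repeats=config.fidelity_repeats,
            n_iterations=config.fidelity_iterations,
            rng=substream(config.seed, "fidelity"),
            rating_bounds=config.experiment.rating_bounds,
        )
        (out / "fidelity.txt").write_text(f"mean_r_squared = {r2:.4f}\n")
        log("validate", f"simulation fidelity r^2={r2:.3f}")

        # stats
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = behavioral_summaries(sessions)
        summary.table1.to_csv(out / "table1.csv")
        summary.posthoc.to_csv(out / "posthoc.csv", index=False)
        nfc_scores = pd.Series(
            {s.subject_id: score_questionnaire(
                s.nfc_items, NFC_REVERSE, NFC_SCALE_MAX, s.screener_pass, "NFC"
            ).score for s in sessions}
        )
        tert = tertile_split(nfc_scores)
        tert.rename("nfc_tertile").to_csv(out / "nfc_tertiles.csv")
        stats_lines = [
            "# behavioral statistics", "",
            f"offer matching: rho={summary.offer_matching['rho']:.3f} "
            f"p={summary.offer_matching['p']:.3f}", "",
            "ANOVA tables and post-hoc tests: see table1.csv / posthoc.csv",
        ]
        (out / "stats_report.txt").write_text("\n".join(stats_lines) + "\n")
        log("stats", f"offer-matching rho={summary.offer_matching['rho']:.3f}")
    except Exception as exc:  # noqa: BLE001
        log("error", f"pipeline halted: {type(exc).__name__}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    log("report", f"completed at {stamp}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
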