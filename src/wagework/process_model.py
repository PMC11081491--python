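"""Working-memory process model: decompose a round into cost components.

A perfect-memory gating model steps through the stimulus stream and tallies
the elementary operations needed to complete the round with 100% accuracy:

* ``n_update`` — trials on which a new stimulus is gated into WM (gating
  out the oldest item simultaneously).  Updating is skipped when the item
  on screen already matches the newest item in storage.
* ``maintenance`` — the instructed WM load of the task (0, 1 or 2 items),
  a per-round quantity.
* ``n_interference`` — 2-back lure trials: the stimulus one trial back in
  storage matches the one on screen and must be rejected as a false match.

Subject behavior contributes the remaining components — button presses,
misses, and false alarms — which are tallied from the observed responses,
never simulated (mistakes are not part of the process model).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tasks import RoundResult, TaskKind, TrialSequence

COST_NAMES = ("update", "maintenance", "interference", "response", "miss", "fa")


@dataclass(frozen=True)
class CostComponents:
    """Per-round tallies of the six cost drivers."""

    n_update: int
    maintenance: int
    n_interference: int
    n_response: int
    n_miss: int
    n_fa: int

    def __getitem__(self, name: str) -> int:
        return {
            "update": self.n_update,
            "maintenance": self.maintenance,
            "interference": self.n_interference,
            "response": self.n_response,
            "miss": self.n_miss,
            "fa": self.n_fa,
        }[name]


def count_updates(
    task: TaskKind,
    letters: tuple[str, ...] | list[str],
    match_any: bool = False,
) -> int:
    """Count WM gating events for a letter stream under a task's load.

    A FIFO buffer holds the last ``wm_load`` stimuli.  While the buffer is
    filling (the first ``wm_load`` trials) every trial gates in one item.
    Thereafter a trial counts as an update unless the incoming letter
    matches the newest buffered item (``match_any=True`` relaxes this to a
    match against any buffered item).  Zero-load tasks never update.
    """
    load = task.wm_load
    if load == 0:
        return 0
    buffer: list[str] = []
    n_update = 0
    for ch in letters:
        if len(buffer) < load:
            buffer.append(ch)
            n_update += 1
            continue
        matched = ch in buffer if match_any else ch == buffer[-1]
        if not matched:
            buffer.pop(0)
            buffer.append(ch)
            n_update += 1
    return n_update


def decompose_round(
    seq: TrialSequence,
    result: RoundResult,
    match_any: bool = False,
) -> CostComponents:
    """Tally the six cost components for one completed round.

    The stimulus-driven components (updates, maintenance, interference)
    come from the perfect-memory simulation of the letter stream alone;
    the behavioral components come from the scored responses.
    """
    if len(result.responded) != seq.n_trials:
        raise ValueError("sequence and result describe different rounds")
    return CostComponents(
        n_update=count_updates(seq.task, seq.letters, match_any=match_any),
        maintenance=seq.task.wm_load,
        n_interference=seq.n_lures,
        n_response=sum(result.responded),
        n_miss=result.misses,
        n_fa=result.false_alarms,
    )


def decompose_session(session: "SessionData") -> pd.DataFrame:  # noqa: F821
    """Component table for every completed round of one session.

    Returns one row per round with the completed task (the rated task when
    the auction was won, otherwise the default), flagging rounds whose
    response data are missing rather than dropping them.
    """
    rows = []
    for rnd in session.rounds:
        if rnd.result is None or rnd.sequence is None:
            rows.append(
                {
                    "subject_id": session.subject_id,
                    "round": rnd.round_index,
                    "task": rnd.completed_task.value,
                    "missing": True,
                }
            )
            continue
        comps = decompose_round(rnd.sequence, rnd.result)
        rows.append(
            {
                "subject_id": session.subject_id,
                "round": rnd.round_index,
                "task": rnd.completed_task.value,
                "missing": False,
                "n_update": comps.n_update,
                "maintenance": comps.maintenance,
                "n_interference": comps.n_interference,
                "n_response": comps.n_response,
                "n_miss": comps.n_miss,
                "n_fa": comps.n_fa,
            }
        )
    return pd.DataFrame(rows)
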