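"""Letter-sequence engine for the four attention/working-memory tasks.

The paradigm interleaves four tasks built on a common stimulus stream of
uppercase letters shown one at a time:

* ``detect1`` — respond to the letter T (the low-effort default task),
* ``detect3`` — respond when any letter appears three times in a row,
* ``back1``  — respond when the letter matches the one shown 1 trial ago,
* ``back2``  — respond when the letter matches the one shown 2 trials ago.

Sequences are standardized so each 15-trial round contains 3-5 targets
(20-33% target rate).  2-back sequences additionally contain *lure* trials:
a letter matching the 1-back stimulus without being a 2-back target, the
event that drives the interference cost in the process model.

Online accuracy weighs hits three times as heavily as correct rejections;
it is the quantity used for the every-8-rounds exclusion check.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from enum import Enum

import numpy as np

ALPHABET = tuple(string.ascii_uppercase)

#: stimulus duration; responses after this deadline count as non-responses
STIMULUS_MS = 1500
ISI_MS = 300

DEFAULT_N_TRIALS = 15
DEFAULT_TARGET_RANGE = (3, 5)
DEFAULT_LURE_RANGE = (1, 3)

#: weight of a hit relative to a correct rejection in online accuracy
HIT_WEIGHT = 3.0


class TaskKind(str, Enum):
    """The four tasks, each with its instructed working-memory load."""

    detect1 = "detect1"
    back1 = "back1"
    detect3 = "detect3"
    back2 = "back2"

    @property
    def wm_load(self) -> int:
        """Items the task instructs the subject to hold in WM (0/1/2/2)."""
        return {"detect1": 0, "back1": 1, "detect3": 2, "back2": 2}[self.value]


#: the three tasks that receive fair-wage ratings (detect1 is the default)
RATED_TASKS = (TaskKind.back1, TaskKind.detect3, TaskKind.back2)


class GenerationError(RuntimeError):
    """Raised when no legal sequence is found within the retry budget."""


@dataclass(frozen=True)
class TrialSequence:
    """One round's letters with per-trial target and lure annotations."""

    task: TaskKind
    letters: tuple[str, ...]
    is_target: tuple[bool, ...]
    is_lure: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.letters)
        if n == 0:
            raise ValueError("empty letter sequence")
        if len(self.is_target) != n or len(self.is_lure) != n:
            raise ValueError("target/lure annotations must match sequence length")
        if any(self.is_lure) and self.task is not TaskKind.back2:
            raise ValueError("lure trials are defined only for the 2-back task")

    @property
    def n_trials(self) -> int:
        return len(self.letters)

    @property
    def n_targets(self) -> int:
        return sum(self.is_target)

    @property
    def n_lures(self) -> int:
        return sum(self.is_lure)


@dataclass(frozen=True)
class RoundResult:
    """Scored outcome of one completed round."""

    responded: tuple[bool, ...]
    rt_ms: tuple[float, ...]
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    weighted_accuracy: float

    @property
    def n_responses(self) -> int:
        return self.hits + self.false_alarms


def label_targets(task: TaskKind, letters: list[str] | tuple[str, ...]) -> list[bool]:
    """Apply a task's rule to a letter stream, returning the target mask.

    detect1: letter == 'T'; back1/back2: match 1/2 trials back; detect3:
    any letter appearing three times in a row.
    """
    if len(letters) == 0:
        raise ValueError("empty letter sequence")
    for ch in letters:
        if len(ch) != 1 or ch not in ALPHABET:
            raise ValueError(f"invalid stimulus {ch!r}: expected uppercase A-Z")
    n = len(letters)
    if task is TaskKind.detect1:
        return [ch == "T" for ch in letters]
    if task is TaskKind.back1:
        return [i >= 1 and letters[i] == letters[i - 1] for i in range(n)]
    if task is TaskKind.back2:
        return [i >= 2 and letters[i] == letters[i - 2] for i in range(n)]
    if task is TaskKind.detect3:
        return [
            i >= 2 and letters[i] == letters[i - 1] == letters[i - 2]
            for i in range(n)
        ]
    raise ValueError(f"unknown task {task!r}")


def label_lures(task: TaskKind, letters: list[str] | tuple[str, ...]) -> list[bool]:
    """Mark 2-back lure trials: a 1-back match that is not a 2-back target.

    For every other task the mask is all-False (interference is tallied
    only on the 2-back).
    """
    n = len(letters)
    if task is not TaskKind.back2:
        return [False] * n
    targets = label_targets(task, letters)
    return [
        i >= 1 and letters[i] == letters[i - 1] and not targets[i]
        for i in range(n)
    ]


def _draw_letter(rng: np.random.Generator, exclude: set[str]) -> str:
    pool = [ch for ch in ALPHABET if ch not in exclude]
    return pool[rng.integers(len(pool))]


def _build_detect1(rng, n_trials, n_targets):
    positions = set(rng.choice(n_trials, size=n_targets, replace=False).tolist())
    return [
        "T" if i in positions else _draw_letter(rng, {"T"}) for i in range(n_trials)
    ]


def _choose_positions(rng, candidates, k, min_gap=0):
    """Draw k positions from candidates, no two closer than min_gap."""
    cand = list(candidates)
    rng.shuffle(cand)
    chosen: list[int] = []
    for p in cand:
        if all(abs(p - q) > min_gap for q in chosen):
            chosen.append(p)
            if len(chosen) == k:
                return sorted(chosen)
    return None


def _build_back1(rng, n_trials, n_targets):
    # adjacent targets would form a triple (forbidden in n-back rounds)
    pos = _choose_positions(rng, range(1, n_trials), n_targets, min_gap=1)
    if pos is None:
        return None
    targets = set(pos)
    letters: list[str] = []
    for i in range(n_trials):
        if i in targets:
            letters.append(letters[i - 1])
        else:
            exclude = {letters[i - 1]} if i >= 1 else set()
            letters.append(_draw_letter(rng, exclude))
    return letters


def _build_back2(rng, n_trials, n_targets, n_lures):
    pos = _choose_positions(
        rng, range(2, n_trials), n_targets + n_lures, min_gap=0
    )
    if pos is None:
        return None
    rng.shuffle(pos)
    targets = set(pos[:n_targets])
    lures = set(pos[n_targets:])
    letters: list[str] = []
    for i in range(n_trials):
        if i in targets:
            cand = letters[i - 2]
            if cand == letters[i - 1]:
                return None  # would create a triple / lure-target overlap
            letters.append(cand)
        elif i in lures:
            cand = letters[i - 1]
            if i >= 2 and cand == letters[i - 2]:
                return None  # would be a 2-back target, not a lure
            letters.append(cand)
        else:
            exclude = {letters[i - 1]} if i >= 1 else set()
            if i >= 2:
                exclude.add(letters[i - 2])
            letters.append(_draw_letter(rng, exclude))
    return letters


def _build_detect3(rng, n_trials, n_targets):
    # a run of length L >= 3 yields L-2 targets; compose runs to hit the count
    max_runs = min(n_targets, (n_trials + 1 - n_targets) // 3)
    if max_runs < 1:
        return None
    k = int(rng.integers(1, max_runs + 1))
    # partition n_targets into k positive parts
    if k == 1:
        parts = [n_targets]
    else:
        cuts = sorted(rng.choice(n_targets - 1, size=k - 1, replace=False) + 1)
        parts = [b - a for a, b in zip([0] + cuts, cuts + [n_targets])]
    run_lens = [p + 2 for p in parts]
    total = sum(run_lens) + (k - 1)  # at least one separator between runs
    if total > n_trials:
        return None
    slack = n_trials - total
    # distribute slack among k+1 gaps (before, between, after)
    gaps = [0] * (k + 1)
    for _ in range(slack):
        gaps[rng.integers(k + 1)] += 1
    letters: list[str] = []
    for j, run in enumerate(run_lens):
        for _ in range(gaps[j] + (1 if j > 0 else 0)):
            exclude = {letters[-1]} if letters else set()
            letters.append(_draw_letter(rng, exclude))
        exclude = {letters[-1]} if letters else set()
        run_letter = _draw_letter(rng, exclude)
        letters.extend([run_letter] * run)
    for _ in range(gaps[k]):
        exclude = {letters[-1]} if letters else set()
        letters.append(_draw_letter(rng, exclude))
    return letters


def generate_sequence(
    task: TaskKind,
    n_trials: int = DEFAULT_N_TRIALS,
    target_range: tuple[int, int] = DEFAULT_TARGET_RANGE,
    rng: np.random.Generator | None = None,
    lure_range: tuple[int, int] = DEFAULT_LURE_RANGE,
    max_retries: int = 10_000,
) -> TrialSequence:
    """Generate a task-legal sequence with a target count in ``target_range``.

    Generation is constructive (targets and, for the 2-back, lures are
    placed first, then filler letters are drawn avoiding accidental
    matches) followed by verification against :func:`label_targets`;
    construction conflicts trigger a bounded retry.  Identical seed and
    arguments give identical sequences.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_trials < 3:
        raise ValueError("n_trials must be at least 3")
    lo, hi = target_range
    if not (0 <= lo <= hi <= n_trials):
        raise ValueError(f"invalid target_range {target_range} for {n_trials} trials")

    for _ in range(max_retries):
        n_targets = int(rng.integers(lo, hi + 1))
        if task is TaskKind.detect1:
            letters = _build_detect1(rng, n_trials, n_targets)
        elif task is TaskKind.back1:
            letters = _build_back1(rng, n_trials, n_targets)
        elif task is TaskKind.back2:
            n_lures = int(rng.integers(lure_range[0], lure_range[1] + 1))
            letters = _build_back2(rng, n_trials, n_targets, n_lures)
        elif task is TaskKind.detect3:
            letters = _build_detect3(rng, n_trials, n_targets)
        else:
            raise ValueError(f"unknown task {task!r}")
        if letters is None:
            continue
        targets = label_targets(task, letters)
        if sum(targets) != n_targets:
            continue
        lures = label_lures(task, letters)
        if task is TaskKind.back2 and not (
            lure_range[0] <= sum(lures) <= lure_range[1]
        ):
            continue
        return TrialSequence(
            task=task,
            letters=tuple(letters),
            is_target=tuple(targets),
            is_lure=tuple(lures),
        )
    raise GenerationError(
        f"no legal {task.value} sequence found in {max_retries} attempts "
        f"(n_trials={n_trials}, target_range={target_range})"
    )


def score_responses(
    seq: TrialSequence,
    responded: list[bool] | tuple[bool, ...],
    rt_ms: list[float] | tuple[float, ...] | None = None,
    deadline_ms: float = STIMULUS_MS,
) -> RoundResult:
    """Score a round's responses against the target mask.

    Responses with RT beyond the stimulus deadline are treated as
    non-responses before counting.  Weighted accuracy is
    ``(3*hits + CR) / (3*(hits+misses) + FA + CR)``.
    """
    if len(responded) != seq.n_trials:
        raise ValueError("response vector length does not match sequence")
    if rt_ms is None:
        rt_ms = tuple(np.nan for _ in responded)
    elif len(rt_ms) != seq.n_trials:
        raise ValueError("rt vector length does not match sequence")

    effective = [
        bool(r) and not (np.isfinite(t) and t > deadline_ms)
        for r, t in zip(responded, rt_ms)
    ]
    hits = sum(1 for r, tgt in zip(effective, seq.is_target) if r and tgt)
    misses = sum(1 for r, tgt in zip(effective, seq.is_target) if not r and tgt)
    fa = sum(1 for r, tgt in zip(effective, seq.is_target) if r and not tgt)
    cr = sum(1 for r, tgt in zip(effective, seq.is_target) if not r and not tgt)
    denom = HIT_WEIGHT * (hits + misses) + fa + cr
    wacc = (HIT_WEIGHT * hits + cr) / denom if denom > 0 else float("nan")
    return RoundResult(
        responded=tuple(effective),
        rt_ms=tuple(float(t) for t in rt_ms),
        hits=hits,
        misses=misses,
        false_alarms=fa,
        correct_rejections=cr,
        weighted_accuracy=wacc,
    )
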