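"""Behavioral scoring of keypress streams.

Implements the behavioral analysis of the rotating-cylinder tasks:

* percept-interval extraction — the first keypress opens the first
  dominance interval, every change of reported direction closes one and
  opens the next, same-direction repeats are ignored, and the final
  interval (truncated by block end) is kept but flagged censored and
  excluded from duration summaries;
* switch counting and rates — switches are direction changes (the initial
  report is not a switch); the rate is switches per block duration, log10
  transformed with zero counts replaced by 0.5 switches per block to keep
  the transform finite;
* real-switch scoring — a response is correct if it reports the post-switch
  direction within a 4-s window after a physical switch; each switch is
  credited at most once by its earliest eligible response (responses are
  consumed once); sessions with 6 or fewer correct of the 11 switches
  (accuracy <= 63.6%) are excluded from further analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import BlockRecord, Cohort, KeypressEvent, SessionRecord
from .stimulus import SwitchSchedule

__all__ = [
    "PerceptInterval",
    "RealSwitchScore",
    "BlockMetrics",
    "SubjectMetrics",
    "extract_percepts",
    "count_switches",
    "block_switch_rate",
    "score_real_switch",
    "block_metrics",
    "subject_metrics",
    "cohort_metrics",
    "DEFAULT_WINDOW",
    "MIN_CORRECT",
    "ZERO_COUNT_REPLACEMENT",
]

#: Response window after a physical switch within which a matching report
#: counts as correct (seconds).
DEFAULT_WINDOW = 4.0

#: Minimum credited responses (of 11) for a session to be included.
MIN_CORRECT = 7

#: Replacement for a zero switch count before the log10 transform.
ZERO_COUNT_REPLACEMENT = 0.5


@dataclass(frozen=True)
class PerceptInterval:
    """One dominance interval; ``censored`` marks the block-end truncated tail."""

    start: float
    end: float
    direction: str
    censored: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class RealSwitchScore:
    n_physical: int
    n_correct: int
    mean_rt_correct: float  # NaN when no correct responses
    mean_rt_all: float  # mean latency of every first post-switch matching report
    included: bool

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_physical


@dataclass(frozen=True)
class BlockMetrics:
    n_switches: int
    switch_rate: float
    log10_rate: float
    durations: tuple[float, ...]
    mean_duration: float  # NaN when no completed durations
    cv: float  # NaN when fewer than 2 durations


@dataclass(frozen=True)
class SubjectMetrics:
    """Per subject-session summary over the bi-stable blocks."""

    subject_id: str
    session_index: int
    group: str
    mean_log10_rate: float
    mean_switch_rate: float
    block_log10_rates: tuple[float, ...]
    block_counts: tuple[int, ...]
    pooled_durations: tuple[float, ...]
    mean_duration: float
    cv: float
    real_switch: Optional[RealSwitchScore]
    included: bool


def _check_sorted(events: Sequence[KeypressEvent]) -> None:
    times = [e.t for e in events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("events must be sorted by time")


def extract_percepts(
    events: Sequence[KeypressEvent], block_duration: float
) -> list[PerceptInterval]:
    """Split a keypress stream into dominance intervals.

    Durations are defined only after the initial report; the trailing
    interval is returned with ``censored=True`` so callers can keep the
    conservation identity (pre-response time + completed durations +
    censored tail = block duration) while excluding the truncated tail
    from duration statistics.
    """
    _check_sorted(events)
    if events and (events[0].t < 0 or events[-1].t > block_duration):
        raise ValueError("event times must lie within [0, block_duration]")
    if not events:
        return []

    intervals: list[PerceptInterval] = []
    start = events[0].t
    direction = events[0].key
    for e in events[1:]:
        if e.key == direction:  # repeat of the same percept: no new interval
            continue
        intervals.append(PerceptInterval(start=start, end=e.t, direction=direction))
        start, direction = e.t, e.key
    intervals.append(
        PerceptInterval(start=start, end=block_duration, direction=direction, censored=True)
    )
    return intervals


def count_switches(events: Sequence[KeypressEvent]) -> int:
    """Number of reported direction changes (the initial report is not one)."""
    _check_sorted(events)
    n = 0
    prev: Optional[str] = None
    for e in events:
        if prev is not None and e.key != prev:
            n += 1
        prev = e.key
    return n


def block_switch_rate(n_switches: int, block_duration: float) -> tuple[float, float]:
    """(switch rate in Hz, log10 rate) with the zero-count replacement.

    The stored rate is the plain ``n / duration`` (0 Hz for silent blocks);
    only the log10 transform substitutes 0.5 switches per block so it stays
    finite.
    """
    if n_switches < 0:
        raise ValueError("n_switches must be non-negative")
    if block_duration <= 0:
        raise ValueError("block_duration must be positive")
    rate = n_switches / block_duration
    log10_rate = float(np.log10(max(n_switches, ZERO_COUNT_REPLACEMENT) / block_duration))
    return rate, log10_rate


def score_real_switch(
    events: Sequence[KeypressEvent],
    schedule: SwitchSchedule,
    window: float = DEFAULT_WINDOW,
    min_correct: int = MIN_CORRECT,
) -> RealSwitchScore:
    """Score responses to the physical switch schedule.

    Greedy one-to-one matching in time order: each physical switch is
    credited by the earliest not-yet-consumed response that reports the
    post-switch direction with latency in ``[0, window)``. Anticipatory
    responses (before the switch) are never credited. With eligibility
    windows ordered along the timeline this greedy matching attains the
    maximum possible number of credits.
    """
    _check_sorted(events)
    if events and events[-1].t > schedule.block_duration:
        raise ValueError("events extend past the schedule's block duration")

    used = [False] * len(events)
    rts_correct: list[float] = []
    rts_all: list[float] = []
    n_correct = 0
    for t_switch, new_dir in zip(schedule.switch_times, schedule.directions[1:]):
        first_match: Optional[float] = None
        for j, e in enumerate(events):
            if e.t < t_switch or e.key != new_dir:
                continue
            if first_match is None:
                first_match = e.t - t_switch
            if used[j] or e.t - t_switch >= window:
                continue
            used[j] = True
            n_correct += 1
            rts_correct.append(e.t - t_switch)
            break
        if first_match is not None:
            rts_all.append(first_match)

    return RealSwitchScore(
        n_physical=schedule.n_switches,
        n_correct=n_correct,
        mean_rt_correct=float(np.mean(rts_correct)) if rts_correct else float("nan"),
        mean_rt_all=float(np.mean(rts_all)) if rts_all else float("nan"),
        included=n_correct >= min_correct,
    )


def block_metrics(block: BlockRecord) -> BlockMetrics:
    """Switch count, rates and duration summary for one block."""
    n = count_switches(block.events)
    rate, log10_rate = block_switch_rate(n, block.duration)
    intervals = extract_percepts(block.events, block.duration)
    durations = tuple(iv.duration for iv in intervals if not iv.censored)
    if durations:
        mean_d = float(np.mean(durations))
        cv = float(np.std(durations, ddof=1) / mean_d) if len(durations) > 1 else float("nan")
    else:
        mean_d, cv = float("nan"), float("nan")
    return BlockMetrics(
        n_switches=n,
        switch_rate=rate,
        log10_rate=log10_rate,
        durations=durations,
        mean_duration=mean_d,
        cv=cv,
    )


def subject_metrics(
    session: SessionRecord,
    window: float = DEFAULT_WINDOW,
    min_correct: int = MIN_CORRECT,
) -> SubjectMetrics:
    """Per-session summary: mean log10 rate over bi-stable blocks, pooled
    durations, coefficient of variation, and real-switch inclusion.

    The subject-level rate is the mean of per-block log10 rates (each with
    the zero-count replacement applied per block). The coefficient of
    variation is SD / mean of the pooled completed durations. Sessions
    without a real-switch block bypass exclusion (``included=True``).
    """
    bistable = session.bistable_blocks()
    if not bistable:
        raise ValueError(f"session {session.subject_id}/{session.session_index} has no bi-stable blocks")

    per_block = [block_metrics(b) for b in bistable]
    pooled = tuple(d for bm in per_block for d in bm.durations)
    if pooled:
        mean_d = float(np.mean(pooled))
        cv = float(np.std(pooled, ddof=1) / mean_d) if len(pooled) > 1 else float("nan")
    else:
        mean_d, cv = float("nan"), float("nan")

    rs_block = session.real_switch_block()
    rs_score = None
    included = True
    if rs_block is not None:
        if rs_block.schedule is None:
            raise ValueError("real-switch block lacks a schedule")
        rs_score = score_real_switch(rs_block.events, rs_block.schedule, window, min_correct)
        included = rs_score.included

    return SubjectMetrics(
        subject_id=session.subject_id,
        session_index=session.session_index,
        group=session.group,
        mean_log10_rate=float(np.mean([bm.log10_rate for bm in per_block])),
        mean_switch_rate=float(np.mean([bm.switch_rate for bm in per_block])),
        block_log10_rates=tuple(bm.log10_rate for bm in per_block),
        block_counts=tuple(bm.n_switches for bm in per_block),
        pooled_durations=pooled,
        mean_duration=mean_d,
        cv=cv,
        real_switch=rs_score,
        included=included,
    )


def cohort_metrics(
    cohort: Cohort, window: float = DEFAULT_WINDOW, min_correct: int = MIN_CORRECT
) -> pd.DataFrame:
    """Score every session of a cohort into a tidy metrics table.

    One row per subject-session; per-block log10 rates in
    ``log10_rate_block{k}`` columns, real-switch accuracy and the
    inclusion flag alongside.
    """
    rows = []
    for session in cohort:
        m = subject_metrics(session, window, min_correct)
        row: dict = {
            "subject_id": m.subject_id,
            "session": m.session_index,
            "group": m.group,
            "mean_log10_rate": m.mean_log10_rate,
            "mean_switch_rate": m.mean_switch_rate,
            "mean_duration": m.mean_duration,
            "cv": m.cv,
            "included": m.included,
            "rs_accuracy": m.real_switch.accuracy if m.real_switch else np.nan,
            "rs_n_correct": m.real_switch.n_correct if m.real_switch else np.nan,
            "rs_mean_rt": m.real_switch.mean_rt_correct if m.real_switch else np.nan,
        }
        for k, (lr, c) in enumerate(zip(m.block_log10_rates, m.block_counts), start=1):
            row[f"log10_rate_block{k}"] = lr
            row[f"n_switches_block{k}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_from_counts(counts: pd.DataFrame, block_duration: float = 120.0) -> pd.DataFrame:
    """Per subject-session mean log10 switch rate from a block-count table.

    ``counts`` is the tidy frame produced by
    :func:`cylsfm.observer.generate_cohort_rates` (columns ``subject_id``,
    ``group``, ``session``, ``block``, ``n_switches`` plus covariates). The
    zero-count replacement and log10 transform are applied per block, then
    averaged within subject-session, matching :func:`subject_metrics`.
    """
    frame = counts.copy()
    if (frame["n_switches"] < 0).any():
        raise ValueError("n_switches must be non-negative")
    frame["log10_rate"] = np.log10(
        np.maximum(frame["n_switches"], ZERO_COUNT_REPLACEMENT) / block_duration
    )
    keys = ["subject_id", "group", "session"]
    extra = [
        c for c in frame.columns
        if c not in keys + ["block", "n_switches", "log10_rate"]
    ]
    agg = {"log10_rate": "mean", **{c: "first" for c in extra}}
    out = frame.groupby(keys, observed=True, sort=False).agg(agg).reset_index()
    return out.rename(columns={"log10_rate": "mean_log10_rate"})


def pooled_durations_by_group(
    cohort: Cohort, metrics: Optional[pd.DataFrame] = None, session: int = 1
) -> dict[str, np.ndarray]:
    """Completed percept durations pooled across included participants per group."""
    if metrics is None:
        metrics = cohort_metrics(cohort)
    inc = metrics.loc[(metrics["session"] == session) & metrics["included"], "subject_id"]
    keep = set(inc)
    out: dict[str, list[float]] = {}
    for s in cohort:
        if s.session_index != session or s.subject_id not in keep:
            continue
        m = subject_metrics(s)
        out.setdefault(s.group, []).extend(m.pooled_durations)
    return {g: np.asarray(v) for g, v in out.items()}
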