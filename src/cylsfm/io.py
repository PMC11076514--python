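"""Plain-text serialization of behavioral sessions.

Formats:

* ``events.csv`` — one row per keypress: ``subject_id, session, block,
  block_type, t, key`` (seconds from block onset; key ``left``/``right``,
  referring to the front surface's motion).
* ``sessions.csv`` — one row per subject-session with group label,
  covariates and metabolite concentrations.
* ``schedule.json`` — the physical switch schedule of the real-switch
  block (shared by all subjects).

Validation is strict and reports offending row numbers; a malformed file
should fail loudly, not produce silent misscoring.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .records import BlockRecord, Cohort, KeypressEvent, SessionRecord
from .stimulus import SwitchSchedule

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["subject_id", "session", "block", "block_type", "t", "key"]
_VALID_KEYS = {"left", "right"}
_VALID_BLOCK_TYPES = {"bistable", "real_switch"}

SESSION_META_COLUMNS = ["subject_id", "group", "session", "diagnosis", "benzodiazepine"]


class ValidationError(ValueError):
    """Raised when an input table violates the event-file contract."""


def write_events(cohort: Cohort, path: str | Path) -> None:
    cohort.events_frame().to_csv(path, index=False)


def write_sessions(cohort: Cohort, path: str | Path) -> None:
    cohort.sessions_frame().to_csv(path, index=False)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write events.csv, sessions.csv and (if present) schedule.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_events(cohort, outdir / "events.csv")
    write_sessions(cohort, outdir / "sessions.csv")
    for s in cohort:
        rs = s.real_switch_block()
        if rs is not None and rs.schedule is not None:
            rs.schedule.to_json(outdir / "schedule.json")
            break


def read_events(
    path: str | Path,
    block_duration: float = 120.0,
    schedule: Optional[SwitchSchedule] = None,
) -> Cohort:
    """Parse an events.csv into a cohort of sessions with typed blocks.

    Real-switch blocks are attached the given ``schedule``. Raises
    :class:`ValidationError` listing 1-based data row numbers for missing
    columns, unknown keys or block types, out-of-range times, or
    non-monotone times within a block.
    """
    frame = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    problems: list[str] = []
    rownum = frame.index + 1

    bad_key = ~frame["key"].isin(_VALID_KEYS)
    for r, k in zip(rownum[bad_key], frame.loc[bad_key, "key"]):
        problems.append(f"row {r}: invalid key {k!r}")
    bad_type = ~frame["block_type"].isin(_VALID_BLOCK_TYPES)
    for r, k in zip(rownum[bad_type], frame.loc[bad_type, "block_type"]):
        problems.append(f"row {r}: invalid block_type {k!r}")
    t = pd.to_numeric(frame["t"], errors="coerce")
    bad_t = t.isna() | (t < 0) | (t > block_duration)
    for r, v in zip(rownum[bad_t], frame.loc[bad_t, "t"]):
        problems.append(f"row {r}: time {v!r} outside [0, {block_duration}]")
    if not problems:
        for (_, _, _), grp in frame.groupby(["subject_id", "session", "block"], sort=False):
            tt = grp["t"].to_numpy()
            if np.any(np.diff(tt) < 0):
                bad = grp.index[1:][np.diff(tt) < 0] + 1
                problems.append(f"rows {list(bad)}: non-monotone times within a block")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems[:20]))

    sessions: list[SessionRecord] = []
    for (subj, sess), sgrp in frame.groupby(["subject_id", "session"], sort=False):
        blocks = []
        for (blk, btype), bgrp in sgrp.groupby(["block", "block_type"], sort=False):
            events = [
                KeypressEvent(t=float(r.t), key=str(r.key)) for r in bgrp.itertuples()
            ]
            blocks.append(
                BlockRecord(
                    block_index=int(blk),
                    block_type=str(btype),  # type: ignore[arg-type]
                    duration=block_duration,
                    events=events,
                    schedule=schedule if btype == "real_switch" else None,
                )
            )
        blocks.sort(key=lambda b: b.block_index)
        sessions.append(
            SessionRecord(
                subject_id=str(subj), group="", session_index=int(sess), blocks=blocks
            )
        )
    return Cohort(sessions=sessions)


def read_cohort(indir: str | Path, block_duration: float = 120.0) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`.

    Merges group labels, covariates and metabolites from sessions.csv onto
    the event-derived sessions.
    """
    indir = Path(indir)
    schedule = None
    if (indir / "schedule.json").exists():
        schedule = SwitchSchedule.from_json(indir / "schedule.json")
    cohort = read_events(indir / "events.csv", block_duration, schedule)

    meta_path = indir / "sessions.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        keyed = meta.set_index(["subject_id", "session"])
        extra_cols = [c for c in meta.columns if c not in SESSION_META_COLUMNS]
        for s in cohort:
            try:
                row = keyed.loc[(s.subject_id, s.session_index)]
            except KeyError:
                logger.warning("no metadata for %s/%s", s.subject_id, s.session_index)
                continue
            s.group = str(row.get("group", ""))
            s.diagnosis = str(row.get("diagnosis", "none"))
            s.benzodiazepine_flag = bool(row.get("benzodiazepine", False))
            s.covariates = {
                c: float(row[c]) for c in extra_cols
                if c in ("BPRS", "SPQ", "BACS", "SGI", "BPRS_D", "SPQ_CP") and pd.notna(row[c])
            }
            mets = {
                c: float(row[c]) for c in ("GABA", "glutamate", "glutamine")
                if c in extra_cols and pd.notna(row.get(c))
            }
            s.metabolites = mets or None
    return cohort
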