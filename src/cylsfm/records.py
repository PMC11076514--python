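"""Shared behavioral data containers: keypresses, blocks, sessions, cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stimulus import Direction, SwitchSchedule

GROUPS = ("control", "relative", "pwpp")

BlockType = Literal["bistable", "real_switch"]


@dataclass(frozen=True)
class KeypressEvent:
    """One directional report: time in seconds from block onset, key pressed."""

    t: float
    key: Direction


@dataclass
class BlockRecord:
    """Keypress stream of one 120-s block, tagged by task type.

    Real-switch blocks carry the physical ``schedule``; bi-stable blocks
    have ``schedule=None``.
    """

    block_index: int
    block_type: BlockType
    duration: float
    events: list[KeypressEvent]
    schedule: Optional[SwitchSchedule] = None

    def __post_init__(self) -> None:
        times = [e.t for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("block events must be sorted by time")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("event times must lie within [0, duration]")


@dataclass
class SessionRecord:
    """One subject-session: 1 real-switch block + 5 bi-stable blocks plus covariates."""

    subject_id: str
    group: str
    session_index: int
    blocks: list[BlockRecord]
    covariates: dict[str, float] = field(default_factory=dict)
    metabolites: Optional[dict[str, float]] = None
    benzodiazepine_flag: bool = False
    diagnosis: str = "none"

    def bistable_blocks(self) -> list[BlockRecord]:
        return [b for b in self.blocks if b.block_type == "bistable"]

    def real_switch_block(self) -> Optional[BlockRecord]:
        for b in self.blocks:
            if b.block_type == "real_switch":
                return b
        return None


@dataclass
class Cohort:
    """A collection of subject-sessions generated or loaded together."""

    sessions: list[SessionRecord]

    def __iter__(self) -> Iterator[SessionRecord]:
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)

    def sessions_frame(self) -> pd.DataFrame:
        """One row per subject-session with group, covariates and metabolites."""
        rows = []
        for s in self.sessions:
            row: dict = {
                "subject_id": s.subject_id,
                "group": s.group,
                "session": s.session_index,
                "diagnosis": s.diagnosis,
                "benzodiazepine": s.benzodiazepine_flag,
            }
            row.update(s.covariates)
            if s.metabolites:
                row.update(s.metabolites)
            rows.append(row)
        return pd.DataFrame(rows)

    def events_frame(self) -> pd.DataFrame:
        """Long-format keypress table (subject, session, block, type, t, key)."""
        cols = {k: [] for k in ("subject_id", "session", "block", "block_type", "t", "key")}
        for s in self.sessions:
            for b in s.blocks:
                for e in b.events:
                    cols["subject_id"].append(s.subject_id)
                    cols["session"].append(s.session_index)
                    cols["block"].append(b.block_index)
                    cols["block_type"].append(b.block_type)
                    cols["t"].append(e.t)
                    cols["key"].append(e.key)
        return pd.DataFrame(cols)
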