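"""Rotating-cylinder structure-from-motion stimulus kinematics.

The stimulus is the classic dot-defined rotating cylinder: small black and
white squares translate horizontally across a rectangular aperture with a
sinusoidal speed profile — fastest at the aperture midline, stationary at
the edges — as if painted on a transparent cylinder rotating in depth.
Without depth cues the rotation direction is ambiguous and perception
alternates spontaneously; with an occlusion cue (the "real switch" task)
the direction is unambiguous and reverses on a fixed schedule.

This module generates dot trajectories as coordinate time series and the
physical direction-reversal schedule of the real-switch task. Nothing is
rendered; the output is analysis-grade data.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Direction = Literal["left", "right"]

#: Inter-switch intervals (seconds) used by the real-switch schedule.
REAL_SWITCH_INTERVALS = (9.0, 11.0, 13.0)


@dataclass(frozen=True)
class CylinderParams:
    """Geometry and timing of the rotating-cylinder stimulus.

    Defaults are the standard configuration: a 7 deg x 10 deg aperture of
    400 dots (200 black, 200 white, each 0.25 deg) simulating a cylinder
    rotating at 90 deg/s, sampled at a 60 Hz frame rate for a 120 s block.
    """

    n_dots: int = 400
    dot_size: float = 0.25
    n_black: int = 200
    n_white: int = 200
    width: float = 7.0
    height: float = 10.0
    rotation_speed: float = 90.0  # degrees of cylinder rotation per second
    fixation_diameter: float = 0.6
    cue_circle_diameter: float = 1.8
    frame_rate: float = 60.0
    block_duration: float = 120.0

    def __post_init__(self) -> None:
        if self.n_black + self.n_white != self.n_dots:
            raise ValueError(
                f"n_black + n_white must equal n_dots "
                f"({self.n_black} + {self.n_white} != {self.n_dots})"
            )
        for name in ("width", "height", "rotation_speed", "frame_rate", "block_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def radius(self) -> float:
        """Cylinder radius in degrees of visual angle (= width / 2)."""
        return self.width / 2.0

    @property
    def omega(self) -> float:
        """Angular rotation speed in radians per second."""
        return math.radians(self.rotation_speed)

    @property
    def period(self) -> float:
        """Full rotation period in seconds (360 deg / rotation_speed)."""
        return 360.0 / self.rotation_speed


@dataclass(frozen=True)
class DotTrajectory:
    """One dot's horizontal position series over a block.

    ``x_series`` samples ``x(t) = R sin(omega t + phase0)`` at the frame
    rate: the screen projection of uniform circular motion, so horizontal
    speed peaks at the aperture midline and vanishes at the edges. ``y`` is
    fixed per dot. ``surface`` distinguishes the two counter-phase dot
    sheets (offset by pi in phase) that form the front and back of the
    cylinder.
    """

    dot_id: int
    polarity: Literal["black", "white"]
    surface: Literal[1, 2]
    y: float
    phase0: float
    x_series: np.ndarray


@dataclass(frozen=True)
class SwitchSchedule:
    """Physical rotation-direction timeline for a real-switch block.

    ``directions`` has one more entry than ``switch_times``: the initial
    direction plus the direction after each switch. Directions alternate.
    """

    block_duration: float
    switch_times: tuple[float, ...]
    directions: tuple[Direction, ...]

    def __post_init__(self) -> None:
        times = self.switch_times
        if len(self.directions) != len(times) + 1:
            raise ValueError("directions must have exactly one more entry than switch_times")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("switch_times must be strictly increasing")
        if times and not (0.0 < times[0] and times[-1] < self.block_duration):
            raise ValueError("switch_times must lie strictly inside (0, block_duration)")
        for d1, d2 in zip(self.directions, self.directions[1:]):
            if d1 == d2:
                raise ValueError("consecutive directions must alternate")

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    @property
    def mean_rate(self) -> float:
        """Physical switch rate in Hz (switches per block duration)."""
        return self.n_switches / self.block_duration

    def direction_at(self, t: float) -> Direction:
        """Front-surface rotation direction at time ``t``."""
        idx = int(np.searchsorted(np.asarray(self.switch_times), t, side="right"))
        return self.directions[idx]

    def intervals(self) -> tuple[float, ...]:
        """Inter-switch intervals, including block onset to first switch."""
        prev = (0.0,) + self.switch_times[:-1]
        return tuple(t - p for t, p in zip(self.switch_times, prev))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "block_duration": self.block_duration,
            "switch_times": list(self.switch_times),
            "directions": list(self.directions),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SwitchSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            block_duration=float(payload["block_duration"]),
            switch_times=tuple(float(t) for t in payload["switch_times"]),
            directions=tuple(payload["directions"]),
        )


def dot_x(t, phase0: float, params: CylinderParams):
    """Horizontal dot position (degrees) at time ``t``.

    ``x(t) = (width/2) * sin(omega * t + phase0)`` with omega the rotation
    speed in rad/s — the orthographic projection of a point on a cylinder
    of radius width/2 rotating uniformly in depth.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return params.radius * np.sin(params.omega * t + phase0)


def generate_trajectories(params: CylinderParams, seed: int) -> list[DotTrajectory]:
    """Generate the full dot field for one block.

    Dots are split evenly between the two counter-phase surfaces; paired
    dots on opposite surfaces differ by pi in initial phase, so the sheets
    always move in opposite horizontal directions. Vertical positions are
    uniform over the aperture height. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    n = params.n_dots
    if n == 0:
        logger.warning("n_dots = 0: returning empty trajectory collection")
        return []

    t = frame_times(params)
    ys = rng.uniform(-params.height / 2.0, params.height / 2.0, size=n)
    # Half the dots get free phases; their surface-2 partners are offset by pi.
    n_half = n // 2
    base_phases = rng.uniform(0.0, 2.0 * np.pi, size=n - n_half)
    phases = np.concatenate([base_phases, base_phases[:n_half] + np.pi])
    surfaces = np.concatenate([np.ones(n - n_half, dtype=int), np.full(n_half, 2, dtype=int)])
    # Polarity balanced within each surface where possible.
    polarity = np.array(["black", "white"])[np.arange(n) % 2]
    if params.n_black != params.n_white:
        polarity = np.array(
            ["black"] * params.n_black + ["white"] * params.n_white, dtype=object
        )
        rng.shuffle(polarity)

    out = []
    for i in range(n):
        x = params.radius * np.sin(params.omega * t + phases[i])
        out.append(
            DotTrajectory(
                dot_id=i,
                polarity=str(polarity[i]),  # type: ignore[arg-type]
                surface=int(surfaces[i]),  # type: ignore[arg-type]
                y=float(ys[i]),
                phase0=float(phases[i]),
                x_series=x,
            )
        )
    return out


def frame_times(params: CylinderParams) -> np.ndarray:
    """Sample times (seconds) for one block at the configured frame rate."""
    n_frames = int(round(params.block_duration * params.frame_rate)) + 1
    return np.arange(n_frames) / params.frame_rate


def trajectories_to_frame(trajectories: Sequence[DotTrajectory], params: CylinderParams) -> pd.DataFrame:
    """Tidy long-format table: one row per (dot, frame)."""
    t = frame_times(params)
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "dot_id": tr.dot_id,
                    "frame": np.arange(t.size),
                    "t": t,
                    "x": tr.x_series,
                    "y": tr.y,
                    "polarity": tr.polarity,
                    "surface": tr.surface,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def recover_rotation_speed(trajectories: Sequence[DotTrajectory], params: CylinderParams) -> float:
    """Recover the angular rotation speed (deg/s) from generated trajectories.

    For each dot the angular phase is obtained as arcsin(x / R), which folds
    the true phase into [-pi/2, pi/2]; the folds are undone by tracking the
    monotone segments (between folds the folded phase moves at exactly the
    rotation speed, alternating sign). The unwrapped phase is regressed
    against time and the median fitted slope across dots is returned in
    degrees per second.
    """
    t = frame_times(params)
    speeds = []
    for tr in trajectories:
        s = np.arcsin(np.clip(tr.x_series / params.radius, -1.0, 1.0))
        d = np.diff(s)
        sign = np.sign(d)
        sign[sign == 0] = 1
        # Orient so the folded phase starts ascending, then count folds
        # (sign changes of the folded derivative) before each sample.
        s = s * sign[0]
        sign = sign * sign[0]
        folds = np.concatenate([[0, 0], np.cumsum(sign[1:] != sign[:-1])])
        phase = folds * np.pi + (-1.0) ** folds * s
        slope = np.polyfit(t, phase, 1)[0]
        speeds.append(abs(math.degrees(slope)))
    return float(np.median(speeds))


def make_real_switch_schedule(
    params: CylinderParams, seed_or_fixed: int | str = "paper"
) -> SwitchSchedule:
    """Build the real-switch block's physical direction schedule.

    Eleven switches at pseudo-random intervals of 9, 11 or 13 s within a
    120 s block (mean physical rate 11/120 ~ 0.09 Hz). ``"paper"`` returns
    the fixed canonical schedule shared by all simulated observers, as the
    task used one timing for all subjects; an integer seed samples a fresh
    feasible interval sequence. Directions alternate starting leftward.
    """
    n_switches = 11
    if params.block_duration < n_switches * min(REAL_SWITCH_INTERVALS):
        raise ValueError(
            f"cannot fit {n_switches} switches with minimum interval "
            f"{min(REAL_SWITCH_INTERVALS)} s in a {params.block_duration} s block"
        )

    if seed_or_fixed == "paper":
        # Fixed canonical interval sequence; sums to 113 s < 120 s.
        intervals = [9, 11, 13, 9, 11, 13, 9, 11, 9, 9, 9]
    elif isinstance(seed_or_fixed, (int, np.integer)):
        rng = np.random.default_rng(int(seed_or_fixed))
        for _ in range(10_000):
            intervals = list(rng.choice(REAL_SWITCH_INTERVALS, size=n_switches))
            if sum(intervals) < params.block_duration:
                break
        else:  # pragma: no cover - the feasible region is large
            raise ValueError("could not sample a feasible switch schedule")
    else:
        raise TypeError("seed_or_fixed must be an integer seed or the string 'paper'")

    switch_times = tuple(float(t) for t in np.cumsum(intervals))
    directions: tuple[Direction, ...] = tuple(
        "left" if i % 2 == 0 else "right" for i in range(n_switches + 1)
    )
    return SwitchSchedule(
        block_duration=params.block_duration,
        switch_times=switch_times,
        directions=directions,
    )
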