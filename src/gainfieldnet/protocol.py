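"""Saccade-and-fixation stimulus protocol.

During one *training period* a visual target sits at a fixed head-centered
location h while the eyes saccade through a random sequence of fixation
positions drawn uniformly from the permissible eye range.  Eye position is
piecewise linear in time: constant during fixations, constant-velocity
ramps during saccades.  The retinal location of the target obeys the
coordinate identity x = h - e at every sample.

Testing uses a static grid of all (eye position, head location)
combinations, each presented as a constant stimulus for a settle duration.

Trajectories are sampled at the stimulus rate (default 1 kHz) and
re-sampled by linear interpolation onto the numerical integration grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TrainingSchedule",
    "StimulusTrajectory",
    "TestGrid",
    "make_training_period",
    "make_test_conditions",
    "resample_to_step",
    "trajectory_to_frame",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """Protocol constants for training periods."""

    target_locations: tuple[float, ...]
    fixations_per_period: int
    fixation_duration_ms: float
    saccade_speed_deg_per_s: float
    eye_sample_range: tuple[float, float]
    stimulus_rate_khz: float = 1.0
    retinal_range: Optional[tuple[float, float]] = None  # for visibility checks

    def __post_init__(self):
        if self.fixations_per_period < 1:
            raise ValueError("fixations_per_period must be >= 1")
        if self.fixation_duration_ms <= 0:
            raise ValueError("fixation_duration_ms must be positive")
        if self.saccade_speed_deg_per_s <= 0:
            raise ValueError("saccade_speed must be positive")
        lo, hi = self.eye_sample_range
        if hi < lo:
            raise ValueError("eye_sample_range must be ordered")


@dataclass(frozen=True)
class StimulusTrajectory:
    """Uniformly sampled eye position and target retinal location.

    ``retinal_loc + eye_pos == head_loc`` at every sample.
    """

    times: np.ndarray  # ms
    eye_pos: np.ndarray  # deg
    retinal_loc: np.ndarray  # deg
    head_loc: float  # deg

    def __post_init__(self):
        if not (len(self.times) == len(self.eye_pos) == len(self.retinal_loc)):
            raise ValueError("trajectory arrays must have equal length")
        if len(self.times) >= 2:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=0, atol=1e-9):
                raise ValueError("trajectory must be uniformly sampled")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def sample_step(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass(frozen=True)
class TestGrid:
    """Static test conditions: the cross product of eye and head grids."""

    eye_positions: tuple[float, ...]
    head_locations: tuple[float, ...] = field(default=())
    settle_ms: float = 300.0
    stimulus_rate_khz: float = 1.0

    def __post_init__(self):
        eyes = np.asarray(self.eye_positions, dtype=float)
        if np.any(np.diff(eyes) < 0):
            raise ValueError("eye_positions must be sorted ascending")
        heads = np.asarray(self.head_locations, dtype=float)
        if len(heads) >= 2:
            dh = np.diff(heads)
            if not np.allclose(dh, dh[0], rtol=0, atol=1e-9) or dh[0] <= 0:
                raise ValueError("head_locations must be uniformly spaced ascending")
        if self.settle_ms <= 0:
            raise ValueError("settle_ms must be positive")

    @classmethod
    def from_range(
        cls,
        eye_positions,
        head_range: tuple[float, float],
        head_step: float,
        settle_ms: float = 300.0,
    ) -> "TestGrid":
        lo, hi = head_range
        n = int(round((hi - lo) / head_step))
        if abs(lo + n * head_step - hi) > 1e-9:
            raise ValueError("head_step does not evenly tile head_range")
        heads = tuple(lo + head_step * np.arange(n + 1))
        return cls(tuple(eye_positions), heads, settle_ms)


def _sample_breakpoints(
    break_t: np.ndarray, break_e: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a piecewise-linear (t, e) path on a uniform grid of step dt."""
    total = break_t[-1]
    n = int(np.floor(total / dt + 1e-9))
    times = dt * np.arange(n + 1)
    return times, np.interp(times, break_t, break_e)


def make_training_period(
    schedule: TrainingSchedule, head_loc: float, rng: np.random.Generator
) -> StimulusTrajectory:
    """One training period: N_f fixation plateaus joined by constant-speed ramps.

    Fixation positions are i.i.d. uniform on ``schedule.eye_sample_range``.
    The period starts at the first drawn fixation (no initial saccade).
    """
    if head_loc not in schedule.target_locations:
        raise ValueError(f"head_loc {head_loc} is not one of the scheduled target locations")
    lo, hi = schedule.eye_sample_range
    fixations = rng.uniform(lo, hi, size=schedule.fixations_per_period)

    if schedule.retinal_range is not None:
        rlo, rhi = schedule.retinal_range
        retinal = head_loc - fixations
        if retinal.min() < rlo - 1e-9 or retinal.max() > rhi + 1e-9:
            raise ValueError(
                f"target at head location {head_loc} leaves the retinal space "
                f"[{rlo}, {rhi}] during the sampled eye movements"
            )

    speed_ms = schedule.saccade_speed_deg_per_s / 1000.0  # deg per ms
    break_t, break_e = [0.0], [fixations[0]]
    t = 0.0
    for k, e in enumerate(fixations):
        t += schedule.fixation_duration_ms
        break_t.append(t)
        break_e.append(e)
        if k + 1 < len(fixations):
            nxt = fixations[k + 1]
            t += abs(nxt - e) / speed_ms
            break_t.append(t)
            break_e.append(nxt)

    dt = 1.0 / schedule.stimulus_rate_khz
    times, eye = _sample_breakpoints(np.asarray(break_t), np.asarray(break_e), dt)
    return StimulusTrajectory(
        times=times, eye_pos=eye, retinal_loc=head_loc - eye, head_loc=float(head_loc)
    )


def period_duration(schedule: TrainingSchedule, fixations: np.ndarray) -> float:
    """Exact bookkeeping: N_f * fixation_duration + sum |delta e| / v (ms)."""
    speed_ms = schedule.saccade_speed_deg_per_s / 1000.0
    return len(fixations) * schedule.fixation_duration_ms + float(
        np.sum(np.abs(np.diff(fixations))) / speed_ms
    )


def make_test_conditions(grid: TestGrid) -> list[tuple[float, float, StimulusTrajectory]]:
    """One constant trajectory per (eye, head) combination, eye outer loop."""
    dt = 1.0 / grid.stimulus_rate_khz
    n = int(np.floor(grid.settle_ms / dt + 1e-9))
    times = dt * np.arange(n + 1)
    conditions = []
    for e in grid.eye_positions:
        for h in grid.head_locations:
            traj = StimulusTrajectory(
                times=times,
                eye_pos=np.full_like(times, e),
                retinal_loc=np.full_like(times, h - e),
                head_loc=float(h),
            )
            conditions.append((float(e), float(h), traj))
    return conditions


def resample_to_step(traj: StimulusTrajectory, dt: float) -> StimulusTrajectory:
    """Linear interpolation of a trajectory onto a uniform grid of step dt (ms)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > traj.duration:
        raise ValueError("dt exceeds the trajectory duration")
    t0 = float(traj.times[0])
    n = int(np.floor(traj.duration / dt + 1e-9))
    times = t0 + dt * np.arange(n + 1)
    eye = np.interp(times, traj.times, traj.eye_pos)
    return StimulusTrajectory(
        times=times, eye_pos=eye, retinal_loc=traj.head_loc - eye, head_loc=traj.head_loc
    )


def trajectory_to_frame(traj: StimulusTrajectory):
    """Delimited-text view of a trajectory for inspection and plotting."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time_ms": traj.times,
            "eye_deg": traj.eye_pos,
            "retinal_deg": traj.retinal_loc,
            "head_deg": np.full_like(traj.times, traj.head_loc),
        }
    )
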