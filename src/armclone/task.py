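"""Center-out-center reaching task: target grid, timing and reference path.

Eight targets sit on a 0.5 m-diameter circle in a horizontal plane; each
trial moves a reference point from the circle's center out to one target
(reach), holds it there briefly (touch), brings it back (return) and
pauses at the center (wait).  The moving point is the tracking reference
for the reinforcement-learning agent and the fingertip path template for
the surrogate subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TargetGrid",
    "PhaseTiming",
    "MovingPointTrajectory",
    "PHASES",
    "generate_target_grid",
    "moving_point_position",
    "moving_point_trajectory",
    "trial_schedule",
]

PHASES = ("reach", "touch", "return", "wait")


@dataclass(frozen=True)
class TargetGrid:
    """Center and numbered targets of the circular grid.

    Target 1 lies in the +x direction from the center (farthest from the
    body); numbering proceeds clockwise when viewed from above.
    """

    center: np.ndarray
    diameter: float
    targets: np.ndarray  # (n, 3); row k is target k+1

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "targets", np.asarray(self.targets, float))

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def target(self, target_id: int) -> np.ndarray:
        """Target position for a 1-based target id."""
        if not 1 <= target_id <= self.n_targets:
            raise ValueError(f"target_id must be in 1..{self.n_targets}")
        return self.targets[target_id - 1]

    def to_dict(self) -> dict:
        return {
            "center": list(map(float, self.center)),
            "diameter_m": float(self.diameter),
            "n_targets": int(self.n_targets),
        }


@dataclass(frozen=True)
class PhaseTiming:
    """Durations of the four trial phases and the sampling period, seconds.

    The defaults use the 2 s cue interval for the outward reach, a 0.5 s
    hold at the target, 2 s for the return and a 1 s center pause, all
    sampled at 50 Hz.
    """

    reach_s: float = 2.0
    touch_hold_s: float = 0.5
    return_s: float = 2.0
    center_wait_s: float = 1.0
    dt: float = 0.02

    def __post_init__(self):
        for name in ("reach_s", "touch_hold_s", "return_s", "center_wait_s", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("reach_s", "touch_hold_s", "return_s", "center_wait_s"):
            ratio = getattr(self, name) / self.dt
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"dt must divide {name} exactly")

    @property
    def trial_duration(self) -> float:
        return self.reach_s + self.touch_hold_s + self.return_s + self.center_wait_s

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration / self.dt))

    @property
    def phase_durations(self) -> tuple[float, float, float, float]:
        return (self.reach_s, self.touch_hold_s, self.return_s, self.center_wait_s)

    def to_dict(self) -> dict:
        return {
            "reach_s": self.reach_s,
            "touch_hold_s": self.touch_hold_s,
            "return_s": self.return_s,
            "center_wait_s": self.center_wait_s,
            "dt": self.dt,
        }


@dataclass(frozen=True)
class MovingPointTrajectory:
    """Sampled reference trajectory of one trial towards one target."""

    target_id: int
    times: np.ndarray
    positions: np.ndarray
    phase_labels: tuple[str, ...] = field(repr=False)


def generate_target_grid(
    center=(0.35, 0.0, -0.25), diameter: float = 0.5, n_targets: int = 8
) -> TargetGrid:
    """Evenly spaced targets on a horizontal circle around ``center``.

    The default center places the circle 0.35 m in front of and 0.25 m
    below the shoulder, a comfortable desk-height plane.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    center = np.asarray(center, float)
    r = diameter / 2.0
    # Clockwise viewed from above (+x towards -y), target 1 at +x.
    ang = -2.0 * np.pi * np.arange(n_targets) / n_targets
    offsets = r * np.stack([np.cos(ang), np.sin(ang), np.zeros(n_targets)], axis=1)
    return TargetGrid(center=center, diameter=diameter, targets=center + offsets)


def moving_point_position(
    grid: TargetGrid, timing: PhaseTiming, target_id: int, t: float
) -> tuple[np.ndarray, str]:
    """Reference position and phase label at time ``t`` within a trial.

    The point moves linearly (constant speed) from center to target over
    the reach phase, holds at the target, returns linearly and waits at
    the center.
    """
    if not 0 <= t <= timing.trial_duration + 1e-9:
        raise ValueError(
            f"t={t} outside trial duration {timing.trial_duration}"
        )
    target = grid.target(target_id)
    t1 = timing.reach_s
    t2 = t1 + timing.touch_hold_s
    t3 = t2 + timing.return_s
    if t < t1:
        frac = t / timing.reach_s
        return grid.center + frac * (target - grid.center), "reach"
    if t < t2:
        return target.copy(), "touch"
    if t < t3:
        frac = (t - t2) / timing.return_s
        return target + frac * (grid.center - target), "return"
    return grid.center.copy(), "wait"


def moving_point_trajectory(
    grid: TargetGrid, timing: PhaseTiming, target_id: int
) -> MovingPointTrajectory:
    """The full sampled trial trajectory (one sample per ``dt``)."""
    n = timing.samples_per_trial
    times = np.arange(n) * timing.dt
    pos = np.empty((n, 3))
    labels = []
    for i, t in enumerate(times):
        pos[i], lab = moving_point_position(grid, timing, target_id, t)
        labels.append(lab)
    return MovingPointTrajectory(
        target_id=target_id,
        times=times,
        positions=pos,
        phase_labels=tuple(labels),
    )


def trial_schedule(
    grid: TargetGrid,
    timing: PhaseTiming,
    repetitions: int,
    order: tuple[int, ...] | None = None,
) -> list[tuple[int, float]]:
    """Back-to-back schedule of (target_id, trial start time) tuples.

    ``order`` defaults to targets 1..n in sequence; the whole order is
    repeated ``repetitions`` times.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if order is None:
        order = tuple(range(1, grid.n_targets + 1))
    if len(order) == 0:
        raise ValueError("order must not be empty")
    for tid in order:
        grid.target(tid)  # validates range
    schedule = []
    t0 = 0.0
    for _ in range(repetitions):
        for tid in order:
            schedule.append((tid, t0))
            t0 += timing.trial_duration
    return schedule
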