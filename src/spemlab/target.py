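"""Deterministic generator of the five-stage bouncing-ball pursuit stimulus.

The standard task (14 s at 60 Hz, N = 840 samples, 250 px/s) is:

1. the target appears at the start position and stays still for 1 s;
2. it moves along a random straight direction for 5 s, reflecting specularly
   off the screen edges;
3. it stops for 2 s;
4. it resumes along the direction it held when it stopped, for another 5 s;
5. it stops for a final 1 s.

The generator records ground-truth bounce samples and stage boundaries so the
segment-based direction index can be validated against known events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ScreenGeometry, STUDY_GEOMETRY
from .trajectory import Trajectory

__all__ = [
    "TaskConfig",
    "TargetTrajectory",
    "generate_target_trajectory",
    "reflect_step",
    "find_bounce_points",
    "straight_segments",
]

_MOTION_STAGES = (1, 3)  # 0-based stage numbers of the two 5 s motion stages


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the bouncing-ball task.

    ``seed`` fixes the random initial direction (drawn uniformly on
    [0, 2*pi)); everything else is deterministic.  ``ball_radius_px`` is the
    rendered ball size only -- reflection happens at the ball *center*
    (``reflect_at_ball_edge`` shrinks the bounce box by the radius instead).
    """

    geometry: ScreenGeometry = STUDY_GEOMETRY
    speed_px_s: float = 250.0
    stage_durations_s: tuple[float, ...] = (1.0, 5.0, 2.0, 5.0, 1.0)
    rate_hz: float = 60.0
    seed: int = 0
    start_position: tuple[float, float] | None = None
    ball_radius_px: float = 0.0
    reflect_at_ball_edge: bool = False

    def __post_init__(self) -> None:
        if self.speed_px_s <= 0:
            raise ValueError("speed_px_s must be positive")
        if len(self.stage_durations_s) != 5 or any(
            d <= 0 for d in self.stage_durations_s
        ):
            raise ValueError("stage_durations_s must be five positive durations")
        if self.ball_radius_px < 0:
            raise ValueError("ball_radius_px must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate_hz * sum(self.stage_durations_s)))

    def stage_sample_counts(self) -> list[int]:
        return [int(round(self.rate_hz * d)) for d in self.stage_durations_s]

    def resolved_start(self) -> tuple[float, float]:
        return (
            self.start_position
            if self.start_position is not None
            else self.geometry.center
        )


@dataclass(frozen=True)
class TargetTrajectory:
    """A generated stimulus trajectory plus its ground-truth event log."""

    trajectory: Trajectory
    bounce_indices: tuple[int, ...]
    stage_bounds: tuple[int, ...]  # cumulative sample offsets, len 6
    initial_direction_rad: float

    def stage_slices(self) -> list[slice]:
        b = self.stage_bounds
        return [slice(b[i], b[i + 1]) for i in range(5)]

    def segments(self) -> list[tuple[int, int]]:
        """Straight motion segments as inclusive (start, stop) sample pairs.

        Segment boundaries are the stage transitions and the logged bounces.
        The junction (apex) sample of a bounce is excluded from both adjacent
        segments: the within-step fold-back places it slightly off one of the
        two lines, so keeping it would bias the regression fit.  For a motion
        stage spanning samples [b_k, b_{k+1}) the straight run starts at
        sample b_k - 1 (the departure point) and ends at the last sample of
        the stage.
        """
        segs: list[tuple[int, int]] = []
        for stage in _MOTION_STAGES:
            lo = self.stage_bounds[stage] - 1
            hi = self.stage_bounds[stage + 1] - 1
            bounces = [b for b in self.bounce_indices if lo < b < hi]
            segs.extend(_split_run(lo, hi, bounces))
        return segs


def _split_run(lo: int, hi: int, bounces: list[int]) -> list[tuple[int, int]]:
    """Split a straight run of samples [lo, hi] at bounce apices, excluding
    each apex sample from both adjacent segments."""
    cuts = [lo] + sorted(bounces) + [hi]
    segs = []
    for j in range(len(cuts) - 1):
        a = cuts[j] + 1 if j > 0 else cuts[j]
        b = cuts[j + 1] - 1 if j + 1 < len(cuts) - 1 else cuts[j + 1]
        if b > a:
            segs.append((a, b))
    return segs


def reflect_step(
    pos: tuple[float, float],
    step: tuple[float, float],
    bounds: tuple[float, float, float, float],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Advance one step with specular reflection at the rectangle edges.

    ``bounds`` is (xmin, xmax, ymin, ymax).  A point exiting an edge by delta
    re-enters by delta with the corresponding direction component mirrored;
    corner exits mirror both components.  Per-step path length is preserved
    (the overshoot is folded back, not clamped).

    Returns ``(new_pos, new_step_direction)`` where the direction vector has
    the magnitude of ``step``.
    """
    xmin, xmax, ymin, ymax = bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty bounds rectangle")
    if not (xmin <= pos[0] <= xmax and ymin <= pos[1] <= ymax):
        raise ValueError(f"position {pos} outside bounds {bounds}")
    span = (xmax - xmin, ymax - ymin)
    if math.hypot(*step) > max(span):
        raise ValueError("step magnitude exceeds both screen dimensions")

    out = []
    newdir = []
    for p, s, lo, hi in (
        (pos[0], step[0], xmin, xmax),
        (pos[1], step[1], ymin, ymax),
    ):
        q = p + s
        d = s
        # fold until inside; at most a couple of iterations for physical steps
        while q < lo or q > hi:
            if q < lo:
                q = 2 * lo - q
            else:
                q = 2 * hi - q
            d = -d
        out.append(q)
        newdir.append(d)
    return (out[0], out[1]), (newdir[0], newdir[1])


def generate_target_trajectory(cfg: TaskConfig) -> TargetTrajectory:
    """Generate the five-stage stimulus; identical seeds give identical output.

    Bounce indices are logged with the convention used by
    :func:`find_bounce_points`: a bounce is attributed to the sample index at
    which the sign of the per-step displacement flips.  When the fold-back
    happens so close to the end of a step that the *net* displacement keeps
    the incoming sign, the flip only becomes visible one step later and the
    bounce is logged there.
    """
    geo = cfg.geometry
    start = cfg.resolved_start()
    if not geo.contains(*start):
        raise ValueError(f"start position {start} outside screen")

    margin = cfg.ball_radius_px if cfg.reflect_at_ball_edge else 0.0
    bounds = (margin, geo.width_px - 1 - margin, margin, geo.height_px - 1 - margin)

    rng = np.random.default_rng(cfg.seed)
    angle = float(rng.uniform(0.0, 2.0 * math.pi))
    step_len = cfg.speed_px_s / cfg.rate_hz
    direction = (step_len * math.cos(angle), step_len * math.sin(angle))

    counts = cfg.stage_sample_counts()
    n = sum(counts)
    pos = np.empty((n, 2), dtype=float)
    stage_bounds = [0]
    for c in counts:
        stage_bounds.append(stage_bounds[-1] + c)

    stage_of = np.repeat(np.arange(5), counts)
    pos[0] = start
    bounces: list[int] = []
    for i in range(1, n):
        if stage_of[i] in _MOTION_STAGES:
            p0 = (pos[i - 1, 0], pos[i - 1, 1])
            old_dir = direction
            new_pos, direction = reflect_step(p0, direction, bounds)
            pos[i] = new_pos
            net = (new_pos[0] - p0[0], new_pos[1] - p0[1])
            for ax in range(2):
                if math.copysign(1, direction[ax]) != math.copysign(1, old_dir[ax]):
                    # reflection occurred on this axis during step i-1 -> i
                    if math.copysign(1, net[ax]) != math.copysign(1, old_dir[ax]):
                        bounces.append(i - 1)  # net displacement already flipped
                    else:
                        bounces.append(i)  # flip visible only at the next step
        else:
            pos[i] = pos[i - 1]

    bounce_idx = tuple(sorted(set(bounces)))
    return TargetTrajectory(
        trajectory=Trajectory(pos, rate_hz=cfg.rate_hz),
        bounce_indices=bounce_idx,
        stage_bounds=tuple(stage_bounds),
        initial_direction_rad=angle,
    )


def find_bounce_points(traj: Trajectory, atol: float = 1e-9) -> list[int]:
    """Sample indices where the motion direction flips sign in x or y.

    A flip between consecutive displacement vectors d[k-1] and d[k] is
    reported at sample index k.  Steps with a displacement component smaller
    than ``atol`` carry no sign information; junctions where motion stops or
    starts are not bounces and are excluded.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 samples")
    d = traj.displacements()
    moving = np.hypot(d[:, 0], d[:, 1]) > atol
    out = []
    for k in range(1, d.shape[0]):
        if not (moving[k - 1] and moving[k]):
            continue
        for ax in range(2):
            a, b = d[k - 1, ax], d[k, ax]
            if abs(a) > atol and abs(b) > atol and (a > 0) != (b > 0):
                out.append(k)
                break
    return out


def straight_segments(
    traj: Trajectory, bounces: list[int] | None = None, atol: float = 1e-9
) -> list[tuple[int, int]]:
    """Straight motion segments of an arbitrary target trajectory.

    Segments are maximal runs of consecutive moving steps split at bounce
    points, returned as inclusive (start, stop) sample index pairs.  For a
    generated target this reproduces :meth:`TargetTrajectory.segments`.
    """
    if bounces is None:
        bounces = find_bounce_points(traj, atol=atol)
    d = traj.displacements()
    moving = np.hypot(d[:, 0], d[:, 1]) > atol
    cut = sorted(set(bounces))
    segs: list[tuple[int, int]] = []
    k, n_steps = 0, d.shape[0]
    while k < n_steps:
        if not moving[k]:
            k += 1
            continue
        a = k
        while k < n_steps and moving[k]:
            k += 1
        # moving run over displacement indices a..k-1 covers samples a..k
        segs.extend(_split_run(a, k, [c for c in cut if a < c < k]))
    return segs
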