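"""Gaze-target trajectory similarity indices.

Three families of indices quantify how well a gaze trajectory tracks the
stimulus:

* **Spatiotemporal colocality** ``Co``: both trajectories are dressed with
  closed balls on the integer pixel lattice (radius r1 for the target, r2
  for the gaze) and the time-summed cardinality of the ball intersections is
  normalized by the time-summed gaze-ball cardinality,

      Co = sum_t |B_r1(o(t)) n B_r2(g(t))| / sum_t |B_r2(g(t))|.

  With r2 <= r1, Co is 1 exactly when every gaze ball sits inside its paired
  target ball, and 0 when the balls never touch.

* **Direction difference**: per-step motion angles theta(t) =
  arctan2(dy, dx).  The sample index is one minus the length of the circular
  mean resultant of the per-step angle differences (0 = coherent tracking,
  -> 1 = uniformly scattered directions; range [0, 2] since an anti-aligned
  resultant is possible).  The regression index fits a total-least-squares
  line to the gaze points of each straight target segment and averages the
  acute orientation difference (radians, [0, pi/2]) to the segment.

* **Polygon area**: the trajectory is cut into non-overlapping windows of n
  samples; each window's points form a (possibly self-intersecting) polygon
  whose signed area comes from the Shoelace formula.  Straight tracking
  yields near-zero areas; wandering gaze inflates them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import ScreenGeometry, STUDY_GEOMETRY
from .target import straight_segments
from .trajectory import Trajectory

__all__ = [
    "ColocalityParams",
    "DirectionResult",
    "gauss_disk_cardinality",
    "disk_intersection_cardinality",
    "colocality",
    "step_angles",
    "sample_direction_index",
    "regression_direction_index",
    "direction_indices",
    "shoelace_area",
    "polygon_area_index",
    "normalize_area_cohort",
]

#: Default radius grids (mm) for the colocality parameter sweep.
DEFAULT_R1_MM = (5.0, 10.0, 15.0)
DEFAULT_R2_MM = (2.0, 4.0, 8.0)
#: Default polygon window lengths in samples (250 ms ... 1500 ms at 60 Hz).
DEFAULT_WINDOWS = (15, 30, 45, 60, 90)


@dataclass(frozen=True)
class ColocalityParams:
    """Ball radii (mm) and the geometry used to convert them to pixels."""

    r1_mm: float = 5.0
    r2_mm: float = 2.0
    geometry: ScreenGeometry = STUDY_GEOMETRY

    def __post_init__(self) -> None:
        if self.r1_mm <= 0 or self.r2_mm <= 0:
            raise ValueError("ball radii must be positive")

    @property
    def r1_px(self) -> float:
        return self.geometry.mm_to_px(self.r1_mm)

    @property
    def r2_px(self) -> float:
        return self.geometry.mm_to_px(self.r2_mm)


@dataclass(frozen=True)
class DirectionResult:
    """Both direction indices for one gaze/target pair."""

    delta_theta_sample: float
    delta_theta_regr: float
    n_segments: int


def _round_half_away(a: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, halves away from zero (lattice snap)."""
    return np.sign(a) * np.floor(np.abs(a) + 0.5)


@lru_cache(maxsize=64)
def _disk_offsets(radius_px: float) -> np.ndarray:
    """Integer offsets (k, 2) of the closed lattice ball of given radius."""
    r = int(np.floor(radius_px))
    rng = np.arange(-r, r + 1)
    gx, gy = np.meshgrid(rng, rng, indexing="ij")
    mask = gx * gx + gy * gy <= radius_px * radius_px
    return np.column_stack([gx[mask], gy[mask]])


def gauss_disk_cardinality(radius_px: float) -> int:
    """Number of integer lattice points within Euclidean distance ``radius_px``
    of a lattice point (translation-invariant, so no center argument needed)."""
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    return int(_disk_offsets(float(radius_px)).shape[0])


def disk_intersection_cardinality(
    c1: tuple[int, int], r1_px: float, c2: tuple[int, int], r2_px: float
) -> int:
    """Lattice points within ``r1_px`` of ``c1`` and within ``r2_px`` of ``c2``."""
    if r1_px < 0 or r2_px < 0:
        raise ValueError("radii must be >= 0")
    # enumerate the smaller ball, test against the other center
    if r2_px > r1_px:
        c1, r1_px, c2, r2_px = c2, r2_px, c1, r1_px
    pts = _disk_offsets(float(r2_px)) + np.asarray(c2, dtype=float)
    d2 = np.sum((pts - np.asarray(c1, dtype=float)) ** 2, axis=1)
    return int(np.count_nonzero(d2 <= r1_px * r1_px))


def colocality(
    target: Trajectory,
    gaze: Trajectory,
    params: ColocalityParams | None = None,
    chunk: int = 256,
) -> float:
    """Spatiotemporal colocality of a gaze trajectory against its target.

    Positions are snapped to the pixel lattice (round half away from zero)
    before the balls are built; the radii stay real-valued.  Balls are not
    clipped at the screen edges, so the per-frame gaze-ball cardinality in
    the denominator is center-independent.
    """
    if params is None:
        params = ColocalityParams()
    if len(target) != len(gaze):
        raise ValueError(
            f"trajectory length mismatch: target {len(target)} vs gaze {len(gaze)}"
        )
    if len(target) < 1:
        raise ValueError("empty trajectories")
    o = _round_half_away(target.positions)
    g = _round_half_away(gaze.positions)
    r1, r2 = params.r1_px, params.r2_px
    off = _disk_offsets(float(r2))  # (K, 2)
    k = off.shape[0]
    num = 0
    r1sq = r1 * r1
    for lo in range(0, len(target), chunk):
        hi = min(lo + chunk, len(target))
        # (n, K, 2): gaze-ball lattice points relative to the target center
        rel = g[lo:hi, None, :] + off[None, :, :] - o[lo:hi, None, :]
        num += int(np.count_nonzero(np.sum(rel * rel, axis=2) <= r1sq))
    return num / (len(target) * k)


def step_angles(traj: Trajectory, atol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Per-step motion angles and a validity mask.

    Returns ``(theta, valid)`` with N-1 entries: theta(t) = arctan2(dy, dx)
    in (-pi, pi]; ``valid`` is False for steps with (numerically) zero
    displacement, whose angle is undefined.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 samples")
    d = traj.displacements()
    valid = np.hypot(d[:, 0], d[:, 1]) > atol
    theta = np.arctan2(d[:, 1], d[:, 0])
    return theta, valid


def sample_direction_index(target: Trajectory, gaze: Trajectory) -> float:
    """Per-step circular direction difference, 1 - |mean resultant|.

    Only steps where *both* trajectories have nonzero displacement enter the
    mean: a stopped target has no defined direction (arctan2(0, 0)), so stop
    phases are excluded.  The result is real in [0, 2]; 0 means perfectly
    coherent step directions (any constant angular offset included), values
    near 1 mean uniform scatter.  Not a metric: it is invariant under adding
    a constant angle to one trajectory.
    """
    if len(target) != len(gaze):
        raise ValueError("trajectory length mismatch")
    th_o, ok_o = step_angles(target)
    th_g, ok_g = step_angles(gaze)
    both = ok_o & ok_g
    m = int(np.count_nonzero(both))
    if m == 0:
        raise ValueError("no steps where both trajectories move")
    resultant = np.mean(np.exp(1j * (th_o[both] - th_g[both])))
    return float(1.0 - np.abs(resultant))


def _tls_orientation(points: np.ndarray) -> float:
    """Orientation (mod pi) of the total-least-squares line through points.

    Returns the principal-axis angle in [0, pi); raises if all points are
    coincident (no orientation).
    """
    centered = points - points.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("all points coincident")
    # principal axis of the 2x2 scatter matrix
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    vx, vy = vt[0]
    return float(np.arctan2(vy, vx) % np.pi)


def _acute_orientation_diff(a: float, b: float) -> float:
    """Acute difference of two line orientations, folded to [0, pi/2]."""
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)


def regression_direction_index(
    target: Trajectory,
    gaze: Trajectory,
    segments: list[tuple[int, int]] | None = None,
) -> tuple[float, int]:
    """Segment-wise regression-line direction difference.

    For each straight target segment (between consecutive bounces and stage
    events) a total-least-squares line is fitted to the gaze points; the
    acute orientation difference (mod pi, folded to [0, pi/2]) to the target
    segment's orientation is averaged across segments.  TLS is used because
    an ordinary y-on-x regression is undefined for vertical target segments;
    a fitted line has an orientation but no direction, hence the folding.

    Returns ``(mean_difference_rad, n_segments_used)``.  Segments with fewer
    than 3 gaze samples or with all gaze points coincident are skipped with
    a warning; zero usable segments is an error.
    """
    if len(target) != len(gaze):
        raise ValueError("trajectory length mismatch")
    if segments is None:
        segments = straight_segments(target)
    diffs = []
    for i0, i1 in segments:
        if i1 - i0 + 1 < 3:
            continue
        tgt_pts = target.positions[i0 : i1 + 1]
        gaze_pts = gaze.positions[i0 : i1 + 1]
        tgt_vec = tgt_pts[-1] - tgt_pts[0]
        theta_t = float(np.arctan2(tgt_vec[1], tgt_vec[0]) % np.pi)
        try:
            theta_g = _tls_orientation(gaze_pts)
        except ValueError:
            warnings.warn(
                f"segment ({i0}, {i1}): gaze points coincident, skipped",
                stacklevel=2,
            )
            continue
        diffs.append(_acute_orientation_diff(theta_t, theta_g))
    if not diffs:
        raise ValueError("no usable straight segments")
    return float(np.mean(diffs)), len(diffs)


def direction_indices(
    target: Trajectory,
    gaze: Trajectory,
    segments: list[tuple[int, int]] | None = None,
) -> DirectionResult:
    """Convenience wrapper computing both direction indices."""
    dts = sample_direction_index(target, gaze)
    dtr, nseg = regression_direction_index(target, gaze, segments=segments)
    return DirectionResult(
        delta_theta_sample=dts, delta_theta_regr=dtr, n_segments=nseg
    )


def shoelace_area(vertices: np.ndarray) -> tuple[float, float]:
    """Signed and absolute polygon area by the Shoelace formula.

    ``A = 1/2 * sum_i (x_i * y_{i+1} - y_i * x_{i+1})`` with wraparound.  The
    sign follows vertex orientation; for self-intersecting polygons the
    signed contributions of opposite-orientation loops cancel.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("need at least 3 vertices of shape (n, 2)")
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * float(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1)))
    return signed, abs(signed)


def polygon_area_index(traj: Trajectory, window_n: int) -> float:
    """Mean absolute Shoelace area over non-overlapping windows (px^2).

    The trajectory is partitioned into floor(N / window_n) consecutive
    windows of ``window_n`` samples (a trailing partial window is dropped);
    each window's points are taken as polygon vertices in temporal order,
    closing last-to-first.  A perfectly straight trajectory yields 0.
    """
    if window_n < 3:
        raise ValueError("window_n must be >= 3")
    n = len(traj)
    if n < window_n:
        raise ValueError(f"trajectory has {n} samples < window_n={window_n}")
    k = n // window_n
    areas = [
        shoelace_area(traj.positions[i * window_n : (i + 1) * window_n])[1]
        for i in range(k)
    ]
    return float(np.mean(areas))


def normalize_area_cohort(values) -> np.ndarray:
    """Divide per-subject mean areas by the cohort-wide maximum.

    A monotone rescaling into [0, 1] (normalized units); the cohort maximum
    maps to exactly 1.  All-zero cohorts have no scale and are an error.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("empty cohort")
    if np.any(v < 0):
        raise ValueError("areas must be >= 0")
    vmax = v.max()
    if vmax == 0:
        raise ValueError("all-zero cohort cannot be normalized")
    return v / vmax
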