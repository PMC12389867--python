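"""Trajectory and raw-recording data model, resampling and CSV I/O.

A :class:`Trajectory` is an ordered sequence of (x, y) screen positions on a
uniform clock (60 Hz for the standard 14 s task, hence N = 840 samples); the
same representation is shared by the stimulus target and the recorded gaze.
Raw eye-tracker output arrives as irregularly spaced timestamped samples
(:class:`GazeRecording`, effectively ~20 Hz for the low-cost tracker used in
the study setting) and is brought onto the uniform clock by strictly linear
interpolation -- no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = [
    "Trajectory",
    "GazeRecording",
    "resample_to_uniform",
    "load_gaze_csv",
    "save_gaze_csv",
]


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled 2-D path in pixel coordinates.

    ``positions`` is an (N, 2) float array; positions may lie outside the
    screen rectangle (raw gaze can wander off-screen) unless explicitly
    clamped with :meth:`clamp`.
    """

    positions: np.ndarray
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError(f"positions must have shape (N, 2), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, t=0 at the first sample."""
        return np.arange(len(self)) / self.rate_hz

    def displacements(self) -> np.ndarray:
        """(N-1, 2) per-step displacement vectors."""
        return np.diff(self.positions, axis=0)

    def clamp(self, geometry: ScreenGeometry) -> "Trajectory":
        """Clip positions to the screen rectangle [0, W-1] x [0, H-1]."""
        pos = self.positions.copy()
        pos[:, 0] = np.clip(pos[:, 0], 0, geometry.width_px - 1)
        pos[:, 1] = np.clip(pos[:, 1], 0, geometry.height_px - 1)
        return Trajectory(pos, self.rate_hz)


@dataclass(frozen=True)
class GazeRecording:
    """Raw, irregularly timestamped gaze samples.

    Timestamps must be strictly increasing; at least two samples are needed
    before resampling is meaningful.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a recording needs at least 2 samples")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"timestamps must be strictly increasing; first violation at "
                f"row {bad[0] + 1} (t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def empirical_rate_hz(self) -> float:
        """Median sampling rate of the raw stream (no nominal-rate assumption)."""
        return float(1.0 / np.median(np.diff(self.t)))


def resample_to_uniform(
    rec: GazeRecording, rate_hz: float = 60.0, duration_s: float = 14.0
) -> Trajectory:
    """Resample a raw recording to a uniform clock by linear interpolation.

    The time origin is the first raw sample.  The output has
    ``round(rate_hz * duration_s)`` samples at times k/rate_hz; each output
    position is the linear interpolation of the two bracketing raw samples,
    so output at a raw timestamp reproduces that raw sample exactly.
    """
    n = int(round(rate_hz * duration_s))
    if n < 1:
        raise ValueError("requested window is empty")
    grid = np.arange(n) / rate_hz
    t0 = rec.t[0]
    rel = rec.t - t0
    if grid[-1] > rel[-1] + 1e-12:
        raise ValueError(
            f"recording covers [0, {rel[-1]:.6f}] s after origin shift but "
            f"interval ({rel[-1]:.6f}, {grid[-1]:.6f}] s is requested and uncovered"
        )
    xi = np.interp(grid, rel, rec.x)
    yi = np.interp(grid, rel, rec.y)
    return Trajectory(np.column_stack([xi, yi]), rate_hz=rate_hz)


def load_gaze_csv(
    path,
    delimiter: str = ",",
    time_col: str = "t_s",
    x_col: str = "x_px",
    y_col: str = "y_px",
    source_id: str | None = None,
) -> GazeRecording:
    """Read a delimited gaze file with a header naming time, x and y columns."""
    df = pd.read_csv(path, sep=delimiter, comment="#", float_precision="round_trip")
    for col in (time_col, x_col, y_col):
        if col not in df.columns:
            raise ValueError(
                f"missing column {col!r} in {path} (found {list(df.columns)})"
            )
    return GazeRecording(
        t=df[time_col].to_numpy(float),
        x=df[x_col].to_numpy(float),
        y=df[y_col].to_numpy(float),
        source_id=source_id if source_id is not None else str(path),
    )


def save_gaze_csv(
    rec: GazeRecording,
    path,
    delimiter: str = ",",
    time_col: str = "t_s",
    x_col: str = "x_px",
    y_col: str = "y_px",
) -> None:
    """Write a recording; 17 significant digits so save->load round-trips exactly."""
    df = pd.DataFrame({time_col: rec.t, x_col: rec.x, y_col: rec.y})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def trajectory_to_recording(traj: Trajectory, source_id: str = "") -> GazeRecording:
    """View a uniform trajectory as a timestamped recording (for CSV export)."""
    return GazeRecording(t=traj.times, x=traj.x, y=traj.y, source_id=source_id)
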