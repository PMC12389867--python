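"""Synthetic gaze simulator with controllable pursuit fidelity.

No public recordings exist for this task, so paired target/gaze trajectories
are simulated to exercise every downstream stage.  The simulator is a
minimal pursuit model, not a physiological one:

* **pursuit** -- the gaze integrates the target velocity *delayed* by the
  oculomotor latency ``lag_ms`` and continuously closes a fraction
  ``catchup_gain`` of the remaining positional error each frame.  Latency
  therefore degrades tracking transiently after motion onsets and bounces
  (as pursuit latency does) rather than imposing a standing positional
  offset, which at 250 px/s would dwarf any plausible tracking error.
* **jitter** -- isotropic Gaussian noise added per frame.
* **attentional lapses** -- Poisson onsets at ``lapse_rate_per_s``; during a
  lapse (exponential duration, mean ``lapse_duration_s``) the gaze performs
  a random walk decoupled from the target, after which it re-acquires the
  target by exponential catch-up at ``catchup_gain`` per frame.

With an all-zero noise profile and zero lag the output is exactly the
target.  Identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import CohortTable
from .metrics import (
    DEFAULT_R1_MM,
    DEFAULT_R2_MM,
    DEFAULT_WINDOWS,
    ColocalityParams,
    colocality,
    normalize_area_cohort,
    polygon_area_index,
    regression_direction_index,
    sample_direction_index,
)
from .target import TaskConfig, generate_target_trajectory
from .trajectory import Trajectory

__all__ = [
    "GazeProfile",
    "control_profile",
    "impaired_profile",
    "simulate_gaze",
    "make_cohort",
]

_TRACK, _LAPSE = 0, 1


@dataclass(frozen=True)
class GazeProfile:
    """Tunable pursuit-fidelity parameters of one simulated subject.

    All scales are in screen pixels at 60 Hz; ``lag_ms`` is the pursuit
    latency, ``lapse_rate_per_s`` the Poisson rate of attentional lapses,
    ``lapse_duration_s`` the mean (exponential) lapse length,
    ``drift_sd_px`` the random-walk step scale during a lapse, and
    ``catchup_gain`` in (0, 1] the fraction of positional error closed per
    frame.  ``jitter_ar1`` in [0, 1) is the lag-one autocorrelation of the
    jitter: 0 is white sensor noise, values near 1 give slow gaze wander
    with the same marginal SD.
    """

    jitter_sd_px: float = 0.0
    jitter_ar1: float = 0.0
    lag_ms: float = 0.0
    lapse_rate_per_s: float = 0.0
    lapse_duration_s: float = 1.0
    drift_sd_px: float = 6.0
    catchup_gain: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("jitter_sd_px", "lag_ms", "lapse_rate_per_s",
                     "lapse_duration_s", "drift_sd_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.jitter_ar1 < 1):
            raise ValueError("jitter_ar1 must be in [0, 1)")
        if not (0 < self.catchup_gain <= 1):
            raise ValueError("catchup_gain must be in (0, 1]")


def control_profile(seed: int = 0) -> GazeProfile:
    """Default healthy-control profile: tight, low-lapse tracking.

    Calibrated (together with :func:`impaired_profile`) so that simulated
    group means of Co(5 mm, 2 mm), the per-step and the regression direction
    indices land near the reference cohort's group means; see
    docs/methods.md for the calibration targets and tolerance.
    """
    return GazeProfile(
        jitter_sd_px=4.0,
        jitter_ar1=0.0,
        lag_ms=100.0,
        lapse_rate_per_s=0.02,
        lapse_duration_s=1.0,
        drift_sd_px=6.0,
        catchup_gain=0.3,
        seed=seed,
    )


def impaired_profile(seed: int = 0) -> GazeProfile:
    """Default impaired-pursuit profile: noisy, laggy, lapse-prone tracking.

    Relative to controls: doubled pursuit latency, slower error correction,
    larger and temporally correlated gaze wander, and an order of magnitude
    more attentional lapses.
    """
    return GazeProfile(
        jitter_sd_px=8.0,
        jitter_ar1=0.7,
        lag_ms=200.0,
        lapse_rate_per_s=0.25,
        lapse_duration_s=0.9,
        drift_sd_px=6.0,
        catchup_gain=0.2,
        seed=seed,
    )


def simulate_gaze(
    target: Trajectory, profile: GazeProfile, seed: int | None = None
) -> Trajectory:
    """Simulate one gaze trajectory paired to ``target``.

    ``seed`` overrides ``profile.seed`` when given.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    rate = target.rate_hz
    dt = 1.0 / rate
    n = len(target)
    tgt = target.positions
    lag_n = int(round(profile.lag_ms / 1000.0 * rate))
    # delayed position reference: target as seen through the latency
    idx = np.clip(np.arange(n) - lag_n, 0, n - 1)
    des = tgt[idx]

    if profile.jitter_sd_px > 0:
        w = rng.normal(0.0, profile.jitter_sd_px, size=(n, 2))
        rho = profile.jitter_ar1
        if rho > 0:
            jitter = np.empty((n, 2))
            jitter[0] = w[0]
            c = np.sqrt(1.0 - rho * rho)
            for t in range(1, n):
                jitter[t] = rho * jitter[t - 1] + c * w[t]
        else:
            jitter = w
    else:
        jitter = np.zeros((n, 2))
    p_onset = profile.lapse_rate_per_s * dt

    pos = np.empty((n, 2))
    pos[0] = des[0]
    state = _TRACK
    lapse_left = 0
    for t in range(1, n):
        if state == _LAPSE:
            step = lapse_bias + rng.normal(0.0, 0.5 * profile.drift_sd_px, size=2)
            pos[t] = pos[t - 1] + step
            lapse_left -= 1
            if lapse_left <= 0:
                state = _TRACK
            continue
        # delayed velocity command plus closed-loop correction toward the
        # *current* target position: latency shows up as a transient after
        # velocity changes, not as a standing offset, and the same
        # proportional term performs the exponential post-lapse catch-up
        # (a catchup_gain fraction of the positional error closed per frame)
        vel = des[t] - des[t - 1]
        err = tgt[t - 1] - pos[t - 1]
        pos[t] = pos[t - 1] + vel + profile.catchup_gain * err
        # lapse onsets are gated to target motion: pursuit is what loads
        # attention, and a lapse while parked on a static target is invisible
        # to every index anyway
        target_moving = bool(np.any(tgt[t] != tgt[t - 1]))
        if p_onset > 0 and target_moving and rng.random() < p_onset:
            # a lapse is a drifting excursion: the gaze decouples from the
            # target and wanders off along a random direction at drift_sd_px
            # per frame (plus half-scale walk noise) until the lapse ends
            state = _LAPSE
            ang = rng.uniform(0.0, 2.0 * np.pi)
            lapse_bias = profile.drift_sd_px * np.array([np.cos(ang), np.sin(ang)])
            lapse_left = max(
                1, int(round(rng.exponential(profile.lapse_duration_s) * rate))
            )
    # jitter is oculomotor tremor plus tracker measurement noise: it rides on
    # the recorded trace, it does not feed back into the pursuit loop
    return Trajectory(pos + jitter, rate_hz=rate)


def _subject_measures(
    target_traj,
    gaze: Trajectory,
    colocality_pairs,
    windows,
    geometry,
) -> dict[str, float]:
    tgt = target_traj.trajectory
    segs = target_traj.segments()
    out: dict[str, float] = {}
    for r1, r2 in colocality_pairs:
        params = ColocalityParams(r1_mm=r1, r2_mm=r2, geometry=geometry)
        out[f"co_{r1:g}_{r2:g}"] = colocality(tgt, gaze, params)
    out["dtheta_sample"] = sample_direction_index(tgt, gaze)
    out["dtheta_regr"] = regression_direction_index(tgt, gaze, segments=segs)[0]
    for w in windows:
        ms = int(round(w / tgt.rate_hz * 1000))
        out[f"area_{ms}"] = polygon_area_index(gaze, w)
    return out


def make_cohort(
    n_per_group: int,
    control: GazeProfile | None = None,
    impaired: GazeProfile | None = None,
    seed: int = 0,
    target_seeds: list[int] | None = None,
    task: TaskConfig | None = None,
    colocality_pairs: list[tuple[float, float]] | None = None,
    windows: list[int] | None = None,
) -> CohortTable:
    """Simulate a two-group cohort and compute every index for each subject.

    One independent target realization per subject (per-session stimulus
    randomness).  Per-subject simulation seeds derive from ``seed`` via a
    seed sequence, so the whole cohort is reproducible from one integer.
    Polygon areas are cohort-normalized per window (normalized units), as in
    the reference cohort table.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    control = control if control is not None else control_profile()
    impaired = impaired if impaired is not None else impaired_profile()
    task = task if task is not None else TaskConfig()
    if colocality_pairs is None:
        colocality_pairs = [(r1, r2) for r1 in DEFAULT_R1_MM for r2 in DEFAULT_R2_MM]
    if windows is None:
        windows = list(DEFAULT_WINDOWS)

    ss = np.random.SeedSequence(seed)
    n_total = 2 * n_per_group
    sim_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_total)]
    if target_seeds is None:
        tgt_ss = np.random.SeedSequence(seed + 1)
        target_seeds = [
            int(s.generate_state(1)[0] % (2**31)) for s in tgt_ss.spawn(n_total)
        ]
    elif len(target_seeds) < n_total:
        raise ValueError(f"need {n_total} target seeds, got {len(target_seeds)}")

    rows = []
    subjects = [("SZ", impaired, i) for i in range(n_per_group)] + [
        ("CNT", control, i) for i in range(n_per_group)
    ]
    for j, (group, profile, i) in enumerate(subjects):
        tt = generate_target_trajectory(replace(task, seed=target_seeds[j]))
        gaze = simulate_gaze(tt.trajectory, profile, seed=sim_seeds[j])
        meas = _subject_measures(
            tt, gaze, colocality_pairs, windows, task.geometry
        )
        for k, v in meas.items():
            rows.append((f"{group}_{i + 1}", group, k, v))

    import pandas as pd

    df = pd.DataFrame(rows, columns=["subject", "group", "measure", "value"])
    # polygon areas -> normalized units, cohort-wide per window
    for w in windows:
        ms = int(round(w / task.rate_hz * 1000))
        key = f"area_{ms}"
        mask = df["measure"] == key
        vals = df.loc[mask, "value"].to_numpy()
        if vals.max() > 0:
            df.loc[mask, "value"] = normalize_area_cohort(vals)
    return CohortTable(df)
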