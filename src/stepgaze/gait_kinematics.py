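"""Gait events and obstacle-crossing metrics from foot-marker trajectories.

Conventions: trajectories are 5th-metatarsal marker positions sampled near
100 Hz in a frame whose x axis points from the start position toward the
obstacle, z is vertical, the origin is the starting foot position, and t=0 is
cue onset.  Units are cm and ms.

* Step onset: first sample whose forward or upward deviation from the
  position at cue onset reaches 0.5 cm.
* Timing validity: onset must fall after the Gabor offset (377.8 ms) and at
  or before 1000 ms.
* Crossing metrics: foot clearance is the vertical gap between the marker and
  the obstacle's top edge at the instant the marker passes the obstacle plane
  (linear interpolation in x); horizontal distance is measured from the
  stance preceding the crossing to the obstacle.
* Foot placement: planar distance between the midstance foot position and the
  Gabor-patch center.  Stance phases are detected as maximal contiguous
  intervals of planar speed < 2 cm/s whose height stays within 1 cm of the
  interval minimum; midstance is the temporal midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ONSET_DEVIATION_CM = 0.5
FAST_BOUND_MS = 377.8   # Gabor offset; onsets at or before this are too fast
SLOW_BOUND_MS = 1000.0
OBSTACLE_HEIGHT_CM = 5.0

STATUS_VALID = "valid"
STATUS_TOO_FAST = "too_fast"
STATUS_TOO_SLOW = "too_slow"
STATUS_NO_ONSET = "no_onset"

STANCE_SPEED_CM_S = 2.0
STANCE_Z_BAND_CM = 1.0


class TrajectoryError(ValueError):
    pass


@dataclass
class FootTrajectory:
    trial_id: int
    limb: str                 # "lead" or "trail"
    side: str                 # "left" or "right"
    t_ms: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    z_cm: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        self.z_cm = np.asarray(self.z_cm, dtype=float)
        if np.any(np.diff(self.t_ms) <= 0):
            raise TrajectoryError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class TimingVerdict:
    status: str

    @property
    def valid(self) -> bool:
        return self.status == STATUS_VALID


@dataclass(frozen=True)
class GaitMetrics:
    trial_id: int
    step_onset_ms: float | None
    timing: TimingVerdict
    lead_horizontal_distance: float | None = None
    trail_horizontal_distance: float | None = None
    lead_clearance: float | None = None
    trail_clearance: float | None = None
    foot_placement_step1: float | None = None
    foot_placement_step2: float | None = None
    contact: bool = False


def detect_step_onset(traj: FootTrajectory, cue_time: float = 0.0,
                      threshold_cm: float = ONSET_DEVIATION_CM) -> float | None:
    """Earliest sample with forward or upward deviation >= 0.5 cm from cue.

    Returns the sample time in ms, or ``None`` when the deviation threshold is
    never reached (e.g. stationary trials).
    """
    if traj.t_ms[0] > cue_time:
        raise TrajectoryError(
            f"trajectory starts at {traj.t_ms[0]} ms, after cue {cue_time} ms")
    i0 = int(np.searchsorted(traj.t_ms, cue_time))
    dx = traj.x_cm[i0:] - traj.x_cm[i0]
    dz = traj.z_cm[i0:] - traj.z_cm[i0]
    hits = np.nonzero((dx >= threshold_cm) | (dz >= threshold_cm))[0]
    if hits.size == 0:
        return None
    return float(traj.t_ms[i0 + hits[0]])


def classify_trial_timing(onset_ms: float | None,
                          fast_bound: float = FAST_BOUND_MS,
                          slow_bound: float = SLOW_BOUND_MS) -> TimingVerdict:
    """Validity window for step onset: fast_bound < onset <= slow_bound."""
    if onset_ms is None:
        return TimingVerdict(STATUS_NO_ONSET)
    if onset_ms <= fast_bound:
        return TimingVerdict(STATUS_TOO_FAST)
    if onset_ms > slow_bound:
        return TimingVerdict(STATUS_TOO_SLOW)
    return TimingVerdict(STATUS_VALID)


def find_stance_intervals(traj: FootTrajectory,
                          speed_thresh: float = STANCE_SPEED_CM_S,
                          z_band: float = STANCE_Z_BAND_CM,
                          min_samples: int = 3) -> list[tuple[int, int]]:
    """Maximal low-speed, low-height runs of samples (index ranges, inclusive)."""
    dt_s = np.diff(traj.t_ms) / 1000.0
    speed = np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm)) / dt_s
    slow = np.concatenate([[True], speed < speed_thresh])  # sample-aligned
    intervals: list[tuple[int, int]] = []
    i = 0
    n = len(slow)
    while i < n:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and slow[j + 1]:
            j += 1
        z = traj.z_cm[i:j + 1]
        keep = np.nonzero(z - z.min() <= z_band)[0]
        if keep.size >= min_samples:
            intervals.append((i + int(keep[0]), i + int(keep[-1])))
        i = j + 1
    return intervals


def midstance_position(traj: FootTrajectory,
                       interval: tuple[int, int]) -> tuple[float, float, float]:
    """(t, x, y) at the temporal midpoint of a stance interval."""
    mid = (interval[0] + interval[1]) // 2
    return float(traj.t_ms[mid]), float(traj.x_cm[mid]), float(traj.y_cm[mid])


def _crossing(traj: FootTrajectory, obstacle_x: float) -> tuple[int, float]:
    """Index of first sample beyond the obstacle plane and interpolated z there."""
    beyond = np.nonzero(traj.x_cm > obstacle_x)[0]
    if beyond.size == 0 or beyond[0] == 0:
        raise TrajectoryError(
            f"trial {traj.trial_id} {traj.limb}: trajectory never crosses "
            f"the obstacle plane x={obstacle_x}")
    i = int(beyond[0])
    x0, x1 = traj.x_cm[i - 1], traj.x_cm[i]
    w = (obstacle_x - x0) / (x1 - x0)
    z = traj.z_cm[i - 1] + w * (traj.z_cm[i] - traj.z_cm[i - 1])
    return i, float(z)


def _pre_crossing_stance(traj: FootTrajectory, crossing_idx: int) -> tuple[int, int]:
    stances = [s for s in find_stance_intervals(traj) if s[1] < crossing_idx]
    if not stances:
        raise TrajectoryError(
            f"trial {traj.trial_id} {traj.limb}: no stance before crossing")
    return stances[-1]


def compute_crossing_metrics(lead: FootTrajectory, trail: FootTrajectory,
                             obstacle_x: float,
                             obstacle_height: float = OBSTACLE_HEIGHT_CM) -> dict:
    """Lead/trail horizontal distances and clearances for one crossing trial.

    Clearance is marker height above the obstacle's top edge at the plane
    crossing; a negative clearance means the foot was below the top edge,
    i.e. obstacle contact, and is flagged rather than clipped.
    """
    out: dict[str, float | bool] = {"contact": False}
    for traj, name in ((lead, "lead"), (trail, "trail")):
        idx, z_at_cross = _crossing(traj, obstacle_x)
        clearance = z_at_cross - obstacle_height
        stance = _pre_crossing_stance(traj, idx)
        _, x_mid, _ = midstance_position(traj, stance)
        out[f"{name}_horizontal_distance"] = obstacle_x - x_mid
        out[f"{name}_clearance"] = clearance
        if clearance < 0:
            out["contact"] = True
    return out


def compute_foot_placement(traj: FootTrajectory,
                           gabor_xy: tuple[float, float]) -> float:
    """Planar distance between the midstance foot position and the Gabor center.

    When several stance phases exist the one whose midstance lies closest to
    the Gabor location is used (stances are separated by full swing phases,
    so the choice is unambiguous on real and simulated walks).
    """
    stances = find_stance_intervals(traj)
    if not stances:
        raise TrajectoryError(f"trial {traj.trial_id}: no stance detected")
    best = None
    for s in stances:
        _, x, y = midstance_position(traj, s)
        d = float(np.hypot(x - gabor_xy[0], y - gabor_xy[1]))
        if best is None or d < best:
            best = d
    return best


def trial_gait_metrics(lead: FootTrajectory, trail: FootTrajectory | None,
                       obstacle_x: float,
                       step1_xy: tuple[float, float] | None = None,
                       step2_xy: tuple[float, float] | None = None,
                       obstacle_height: float = OBSTACLE_HEIGHT_CM) -> GaitMetrics:
    """Full per-trial kinematic summary: onset, validity, crossing metrics."""
    onset = detect_step_onset(lead)
    timing = classify_trial_timing(onset)
    if timing.status == STATUS_NO_ONSET or trail is None:
        return GaitMetrics(trial_id=lead.trial_id, step_onset_ms=onset, timing=timing)
    kwargs: dict = {}
    try:
        kwargs.update(compute_crossing_metrics(lead, trail, obstacle_x,
                                               obstacle_height))
    except TrajectoryError:
        pass  # e.g. too-fast aborted trials may not cross; metrics stay None
    if step1_xy is not None:
        kwargs["foot_placement_step1"] = compute_foot_placement(lead, step1_xy)
    if step2_xy is not None:
        kwargs["foot_placement_step2"] = compute_foot_placement(trail, step2_xy)
    return GaitMetrics(trial_id=lead.trial_id, step_onset_ms=onset, timing=timing,
                       **kwargs)


def metrics_frame(metrics) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append({"trial_id": m.trial_id, "step_onset_ms": m.step_onset_ms,
                     "timing": m.timing.status,
                     "lead_horizontal_distance": m.lead_horizontal_distance,
                     "trail_horizontal_distance": m.trail_horizontal_distance,
                     "lead_clearance": m.lead_clearance,
                     "trail_clearance": m.trail_clearance,
                     "foot_placement_step1": m.foot_placement_step1,
                     "foot_placement_step2": m.foot_placement_step2,
                     "contact": m.contact})
    return pd.DataFrame(rows)
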