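"""Trajectory containers, velocity profiles, segmentation and trial metrics.

A trial is a uniformly sampled (nominally 110 Hz) 2-D position time series.
The tangential speed is the magnitude of the central-difference derivative
of position, Gaussian-smoothed with sigma = 2 samples.  The profile is cut
into the 8 submovement segments of the reach sequence by the 2-cm proximity
rule: segment k ends at the first sample within 2 cm of the k-th sequence
waypoint.  Per-segment peak speeds (vmax), per-transition minimum speeds
(vmin), movement time (start-box exit to final-target entry) and reaction
time are the trial-level kinematic measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DataError, IncompleteTrialError
from .geometry import TaskGeometry

#: Start-box exit threshold (cm): distance from the trial's start position
#: that defines both reaction-time end and movement-time start.
START_EXIT_RADIUS = 2.0


@dataclass
class Trajectory:
    """One trial's uniformly sampled 2-D positions (cm) with timestamps (s)."""

    sample_times: np.ndarray
    positions: np.ndarray  # (n, 2)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sample_times.ndim != 1 or len(self.sample_times) < 2:
            raise DataError("a trajectory needs at least 2 samples")
        if self.positions.shape != (len(self.sample_times), 2):
            raise DataError("positions must be (n_samples, 2)")
        if np.any(np.diff(self.sample_times) <= 0):
            raise DataError("sample times must be strictly increasing")
        if not (np.all(np.isfinite(self.sample_times)) and np.all(np.isfinite(self.positions))):
            raise DataError("non-finite coordinates in trajectory")

    def __len__(self) -> int:
        return len(self.sample_times)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.sample_times)))


@dataclass
class VelocityProfile:
    """Tangential speed (cm/s) aligned with the source trajectory."""

    sample_times: np.ndarray
    speed: np.ndarray
    smoothing_sd_samples: float

    def __len__(self) -> int:
        return len(self.speed)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.sample_times)))


@dataclass
class SegmentedTrial:
    """Index ranges of the 8 submovements and 7 transition windows."""

    segments: list[tuple[int, int]]       # inclusive (start, end) sample indices
    transitions: list[tuple[int, int]]    # inclusive windows around each via transition
    waypoint_labels: tuple[str, ...]

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass
class TrialMetrics:
    movement_time: float
    reaction_time: float
    vmax_per_segment: np.ndarray   # 8 values, cm/s
    vmin_per_transition: np.ndarray  # 7 values, cm/s
    corrected: bool = False

    @property
    def vmax_mean(self) -> float:
        return float(np.mean(self.vmax_per_segment))

    @property
    def vmin_mean(self) -> float:
        return float(np.mean(self.vmin_per_transition))


def compute_velocity(trajectory: Trajectory, smoothing_sd_samples: float = 2.0) -> VelocityProfile:
    """Tangential speed by central differences, Gaussian-smoothed.

    ``smoothing_sd_samples`` is the kernel sigma in *samples* (2 by
    default), the convention of fixed-rate motion-capture pipelines; the
    kernel is truncated at 4 sigma with reflected boundaries.  Speed of a
    constant-velocity trajectory is invariant under this smoothing.
    """
    if len(trajectory) < 3:
        raise DataError("velocity computation needs at least 3 samples")
    t, xy = trajectory.sample_times, trajectory.positions
    vel = np.gradient(xy, t, axis=0)  # central differences, one-sided at ends
    speed = np.linalg.norm(vel, axis=1)
    if smoothing_sd_samples > 0:
        speed = gaussian_filter1d(speed, smoothing_sd_samples, mode="reflect", truncate=4.0)
    return VelocityProfile(t, np.maximum(speed, 0.0), smoothing_sd_samples)


def segment_trial(
    profile: VelocityProfile, trajectory: Trajectory, geometry: TaskGeometry
) -> SegmentedTrial:
    """Cut a trial into 8 segments and 7 transition windows.

    Segment k ends at the first sample strictly within the proximity
    radius of the k-th sequence waypoint occurring after segment k-1's
    end; segment k+1 starts at the next sample.  Transition window k is
    the maximal contiguous run of samples within the proximity radius of
    intermediate waypoint k that contains that boundary sample.

    Raises
    ------
    IncompleteTrialError
        Naming the first waypoint never approached within the radius.
    """
    xy = trajectory.positions
    seq = geometry.reach_sequence
    prox = geometry.proximity_radius
    n = len(xy)

    boundaries: list[int] = []
    search_from = 0
    for k, label in enumerate(seq[1:], start=1):
        wp = geometry.waypoint(label)
        d = np.linalg.norm(xy[search_from:] - wp, axis=1)
        hits = np.nonzero(d < prox)[0]
        if len(hits) == 0:
            raise IncompleteTrialError(label, f"waypoint {k} ({label!r}) never approached within {prox} cm")
        end = search_from + int(hits[0])
        boundaries.append(end)
        search_from = end + 1
        if search_from >= n and k < len(seq) - 1:
            raise IncompleteTrialError(seq[k + 1])

    segments = []
    start = 0
    for end in boundaries:
        segments.append((start, end))
        start = min(end + 1, n - 1)

    transitions = []
    for k, end in enumerate(boundaries[:-1], start=1):
        wp = geometry.waypoint(seq[k])
        inside = np.linalg.norm(xy - wp, axis=1) < prox
        lo = end
        while lo > 0 and inside[lo - 1]:
            lo -= 1
        hi = end
        while hi < n - 1 and inside[hi + 1]:
            hi += 1
        transitions.append((lo, hi))

    return SegmentedTrial(segments, transitions, seq)


def trial_metrics(
    segmented: SegmentedTrial,
    profile: VelocityProfile,
    trajectory: Trajectory,
    geometry: TaskGeometry | None = None,
    corrected: bool | None = None,
) -> TrialMetrics:
    """Extract vmax/vmin, movement time and reaction time from one trial.

    The movement clock starts at start-box exit — the first sample farther
    than 2 cm from the trial's start position (the same threshold the task
    uses to end the reaction-time window) — and stops at the end of the
    final segment (first entry of the last waypoint's proximity region).
    """
    t = profile.sample_times
    v = profile.speed
    vmax = np.array([float(np.max(v[a : b + 1])) for a, b in segmented.segments])
    vmin = []
    for a, b in segmented.transitions:
        if b < a:
            raise DataError("empty transition window")
        vmin.append(float(np.min(v[a : b + 1])))
    vmin = np.array(vmin)

    start_pos = trajectory.positions[0]
    away = np.nonzero(np.linalg.norm(trajectory.positions - start_pos, axis=1) > START_EXIT_RADIUS)[0]
    if len(away) == 0:
        raise DataError("trajectory never left the start box")
    exit_idx = int(away[0])
    final_idx = segmented.segments[-1][1]
    if final_idx <= exit_idx:
        raise DataError("final-target entry precedes start-box exit")

    if corrected is None:
        corrected = detect_corrected(segmented, trajectory, geometry) if geometry is not None else False

    return TrialMetrics(
        movement_time=float(t[final_idx] - t[exit_idx]),
        reaction_time=float(t[exit_idx] - t[0]),
        vmax_per_segment=vmax,
        vmin_per_transition=vmin,
        corrected=bool(corrected),
    )


def movement_window(trajectory: Trajectory, threshold_cm: float = 0.5) -> tuple[int, int]:
    """Inclusive sample range of the moving portion of a trial.

    Trims the stationary pre-cue hold and terminal settling: the window
    runs from one sample before the position first leaves ``threshold_cm``
    of the start position to one sample after it last sits farther than
    ``threshold_cm`` from the final position.  Used to crop profiles for
    smoothness scoring, which compares movement shapes, not holds.
    """
    xy = trajectory.positions
    away_start = np.linalg.norm(xy - xy[0], axis=1) > threshold_cm
    away_end = np.linalg.norm(xy - xy[-1], axis=1) > threshold_cm
    moving = np.nonzero(away_start | away_end)[0]
    if len(moving) == 0:
        raise DataError("trajectory never moves; no movement window")
    onset = np.nonzero(away_start)[0]
    offset = np.nonzero(away_end)[0]
    i0 = int(onset[0]) - 1 if len(onset) else 0
    i1 = int(offset[-1]) + 1 if len(offset) else len(xy) - 1
    return max(i0, 0), min(i1, len(xy) - 1)


def detect_corrected(
    segmented: SegmentedTrial | None,
    trajectory: Trajectory,
    geometry: TaskGeometry,
    miss_margin: float = 0.2,
    approach_window: float = 4.0,
) -> bool:
    """Flag trials containing a corrective submovement.

    A trial is corrected when some waypoint is first passed at a distance
    greater than the proximity radius (a miss: a local minimum of the
    distance series below ``approach_window`` but above the radius, at the
    end of a directed approach) and is subsequently re-acquired within the
    target radius after the heading reverses.  The scan walks the reach
    sequence directly from positions, so it works on trials whose
    segmentation failed.
    """
    xy = trajectory.positions
    seq = geometry.reach_sequence
    prox = geometry.proximity_radius
    n = len(xy)
    all_wp = np.vstack([geometry.via_center, geometry.target_centers])

    idx = 0
    for label in seq[1:]:
        wp = geometry.waypoint(label)
        other_wp = all_wp[np.linalg.norm(all_wp - wp, axis=1) > 1e-9]
        d = np.linalg.norm(xy[idx:] - wp, axis=1)
        hits = np.nonzero(d < prox)[0]
        if len(hits) == 0:
            return True  # degenerate: waypoint never reached at all
        first_in = int(hits[0])

        # local minima of the approach distance before the proximity entry
        seg = d[: first_in + 1]
        if len(seg) > 2:
            interior = np.nonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:]))[0] + 1
            for m in interior:
                if prox + miss_margin < seg[m] < approach_window:
                    # a genuine missed pass happens in open space; noise
                    # wiggles while hovering at a neighbouring target or
                    # via region are not passes of this waypoint
                    d_others = np.linalg.norm(other_wp - xy[idx + m], axis=1)
                    if np.any(d_others < 1.25 * prox):
                        continue
                    rel = np.nonzero(d[m:] < geometry.target_radius)[0]
                    if len(rel) == 0:
                        continue
                    reentry = m + int(rel[0])
                    w = 3
                    before = xy[idx + m] - xy[max(idx, idx + m - w)]
                    # heading of the corrective approach just before re-entry
                    after = xy[min(n - 1, idx + reentry)] - xy[max(idx + m, idx + reentry - w)]
                    if float(before @ after) < 0.0:
                        return True
        idx = min(idx + first_in + 1, n - 1)
    return False
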