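"""Synthetic trial and dataset generator for the sequential reaching task.

Trials are built from minimum-jerk primitives so that every downstream
stage (segmentation, fusion metrics, smoothness scoring, reward replay,
bootstrap inference) can be exercised against known ground truth:

* fusion level 0: each of the 8 reaches is an independent rest-to-rest
  minimum-jerk movement, separated by a dwell of zero velocity at every
  transition target;
* fusion level 1: the whole sequence is one minimum-jerk via-point pass
  with optimized passage times and no stops;
* intermediate levels: the dwell shrinks to (1 - f) * dwell_s and the
  boundary velocity and acceleration at each transition are f times the
  fused pass's values there, realized as quintic segments with
  prescribed boundary conditions (a quintic is fully determined by its
  endpoint position, velocity and acceleration, so f = 1 reproduces the
  fused pass segment-by-segment and f = 0 gives rest-to-rest reaches).

The configured movement time refers to the *measured* definition used by
the analysis — from start-box exit (2 cm from the start position) to first
entry of the final target's proximity region — and is matched exactly by a
single time-rescaling pass, which is exact because every moving phase is
time-scalable.

Optionally, trials are "corrected": one outer target is missed laterally
(first pass outside the 2-cm proximity region) and re-acquired with a
corrective submovement after a heading reversal, emulating the
miss-and-fix trials the analysis must flag and exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import TaskGeometry
from .kinematics import Trajectory
from .minjerk import MinJerkProblem, MinJerkResult, min_jerk_via

__all__ = [
    "LearningModel",
    "FusionTrend",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_trial",
    "simulate_mt_series",
    "simulate_learning_dataset",
]


@dataclass(frozen=True)
class LearningModel:
    """Linear trial-wise trend of true movement time (seconds).

    true MT of participant i at trial x is
    ``intercept + slope * x + offset_i + eps``, with ``offset_i`` drawn
    once per participant from N(0, participant_sd) and ``eps`` from
    N(0, trial_sd) per trial, truncated below at ``floor``.
    """

    intercept: float = 5.0
    slope: float = -0.002
    participant_sd: float = 0.3
    trial_sd: float = 0.2
    floor: float = 2.0


@dataclass(frozen=True)
class FusionTrend:
    """Linear trial-wise trend of the per-transition fusion level in [0, 1]."""

    intercept: float = 0.1
    slope: float = 0.0015


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic generator.

    fusion_level may be a scalar shared by all 7 transitions or a
    7-vector; dwell_s is the full stop duration at fusion level 0.
    """

    fusion_level: float | tuple = 0.0
    movement_time_s: float = 5.0
    dwell_s: float = 0.15
    sampling_rate_hz: float = 110.0
    noise_sd_cm: float = 0.05
    seed: int = 0
    corrected_trial_prob: float = 0.087
    learning_model: LearningModel = field(default_factory=LearningModel)
    fusion_trend: FusionTrend = field(default_factory=FusionTrend)
    pre_hold_s: float = 0.3
    post_hold_s: float = 0.2

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.fusion_level, dtype=float))
        if np.any(f < 0) or np.any(f > 1):
            raise ParameterError("fusion_level must lie in [0, 1]")
        if self.movement_time_s <= 0:
            raise ParameterError("movement_time_s must be positive")
        if self.dwell_s < 0:
            raise ParameterError("dwell_s must be nonnegative")
        if self.sampling_rate_hz <= 0:
            raise ParameterError("sampling_rate_hz must be positive")
        if self.noise_sd_cm < 0:
            raise ParameterError("noise_sd_cm must be nonnegative")
        if not 0.0 <= self.corrected_trial_prob <= 1.0:
            raise ParameterError("corrected_trial_prob must be a probability")

    def fusion_vector(self, n_transitions: int) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.fusion_level, dtype=float))
        if f.size == 1:
            return np.full(n_transitions, float(f[0]))
        if f.size != n_transitions:
            raise ParameterError(f"fusion_level must be scalar or length {n_transitions}")
        return f.astype(float)


@dataclass
class SyntheticDataset:
    """Simulated trials plus lossless ground-truth labels."""

    trajectories: list[Trajectory]
    truth: pd.DataFrame  # participant, trial, true_mt, true_fusion, corrected, group
    geometry: TaskGeometry
    config: SimulationConfig


# --------------------------------------------------------------------------
# phase-based trial construction
# --------------------------------------------------------------------------

_fused_cache: dict[bytes, MinJerkResult] = {}


def fused_reference(geometry: TaskGeometry, duration: float) -> MinJerkResult:
    """Minimum-jerk via-point pass over the full sequence, any duration.

    The optimal relative passage times are duration-invariant (the jerk
    cost scales uniformly as T^-5), so the optimization runs once per
    geometry at unit duration and is rescaled exactly.
    """
    key = np.ascontiguousarray(geometry.sequence_points).tobytes()
    if key not in _fused_cache:
        pts = geometry.sequence_points
        _fused_cache[key] = min_jerk_via(MinJerkProblem(pts[0], pts[-1], pts[1:-1], 1.0))
    return _fused_cache[key].time_rescaled(duration)


@dataclass
class _Phase:
    duration: float
    kind: str                       # "hold" or "move"
    coeffs: np.ndarray | None = None  # (6, 2) quintic coeffs for moves
    point: np.ndarray | None = None   # hold position

    def positions(self, tau: np.ndarray) -> np.ndarray:
        if self.kind == "hold":
            return np.broadcast_to(self.point, (len(tau), 2)).copy()
        powers = tau[:, None] ** np.arange(6)[None, :]
        return powers @ self.coeffs


def _quintic_boundary(p0, v0, p1, v1, d: float, a0=None, a1=None) -> np.ndarray:
    """Quintic coefficients for boundary (p0, v0, a0) -> (p1, v1, a1).

    A quintic is fully determined by position, velocity and acceleration
    at both ends; accelerations default to zero.
    """
    a0 = np.zeros(2) if a0 is None else np.asarray(a0, float)
    a1 = np.zeros(2) if a1 is None else np.asarray(a1, float)
    c0, c1, c2 = np.asarray(p0, float), np.asarray(v0, float), a0 / 2.0
    A = np.array(
        [
            [d**3, d**4, d**5],
            [3 * d**2, 4 * d**3, 5 * d**4],
            [6 * d, 12 * d**2, 20 * d**3],
        ]
    )
    b = np.stack(
        [
            np.asarray(p1, float) - (c0 + c1 * d + c2 * d**2),
            np.asarray(v1, float) - (c1 + 2 * c2 * d),
            a1 - 2 * c2,
        ]
    )
    c345 = np.linalg.solve(A, b)
    return np.vstack([c0, c1, c2, c345])


def _build_phases(
    geometry: TaskGeometry,
    fusion: np.ndarray,
    t_move: float,
    dwell_s: float,
    pre_hold: float,
    post_hold: float,
    corrected_reach: int | None,
    miss_side: float = 1.0,
) -> list[_Phase]:
    pts = geometry.sequence_points
    n_mov = geometry.n_movements

    if corrected_reach is None and np.all(fusion >= 1.0):
        fused = fused_reference(geometry, t_move)
        phases = [_Phase(pre_hold, "hold", point=pts[0])]
        for j in range(n_mov):
            d = fused.knot_times[j + 1] - fused.knot_times[j]
            phases.append(_Phase(d, "move", coeffs=fused.coeffs[j]))
        phases.append(_Phase(post_hold, "hold", point=pts[-1]))
        return phases

    # segment durations, boundary velocities and accelerations come from
    # the fused reference pass, scaled by the fusion level: at f = 1 each
    # quintic segment reproduces the fused pass exactly (a quintic is
    # determined by its endpoint pos/vel/acc), at f = 0 each reach is a
    # rest-to-rest minimum-jerk movement
    fused = fused_reference(geometry, t_move)
    durations = np.diff(fused.knot_times)
    dwells = (1.0 - fusion) * dwell_s
    via_vel = fused.velocity(fused.passage_times)        # (7, 2)
    via_acc = fused.acceleration(fused.passage_times)    # (7, 2)
    boundary_vel = fusion[:, None] * via_vel
    boundary_acc = fusion[:, None] * via_acc
    if corrected_reach is not None:
        # a missed reach starts and ends at rest; so do its neighbours at
        # the shared waypoints
        for k in (corrected_reach - 1, corrected_reach):
            if 0 <= k < len(boundary_vel):
                boundary_vel[k] = 0.0
                boundary_acc[k] = 0.0

    phases = [_Phase(pre_hold, "hold", point=pts[0])]
    for j in range(n_mov):
        p0, p1 = pts[j], pts[j + 1]
        v0 = boundary_vel[j - 1] if j > 0 else np.zeros(2)
        v1 = boundary_vel[j] if j < n_mov - 1 else np.zeros(2)
        a0 = boundary_acc[j - 1] if j > 0 else np.zeros(2)
        a1 = boundary_acc[j] if j < n_mov - 1 else np.zeros(2)
        if corrected_reach == j:
            # miss the target laterally (2.8 cm, 85 deg off the reach
            # direction, so the first pass stays outside the proximity
            # region), pause, then correct back with a heading reversal
            direction = (p1 - p0) / np.linalg.norm(p1 - p0)
            th = np.deg2rad(85.0) * miss_side
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            miss = p1 + 2.8 * (rot @ direction)
            phases.append(_Phase(durations[j], "move", coeffs=_quintic_boundary(p0, v0, miss, np.zeros(2), durations[j])))
            phases.append(_Phase(0.08, "hold", point=miss))
            d_corr = 0.07 * t_move
            phases.append(_Phase(d_corr, "move", coeffs=_quintic_boundary(miss, np.zeros(2), p1, np.zeros(2), d_corr)))
            if j < n_mov - 1 and dwells[j] > 0:
                phases.append(_Phase(dwells[j], "hold", point=p1))
            continue
        phases.append(
            _Phase(durations[j], "move", coeffs=_quintic_boundary(p0, v0, p1, v1, durations[j], a0, a1))
        )
        if j < n_mov - 1 and dwells[j] > 0:
            phases.append(_Phase(dwells[j], "hold", point=p1))
    phases.append(_Phase(post_hold, "hold", point=pts[-1]))
    return phases


def _evaluate_phases(phases: list[_Phase], times: np.ndarray) -> np.ndarray:
    bounds = np.concatenate([[0.0], np.cumsum([p.duration for p in phases])])
    seg = np.clip(np.searchsorted(bounds, times, side="right") - 1, 0, len(phases) - 1)
    out = np.empty((len(times), 2))
    for i, ph in enumerate(phases):
        mask = seg == i
        if np.any(mask):
            out[mask] = ph.positions(times[mask] - bounds[i])
    return out


def _measured_mt_continuous(phases: list[_Phase], geometry: TaskGeometry, fs_dense: float = 2000.0):
    """Measured MT (2-cm exit to 2-cm final entry) on a dense evaluation."""
    total = sum(p.duration for p in phases)
    t = np.arange(0.0, total, 1.0 / fs_dense)
    xy = _evaluate_phases(phases, t)
    start = xy[0]
    away = np.nonzero(np.linalg.norm(xy - start, axis=1) > 2.0)[0]
    # final entry: first time inside the last waypoint's proximity region
    # during the final move phase
    bounds = np.concatenate([[0.0], np.cumsum([p.duration for p in phases])])
    last_move = max(i for i, p in enumerate(phases) if p.kind == "move")
    in_final = (t >= bounds[last_move]) & (t < bounds[last_move + 1])
    wp = geometry.sequence_points[-1]
    near = np.nonzero(in_final & (np.linalg.norm(xy - wp, axis=1) < geometry.proximity_radius))[0]
    if len(away) == 0 or len(near) == 0:
        raise ParameterError("degenerate trial: start-box exit or final entry not found")
    return float(t[near[0]] - t[away[0]])


def simulate_trial(
    geometry: TaskGeometry,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    fusion: np.ndarray | float | None = None,
    movement_time_s: float | None = None,
    corrected: bool = False,
    metadata: dict | None = None,
) -> Trajectory:
    """Simulate one trial; reproducible under a fixed seed.

    ``fusion`` and ``movement_time_s`` override the config per trial (used
    by the learning-dataset generator).  When ``corrected`` is True one
    outer target of the sequence is overshot and re-acquired.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if fusion is None:
        f = config.fusion_vector(geometry.n_transitions)
    else:
        f = np.broadcast_to(np.atleast_1d(np.asarray(fusion, float)), (geometry.n_transitions,)).copy()
        if np.any(f < 0) or np.any(f > 1):
            raise ParameterError("fusion level must lie in [0, 1]")
    mt_target = config.movement_time_s if movement_time_s is None else float(movement_time_s)
    if mt_target <= 0:
        raise ParameterError("movement time must be positive")

    corrected_reach = None
    miss_side = 1.0
    if corrected:
        # outer targets sit at sequence positions 1, 3, 5, 7 -> reaches 0, 2, 4, 6
        corrected_reach = int(rng.choice([0, 2, 4, 6]))
        miss_side = float(rng.choice([-1.0, 1.0]))

    fixed = float(np.sum((1.0 - f) * config.dwell_s)) + (0.08 if corrected else 0.0)
    if mt_target <= fixed + 0.2:
        raise ParameterError(
            f"movement_time_s={mt_target} too short for {fixed:.2f} s of dwell/pause time"
        )

    t_move0 = mt_target - fixed
    phases = _build_phases(
        geometry, f, t_move0, config.dwell_s, config.pre_hold_s, config.post_hold_s,
        corrected_reach, miss_side,
    )
    measured = _measured_mt_continuous(phases, geometry)
    beta = (mt_target - fixed) / (measured - fixed)
    phases = _build_phases(
        geometry, f, t_move0 * beta, config.dwell_s, config.pre_hold_s, config.post_hold_s,
        corrected_reach, miss_side,
    )

    total = sum(p.duration for p in phases)
    dt = 1.0 / config.sampling_rate_hz
    times = np.arange(0.0, total + 0.5 * dt, dt)
    xy = _evaluate_phases(phases, times)
    if config.noise_sd_cm > 0:
        xy = xy + rng.normal(0.0, config.noise_sd_cm, size=xy.shape)

    meta = {
        "true_mt": mt_target,
        "true_fusion": tuple(np.round(f, 6)),
        "corrected": bool(corrected),
        "seed": config.seed,
    }
    if metadata:
        meta.update(metadata)
    return Trajectory(times, xy, meta)


def simulate_mt_series(
    model: LearningModel,
    n_participants: int,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ground-truth MT matrix, shape (n_participants, n_trials).

    This is the generative statistical structure the learning-curve
    inference assumes; the trajectory renderer consumes its values as
    per-trial movement times.
    """
    if n_participants < 1 or n_trials < 2:
        raise ParameterError("need at least 1 participant and 2 trials")
    x = np.arange(1, n_trials + 1)
    offsets = rng.normal(0.0, model.participant_sd, size=n_participants)
    noise = rng.normal(0.0, model.trial_sd, size=(n_participants, n_trials))
    mt = model.intercept + model.slope * x[None, :] + offsets[:, None] + noise
    return np.maximum(mt, model.floor)


def simulate_learning_dataset(
    geometry: TaskGeometry,
    config: SimulationConfig,
    n_participants: int,
    n_trials: int,
    rng: np.random.Generator | None = None,
    group: str = "sim",
) -> SyntheticDataset:
    """Multi-participant learning dataset with ground-truth labels.

    Trial-wise true MT follows the learning model; the per-transition
    fusion level follows the fusion trend clamped to [0, 1]; corrected
    trials are injected with probability ``corrected_trial_prob``.
    """
    if n_participants < 1 or n_trials < 2:
        raise ParameterError("need at least 1 participant and 2 trials")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    mts = simulate_mt_series(config.learning_model, n_participants, n_trials, rng)
    x = np.arange(1, n_trials + 1)
    fus = np.clip(config.fusion_trend.intercept + config.fusion_trend.slope * x, 0.0, 1.0)
    corr = rng.random((n_participants, n_trials)) < config.corrected_trial_prob

    trajectories = []
    rows = []
    for p in range(n_participants):
        for tr in range(n_trials):
            traj = simulate_trial(
                geometry,
                config,
                rng=rng,
                fusion=fus[tr],
                movement_time_s=mts[p, tr],
                corrected=bool(corr[p, tr]),
                metadata={"participant": p + 1, "trial": tr + 1, "group": group, "day": 1},
            )
            trajectories.append(traj)
            rows.append(
                {
                    "participant": p + 1,
                    "trial": tr + 1,
                    "true_mt": mts[p, tr],
                    "true_fusion": fus[tr],
                    "corrected": bool(corr[p, tr]),
                    "group": group,
                }
            )
    return SyntheticDataset(trajectories, pd.DataFrame(rows), geometry, config)
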