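"""End-to-end pipeline: simulation -> kinematics -> fusion/smoothness/reward
-> group statistics, with tidy tables and a run manifest.

Defaults match the canonical study conditions: 110-Hz sampling, sigma = 2
sample smoothing, 2-cm proximity radius, 10-trial spatial window, 20-trial
reward window, N = 500 interpolation for the model MSE and 1,000 bootstrap
draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as seqio
from .errors import DataError, IncompleteTrialError, ParameterError
from .fusion import radial_distance, trial_fusion
from .geometry import TaskGeometry, build_geometry
from .groupstats import GroupSeries, bootstrap_fit
from .kinematics import (Trajectory, VelocityProfile, compute_velocity, detect_corrected,
                         movement_window, segment_trial, trial_metrics)
from .reward import RewardSchedule, session_feedback
from .simulate import FusionTrend, LearningModel, SimulationConfig, fused_reference, simulate_learning_dataset
from .smoothness import exclude_corrected, mse_to_model, spectral_arc_length

logger = logging.getLogger("seqreach")

__all__ = ["PipelineConfig", "AnalyzedTrial", "run_pipeline", "analyze_trajectories"]


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    # geometry
    angle_split_deg: float = 126.0
    mirror: bool = False
    # kinematics
    sampling_rate_hz: float = 110.0
    smoothing_sd_samples: float = 2.0
    proximity_radius_cm: float = 2.0
    # fusion / spatial reorganization
    rd_window_trials: int = 10
    rd_coverage: float = 0.95
    # smoothness
    n_interp: int = 500
    sparc_cutoff_hz: float = 20.0
    # reward
    reward_window: int = 20
    # group statistics
    n_boot: int = 1000
    families: tuple[str, ...] = ("poly1",)
    # simulation
    n_participants: int = 15
    n_trials: int = 200
    fusion_trend: FusionTrend = field(default_factory=FusionTrend)
    learning_model: LearningModel = field(default_factory=LearningModel)
    dwell_s: float = 0.15
    noise_sd_cm: float = 0.05
    corrected_trial_prob: float = 0.087
    group: str = "sim"
    seed: int = 0
    # output
    output_dir: str = "seqreach_out"

    def __post_init__(self):
        if self.sampling_rate_hz <= 0 or self.proximity_radius_cm <= 0:
            raise ParameterError("sampling rate and proximity radius must be positive")
        if self.rd_window_trials < 2 or self.reward_window < 1:
            raise ParameterError("window sizes too small")
        if self.n_boot < 1 or self.n_interp < 2:
            raise ParameterError("n_boot and n_interp must be positive")
        if self.n_participants < 1 or self.n_trials < 2:
            raise ParameterError("need at least 1 participant and 2 trials")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "learning_model" in raw:
            raw["learning_model"] = LearningModel(**raw["learning_model"])
        if "fusion_trend" in raw:
            raw["fusion_trend"] = FusionTrend(**raw["fusion_trend"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["families"] = list(self.families)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def geometry(self) -> TaskGeometry:
        return build_geometry(
            self.angle_split_deg, self.mirror, proximity_radius=self.proximity_radius_cm
        )

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            fusion_level=0.0,
            dwell_s=self.dwell_s,
            sampling_rate_hz=self.sampling_rate_hz,
            noise_sd_cm=self.noise_sd_cm,
            seed=self.seed,
            corrected_trial_prob=self.corrected_trial_prob,
            learning_model=self.learning_model,
            fusion_trend=self.fusion_trend,
        )


@dataclass
class AnalyzedTrial:
    """One trial carried through segmentation and metric extraction."""

    trajectory: Trajectory
    profile: object
    segmented: object
    metrics: object

    @property
    def participant(self):
        return self.trajectory.metadata.get("participant", 1)

    @property
    def trial(self):
        return self.trajectory.metadata.get("trial", 1)


def analyze_trajectories(trajectories, geometry, smoothing_sd_samples: float = 2.0):
    """Segment and measure every trial; incomplete trials are dropped.

    Returns ``(analyzed, n_incomplete)``; incomplete trials (a waypoint
    never approached) are excluded from all downstream metrics, mirroring
    the task's abort-and-repeat rule.
    """
    analyzed, n_incomplete = [], 0
    for traj in trajectories:
        profile = compute_velocity(traj, smoothing_sd_samples)
        try:
            segmented = segment_trial(profile, traj, geometry)
        except IncompleteTrialError as e:
            n_incomplete += 1
            logger.warning("dropping incomplete trial %s: %s", traj.metadata, e)
            continue
        corrected = detect_corrected(segmented, traj, geometry)
        metrics = trial_metrics(segmented, profile, traj, corrected=corrected)
        analyzed.append(AnalyzedTrial(traj, profile, segmented, metrics))
    return analyzed, n_incomplete


def run_pipeline(config: PipelineConfig, input: str | Path = "simulate") -> dict:
    """Execute every stage and write tidy tables plus a run manifest.

    ``input`` is either the literal string ``"simulate"`` (generate a
    synthetic learning dataset under the config's conditions) or a path
    to a trajectory CSV in the shared schema.  Deterministic under a
    fixed seed: rerunning with the same config yields identical tables.
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry()
    stage_log: dict[str, float] = {}

    # ---- stage: data -----------------------------------------------------
    t0 = time.time()
    truth = None
    if str(input) == "simulate":
        dataset = simulate_learning_dataset(
            geometry,
            config.simulation_config(),
            config.n_participants,
            config.n_trials,
            group=config.group,
        )
        trajectories = dataset.trajectories
        truth = dataset.truth
        seqio.write_trajectories(outdir / "trajectories.csv", trajectories)
        seqio.write_truth(outdir / "truth.csv", truth)
    else:
        trajectories = seqio.read_trajectories(input)
    stage_log["data_s"] = time.time() - t0

    # ---- stage: kinematics ----------------------------------------------
    t0 = time.time()
    analyzed, n_incomplete = analyze_trajectories(trajectories, geometry, config.smoothing_sd_samples)
    if not analyzed:
        raise DataError("no complete trials to analyze")
    trial_rows = []
    for a in analyzed:
        fm = trial_fusion(a.metrics)
        trial_rows.append(
            {
                "participant": a.participant,
                "trial": a.trial,
                "group": a.trajectory.metadata.get("group", config.group),
                "movement_time_s": a.metrics.movement_time,
                "reaction_time_s": a.metrics.reaction_time,
                "vmax_mean": a.metrics.vmax_mean,
                "vmin_mean": a.metrics.vmin_mean,
                "fi_trial": fm.fi_trial,
                "corrected": a.metrics.corrected,
            }
        )
    trials_df = pd.DataFrame(trial_rows).sort_values(["participant", "trial"])
    stage_log["kinematics_s"] = time.time() - t0

    # ---- stage: spatial reorganization ----------------------------------
    t0 = time.time()
    rd_rows = []
    for pid, group in _by_participant(analyzed).items():
        if len(group) < config.rd_window_trials:
            continue
        for series in radial_distance(group, geometry, config.rd_window_trials, config.rd_coverage):
            rd_rows.append(
                {
                    "participant": pid,
                    "window_start_trial": group[series.window_start_trial].trial,
                    "rd_mean": series.rd_mean,
                    **{f"rd_seg{k}": v for k, v in zip(series.segment_indices, series.rd_percent)},
                }
            )
    rd_df = pd.DataFrame(rd_rows)
    stage_log["spatial_s"] = time.time() - t0

    # ---- stage: smoothness ----------------------------------------------
    t0 = time.time()
    # the model speed shape is duration-invariant, so one reference serves
    # every trial after time/amplitude normalization
    model = fused_reference(geometry, 1.0)
    mt_grid = np.linspace(0.0, 1.0, 2000)
    model_speed = (mt_grid, model.speed(mt_grid))
    kept, excl_report = exclude_corrected(analyzed)
    smooth_rows = []
    for a in kept:
        i0, i1 = movement_window(a.trajectory)
        cropped = VelocityProfile(
            a.profile.sample_times[i0 : i1 + 1],
            a.profile.speed[i0 : i1 + 1],
            a.profile.smoothing_sd_samples,
        )
        smooth_rows.append(
            {
                "participant": a.participant,
                "trial": a.trial,
                "mse": mse_to_model(cropped, model_speed, config.n_interp),
                "sparc": spectral_arc_length(cropped, cutoff_hz=config.sparc_cutoff_hz),
                "jerk_cost_model": model.time_rescaled(a.metrics.movement_time).jerk_cost,
            }
        )
    smooth_df = pd.DataFrame(smooth_rows)
    stage_log["smoothness_s"] = time.time() - t0

    # ---- stage: reward replay -------------------------------------------
    t0 = time.time()
    schedule = RewardSchedule(window=config.reward_window)
    reward_rows = []
    for pid, group in _by_participant(analyzed).items():
        mts = [a.metrics.movement_time for a in group]
        if len(mts) <= config.reward_window:
            continue
        carry, rest = mts[: config.reward_window], mts[config.reward_window :]
        events, total = session_feedback(rest, schedule, carryover=carry)
        cum = 0
        for a, ev in zip(group[config.reward_window :], events):
            cum += ev.payout
            reward_rows.append(
                {
                    "participant": pid,
                    "trial": a.trial,
                    "mt": ev.mt,
                    "percentile": ev.percentile,
                    "payout_pence": ev.payout,
                    "source": ev.source,
                    "cumulative_pence": cum,
                }
            )
    reward_df = pd.DataFrame(reward_rows)
    stage_log["reward_s"] = time.time() - t0

    # ---- stage: group statistics ----------------------------------------
    t0 = time.time()
    fit_rows = []
    series = _group_series(trials_df, "movement_time_s", config.group)
    for family in config.families:
        res = bootstrap_fit(series, family, n_boot=config.n_boot, seed=config.seed)
        for name, (lo, hi) in res.ci.items():
            if name == "r_squared":
                continue
            k = list(res.ci).index(name)
            fit_rows.append(
                {
                    "group": config.group,
                    "measure": "movement_time_s",
                    "family": family,
                    "parameter": name,
                    "estimate": float(res.point.params[k]),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "r_squared": res.point.r_squared,
                }
            )
    fits_df = pd.DataFrame(fit_rows)
    stage_log["groupstats_s"] = time.time() - t0

    # ---- outputs ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_trials_in": len(trajectories),
        "n_incomplete_excluded": n_incomplete,
        "n_corrected_excluded": excl_report["n_excluded"],
        "pct_corrected_excluded": excl_report["pct_excluded"],
        "stage_seconds": {k: round(v, 3) for k, v in stage_log.items()},
    }
    tables = {
        "trials": trials_df,
        "radial_distance": rd_df,
        "smoothness": smooth_df,
        "reward": reward_df,
        "fits": fits_df,
    }
    for name, df in tables.items():
        out = df.copy()
        out.insert(0, "config_hash", config.config_hash)
        out.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    return {"manifest": manifest, **tables, "truth": truth}


def _by_participant(analyzed) -> dict:
    out: dict = {}
    for a in analyzed:
        out.setdefault(a.participant, []).append(a)
    for group in out.values():
        group.sort(key=lambda a: a.trial)
    return out


def _group_series(trials_df: pd.DataFrame, measure: str, group: str) -> GroupSeries:
    pivot = trials_df.pivot_table(index="participant", columns="trial", values=measure, aggfunc="first")
    pivot = pivot.reindex(columns=range(1, int(trials_df["trial"].max()) + 1))
    return GroupSeries(pivot.to_numpy(dtype=float), group=group, measure=measure)
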