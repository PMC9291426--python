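import numpy as np
import pytest

from seqreach import (
    SimulationConfig,
    build_geometry,
    compute_velocity,
    segment_trial,
    simulate_trial,
    trial_metrics,
)
from seqreach.pipeline import AnalyzedTrial


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def analyze_one(geometry):
    """Factory: simulate one trial and carry it through segmentation."""

    def _make(fusion=0.0, noise=0.0, mt=5.0, seed=0, corrected=False, rng=None):
        cfg = SimulationConfig(
            fusion_level=fusion, noise_sd_cm=noise, movement_time_s=mt, seed=seed
        )
        traj = simulate_trial(geometry, cfg, rng=rng, corrected=corrected)
        profile = compute_velocity(traj)
        segmented = segment_trial(profile, traj, geometry)
        metrics = trial_metrics(segmented, profile, traj, geometry)
        return AnalyzedTrial(traj, profile, segmented, metrics)

    return _make


@pytest.fixture(scope="session")
def clean_trial(analyze_one):
    """One noiseless zero-fusion trial (full stops at every transition)."""
    return analyze_one(fusion=0.0, noise=0.0)


@pytest.fixture(scope="session")
def fused_trial(analyze_one):
    """One noiseless fully fused trial (single minimum-jerk via-point pass)."""
    return analyze_one(fusion=1.0, noise=0.0)
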