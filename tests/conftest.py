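"""Shared fixtures: small simulated bouts with known ground truth."""

from dataclasses import dataclass

import numpy as np
import pytest

import gaitpose as gp


@dataclass
class Bout:
    config: gp.SyntheticGaitConfig
    static: gp.KeypointSeries
    run: gp.KeypointSeries
    truth: gp.GroundTruth


def make_bout(**kwargs) -> Bout:
    cfg = gp.SyntheticGaitConfig(**kwargs)
    series, truth = gp.simulate(cfg)
    static, run = gp.split_calibration(series, truth)
    return Bout(cfg, static, run, truth)


@pytest.fixture(scope="session")
def clean_bout() -> Bout:
    """20 s noise-free bout at the default study conditions."""
    return make_bout(duration_s=20.0)


@pytest.fixture(scope="session")
def noisy_bout() -> Bout:
    """20 s bout with 2 px Gaussian keypoint noise."""
    return make_bout(duration_s=20.0, noise_sd_px=2.0, seed=42)


def interior_truth(frames: np.ndarray, truth: gp.GroundTruth, fps: float) -> np.ndarray:
    """Ground-truth event frames far enough from the bout boundaries for a
    peak to be detectable (full lookback window before, a descending flank
    after)."""
    lo = int(round(0.30 * fps))
    hi = truth.n_run_frames - int(round(0.05 * fps))
    return frames[(frames >= lo) & (frames <= hi)]
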