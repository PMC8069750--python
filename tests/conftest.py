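import numpy as np
import pytest

from skategears import (PipelineConfig, TEMPLATES, add_noise, build_lcs,
                        generate_trial, lowpass_trajectory, smooth_spline)
from skategears.classifier import build_feature_corpus, train_nnc

SMALL_COUNTS = {"G2R": 8, "G2L": 12, "G3": 16, "G4R": 12, "G4L": 8}


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_corpus():
    """Reduced-scale labelled feature corpus (same class proportions)."""
    return build_feature_corpus(SMALL_COUNTS, seed=11)


@pytest.fixture(scope="session")
def trained_model(small_corpus):
    feats, labels = small_corpus
    return train_nnc(feats, labels, seed=11)


@pytest.fixture(scope="session")
def g3_preprocessed():
    """Noiseless G3 trial run through the exact (zero-penalty) spline path."""
    traj, truth = generate_trial(TEMPLATES["G3"], 40.0, 3.5, seed=1)
    smooth = smooth_spline(traj, expected_noise_sd=0.0)
    origin = lowpass_trajectory(smooth)
    lcs = build_lcs(smooth, origin)
    return traj, truth, smooth, lcs


@pytest.fixture(scope="session")
def g3_noisy_preprocessed():
    traj, truth = generate_trial(TEMPLATES["G3"], 40.0, 3.5, seed=1)
    noisy = add_noise(traj, 0.030, seed=2)
    smooth = smooth_spline(noisy, expected_noise_sd=0.030)
    origin = lowpass_trajectory(smooth)
    lcs = build_lcs(smooth, origin)
    return traj, truth, smooth, lcs
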