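"""Shared fixtures.

The trained desk-scale models are expensive (minutes of CPU), so they are
session-scoped and built lazily: only tests that need a fitted network pay
for one, and every test that does shares the same fit.
"""

import numpy as np
import pytest

from fluorocad import desk
from fluorocad.simulate import ChannelLayout, SimConfig, generate_frame

SEED = 1234


@pytest.fixture(scope="session")
def desk_classifier():
    """Fitted tiny frame classifier plus its history and validation set."""
    model, history, val = desk.train_desk_classifier(SEED)
    return model, history, val


@pytest.fixture(scope="session")
def desk_segmenter_true():
    """Tiny UNet fitted on ground-truth masks, with held-out phantoms."""
    model, history, val_ph, _ = desk.train_desk_segmenter(SEED, labels="true")
    return model, history, val_ph


@pytest.fixture(scope="session")
def desk_segmenter_weak():
    """Tiny UNet fitted on Chan-Vese weak labels, plus those labels and the
    training phantoms they correspond to."""
    model, history, val_ph, labels = desk.train_desk_segmenter(
        SEED, labels="chanvese")
    train_ph = desk.segmentation_phantoms(SEED)[:200]
    return model, history, val_ph, train_ph, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture()
def suspicious_phantom():
    cfg = SimConfig(size=96, seed=7)
    return generate_frame(cfg, "suspicious")


@pytest.fixture()
def noiseless_cfg():
    return SimConfig(size=96, seed=5, noise_sigma=0.0,
                     lesion_intensity=(0.8, 0.8),
                     background_intensity=(0.4, 0.4))


@pytest.fixture()
def classifier_phantom():
    cfg = SimConfig(size=96, seed=9,
                    channel_layout=ChannelLayout.FLUOR_GREEN_REFL_BLUE)
    return generate_frame(cfg, "suspicious")
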