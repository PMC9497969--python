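"""Desk-scale reference experiments.

The clinical studies this pipeline is designed for are measured on
thousands of patient video frames; these recipes are the package's
self-contained counterpart: small enough to train on one CPU in minutes,
yet exercising every stage end to end on simulated frames with known
ground truth.  Problem sizes: 400/100 train/validation frames for the
classifier, 200/50 phantoms for the segmenter, 96 x 96 pixels throughout.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from . import models as mdl
from .augment import AugmentPolicy
from .chanvese import ChanVeseParams
from .pipeline import weak_label_mask
from .simulate import ChannelLayout, SimConfig, generate_phantom_set

__all__ = [
    "classifier_dataset", "segmentation_phantoms",
    "train_desk_classifier", "train_desk_segmenter",
    "DESK_SIZE",
]

DESK_SIZE = 96


def classifier_dataset(seed: int, n_per_class: int = 250):
    """Balanced suspicious/artifact frames in the classifier's 3-channel
    layout, shuffled and split 400/100 (at the default size)."""
    cfg = SimConfig(size=DESK_SIZE, seed=seed,
                    channel_layout=ChannelLayout.FLUOR_GREEN_REFL_BLUE)
    phantoms = generate_phantom_set(cfg, n_per_class, n_per_class)
    items = [(p.image, 1 if p.frame_class.value == "suspicious" else 0)
             for p in phantoms]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    n_train = int(0.8 * len(items))
    return items[:n_train], items[n_train:]


def segmentation_phantoms(seed: int, n: int = 250):
    """Suspicious-only grayscale phantoms with ground-truth lesion masks."""
    cfg = SimConfig(size=DESK_SIZE, seed=seed)
    return generate_phantom_set(cfg, n, 0)


def train_desk_classifier(seed: int, max_epochs: int = 20):
    """Train the tiny frame classifier; returns (model, history, val_set).

    Geometric distortion is the one augmentation family enabled by default:
    it removes the positional/size biases of the small synthetic corpus,
    which measurably improves out-of-family generalization here just as it
    does on clinical frames.
    """
    train, val = classifier_dataset(seed)
    spec = mdl.BackboneSpec(family="mobile_like", width_multiplier=1.0,
                            depth=3, input_size=DESK_SIZE, in_channels=3)
    model = mdl.build_classifier(spec, seed=seed)
    cfg = mdl.TrainConfig(initial_lr=2e-3, batch_size=16,
                          max_epochs=max_epochs, seed=seed + 1)
    policy = AugmentPolicy(geometric=True, photometric=False, blur_noise=False)
    model, history = mdl.train_classifier(model, train, val, cfg, policy=policy)
    return model, history, val


def train_desk_segmenter(seed: int, labels: str = "true",
                         architecture: str = "unet", max_epochs: int = 10):
    """Train the tiny segmenter on true or Chan-Vese-generated labels.

    Returns ``(model, history, val_phantoms, label_masks)`` where
    ``label_masks`` are the 200 training labels actually used (the weak
    labels when ``labels='chanvese'``).
    """
    phantoms = segmentation_phantoms(seed)
    train_ph, val_ph = phantoms[:200], phantoms[200:]
    if labels == "true":
        masks = [p.lesion_mask for p in train_ph]
    elif labels == "chanvese":
        masks = [weak_label_mask(p.fluorescence(), p.fov_mask,
                                 ChanVeseParams())[0] for p in train_ph]
    else:
        raise ValueError("labels must be 'true' or 'chanvese'")
    train = [(p.fluorescence(), m) for p, m in zip(train_ph, masks)]
    val = [(p.fluorescence(), p.lesion_mask) for p in val_ph]
    depth = 4 if architecture == "bisenet" else 3
    bspec = mdl.BackboneSpec(family="mobile_like", width_multiplier=0.5,
                             depth=depth, input_size=DESK_SIZE, in_channels=1)
    model = mdl.build_segmenter(
        mdl.SegModelSpec(architecture=architecture, backbone=bspec), seed=seed)
    cfg = mdl.TrainConfig(initial_lr=2e-3, batch_size=8,
                          max_epochs=max_epochs, seed=seed + 1)
    model, history = mdl.train_segmenter(model, train, val, cfg)
    return model, history, val_ph, masks
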