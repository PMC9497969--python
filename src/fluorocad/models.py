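"""Frame-selection classifier and fluorescence-target segmenters.

Two trainable networks cover the pipeline's two steps:

* a **frame classifier** — a width/depth-scalable convolutional backbone
  (inverted-residual "mobile_like" or separable-conv "xception_like"
  blocks) followed by global average pooling and two fully connected
  layers, emitting a single suspicious-frame probability;
* a **segmenter** — either a symmetric-skip UNet or a two-path BiSeNet
  (spatial path at 1/8 resolution; context path with attention refinement
  on its last two stages and a global-context tail; feature fusion module),
  emitting per-pixel two-class scores at full input resolution.

Both train with Adam, a learning-rate schedule that multiplies the rate by
0.8 every 10 epochs, and early stopping that restores the weights with the
best validation accuracy.  Backbones are desk-scalable: the default specs
here are deliberately tiny so the whole training loop runs in minutes on
one CPU, while full-size configurations remain constructible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn
from .augment import AugmentPolicy, apply as augment_apply

__all__ = [
    "BackboneSpec", "TrainConfig", "SegModelSpec",
    "build_classifier", "build_segmenter",
    "train_classifier", "train_segmenter",
    "predict_suspicious", "predict_mask", "grad_cam",
    "learning_rate_at_epoch", "save_checkpoint", "load_checkpoint",
    "DegenerateDataError", "UnsupportedModelError",
]


class DegenerateDataError(ValueError):
    pass


class UnsupportedModelError(TypeError):
    pass


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneSpec:
    family: str = "mobile_like"          # or "xception_like"
    width_multiplier: float = 0.5
    depth: int = 3                       # number of stride-2 stages
    input_size: int = 96
    in_channels: int = 3

    def __post_init__(self):
        if self.family not in ("mobile_like", "xception_like"):
            raise ValueError(f"unknown backbone family {self.family!r}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}")

    def stage_channels(self) -> list[int]:
        base = 8
        return [max(4, int(round(base * self.width_multiplier * 2 ** s)))
                for s in range(self.depth)]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 1e-3
    lr_decay_factor: float = 0.8
    lr_decay_every: int = 10             # epochs
    batch_size: int = 16
    max_epochs: int = 30
    patience: int = 15                   # early-stopping patience, epochs
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class SegModelSpec:
    architecture: str = "unet"           # or "bisenet"
    backbone: BackboneSpec = field(
        default_factory=lambda: BackboneSpec(in_channels=1))
    num_classes: int = 2

    def __post_init__(self):
        if self.architecture not in ("unet", "bisenet"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.num_classes != 2:
            raise ValueError("segmentation is two-class (target vs background)")
        if self.architecture == "bisenet" and self.backbone.depth < 4:
            raise ValueError("bisenet needs a backbone of depth >= 4 "
                             "(context path reaches 1/16 resolution)")


def learning_rate_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """LR for a 1-indexed epoch: initial * factor^floor((epoch-1)/every)."""
    return cfg.initial_lr * cfg.lr_decay_factor ** ((epoch - 1) // cfg.lr_decay_every)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvBNRelu(nn.Module):
    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def __call__(self, x):
        return nn.relu(self.bn(self.conv(x)))


class InvertedResidual(nn.Module):
    """MobileNetV2-style block: 1x1 expand, 3x3 depthwise, 1x1 linear project."""

    def __init__(self, cin, cout, stride=1, expand=2, rng=None):
        mid = cin * expand
        self.expand = ConvBNRelu(cin, mid, k=1, rng=rng)
        self.dw = nn.Conv2d(mid, mid, 3, stride=stride, groups=mid, bias=False, rng=rng)
        self.dw_bn = nn.BatchNorm2d(mid)
        self.project = nn.Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.project_bn = nn.BatchNorm2d(cout)
        self.use_skip = stride == 1 and cin == cout

    def __call__(self, x):
        y = self.expand(x)
        y = nn.relu(self.dw_bn(self.dw(y)))
        y = self.project_bn(self.project(y))
        return nn.add(y, x) if self.use_skip else y


class SepConvBlock(nn.Module):
    """Xception-style block: two separable convs plus a linear 1x1 skip."""

    def __init__(self, cin, cout, stride=1, rng=None):
        self.dw1 = nn.Conv2d(cin, cin, 3, groups=cin, bias=False, rng=rng)
        self.pw1 = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.dw2 = nn.Conv2d(cout, cout, 3, stride=stride, groups=cout,
                             bias=False, rng=rng)
        self.pw2 = nn.Conv2d(cout, cout, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.skip = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
        self.skip_bn = nn.BatchNorm2d(cout)

    def __call__(self, x):
        y = nn.relu(self.bn1(self.pw1(self.dw1(x))))
        y = self.bn2(self.pw2(self.dw2(y)))
        return nn.relu(nn.add(y, self.skip_bn(self.skip(x))))


class Backbone(nn.Module):
    """Stacked stride-2 stages; returns one feature map per stage
    (resolutions 1/2, 1/4, ..., 1/2^depth)."""

    def __init__(self, spec: BackboneSpec, rng):
        self.spec = spec
        chans = spec.stage_channels()
        self.stem = ConvBNRelu(spec.in_channels, chans[0], stride=2, rng=rng)
        stages = []
        for s in range(1, spec.depth):
            if spec.family == "mobile_like":
                stages.append(InvertedResidual(chans[s - 1], chans[s], stride=2, rng=rng))
                stages.append(InvertedResidual(chans[s], chans[s], stride=1, rng=rng))
            else:
                stages.append(SepConvBlock(chans[s - 1], chans[s], stride=2, rng=rng))
        self.stages = stages
        self.per_stage = 2 if spec.family == "mobile_like" else 1

    def __call__(self, x):
        feats = [self.stem(x)]
        cur = feats[0]
        for i in range(0, len(self.stages), self.per_stage):
            for blk in self.stages[i:i + self.per_stage]:
                cur = blk(cur)
            feats.append(cur)
        return feats


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class Classifier(nn.Module):
    """Backbone -> global average pooling -> FC -> FC -> sigmoid."""

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.backbone = Backbone(spec, rng)
        c_last = spec.stage_channels()[-1]
        hidden = max(8, 2 * c_last)
        self.fc1 = nn.Linear(c_last, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, 1, rng=rng)

    def forward_logit(self, x: nn.Tensor, keep_feature: bool = False):
        feats = self.backbone(x)
        feature = feats[-1]
        pooled = nn.global_avg_pool(feature)
        logit = self.fc2(nn.relu(self.fc1(pooled)))
        return (logit, feature) if keep_feature else logit

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.sigmoid(self.forward_logit(x))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """images: (N, H, W, C) float in [0,1] -> (N,) probabilities."""
        self.set_training(False)
        x = nn.Tensor(np.transpose(images, (0, 3, 1, 2)))
        return self(x).data.reshape(-1).astype(float)


def build_classifier(spec: BackboneSpec, seed: int = 0) -> Classifier:
    return Classifier(spec, seed=seed)


# ---------------------------------------------------------------------------
# segmenters
# ---------------------------------------------------------------------------

class UNet(nn.Module):
    """Symmetric encoder-decoder with skip connections at every scale."""

    def __init__(self, spec: SegModelSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        bspec = spec.backbone
        self.backbone = Backbone(bspec, rng)
        chans = bspec.stage_channels()
        self.up_blocks = []
        cur = chans[-1]
        for s in range(bspec.depth - 2, -1, -1):
            blk = ConvBNRelu(cur + chans[s], chans[s], rng=rng)
            self.up_blocks.append(blk)
            cur = chans[s]
        self.final_up = ConvBNRelu(cur, cur, rng=rng)
        self.head = nn.Conv2d(cur, spec.num_classes, 1, rng=rng)

    def forward_scores(self, x: nn.Tensor) -> nn.Tensor:
        feats = self.backbone(x)
        cur = feats[-1]
        for blk, skip in zip(self.up_blocks, feats[-2::-1]):
            cur = nn.upsample_nearest(cur, 2)
            cur = blk(nn.concat([cur, skip], axis=1))
        cur = self.final_up(nn.upsample_nearest(cur, 2))
        return self.head(cur)

    __call__ = forward_scores


class AttentionRefinement(nn.Module):
    """Channel attention: GAP -> 1x1 conv -> BN -> sigmoid -> scale."""

    def __init__(self, ch, rng):
        self.fc = nn.Linear(ch, ch, rng=rng)

    def __call__(self, x):
        att = nn.sigmoid(self.fc(nn.global_avg_pool(x)))
        h, w = x.data.shape[2], x.data.shape[3]
        return nn.mul(x, nn.broadcast_spatial(att, h, w))


class FeatureFusion(nn.Module):
    """Concat both paths, 1x1 conv-BN-relu, then residual channel attention."""

    def __init__(self, cin, cout, rng):
        self.fuse = ConvBNRelu(cin, cout, k=1, rng=rng)
        self.fc1 = nn.Linear(cout, cout, rng=rng)
        self.fc2 = nn.Linear(cout, cout, rng=rng)

    def __call__(self, sp, cx):
        feat = self.fuse(nn.concat([sp, cx], axis=1))
        att = nn.sigmoid(self.fc2(nn.relu(self.fc1(nn.global_avg_pool(feat)))))
        h, w = feat.data.shape[2], feat.data.shape[3]
        return nn.add(feat, nn.mul(feat, nn.broadcast_spatial(att, h, w)))


class BiSeNet(nn.Module):
    """Two-path segmenter: spatial path at 1/8 resolution; context path with
    attention refinement on its last two stages plus a global-context tail."""

    def __init__(self, spec: SegModelSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        bspec = spec.backbone
        chans = bspec.stage_channels()
        cin = bspec.in_channels
        sp_ch = max(8, chans[0] * 2)
        self.spatial = nn.Sequential(
            ConvBNRelu(cin, sp_ch, stride=2, rng=rng),
            ConvBNRelu(sp_ch, sp_ch, stride=2, rng=rng),
            ConvBNRelu(sp_ch, sp_ch, stride=2, rng=rng))
        self.backbone = Backbone(bspec, rng)
        c_ctx = chans[-2]
        self.arm_mid = AttentionRefinement(chans[-2], rng)
        self.arm_last = AttentionRefinement(chans[-1], rng)
        self.ctx_mid = ConvBNRelu(chans[-2], c_ctx, k=1, rng=rng)
        self.ctx_last = ConvBNRelu(chans[-1], c_ctx, k=1, rng=rng)
        self.global_fc = nn.Linear(chans[-1], c_ctx, rng=rng)
        self.ffm = FeatureFusion(sp_ch + c_ctx, c_ctx, rng)
        self.head = nn.Conv2d(c_ctx, spec.num_classes, 1, rng=rng)
        self._mid_to_eighth = 2 ** (bspec.depth - 1) // 8

    def forward_scores(self, x: nn.Tensor) -> nn.Tensor:
        sp = self.spatial(x)
        feats = self.backbone(x)
        mid, last = feats[-2], feats[-1]
        a_mid = self.ctx_mid(self.arm_mid(mid))
        a_last = self.ctx_last(self.arm_last(last))
        g = self.global_fc(nn.global_avg_pool(last))
        h, w = a_last.data.shape[2], a_last.data.shape[3]
        a_last = nn.add(a_last, nn.broadcast_spatial(g, h, w))
        cx = nn.add(a_mid, nn.upsample_nearest(a_last, 2))
        if self._mid_to_eighth > 1:
            cx = nn.upsample_nearest(cx, self._mid_to_eighth)
        fused = self.ffm(sp, cx)
        scores = self.head(fused)
        return nn.upsample_nearest(scores, 8)

    __call__ = forward_scores


def build_segmenter(spec: SegModelSpec, seed: int = 0):
    if spec.architecture == "unet":
        return UNet(spec, seed=seed)
    return BiSeNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _to_nchw(images) -> np.ndarray:
    arr = np.stack([im[:, :, None] if im.ndim == 2 else im for im in images])
    return np.ascontiguousarray(np.transpose(arr, (0, 3, 1, 2)), dtype=np.float32)


def _snapshot(model):
    return [a.copy() for a in model.state_arrays()]


def train_classifier(model: Classifier, train_set, val_set, cfg: TrainConfig,
                     policy: AugmentPolicy | None = None):
    """Fit the frame classifier with Adam + binary cross-entropy.

    ``train_set``/``val_set`` are sequences of ``(image HxWxC in [0,1],
    label in {0,1})`` with 1 = suspicious.  Returns ``(model, history)``;
    the weights restored at the end are those with the best validation
    accuracy (early stopping).
    """
    labels = sorted({int(y) for _, y in train_set})
    if len(labels) < 2:
        raise DegenerateDataError("training set contains a single class")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.initial_lr)
    history = {"train_loss": [], "val_accuracy": [], "lr": []}
    best_acc, best_state, best_epoch = -1.0, _snapshot(model), 0

    val_x = _to_nchw([im for im, _ in val_set])
    val_y = np.array([int(y) for _, y in val_set])

    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = learning_rate_at_epoch(cfg, epoch)
        model.set_training(True)
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, ys = [], []
            for i in idx:
                im, y = train_set[i]
                if policy is not None:
                    im, _ = augment_apply(im, None, policy, rng)
                imgs.append(im)
                ys.append(int(y))
            x = nn.Tensor(_to_nchw(imgs))
            logit = model.forward_logit(x)
            loss = nn.bce_with_logits(logit, np.array(ys))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.set_training(False)
        probs = nn.sigmoid(model.forward_logit(nn.Tensor(val_x))).data.reshape(-1)
        acc = float(np.mean((probs >= 0.5).astype(int) == val_y))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(acc)
        history["lr"].append(opt.lr)
        if acc > best_acc:
            best_acc, best_state, best_epoch = acc, _snapshot(model), epoch
        if epoch - best_epoch >= cfg.patience:
            break
    model.load_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    return model, history


def train_segmenter(model, train_set, val_set, cfg: TrainConfig,
                    policy: AugmentPolicy | None = None):
    """Fit a segmenter with Adam + pixel-wise categorical cross-entropy.

    ``train_set``/``val_set`` are sequences of ``(image HxW in [0,1],
    mask HxW bool)``; the mask is the (possibly Chan-Vese-generated) target
    label.  Early stopping on validation pixel accuracy.
    """
    rng = np.random.default_rng(cfg.seed)
    for im, mk in list(train_set) + list(val_set):
        if im.shape[:2] != mk.shape:
            raise ValueError("image/mask grid mismatch")
    opt = nn.Adam(model.parameters(), lr=cfg.initial_lr)
    history = {"train_loss": [], "val_accuracy": [], "lr": []}
    best_acc, best_state, best_epoch = -1.0, _snapshot(model), 0

    val_x = _to_nchw([im for im, _ in val_set])
    val_y = np.stack([mk.astype(np.int64) for _, mk in val_set])

    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = learning_rate_at_epoch(cfg, epoch)
        model.set_training(True)
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, masks = [], []
            for i in idx:
                im, mk = train_set[i]
                if policy is not None:
                    im, mk = augment_apply(im, mk, policy, rng)
                imgs.append(im)
                masks.append(mk.astype(np.int64))
            x = nn.Tensor(_to_nchw(imgs))
            scores = model.forward_scores(x)
            loss = nn.softmax_cross_entropy(scores, np.stack(masks))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.set_training(False)
        pred = predict_mask_batch(model, val_x)
        acc = float(np.mean(pred == val_y))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(acc)
        history["lr"].append(opt.lr)
        if acc > best_acc:
            best_acc, best_state, best_epoch = acc, _snapshot(model), epoch
        if epoch - best_epoch >= cfg.patience:
            break
    model.load_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    return model, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _frame_to_array(frame) -> np.ndarray:
    return frame.image if hasattr(frame, "image") else np.asarray(frame)


def predict_suspicious(model: Classifier, frame, threshold: float = 0.5):
    """Return ``(probability, probability >= threshold)`` for one frame."""
    img = _frame_to_array(frame)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.shape[0] != model.spec.input_size or img.shape[2] != model.spec.in_channels:
        raise ValueError(
            f"expected {model.spec.input_size}px / {model.spec.in_channels}-channel "
            f"input, got {img.shape}")
    prob = float(model.predict_proba(img[None])[0])
    return prob, bool(prob >= threshold)


def predict_mask_batch(model, x_nchw: np.ndarray) -> np.ndarray:
    """Argmax class map; ties break toward background (class 0)."""
    model.set_training(False)
    out = model.forward_scores(nn.Tensor(x_nchw)).data
    return np.argmax(out, axis=1)  # first max wins -> background on ties


def predict_mask(model, image: np.ndarray) -> np.ndarray:
    """Segment one HxW image; returns a boolean target mask."""
    x = _to_nchw([image])
    return predict_mask_batch(model, x)[0].astype(bool)


def grad_cam(model, frame, target_class: int = 1) -> np.ndarray:
    """Gradient-weighted class activation map on the final conv feature.

    Channel weights are the spatially averaged gradients of the class score
    with respect to the last backbone feature map; the weighted sum is
    rectified, upsampled to the frame grid and max-normalized to [0, 1].
    A constant-gradient degenerate case returns an all-zero map.
    """
    if not isinstance(model, Classifier):
        raise UnsupportedModelError("grad-CAM needs the convolutional classifier")
    img = _frame_to_array(frame)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w = img.shape[:2]
    model.set_training(False)
    x = nn.Tensor(np.transpose(img[None], (0, 3, 1, 2)))
    logit, feature = model.forward_logit(x, keep_feature=True)
    sign = 1.0 if target_class == 1 else -1.0
    logit.backward(np.full_like(logit.data, sign))
    grads = feature.grad
    if grads is None:
        grads = np.zeros_like(feature.data)
    weights = grads.mean(axis=(2, 3))[0]
    cam = np.maximum((weights[:, None, None] * feature.data[0]).sum(axis=0), 0.0)
    cam = resize(cam, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    m = cam.max()
    if m > 0:
        cam = cam / m
    else:
        cam = np.zeros_like(cam)
    return cam


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path):
    """Write weights as .npz plus a JSON sidecar describing the spec."""
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    if isinstance(model, Classifier):
        meta = {"kind": "classifier", "spec": asdict(model.spec)}
    else:
        meta = {"kind": "segmenter", "spec": asdict(model.spec)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["kind"] == "classifier":
        model = build_classifier(BackboneSpec(**meta["spec"]))
    else:
        spec = meta["spec"]
        spec["backbone"] = BackboneSpec(**spec["backbone"])
        model = build_segmenter(SegModelSpec(**spec))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_arrays([data[k] for k in sorted(data.files,
                                                         key=lambda s: int(s[4:]))])
    model.set_training(False)
    return model
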