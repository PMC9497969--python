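"""Synthetic scanning-fiber-endoscopy (SFE) frame simulator.

Clinical SFE videos show a circular field of view containing dim tissue
reflectance and, on suspicious frames, one or more patchy bright
fluorescence targets.  Non-suspicious frames show a normal esophagus or one
of four artifact families that must be rejected before quantification:
saturation, dye pooling at the frame border, air bubbles (bright annuli),
and the occluding mother endoscope.  This module plants all of those
patterns with pixel-level ground truth so every downstream stage —
preprocessing, Chan-Vese weak labels, the two CNNs, and T/B quantification
— is testable without clinical data.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "FrameClass",
    "ArtifactKind",
    "SimConfig",
    "Phantom",
    "generate_frame",
    "generate_dataset",
]


class FrameClass(str, enum.Enum):
    SUSPICIOUS = "suspicious"
    ARTIFACT_OR_NORMAL = "artifact_or_normal"


class ArtifactKind(str, enum.Enum):
    SATURATION = "saturation"
    DYE_POOLING = "dye_pooling"
    AIR_BUBBLES = "air_bubbles"
    INSTRUMENT = "instrument"
    NONE = "none"


class ChannelLayout(str, enum.Enum):
    GRAY = "gray"
    FLUOR_GREEN_REFL_BLUE = "fluor_green_refl_blue"


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Intensities are on the [0, 1] scale of standardized frames.  The lesion
    intensity minimum must exceed the background maximum so every planted
    target has positive contrast (the quantity T/B estimates).
    """

    size: int = 128
    fov_radius_frac: float = 0.95
    lesion_intensity: tuple[float, float] = (0.6, 0.9)
    background_intensity: tuple[float, float] = (0.25, 0.45)
    lesion_count: tuple[int, int] = (1, 3)
    blob_scale: float = 8.0          # px, smoothness of lesion boundaries
    noise_sigma: float = 0.02
    channel_layout: ChannelLayout = ChannelLayout.GRAY
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.lesion_intensity[0] <= self.background_intensity[1]:
            raise ValueError("lesion intensity minimum must exceed background maximum")


@dataclass
class Phantom:
    """A simulated frame plus its full ground truth."""

    image: np.ndarray            # H x W x C float in [0,1]
    fov_mask: np.ndarray         # H x W bool
    lesion_mask: np.ndarray      # H x W bool
    frame_class: FrameClass
    artifact_kinds: frozenset[ArtifactKind]
    seed: int
    planted_tb: float | None = None   # lesion/background intensity ratio, noiseless

    def fluorescence(self) -> np.ndarray:
        """The single fluorescence channel as H x W."""
        if self.image.shape[2] == 1:
            return self.image[:, :, 0]
        return self.image[:, :, 1]


def _fov_mask(size: int, radius_frac: float) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2.0
    r = radius_frac * size / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2


def _smooth_field(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """Low-frequency Gaussian random field in [0,1]-ish range."""
    f = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma=scale)
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _patchy_blobs(rng, cfg: SimConfig, fov: np.ndarray) -> np.ndarray:
    """Irregular lesion mask: thresholded low-frequency field, smoothed."""
    n_lesions = int(rng.integers(cfg.lesion_count[0], cfg.lesion_count[1] + 1))
    size = cfg.size
    mask = np.zeros((size, size), bool)
    c = (size - 1) / 2.0
    max_r = cfg.fov_radius_frac * size / 2.0
    for _ in range(max(n_lesions, 1)):
        # random center well inside the FOV
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.6 * max_r)
        cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
        field = _smooth_field(rng, size, cfg.blob_scale)
        yy, xx = np.mgrid[:size, :size]
        r_blob = rng.uniform(0.10, 0.22) * size
        envelope = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r_blob ** 2))
        blob = (field * 0.5 + envelope) > 0.65
        mask |= blob
    mask &= fov
    # smooth the boundary a little; guarantee non-emptiness
    mask = ndi.binary_closing(mask, iterations=1)
    if not mask.any():
        yy, xx = np.mgrid[:size, :size]
        mask = ((yy - c) ** 2 + (xx - c) ** 2 <= (0.08 * size) ** 2) & fov
    return mask


def _add_saturation(rng, img, fov, size):
    c = (size - 1) / 2.0
    ang = rng.uniform(0, 2 * np.pi)
    rad = rng.uniform(0, 0.5 * size / 2.0)
    cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
    yy, xx = np.mgrid[:size, :size]
    r = rng.uniform(0.08, 0.18) * size
    region = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2) & fov
    img[region] = 1.0
    return img


def _add_dye_pooling(rng, img, fov, size):
    # large diffuse bright pool hugging the FOV border
    ang = rng.uniform(0, 2 * np.pi)
    c = (size - 1) / 2.0
    r_fov = size / 2.0
    cy, cx = c + 0.9 * r_fov * np.sin(ang), c + 0.9 * r_fov * np.cos(ang)
    yy, xx = np.mgrid[:size, :size]
    spread = rng.uniform(0.18, 0.30) * size
    pool = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spread ** 2))
    img[fov] = np.clip(img[fov] + 0.7 * pool[fov], 0, 1)
    return img


def _add_air_bubbles(rng, img, fov, size):
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2.0
    for _ in range(int(rng.integers(2, 6))):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.7 * size / 2.0)
        cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
        r = rng.uniform(0.03, 0.10) * size
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ring = (np.abs(d - r) <= max(1.5, 0.06 * size * 0.3)) & fov
        img[ring] = np.clip(img[ring] + rng.uniform(0.3, 0.5), 0, 1)
    return img


def _add_instrument(rng, img, fov, size):
    # dark occluding disk with a bright rim (mother endoscope)
    c = (size - 1) / 2.0
    ang = rng.uniform(0, 2 * np.pi)
    rad = rng.uniform(0.3, 0.8) * size / 2.0
    cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
    yy, xx = np.mgrid[:size, :size]
    r = rng.uniform(0.15, 0.30) * size
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    disk = (d <= r) & fov
    rim = (np.abs(d - r) <= 1.5) & fov
    img[disk] = img[disk] * 0.08
    img[rim] = np.clip(img[rim] + 0.5, 0, 1)
    return img


_ARTIFACT_PAINTERS = {
    ArtifactKind.SATURATION: _add_saturation,
    ArtifactKind.DYE_POOLING: _add_dye_pooling,
    ArtifactKind.AIR_BUBBLES: _add_air_bubbles,
    ArtifactKind.INSTRUMENT: _add_instrument,
}


def _as_kinds(artifact_kinds) -> frozenset[ArtifactKind]:
    if artifact_kinds is None:
        return frozenset({ArtifactKind.NONE})
    kinds = frozenset(ArtifactKind(k) for k in artifact_kinds)
    if not kinds:
        kinds = frozenset({ArtifactKind.NONE})
    if ArtifactKind.NONE in kinds and len(kinds) > 1:
        raise ValueError("'none' cannot be combined with real artifact kinds")
    return kinds


def generate_frame(cfg: SimConfig,
                   frame_class: FrameClass | str,
                   artifact_kinds=None) -> Phantom:
    """Generate one phantom of the requested class.

    Suspicious frames carry 1-k patchy bright lesions and no artifacts;
    artifact/normal frames carry the requested artifact patterns (or plain
    tissue for ``{none}``) and an empty lesion mask.  Additive Gaussian
    noise of ``cfg.noise_sigma`` is applied before the final clip to [0,1].
    """
    frame_class = FrameClass(frame_class)
    kinds = _as_kinds(artifact_kinds)
    if frame_class is FrameClass.SUSPICIOUS and kinds != {ArtifactKind.NONE}:
        raise ValueError(
            "a suspicious frame cannot carry artifacts: by definition it shows "
            "a clean fluorescence target; request artifact_or_normal instead")

    rng = np.random.default_rng(cfg.seed)
    size = cfg.size
    fov = _fov_mask(size, cfg.fov_radius_frac)

    bg_level = rng.uniform(*cfg.background_intensity)
    fluor = np.zeros((size, size), np.float64)
    fluor[fov] = bg_level
    # gentle tissue texture so the background is not perfectly flat
    if cfg.noise_sigma > 0:
        texture = _smooth_field(rng, size, cfg.blob_scale * 2) * 0.02
        fluor[fov] = np.clip(fluor[fov] + texture[fov], 0, 1)

    lesion_mask = np.zeros((size, size), bool)
    planted_tb = None
    if frame_class is FrameClass.SUSPICIOUS:
        lesion_mask = _patchy_blobs(rng, cfg, fov)
        lesion_level = rng.uniform(*cfg.lesion_intensity)
        fluor[lesion_mask] = lesion_level
        planted_tb = float(lesion_level / bg_level)
    else:
        for kind in sorted(kinds, key=lambda k: k.value):
            if kind is not ArtifactKind.NONE:
                fluor = _ARTIFACT_PAINTERS[kind](rng, fluor, fov, size)

    if cfg.noise_sigma > 0:
        fluor = fluor + rng.normal(0, cfg.noise_sigma, fluor.shape)
    fluor = np.clip(fluor, 0, 1)
    fluor[~fov] = 0.0

    if cfg.channel_layout is ChannelLayout.GRAY:
        image = fluor[:, :, None]
    else:
        refl = np.zeros_like(fluor)
        refl[fov] = 0.35
        refl = ndi.gaussian_filter(refl, 2.0)
        if cfg.noise_sigma > 0:
            refl = refl + rng.normal(0, cfg.noise_sigma, refl.shape)
        refl = np.clip(refl, 0, 1)
        refl[~fov] = 0.0
        image = np.stack([np.zeros_like(fluor), fluor, refl], axis=-1)

    return Phantom(image=image.astype(np.float64), fov_mask=fov,
                   lesion_mask=lesion_mask, frame_class=frame_class,
                   artifact_kinds=kinds, seed=cfg.seed, planted_tb=planted_tb)


_NON_SUSPICIOUS_MENU = [
    frozenset({ArtifactKind.SATURATION}),
    frozenset({ArtifactKind.DYE_POOLING}),
    frozenset({ArtifactKind.AIR_BUBBLES}),
    frozenset({ArtifactKind.INSTRUMENT}),
    frozenset({ArtifactKind.NONE}),          # normal esophagus
]


def generate_phantom_set(cfg: SimConfig, n_suspicious: int, n_artifact: int):
    """In-memory dataset: alternating artifact kinds, per-frame derived seeds."""
    phantoms = []
    for i in range(n_suspicious):
        c = replace(cfg, seed=(cfg.seed * 100003 + i) % (2 ** 31 - 1))
        phantoms.append(generate_frame(c, FrameClass.SUSPICIOUS))
    for i in range(n_artifact):
        kinds = _NON_SUSPICIOUS_MENU[i % len(_NON_SUSPICIOUS_MENU)]
        c = replace(cfg, seed=(cfg.seed * 100003 + 50000 + i) % (2 ** 31 - 1))
        phantoms.append(generate_frame(c, FrameClass.ARTIFACT_OR_NORMAL, kinds))
    return phantoms


def generate_dataset(cfg: SimConfig, n_suspicious: int, n_artifact: int,
                     out_dir) -> list[dict]:
    """Write a phantom dataset to disk and return the manifest rows.

    Images are 8-bit PNG, masks single-channel PNG with values {0, 255}; the
    manifest CSV has columns ``path,mask_path,frame_class,artifact_kinds,seed``.
    """
    if n_suspicious < 0 or n_artifact < 0:
        raise ValueError("counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantoms = generate_phantom_set(cfg, n_suspicious, n_artifact)
    rows = []
    for i, ph in enumerate(phantoms):
        stem = f"frame_{i:05d}"
        img_path = out_dir / f"{stem}.png"
        mask_path = out_dir / f"{stem}_mask.png"
        img8 = np.round(ph.image * 255).astype(np.uint8)
        iio.imwrite(img_path, img8.squeeze())
        iio.imwrite(mask_path, (ph.lesion_mask.astype(np.uint8) * 255))
        rows.append({
            "path": img_path.name,
            "mask_path": mask_path.name,
            "frame_class": ph.frame_class.value,
            "artifact_kinds": "+".join(sorted(k.value for k in ph.artifact_kinds)),
            "seed": ph.seed,
        })
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["path", "mask_path", "frame_class", "artifact_kinds", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return rows
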