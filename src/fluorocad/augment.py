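"""Training-time augmentation with paired image/mask geometric transforms.

Three independent families, each toggled by the policy: (1) geometric
distortion — random flips, 0-90 degree rotation, scaling and shifting,
applied identically to the image and its mask (nearest-neighbor for the
mask so labels stay binary); (2) brightness/contrast adjustment; (3) blur
and noise (motion blur with a random-angle line kernel, Gaussian blur,
additive Gaussian noise).  Photometric and blur/noise families touch the
image only and never alter the mask.  Flips and axis-aligned rotations are
implemented as exact array ops so they are true involutions/bijections;
only arbitrary-angle rotation, scale and shift go through interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, warp

__all__ = ["AugmentPolicy", "apply", "hflip", "vflip", "rot90k",
           "affine_pair", "adjust_brightness_contrast",
           "gaussian_blur", "motion_blur", "add_gaussian_noise"]


@dataclass(frozen=True)
class AugmentPolicy:
    geometric: bool = True
    photometric: bool = True
    blur_noise: bool = True
    rotation_range: float = 90.0          # degrees, sampled in [0, rotation_range]
    scale_range: float = 0.10             # relative, 1 +/- scale_range
    shift_range: float = 0.10             # fraction of the image side
    brightness_range: float = 0.10        # additive offset
    contrast_range: float = 0.20          # multiplicative, 1 +/- contrast_range
    noise_sigma_range: tuple[float, float] = (0.0, 0.05)
    blur_sigma_range: tuple[float, float] = (0.5, 2.0)
    motion_kernel_range: tuple[int, int] = (3, 9)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rotation_range <= 90.0:
            raise ValueError("rotation_range must lie in [0, 90] degrees")
        for name in ("scale_range", "shift_range", "brightness_range",
                     "contrast_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# -- exact geometric primitives ---------------------------------------------

def hflip(arr: np.ndarray) -> np.ndarray:
    return arr[:, ::-1].copy()


def vflip(arr: np.ndarray) -> np.ndarray:
    return arr[::-1].copy()


def rot90k(arr: np.ndarray, k: int) -> np.ndarray:
    return np.rot90(arr, k, axes=(0, 1)).copy()


# -- interpolated geometric transform ---------------------------------------

def affine_pair(image: np.ndarray, mask: np.ndarray | None,
                angle_deg: float = 0.0, scale: float = 1.0,
                shift: tuple[float, float] = (0.0, 0.0)):
    """Rotate/scale/shift about the image center; constant-zero fill.

    The image is interpolated bilinearly; the mask is warped as a bilinear
    indicator function thresholded at 0.5, which keeps it binary (no label
    bleeding) while tracking the image's sub-pixel boundary placement far
    better than nearest-neighbor sampling does.
    """
    h, w = image.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tform = (AffineTransform(translation=-center)
             + AffineTransform(rotation=np.deg2rad(angle_deg), scale=scale)
             + AffineTransform(translation=center + np.array(shift)))
    out_img = warp(image, tform.inverse, order=1, mode="constant", cval=0.0,
                   preserve_range=True)
    out_mask = None
    if mask is not None:
        out_mask = warp(mask.astype(np.float64), tform.inverse, order=1,
                        mode="constant", cval=0.0, preserve_range=True) > 0.5
    return np.clip(out_img, 0.0, 1.0), out_mask


# -- photometric primitives --------------------------------------------------

def adjust_brightness_contrast(image, brightness=0.0, contrast=1.0):
    out = (image - 0.5) * contrast + 0.5 + brightness
    return np.clip(out, 0.0, 1.0)


def gaussian_blur(image, sigma):
    if image.ndim == 3:
        return ndi.gaussian_filter(image, (sigma, sigma, 0))
    return ndi.gaussian_filter(image, sigma)


def motion_blur(image, length: int, angle_deg: float):
    """Convolution with a line kernel of the given length and angle."""
    length = max(int(length), 1)
    k = np.zeros((length, length))
    c = (length - 1) / 2.0
    t = np.deg2rad(angle_deg)
    for i in np.linspace(-c, c, 2 * length + 1):
        y, x = int(round(c + i * np.sin(t))), int(round(c + i * np.cos(t)))
        if 0 <= y < length and 0 <= x < length:
            k[y, x] = 1.0
    k /= k.sum()
    if image.ndim == 3:
        out = np.stack([ndi.convolve(image[:, :, c_], k, mode="constant")
                        for c_ in range(image.shape[2])], axis=-1)
    else:
        out = ndi.convolve(image, k, mode="constant")
    return np.clip(out, 0.0, 1.0)


def add_gaussian_noise(image, sigma, rng):
    return np.clip(image + rng.normal(0.0, sigma, image.shape), 0.0, 1.0)


# -- sampled application ------------------------------------------------------

def apply(image: np.ndarray, mask: np.ndarray | None,
          policy: AugmentPolicy, rng: np.random.Generator):
    """Sample one augmentation per enabled family and apply it.

    The same geometric transform is applied to image and mask; photometric
    and blur/noise transforms are applied to the image only.  Output is
    clipped to [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    msk = None if mask is None else np.asarray(mask).astype(bool)

    if policy.geometric:
        if rng.random() < 0.5:
            img = hflip(img)
            msk = hflip(msk) if msk is not None else None
        if rng.random() < 0.5:
            img = vflip(img)
            msk = vflip(msk) if msk is not None else None
        angle = float(rng.uniform(0.0, policy.rotation_range))
        scale = float(rng.uniform(1.0 - policy.scale_range, 1.0 + policy.scale_range))
        side = img.shape[0]
        shift = rng.uniform(-policy.shift_range, policy.shift_range, 2) * side
        if angle != 0.0 or scale != 1.0 or np.any(shift != 0.0):
            img, msk = affine_pair(img, msk, angle, scale, tuple(shift))

    if policy.photometric:
        b = float(rng.uniform(-policy.brightness_range, policy.brightness_range))
        c = float(rng.uniform(1.0 - policy.contrast_range, 1.0 + policy.contrast_range))
        img = adjust_brightness_contrast(img, b, c)

    if policy.blur_noise:
        choice = rng.integers(0, 3)
        if choice == 0:
            img = gaussian_blur(img, float(rng.uniform(*policy.blur_sigma_range)))
        elif choice == 1:
            lo, hi = policy.motion_kernel_range
            img = motion_blur(img, int(rng.integers(lo, hi + 1)),
                              float(rng.uniform(0.0, 180.0)))
        else:
            img = add_gaussian_noise(
                img, float(rng.uniform(*policy.noise_sigma_range)), rng)

    img = np.clip(img, 0.0, 1.0)
    return img, msk
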