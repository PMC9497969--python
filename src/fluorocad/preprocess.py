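"""Frame loading and standardization.

Every image entering the pipeline is brought to one format: a square float
image in [0, 1] at the configured model size (default 480, the resolution
both networks and the Chan-Vese stage consume), with an explicit boolean
field-of-view (FOV) mask.  Intensities are normalized by the bit-depth
maximum (255 for 8-bit, 65535 for 16-bit).  Images are resized bilinearly;
masks nearest-neighbor so labels never bleed.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .simulate import ChannelLayout

__all__ = [
    "Frame",
    "load_and_standardize",
    "standardize_array",
    "split_multiplex_channels",
    "extract_fluorescence_gray",
    "resize_mask",
]

DEFAULT_TARGET_SIZE = 480


class LayoutError(ValueError):
    """Raised when a channel operation is applied to an incompatible layout."""


@dataclass
class Frame:
    image: np.ndarray                 # H x W x C float in [0,1]
    fov_mask: np.ndarray              # H x W bool
    source_id: str = ""
    channel_layout: ChannelLayout = ChannelLayout.GRAY

    @property
    def size(self) -> int:
        return self.image.shape[0]


def _derive_fov_mask(image: np.ndarray) -> np.ndarray:
    """SFE frames are black outside the circular scan field: the FOV is the
    set of pixels with any nonzero channel, after a 1-pixel closing to fill
    isolated dead pixels."""
    nonzero = image.max(axis=2) > 0
    return ndi.binary_closing(nonzero, structure=np.ones((3, 3)), iterations=1)


def resize_mask(mask: np.ndarray, target_size: int) -> np.ndarray:
    out = resize(mask.astype(np.float64), (target_size, target_size),
                 order=0, anti_aliasing=False, preserve_range=True)
    return out > 0.5


def standardize_array(image: np.ndarray, target_size: int = DEFAULT_TARGET_SIZE,
                      fov_mask: np.ndarray | None = None,
                      source_id: str = "",
                      channel_layout: ChannelLayout | str | None = None) -> Frame:
    """Standardize an in-memory array (integer dtypes are scaled by their
    dtype maximum; float input is assumed already in [0,1])."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("zero-size image")
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float64) / np.iinfo(image.dtype).max
    else:
        image = image.astype(np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.shape[2] not in (1, 3):
        raise ValueError(f"expected 1 or 3 channels, got {image.shape[2]}")

    if channel_layout is None:
        channel_layout = (ChannelLayout.GRAY if image.shape[2] == 1
                          else ChannelLayout.FLUOR_GREEN_REFL_BLUE)
    channel_layout = ChannelLayout(channel_layout)

    if fov_mask is None:
        fov_mask = _derive_fov_mask(image)

    if image.shape[0] != target_size or image.shape[1] != target_size:
        image = resize(image, (target_size, target_size, image.shape[2]),
                       order=1, anti_aliasing=False, preserve_range=True)
        fov_mask = resize_mask(fov_mask, target_size)
    image = np.clip(image, 0.0, 1.0)
    return Frame(image=image, fov_mask=fov_mask.astype(bool),
                 source_id=source_id, channel_layout=channel_layout)


def load_and_standardize(path, target_size: int = DEFAULT_TARGET_SIZE,
                         channel_layout=None) -> Frame:
    """Read a PNG/TIFF frame and standardize it."""
    try:
        raw = iio.imread(path)
    except Exception as exc:  # unreadable or corrupt file
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    if raw.ndim == 3 and raw.shape[2] == 4:   # drop alpha
        raw = raw[:, :, :3]
    from pathlib import Path as _P
    return standardize_array(raw, target_size=target_size,
                             source_id=_P(path).stem,
                             channel_layout=channel_layout)


def split_multiplex_channels(frame: Frame) -> tuple[Frame, Frame]:
    """Split a dual-probe frame into two single-probe frames.

    The dual-probe layout carries one fluorescence probe in red, a second in
    green, and shared reflectance in blue.  Each output maps one
    fluorescence channel to green, copies the reflectance to blue, and
    zeroes red — the layout the frame classifier is trained on.
    """
    if frame.image.shape[2] != 3:
        raise LayoutError("channel split requires a 3-channel frame")
    r, g, b = frame.image[:, :, 0], frame.image[:, :, 1], frame.image[:, :, 2]
    zeros = np.zeros_like(r)
    img1 = np.stack([zeros, r, b], axis=-1)
    img2 = np.stack([zeros, g, b], axis=-1)
    mk = lambda img, tag: Frame(image=img, fov_mask=frame.fov_mask.copy(),
                                source_id=f"{frame.source_id}{tag}",
                                channel_layout=ChannelLayout.FLUOR_GREEN_REFL_BLUE)
    return mk(img1, "_probe1"), mk(img2, "_probe2")


def extract_fluorescence_gray(frame: Frame) -> np.ndarray:
    """Return the fluorescence channel as an H x W array in [0,1] — the
    input of the segmentation path."""
    c = frame.image.shape[2]
    if c == 1:
        return frame.image[:, :, 0]
    if frame.channel_layout is ChannelLayout.FLUOR_GREEN_REFL_BLUE:
        return frame.image[:, :, 1]
    raise LayoutError(
        f"cannot identify the fluorescence channel of layout {frame.channel_layout}")
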