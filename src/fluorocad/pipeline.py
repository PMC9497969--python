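"""End-to-end two-step CAD flow and the weak-label generation workflow.

Step 1 screens every frame with the suspicious-frame classifier; only
frames scoring at or above the selection threshold reach Step 2, where the
fluorescence target is segmented and its T/B ratio computed.  Rejected
frames never reach Step 2 — that gating is the pipeline's efficiency
mechanism.  The weak-label workflow runs Chan-Vese on (labeled or
model-selected) suspicious frames to produce the pixel masks the segmenter
trains on, so no human pixel annotation is ever required.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu

from . import chanvese as cv
from . import models as mdl
from . import tbquant
from .preprocess import extract_fluorescence_gray, load_and_standardize

__all__ = ["RunConfig", "run_cad", "generate_weak_labels", "weak_label_mask"]

log = logging.getLogger("fluorocad")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class RunConfig:
    """Run-wide configuration; one global seed governs all stochastic stages."""

    target_size: int = 96
    threshold: float = 0.5
    band_width: int = 30
    per_lesion: bool = False
    chanvese: cv.ChanVeseParams = field(default_factory=cv.ChanVeseParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {k: raw[k] for k in
                  ("target_size", "threshold", "band_width", "per_lesion", "seed")
                  if k in raw}
        if "chanvese" in raw:
            kwargs["chanvese"] = cv.ChanVeseParams(**raw["chanvese"])
        return cls(**kwargs)


def _list_frames(frames_dir) -> list[Path]:
    frames_dir = Path(frames_dir)
    return sorted(p for p in frames_dir.iterdir()
                  if p.suffix.lower() in IMAGE_SUFFIXES
                  and not p.stem.endswith("_mask"))


def _adapt_channels(frame, in_channels: int) -> np.ndarray:
    """Match a frame's channel count to a model's input contract."""
    img = frame.image
    if img.shape[2] == in_channels:
        return img
    if in_channels == 3 and img.shape[2] == 1:
        g = img[:, :, 0]
        return np.stack([np.zeros_like(g), g, np.zeros_like(g)], axis=-1)
    if in_channels == 1:
        return extract_fluorescence_gray(frame)[:, :, None]
    raise ValueError(f"cannot adapt {img.shape[2]}-channel frame to "
                     f"{in_channels}-channel model")


def _resolve(model_or_path, loader=mdl.load_checkpoint):
    if isinstance(model_or_path, (str, Path)):
        p = Path(model_or_path)
        if not p.with_suffix(".json").exists():
            raise FileNotFoundError(f"missing checkpoint {p}")
        return loader(p)
    return model_or_path


def run_cad(frames_dir, classifier, segmenter, cfg: RunConfig | None = None,
            out_dir=None) -> pd.DataFrame:
    """Run the full two-step flow over a directory of frames.

    Returns one row per frame: suspicious probability, selection flag, and
    (for selected frames only) the mask path and T/B quantities.  Unreadable
    frames are logged and skipped; ``df.attrs['n_failed']`` counts them.
    """
    cfg = cfg or RunConfig()
    classifier = _resolve(classifier)
    segmenter = _resolve(segmenter)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows, n_failed = [], 0
    for path in _list_frames(frames_dir):
        try:
            frame = load_and_standardize(path, target_size=cfg.target_size)
        except (IOError, ValueError) as exc:
            log.error("skipping unreadable frame %s: %s", path, exc)
            n_failed += 1
            continue
        img_cls = _adapt_channels(frame, classifier.spec.in_channels)
        prob, selected = mdl.predict_suspicious(classifier, img_cls,
                                                threshold=cfg.threshold)
        row = {"source_id": frame.source_id, "prob": prob, "selected": selected,
               "mask_path": "", "t_mean": np.nan, "b_mean": np.nan,
               "tb_ratio": np.nan}
        if selected:
            gray = extract_fluorescence_gray(frame)
            mask = mdl.predict_mask(segmenter, gray) & frame.fov_mask
            if mask.any():
                results = tbquant.frame_tb(gray, mask, frame.fov_mask,
                                           width=cfg.band_width,
                                           per_lesion=cfg.per_lesion)
                if results:
                    r = results[0]
                    row.update(t_mean=r.t_mean, b_mean=r.b_mean,
                               tb_ratio=r.tb_ratio)
            if out_dir is not None:
                mask_path = out_dir / f"{frame.source_id}_pred_mask.png"
                iio.imwrite(mask_path, mask.astype(np.uint8) * 255)
                row["mask_path"] = mask_path.name
        rows.append(row)
    df = pd.DataFrame(rows, columns=["source_id", "prob", "selected",
                                     "mask_path", "t_mean", "b_mean", "tb_ratio"])
    df.attrs["n_failed"] = n_failed
    return df


def weak_label_mask(gray: np.ndarray, fov_mask: np.ndarray,
                    params: cv.ChanVeseParams | None = None):
    """Chan-Vese weak label for one fluorescence frame.

    Warm-starts the level set from an Otsu intensity threshold, which lands
    the contour near the bright target and lets the energy descent refine
    it.  Returns ``(mask, degenerate_flag)``.
    """
    params = params or cv.ChanVeseParams()
    inside = gray[fov_mask]
    degenerate = False
    try:
        t0 = threshold_otsu(inside)
        init_mask = (gray > t0) & fov_mask
    except ValueError:
        init_mask = np.zeros_like(fov_mask)
    from dataclasses import replace
    if init_mask.any():
        params = replace(params, init=cv.InitScheme.FROM_MASK, init_mask=init_mask)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", cv.DegenerateImageWarning)
        mask = cv.segment(gray, params, fov_mask)
        degenerate = any(issubclass(w.category, cv.DegenerateImageWarning)
                         for w in caught)
    return mask, degenerate or not mask.any()


def generate_weak_labels(frames_dir, classifier_or_none, chanvese_params,
                         out_dir, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Generate Chan-Vese segmentation labels for suspicious frames.

    Frames are flagged suspicious either by the dataset manifest
    (``manifest.csv`` with a ``frame_class`` column, the labeled route) or,
    when a classifier is given, by Step-1 prediction.  Only suspicious
    frames receive label masks; the returned manifest records provenance
    and a ``label_quality`` flag (``low`` when Chan-Vese reported a
    degenerate input or an empty mask).
    """
    cfg = cfg or RunConfig()
    frames_dir = Path(frames_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    classifier = _resolve(classifier_or_none) if classifier_or_none is not None else None

    manifest_labels = {}
    manifest_path = frames_dir / "manifest.csv"
    if manifest_path.exists():
        man = pd.read_csv(manifest_path)
        manifest_labels = {Path(p).stem: fc == "suspicious"
                           for p, fc in zip(man["path"], man["frame_class"])}

    rows = []
    for path in _list_frames(frames_dir):
        frame = load_and_standardize(path, target_size=cfg.target_size)
        prob = np.nan
        if classifier is not None:
            img_cls = _adapt_channels(frame, classifier.spec.in_channels)
            prob, suspicious = mdl.predict_suspicious(classifier, img_cls,
                                                      threshold=cfg.threshold)
        elif frame.source_id in manifest_labels:
            suspicious = manifest_labels[frame.source_id]
        else:
            raise ValueError(
                f"no suspicious-frame label for {path.name}: provide a manifest "
                "or a Step-1 classifier")
        if not suspicious:
            continue
        gray = extract_fluorescence_gray(frame)
        mask, degenerate = weak_label_mask(gray, frame.fov_mask, chanvese_params)
        mask_path = out_dir / f"{frame.source_id}_cvlabel.png"
        iio.imwrite(mask_path, mask.astype(np.uint8) * 255)
        rows.append({"path": path.name, "mask_path": mask_path.name,
                     "suspicious_prob": prob,
                     "label_quality": "low" if degenerate else "ok"})
    df = pd.DataFrame(rows, columns=["path", "mask_path", "suspicious_prob",
                                     "label_quality"])
    df.to_csv(out_dir / "labels_manifest.csv", index=False)
    return df
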