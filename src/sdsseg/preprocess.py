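"""Volume preprocessing and network-input assembly.

The chain mirrors standard BraTS-style preparation: trim blank slices
from both ends of the stack, crop each slice to the in-plane content
box, histogram-equalize the foreground per modality, min-max normalize
to [-1, 1], and finally cut per-slice samples consisting of a 2D slice
plus its (2k+1)-slice 3D context patch.

Every geometric step records a :class:`CropRecord` so predictions can be
re-embedded exactly into the original volume geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize

from .phantom import LabeledVolume


@dataclass(frozen=True)
class PreprocessConfig:
    crop_size: tuple[int, int] = (160, 160)
    input_size: tuple[int, int] = (224, 224)
    context_halfwidth: int = 2
    norm_range: tuple[float, float] = (-1.0, 1.0)
    he_levels: int = 256
    blank_threshold: float = 0.0

    def validate(self) -> None:
        if self.context_halfwidth < 0:
            raise ValueError("context_halfwidth must be >= 0")
        if self.he_levels < 2:
            raise ValueError("he_levels must be >= 2")
        if self.norm_range[0] >= self.norm_range[1]:
            raise ValueError("norm_range must be increasing")


@dataclass
class CropRecord:
    """Geometry bookkeeping sufficient to invert trim + crop exactly."""

    original_shape: tuple[int, int, int]
    z_range: tuple[int, int] = (0, 0)            # kept slice range, half-open
    y_range: tuple[int, int] = (0, 0)            # in-plane window, half-open
    x_range: tuple[int, int] = (0, 0)
    pad: tuple[int, int, int, int] = (0, 0, 0, 0)  # (y_lo, y_hi, x_lo, x_hi)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CropRecord":
        d = json.loads(s)
        return cls(original_shape=tuple(d["original_shape"]),
                   z_range=tuple(d["z_range"]),
                   y_range=tuple(d["y_range"]),
                   x_range=tuple(d["x_range"]),
                   pad=tuple(d["pad"]))


@dataclass
class SampleBundle:
    """One training/inference sample for slice ``index``."""

    image2d: np.ndarray     # (M, H, W)
    patch3d: np.ndarray     # (M, 2k+1, H, W)
    label2d: np.ndarray     # (H, W) int codes, resized nearest-neighbour
    index: int


def _content_mask(intensities: np.ndarray, threshold: float) -> np.ndarray:
    """Voxels that count as content: above threshold in any modality."""
    return (intensities > threshold).any(axis=-1)


def trim_blank_slices(vol: LabeledVolume, cfg: PreprocessConfig
                      ) -> tuple[LabeledVolume, CropRecord]:
    """Drop leading/trailing Z-slices with no voxel above blank_threshold."""
    cfg.validate()
    content = _content_mask(vol.intensities, cfg.blank_threshold).any(axis=(1, 2))
    if not content.any():
        raise ValueError("no content slices: every slice is blank")
    nz = np.flatnonzero(content)
    lo, hi = int(nz[0]), int(nz[-1]) + 1
    rec = CropRecord(original_shape=vol.shape, z_range=(lo, hi),
                     y_range=(0, vol.shape[1]), x_range=(0, vol.shape[2]))
    out = LabeledVolume(vol.intensities[lo:hi], vol.labels[lo:hi], vol.spacing)
    return out, rec


def crop_to_content(vol: LabeledVolume, cfg: PreprocessConfig
                    ) -> tuple[LabeledVolume, CropRecord]:
    """Center a crop_size window on the in-plane content bounding box.

    The window is clamped to the volume bounds; if crop_size exceeds the
    volume extent the output is zero-padded symmetrically.
    """
    cfg.validate()
    content = _content_mask(vol.intensities, cfg.blank_threshold)
    if not content.any():
        raise ValueError("no content voxels to crop to")
    ys, xs = np.nonzero(content.any(axis=0))
    cy, cx = (ys.min() + ys.max() + 1) / 2.0, (xs.min() + xs.max() + 1) / 2.0
    H, W = vol.shape[1], vol.shape[2]
    ch, cw = cfg.crop_size

    def _window(center, size, extent):
        lo = int(round(center - size / 2.0))
        lo = min(max(lo, 0), max(extent - size, 0)) if extent >= size else 0
        hi = min(lo + size, extent)
        pad_lo = 0 if extent >= size else (size - extent) // 2
        pad_hi = 0 if extent >= size else size - extent - pad_lo
        return lo, hi, pad_lo, pad_hi

    ylo, yhi, pyl, pyh = _window(cy, ch, H)
    xlo, xhi, pxl, pxh = _window(cx, cw, W)
    ints = vol.intensities[:, ylo:yhi, xlo:xhi]
    labs = vol.labels[:, ylo:yhi, xlo:xhi]
    if pyl or pyh or pxl or pxh:
        ints = np.pad(ints, ((0, 0), (pyl, pyh), (pxl, pxh), (0, 0)))
        labs = np.pad(labs, ((0, 0), (pyl, pyh), (pxl, pxh)))
    rec = CropRecord(original_shape=vol.shape, z_range=(0, vol.shape[0]),
                     y_range=(ylo, yhi), x_range=(xlo, xhi), pad=(pyl, pyh, pxl, pxh))
    return LabeledVolume(ints, labs, vol.spacing), rec


def uncrop_labels(labels: np.ndarray, rec: CropRecord) -> np.ndarray:
    """Re-embed a (trimmed and/or cropped) label volume into original extents."""
    pyl, pyh, pxl, pxh = rec.pad
    inner = labels[:,
                   pyl:labels.shape[1] - pyh or None,
                   pxl:labels.shape[2] - pxh or None]
    out = np.zeros(rec.original_shape, dtype=labels.dtype)
    zlo, zhi = rec.z_range
    out[zlo:zhi, rec.y_range[0]:rec.y_range[1], rec.x_range[0]:rec.x_range[1]] = inner
    return out


def histogram_equalize(vol: LabeledVolume, cfg: PreprocessConfig) -> LabeledVolume:
    """CDF-based contrast enhancement of foreground voxels, per modality.

    Foreground intensities are quantized to ``he_levels`` bins; the
    normalized cumulative histogram maps each bin onto the modality's
    original dynamic range.  Background voxels (<= blank_threshold in
    that modality) are left untouched, so the brain/tumor contrast is
    stretched without letting the air background dominate the histogram.
    """
    cfg.validate()
    out = vol.intensities.astype(np.float64, copy=True)
    for m in range(vol.n_modalities):
        ch = out[..., m]
        fg = ch > cfg.blank_threshold
        if not fg.any():
            continue
        vals = ch[fg]
        vmin, vmax = vals.min(), vals.max()
        if vmax <= vmin:
            continue  # constant foreground: CDF is a step, mapping is constant
        bins = np.clip(((vals - vmin) / (vmax - vmin) * cfg.he_levels).astype(np.int64),
                       0, cfg.he_levels - 1)
        hist = np.bincount(bins, minlength=cfg.he_levels)
        cdf = np.cumsum(hist).astype(np.float64)
        cdf /= cdf[-1]
        ch[fg] = vmin + cdf[bins] * (vmax - vmin)
    return LabeledVolume(out.astype(np.float32), vol.labels, vol.spacing)


def normalize_intensity(vol: LabeledVolume, cfg: PreprocessConfig) -> LabeledVolume:
    """Affine min-max map of each modality onto norm_range (default [-1, 1])."""
    cfg.validate()
    lo, hi = cfg.norm_range
    out = vol.intensities.astype(np.float64, copy=True)
    for m in range(vol.n_modalities):
        ch = out[..., m]
        vmin, vmax = ch.min(), ch.max()
        if vmax <= vmin:
            warnings.warn(f"modality {m} is constant; mapped to range midpoint")
            ch[:] = (lo + hi) / 2.0
        else:
            ch[:] = lo + (ch - vmin) / (vmax - vmin) * (hi - lo)
    return LabeledVolume(out.astype(np.float32), vol.labels, vol.spacing)


def preprocess_volume(vol: LabeledVolume, cfg: PreprocessConfig
                      ) -> tuple[LabeledVolume, CropRecord, CropRecord]:
    """Full chain: trim -> crop -> equalize -> normalize."""
    trimmed, zrec = trim_blank_slices(vol, cfg)
    cropped, crec = crop_to_content(trimmed, cfg)
    crec.z_range = zrec.z_range
    crec.original_shape = zrec.original_shape
    eq = histogram_equalize(cropped, cfg)
    return normalize_intensity(eq, cfg), zrec, crec


def _resize_plane(arr: np.ndarray, size: tuple[int, int], order: int) -> np.ndarray:
    if arr.shape[-2:] == tuple(size):
        return arr
    return resize(arr, arr.shape[:-2] + tuple(size), order=order,
                  anti_aliasing=False, preserve_range=True, mode="edge")


def extract_sample(vol: LabeledVolume, n: int, cfg: PreprocessConfig) -> SampleBundle:
    """Cut the 2D slice ``n`` and its (2k+1)-slice context patch.

    Out-of-range context slices at the two ends of the stack are edge
    replicated.  Every slice of the patch is resized in-plane with the
    same bilinear map, so the patch's middle slice is bit-identical to
    the returned 2D slice.
    """
    cfg.validate()
    Z = vol.shape[0]
    if not 0 <= n < Z:
        raise IndexError(f"slice index {n} out of range [0, {Z})")
    k = cfg.context_halfwidth
    idx = np.clip(np.arange(n - k, n + k + 1), 0, Z - 1)
    planes = []
    for j in idx:
        sl = np.moveaxis(vol.intensities[j], -1, 0)  # (M, H, W)
        planes.append(_resize_plane(sl.astype(np.float32), cfg.input_size, order=1))
    patch = np.stack(planes, axis=1)  # (M, 2k+1, H, W)
    image2d = planes[k]
    label2d = _resize_plane(vol.labels[n].astype(np.float32), cfg.input_size,
                            order=0).astype(vol.labels.dtype)
    return SampleBundle(image2d=image2d, patch3d=patch, label2d=label2d, index=n)
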