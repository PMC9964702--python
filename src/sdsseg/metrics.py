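"""Volumetric segmentation evaluation: Dice, sensitivity, specificity, HD.

Overlap measures are plain voxel counting.  ``specificity`` here is the
prediction-conditioned overlap |pred & ref| / |pred| — i.e. precision —
implemented exactly in that form (the name follows the convention of
the evaluation protocol this package reproduces); the conventional
true-negative rate is available behind ``true_negative_rate``.

Hausdorff distances are computed between the surface voxels of the two
masks (6-connectivity boundary) in physical units via the voxel
spacing.  ``hausdorff95`` replaces each directed maximum with the 95th
percentile (linear interpolation) of the per-point nearest-neighbour
distances, then takes the larger of the two directions.

Empty-mask conventions (logged as warnings): Dice of two empty masks is
1.0; sensitivity is undefined for an empty reference, specificity for
an empty prediction, HD for either — all reported as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .phantom import derive_region_masks

REGION_NAMES = ("WT", "TC", "ET")


def _check_shapes(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    return pred, ref


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice similarity 2|P & R| / (|P| + |R|); both empty -> 1.0."""
    pred, ref = _check_shapes(pred, ref)
    denom = int(pred.sum()) + int(ref.sum())
    if denom == 0:
        warnings.warn("both masks empty: Dice reported as 1.0 by convention")
        return 1.0
    return 2.0 * int((pred & ref).sum()) / denom


def sensitivity(pred: np.ndarray, ref: np.ndarray) -> float:
    """|P & R| / |R|; NaN (with warning) when the reference is empty."""
    pred, ref = _check_shapes(pred, ref)
    nref = int(ref.sum())
    if nref == 0:
        warnings.warn("empty reference: sensitivity undefined (NaN)")
        return float("nan")
    return int((pred & ref).sum()) / nref


def specificity(pred: np.ndarray, ref: np.ndarray) -> float:
    """|P & R| / |P| (precision form); NaN when the prediction is empty."""
    pred, ref = _check_shapes(pred, ref)
    npred = int(pred.sum())
    if npred == 0:
        warnings.warn("empty prediction: specificity undefined (NaN)")
        return float("nan")
    return int((pred & ref).sum()) / npred


#: Alias making the printed-form provenance explicit at call sites.
specificity_paper = specificity


def true_negative_rate(pred: np.ndarray, ref: np.ndarray) -> float:
    """Conventional specificity |~P & ~R| / |~R| (optional extra measure)."""
    pred, ref = _check_shapes(pred, ref)
    nneg = int((~ref).sum())
    if nneg == 0:
        warnings.warn("reference covers the whole volume: TNR undefined (NaN)")
        return float("nan")
    return int((~pred & ~ref).sum()) / nneg


# ---------------------------------------------------------------------------
# Hausdorff distances
# ---------------------------------------------------------------------------

def _as_points(a) -> np.ndarray:
    pts = np.asarray(a, dtype=np.float64)
    if pts.ndim != 2:
        raise ValueError("point sets must be (n_points, n_dims) arrays")
    return pts


def _nn_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Distance from each point of src to its nearest neighbour in dst."""
    return cKDTree(dst).query(src, k=1)[0]


def directed_hausdorff(a, b, spacing=None) -> float:
    """max over a of the distance to the nearest point of b (not symmetric)."""
    a, b = _as_points(a), _as_points(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("directed Hausdorff distance is undefined for empty sets")
    if spacing is not None:
        s = np.asarray(spacing, dtype=np.float64)
        a, b = a * s, b * s
    return float(_nn_distances(a, b).max())


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Surface voxels of a binary mask: set minus its 6-connected erosion."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, mask.ndim), dtype=np.int64)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def _surface_dists(pred: np.ndarray, ref: np.ndarray, spacing):
    pred, ref = _check_shapes(pred, ref)
    if not pred.any() or not ref.any():
        warnings.warn("empty mask: Hausdorff distance undefined (NaN)")
        return None
    spacing = np.ones(pred.ndim) if spacing is None else np.asarray(spacing, dtype=np.float64)
    bp = boundary_voxels(pred) * spacing
    br = boundary_voxels(ref) * spacing
    return _nn_distances(br, bp), _nn_distances(bp, br)


def hausdorff(pred: np.ndarray, ref: np.ndarray, spacing=None) -> float:
    """Symmetric Hausdorff distance between mask surfaces."""
    d = _surface_dists(pred, ref, spacing)
    if d is None:
        return float("nan")
    return float(max(d[0].max(), d[1].max()))


def hausdorff95(pred: np.ndarray, ref: np.ndarray, spacing=None) -> float:
    """95th-percentile Hausdorff distance (linear-interpolated percentile)."""
    d = _surface_dists(pred, ref, spacing)
    if d is None:
        return float("nan")
    return float(max(np.percentile(d[0], 95), np.percentile(d[1], 95)))


# ---------------------------------------------------------------------------
# per-volume report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-region measures for one predicted vs reference volume."""

    values: dict[str, dict[str, float]]   # region -> measure -> value
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    distance_unit: str = "mm"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values).T[["dice", "sensitivity", "specificity",
                                            "hd", "hd95"]]

    def __getitem__(self, region: str) -> dict[str, float]:
        return self.values[region]


def aggregate_reports(reports: list["MetricsReport"]) -> pd.DataFrame:
    """Cohort mean +- standard deviation per region and measure."""
    frames = [r.to_frame() for r in reports]
    stacked = pd.concat(frames, keys=range(len(frames)))
    mean = stacked.groupby(level=1, sort=False).mean()
    std = stacked.groupby(level=1, sort=False).std(ddof=0)
    out = mean.round(4).astype(str) + " ± " + std.round(4).astype(str)
    return out.loc[list(REGION_NAMES)]


def evaluate_volume(pred_labels: np.ndarray, ref_labels: np.ndarray,
                    spacing=(1.0, 1.0, 1.0)) -> MetricsReport:
    """All five measures for the three nested regions of two label volumes."""
    pred_masks = derive_region_masks(pred_labels)
    ref_masks = derive_region_masks(ref_labels)
    values: dict[str, dict[str, float]] = {}
    for region in REGION_NAMES:
        p = getattr(pred_masks, region.lower())
        r = getattr(ref_masks, region.lower())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values[region] = {
                "dice": dice(p, r),
                "sensitivity": sensitivity(p, r),
                "specificity": specificity(p, r),
                "hd": hausdorff(p, r, spacing),
                "hd95": hausdorff95(p, r, spacing),
            }
    return MetricsReport(values=values, spacing=tuple(spacing))
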