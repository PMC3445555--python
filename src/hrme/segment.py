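"""Nuclear segmentation: thresholding, labeling, and object size filtering.

The preprocessed grayscale image is binarized at an adjustable threshold
(initialized by Otsu's method within the ROI), connected components are
labeled under 8-connectivity, and objects with fewer than 50 pixels (noise)
or more than 1500 pixels (debris) are removed.  Both bounds are strict:
objects of exactly 50 or exactly 1500 pixels are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .frame import Frame
from .preprocess import ROIMask

#: strict size bounds, in pixels: objects with fewer than MIN_OBJECT_PX or
#: more than MAX_OBJECT_PX pixels are removed
MIN_OBJECT_PX = 50
MAX_OBJECT_PX = 1500

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SegmentationResult:
    """Binary and labeled nuclear masks with the per-object table.

    ``objects`` has columns label, area_px, centroid_y, centroid_x; labels
    are contiguous positive integers in raster order of each object's first
    pixel, and the object areas sum to the set-pixel count of the mask.
    """

    binary_mask: np.ndarray
    labeled_mask: np.ndarray
    threshold_used: float | None
    objects: pd.DataFrame = field(default_factory=lambda: _empty_table())

    @property
    def nuclear_area_px(self) -> int:
        return int(self.binary_mask.sum())


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({"label": pd.Series(dtype=int),
                         "area_px": pd.Series(dtype=int),
                         "centroid_y": pd.Series(dtype=float),
                         "centroid_x": pd.Series(dtype=float)})


def suggest_threshold(frame: Frame, roi: ROIMask) -> float:
    """Otsu threshold (maximal between-class variance) over ROI pixels only.

    This initializes the study's operator-adjustable threshold; a per-site
    override can replace it downstream.
    """
    if roi.mask.shape != frame.shape:
        raise ValueError("ROI shape does not match frame")
    vals = frame.normalized()[roi.mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    if np.unique(vals).size < 2:
        raise ValueError("ROI is constant: no threshold separates two classes")
    return float(threshold_otsu(vals))


def binarize(frame: Frame, roi: ROIMask, threshold: float) -> np.ndarray:
    """Pixel set iff its intensity is strictly above the threshold and it
    lies inside the ROI."""
    if roi.mask.shape != frame.shape:
        raise ValueError("ROI shape does not match frame")
    return (frame.normalized() > threshold) & roi.mask


def label_objects(mask: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Connected components under 8-connectivity.

    Labels are assigned in raster order of each component's first pixel.
    Returns the labeled image and the object table.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return labeled, _empty_table()
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, index=idx).astype(int)
    centroids = ndimage.center_of_mass(mask, labeled, index=idx)
    table = pd.DataFrame({
        "label": idx,
        "area_px": areas,
        "centroid_y": [c[0] for c in centroids],
        "centroid_x": [c[1] for c in centroids],
    })
    return labeled, table


def filter_objects(labeled_mask: np.ndarray, min_px: int = MIN_OBJECT_PX,
                   max_px: int = MAX_OBJECT_PX,
                   threshold_used: float | None = None) -> SegmentationResult:
    """Remove objects with fewer than ``min_px`` or more than ``max_px``
    pixels; objects of exactly ``min_px`` or ``max_px`` pixels are retained
    (both bounds are strict).  Idempotent: re-filtering the result changes
    nothing.  Survivors are relabeled contiguously in raster order."""
    if min_px > max_px:
        raise ValueError(f"min_px {min_px} exceeds max_px {max_px}")
    labeled_mask = np.asarray(labeled_mask)
    n = int(labeled_mask.max())
    if n == 0:
        empty = np.zeros_like(labeled_mask)
        return SegmentationResult(empty.astype(bool), empty, threshold_used)
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labeled_mask), labeled_mask, index=idx).astype(int)
    keep = (areas >= min_px) & (areas <= max_px)
    drop = np.isin(labeled_mask, idx[~keep])
    binary = (labeled_mask > 0) & ~drop
    relabeled, table = label_objects(binary)
    return SegmentationResult(binary, relabeled, threshold_used, table)


def segment_frame(frame: Frame, roi: ROIMask, *, threshold: float | None = None,
                  min_px: int = MIN_OBJECT_PX, max_px: int = MAX_OBJECT_PX,
                  ) -> SegmentationResult:
    """Full segmentation stage: threshold (Otsu unless overridden), binarize,
    label, size-filter."""
    thr = suggest_threshold(frame, roi) if threshold is None else float(threshold)
    mask = binarize(frame, roi, thr)
    labeled, _ = label_objects(mask)
    return filter_objects(labeled, min_px, max_px, threshold_used=thr)
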