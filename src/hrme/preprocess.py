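"""ROI restriction, CLAHE contrast adjustment, and fiber-pattern removal.

The processing order is fixed: ROI restriction, then contrast-limited
adaptive histogram equalization, then median filtering to suppress the
honeycomb pattern of the fiber bundle.  Pixels outside the FOV are replaced
by a constant before any filtering, so nothing inside the FOV depends on
intensities recorded outside it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw, exposure, morphology

from .frame import Frame


@dataclass
class ROIMask:
    """Operator-chosen region of interest.

    ``provenance`` records where the mask came from: ``"full-FOV"``,
    ``"manual-polygon"`` or ``"file"``.  The mask must be nonempty and lie
    inside the FOV; pixels outside it are excluded from all downstream
    statistics, not merely zeroed.
    """

    mask: np.ndarray
    provenance: str = "full-FOV"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty ROI")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def full_fov(cls, frame: Frame) -> "ROIMask":
        return cls(frame.fov_mask.copy(), provenance="full-FOV")

    @classmethod
    def from_polygon(cls, vertices, shape: tuple[int, int]) -> "ROIMask":
        """Polygon vertices as (x, y) pixel coordinates, origin top-left,
        x rightward, y downward, 0-based."""
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValueError("polygon needs at least three (x, y) vertices")
        # polygon2mask expects (row, col) = (y, x)
        mask = draw.polygon2mask(shape, verts[:, ::-1])
        return cls(mask, provenance="manual-polygon")

    @classmethod
    def from_file(cls, path: str | os.PathLike, shape: tuple[int, int]) -> "ROIMask":
        """Load a polygon vertex list from JSON ([[x, y], ...]) or CSV."""
        path = os.fspath(path)
        if path.lower().endswith(".json"):
            with open(path) as fh:
                verts = json.load(fh)
        else:
            verts = np.loadtxt(path, delimiter=",", ndmin=2)
        roi = cls.from_polygon(verts, shape)
        roi.provenance = "file"
        return roi


def apply_roi(frame: Frame, roi: ROIMask) -> tuple[Frame, ROIMask]:
    """Validate and attach an ROI to a frame.

    The ROI is clipped to the FOV; downstream operations treat pixels outside
    it as excluded.  Raises on shape mismatch or an ROI empty inside the FOV.
    """
    if roi.mask.shape != frame.shape:
        raise ValueError(f"ROI shape {roi.mask.shape} does not match frame {frame.shape}")
    clipped = roi.mask & frame.fov_mask
    if not clipped.any():
        raise ValueError("ROI is empty inside the field of view")
    return frame, ROIMask(clipped, provenance=roi.provenance)


def equalize_contrast(frame: Frame, tile_grid: tuple[int, int] = (8, 8),
                      clip_limit: float = 0.01) -> Frame:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    ``tile_grid`` divides the image into that many tiles per axis;
    ``clip_limit`` is the per-tile histogram clip fraction.  Output stays in
    the [0, 1] dynamic range; pixels outside the FOV are held at 0.
    """
    ty, tx = tile_grid
    if ty < 1 or tx < 1:
        raise ValueError("tile grid dimensions must be positive")
    if not 0 < clip_limit <= 1:
        raise ValueError("clip_limit must be in (0, 1]")
    h, w = frame.shape
    kh, kw = h // ty, w // tx
    if kh < 1 or kw < 1:
        raise ValueError("tile larger than image")
    px = frame.normalized()
    # fill outside the FOV with the inside mean: filter windows near the rim
    # then depend only on intensities recorded inside the FOV
    fill = px[frame.fov_mask].mean()
    px = np.where(frame.fov_mask, px, fill)
    if np.ptp(px[frame.fov_mask]) == 0:
        out = np.where(frame.fov_mask, px, 0.0)  # constant: nothing to equalize
    else:
        out = exposure.equalize_adapthist(np.clip(px, 0, 1), kernel_size=(kh, kw),
                                          clip_limit=clip_limit)
        out = np.where(frame.fov_mask, out, 0.0)
    return Frame(out, pixel_size_um=frame.pixel_size_um, fov_mask=frame.fov_mask)


def remove_fiber_pattern(frame: Frame, kernel_radius_px: int = 3) -> Frame:
    """Median filter over a disc neighborhood to suppress the honeycomb
    pattern of the fiber bundle.

    The default radius is sized to span one fiber core (~0.75 of the 4 px
    core spacing, rounded up) so the periodic pattern is flattened while
    nuclei several pixels across survive.
    """
    if kernel_radius_px < 1:
        raise ValueError("kernel_radius_px must be >= 1")
    px = frame.normalized()
    fill = px[frame.fov_mask].mean()
    px = np.where(frame.fov_mask, px, fill)
    footprint = morphology.disk(kernel_radius_px)
    out = ndimage.median_filter(px, footprint=footprint, mode="nearest")
    out = np.where(frame.fov_mask, out, 0.0)
    return Frame(out, pixel_size_um=frame.pixel_size_um, fov_mask=frame.fov_mask)


def default_median_radius(core_spacing_px: float) -> int:
    """ceil(0.75 * core spacing), the default pattern-removal kernel radius."""
    return int(np.ceil(0.75 * core_spacing_px))


def preprocess(frame: Frame, roi: ROIMask, *, tile_grid: tuple[int, int] = (8, 8),
               clip_limit: float = 0.01, median_radius_px: int = 3,
               median_before_clahe: bool = False) -> tuple[Frame, ROIMask]:
    """Full preprocessing stage: ROI -> CLAHE -> median filter.

    ``median_before_clahe`` swaps the two filters and exists only for
    sensitivity checks; it defaults off and the standard order should be used
    for any quantitative analysis.
    """
    frame, roi = apply_roi(frame, roi)
    steps = [lambda f: equalize_contrast(f, tile_grid, clip_limit),
             lambda f: remove_fiber_pattern(f, median_radius_px)]
    if median_before_clahe:
        steps.reverse()
    for step in steps:
        frame = step(frame)
    return frame, roi
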