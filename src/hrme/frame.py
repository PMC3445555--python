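"""Image containers for microendoscopy frames and movies.

A :class:`Frame` is one grayscale intensity image together with its physical
pixel size and the circular field-of-view (FOV) mask imposed by the imaging
fiber bundle.  A :class:`Movie` is an ordered sequence of same-shaped frames
from a single imaged site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile
import imageio.v3 as iio


def disc_mask(shape: tuple[int, int], diameter_px: float,
              center: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean mask of a disc of the given diameter (pixels), centered by default.

    A pixel belongs to the disc when its center lies within ``diameter_px / 2``
    of the disc center.
    """
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cy, cx = center
    yy, xx = np.ogrid[:h, :w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return r2 <= (diameter_px / 2.0) ** 2


@dataclass
class Frame:
    """One 2-D grayscale intensity image.

    Parameters
    ----------
    pixels
        Non-negative finite intensities, shape ``(rows, cols)``.
    pixel_size_um
        Physical edge length of one pixel, micrometers.
    fov_mask
        Boolean mask of the circular field of view; same shape as ``pixels``.
        If omitted, the largest centered disc is used.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    fov_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Frame pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Frame intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("Frame intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.fov_mask is None:
            self.fov_mask = disc_mask(self.pixels.shape, min(self.pixels.shape))
        self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
        if self.fov_mask.shape != self.pixels.shape:
            raise ValueError("fov_mask shape must match pixels shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def normalized(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] by the dtype dynamic range.

        Integer images divide by the dtype maximum; float images are assumed
        to already live on a [0, 1] dynamic range and are returned unscaled.
        """
        px = self.pixels
        if np.issubdtype(px.dtype, np.integer):
            return px.astype(np.float64) / np.iinfo(px.dtype).max
        return px.astype(np.float64)


@dataclass
class Movie:
    """Ordered frame sequence from one imaged site."""

    frames: list[Frame]
    site_id: str = ""
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("Movie must contain at least one frame")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise ValueError(f"frame {i} shape {f.shape} differs from {shape}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


def save_frame(frame: Frame, path: str | os.PathLike) -> None:
    """Write a frame as a single-channel TIFF/PNG.

    Float frames (dynamic range [0, 1]) are quantized to 16-bit; integer
    frames are written bit-exactly.
    """
    px = frame.pixels
    if np.issubdtype(px.dtype, np.floating):
        px = np.round(np.clip(px, 0.0, 1.0) * 65535).astype(np.uint16)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)


def _read_image(path: str) -> np.ndarray:
    try:
        if path.lower().endswith((".tif", ".tiff")):
            return tifffile.imread(path)
        return np.asarray(iio.imread(path))
    except Exception as exc:
        raise IOError(f"could not read image {path!r}: {exc}") from exc


def load_frames(paths: Sequence[str | os.PathLike], pixel_size_um: float = 1.0,
                fov_mask: np.ndarray | None = None, site_id: str = "") -> Movie:
    """Load raster files of identical shape into a Movie.

    Intensities are preserved bit-exactly.  The FOV mask is inferred as the
    largest centered disc unless supplied.
    """
    frames: list[Frame] = []
    shape: tuple[int, int] | None = None
    for p in paths:
        p = os.fspath(p)
        px = _read_image(p)
        if px.ndim != 2:
            raise IOError(f"{p!r}: expected a single-channel 2-D image, got shape {px.shape}")
        if shape is None:
            shape = px.shape
        elif px.shape != shape:
            raise IOError(f"{p!r}: shape {px.shape} does not match first frame {shape}")
        frames.append(Frame(px, pixel_size_um=pixel_size_um, fov_mask=fov_mask))
    if not frames:
        raise ValueError("no frame paths given")
    return Movie(frames, site_id=site_id)
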