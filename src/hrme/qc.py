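"""Representative-frame selection and quality control.

One representative frame is chosen per movie (maximizing sharpness while
penalizing motion and obstruction), then the site is discarded if more than
half the field of view is out of focus, if there is evidence of motion
artifact, or if the frame contains significant debris.

Focus is defined by resolvability of the fiber-bundle core lattice: the
bundle face sits at a fixed optical conjugate, so whenever the image is in
focus its honeycomb modulation is present everywhere in the field of view,
and defocus removes it together with all other fine structure.  The lattice
spot frequencies are calibrated per frame from the whole-field spectrum and
each tile is then matched-filtered at those exact frequencies; tiles whose
in-focus evidence instead comes from tissue edges are caught by a second,
mid-frequency band-power channel.  All focus statistics are computed on
tiles normalized by their own mean intensity, so QC decisions are invariant
to rescaling the image by any positive constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frame import Frame, Movie


@dataclass(frozen=True)
class QCThresholds:
    """Tunable QC rule parameters.

    Focus channel A (lattice): the three independent reciprocal-lattice
    spot frequencies of the honeycomb (fundamental at ``2 / (sqrt(3) *
    core_spacing_px)`` cycles/px) are located once per frame from the
    whole-field power spectrum; a tile is in focus when the mean matched
    spot power, in units of the tile's high-frequency noise floor, reaches
    ``focus_matched_threshold``.  Channel B (tissue edges): a tile is also
    in focus when its noise-subtracted mid-band variance (relative-contrast
    units) reaches ``focus_excess_threshold``; this rescues tiles whose
    lattice carrier is swamped by strong in-focus nuclear edges.  Both
    default thresholds were calibrated once on synthetic sharp vs.
    defocused fiber-bundle frames and sit several-fold away from either
    class.

    max_out_of_focus_fraction
        Discard when more of the FOV than this is out of focus.
    max_motion_score
        Discard when the frame's best dissimilarity (1 - normalized cross
        correlation) to a temporal neighbor exceeds this.
    max_debris_fraction
        Discard when saturated/occluding blobs larger than ``debris_min_px``
        cover more than this fraction of the FOV.
    """

    tile_px: int = 32
    core_spacing_px: float = 4.0
    focus_matched_threshold: float = 6.0
    focus_excess_threshold: float = 1.5e-3
    max_out_of_focus_fraction: float = 0.5
    max_motion_score: float = 0.3
    max_debris_fraction: float = 0.05
    debris_min_px: int = 1500
    saturation_level: float = 0.98


@dataclass
class QCReport:
    """Outcome of the QC rules for one frame."""

    passed: bool
    out_of_focus_fraction: float
    motion_score: float
    debris_fraction: float
    reasons: list[str] = field(default_factory=list)


def _normalize(frame: Frame) -> np.ndarray:
    """Range-normalize intensities inside the FOV to [0, 1]."""
    px = frame.normalized()
    vals = px[frame.fov_mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros_like(px)
    out = (px - lo) / (hi - lo)
    out[~frame.fov_mask] = 0.0
    return np.clip(out, 0.0, 1.0)


def _lattice_spots(frame: Frame, core_spacing_px: float) -> list[np.ndarray]:
    """Locate the honeycomb's three independent spot frequencies (cycles/px).

    The strongest whole-field spectral peak in an annulus around the
    expected reciprocal-lattice radius gives one spot; the other two follow
    by 60-degree rotations (triangular-lattice symmetry).
    """
    px = frame.normalized()
    fov = frame.fov_mask
    m = px[fov].mean()
    if m <= 0:
        return []
    img = np.where(fov, px, m) / m - 1.0
    h, w = img.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    power = np.abs(np.fft.fft2(img * win)) ** 2
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f_expected = 2.0 / (math.sqrt(3.0) * core_spacing_px)
    annulus = (np.hypot(fy, fx) >= 0.75 * f_expected) & \
              (np.hypot(fy, fx) <= 1.3 * f_expected)
    if not annulus.any():
        return []
    iy, ix = np.unravel_index(np.argmax(np.where(annulus, power, 0.0)), power.shape)
    f1 = np.array([float(fy[iy, 0]), float(fx[0, ix])])

    def rotate(v: np.ndarray, a: float) -> np.ndarray:
        c, s = math.cos(a), math.sin(a)
        return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])

    return [f1, rotate(f1, math.pi / 3), rotate(f1, 2 * math.pi / 3)]


def _tile_focus_map(frame: Frame, thresholds: QCThresholds) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile in-focus flags and a per-tile in-FOV validity mask."""
    t = thresholds.tile_px
    h, w = frame.shape
    if h < t or w < t:
        raise ValueError(f"frame {frame.shape} smaller than one {t}x{t} tile")
    px = frame.normalized()
    ny, nx = h // t, w // t

    spots = _lattice_spots(frame, thresholds.core_spacing_px)
    hann = np.outer(np.hanning(t), np.hanning(t))
    # scale so summed bin power is in variance units of the input tile
    power_scale = t * t * (hann ** 2).sum()
    Y, X = np.mgrid[0:t, 0:t]
    waves = [np.exp(-2j * np.pi * (f[0] * Y + f[1] * X)) * hann for f in spots]

    f0 = t * 2.0 / (math.sqrt(3.0) * thresholds.core_spacing_px)
    fbins = np.fft.fftfreq(t) * t
    rr = np.hypot(*np.meshgrid(fbins, fbins, indexing="ij"))
    nyq = t / 2.0
    # mid band: above the Hann leakage of blurred low-frequency blobs,
    # through the lattice ring; floor band: the highest clean frequencies
    signal_band = (rr >= 6.0) & (rr <= f0 + 1.5)
    hf_band = (rr >= min(f0 + 2.5, nyq * 0.8)) & (rr <= nyq * 0.95)

    in_focus = np.zeros((ny, nx), dtype=bool)
    valid = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            sl = (slice(i * t, (i + 1) * t), slice(j * t, (j + 1) * t))
            fov = frame.fov_mask[sl]
            valid[i, j] = fov.mean() >= 0.5
            if not fov.any():
                continue
            mean = px[sl][fov].mean()
            if mean <= 0:
                continue  # dark tile: nothing resolvable
            tile = np.where(fov, px[sl], mean) / mean - 1.0  # relative contrast
            power = np.abs(np.fft.fft2(tile * hann)) ** 2 / power_scale
            # robust white-noise floor per bin (median of ~exponential bins)
            mu = np.median(power[hf_band]) / math.log(2.0) + 1e-30
            lattice_ok = False
            if waves:
                matched = np.mean([abs((tile * w_).sum()) ** 2 / power_scale
                                   for w_ in waves])
                # absolute guard: with negligible noise the floor vanishes,
                # and spectral leakage alone must not count as a lattice
                lattice_ok = (matched >= thresholds.focus_matched_threshold * mu
                              and matched >= 1e-5)
            excess = power[signal_band].sum() - mu * signal_band.sum()
            in_focus[i, j] = lattice_ok or excess >= thresholds.focus_excess_threshold
    return in_focus, valid


def sharpness_fraction(frame: Frame, thresholds: QCThresholds = QCThresholds()) -> float:
    """Fraction of in-FOV tiles that are in focus."""
    in_focus, valid = _tile_focus_map(frame, thresholds)
    if not valid.any():
        return 0.0
    return float(in_focus[valid].mean())


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Normalized cross-correlation of two frames inside a mask; 0 when
    either has zero variance."""
    av, bv = a[mask], b[mask]
    sa, sb = av.std(), bv.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((av - av.mean()) * (bv - bv.mean())).mean() / (sa * sb))


def motion_score(movie: Movie, index: int) -> float:
    """Dissimilarity (1 - NCC) to the best-matching temporally adjacent frame.

    Zero for a single-frame movie.  Using the *minimum* dissimilarity over
    the neighbors means a frame is only penalized when it matches neither
    neighbor, so appending a degenerate (e.g. all-black) frame can never
    change an existing frame's score.
    """
    neighbors = [j for j in (index - 1, index + 1) if 0 <= j < len(movie)]
    if not neighbors:
        return 0.0
    f = movie[index]
    norm_i = _normalize(f)
    best = min(1.0 - _ncc(norm_i, _normalize(movie[j]), f.fov_mask) for j in neighbors)
    return max(0.0, best)


def debris_fraction(frame: Frame, thresholds: QCThresholds = QCThresholds()) -> float:
    """Fraction of the FOV covered by large saturated/occluding blobs."""
    norm = _normalize(frame)
    candidate = (norm >= thresholds.saturation_level) & frame.fov_mask
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0.0
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    big = areas[areas > thresholds.debris_min_px].sum()
    return float(big / frame.fov_mask.sum())


def qc_evaluate(frame: Frame, thresholds: QCThresholds = QCThresholds(), *,
                movie: Movie | None = None, frame_index: int | None = None) -> QCReport:
    """Apply the discard rules to one frame.

    The motion rule needs movie context (pass ``movie`` and ``frame_index``);
    for an isolated frame the motion score is 0.
    """
    in_focus, valid = _tile_focus_map(frame, thresholds)
    oof = float((~in_focus[valid]).mean()) if valid.any() else 1.0
    mot = motion_score(movie, frame_index) if movie is not None and frame_index is not None else 0.0
    deb = debris_fraction(frame, thresholds)

    reasons = []
    if oof > thresholds.max_out_of_focus_fraction:
        reasons.append("out_of_focus")
    if mot > thresholds.max_motion_score:
        reasons.append("motion_artifact")
    if deb > thresholds.max_debris_fraction:
        reasons.append("debris")
    return QCReport(passed=not reasons, out_of_focus_fraction=oof,
                    motion_score=mot, debris_fraction=deb, reasons=reasons)


def select_frame(movie: Movie, thresholds: QCThresholds = QCThresholds()) -> int:
    """Index of the representative frame: maximal sharpness minus motion and
    obstruction penalties; ties broken by the lowest index."""
    if len(movie) == 0:
        raise ValueError("empty movie")
    best_idx, best_score = 0, -np.inf
    for i, f in enumerate(movie.frames):
        score = (sharpness_fraction(f, thresholds)
                 - motion_score(movie, i)
                 - debris_fraction(f, thresholds))
        if score > best_score:
            best_idx, best_score = i, score
    return best_idx
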