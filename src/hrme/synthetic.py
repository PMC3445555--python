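"""Synthetic fiber-bundle microendoscopy frames, movies, and cohorts.

Renders proflavine-like fluorescence frames with known ground truth: bright,
non-overlapping nuclei on a dimmer cytoplasmic background, multiplied by the
honeycomb modulation of a coherent imaging fiber bundle, with optional shot
and read noise, defocus blur, and saturated debris.  Every rendered frame
carries a :class:`SyntheticTruth` whose nuclear mask and true N/C ratio are
exact pixel counts, so downstream segmentation and metrics can be validated
against ground truth.

A whole study cohort can be sampled: each imaged site receives a
histopathologic diagnosis, a diagnostic category, and a true N/C ratio drawn
from a per-category Beta distribution.  A configurable fraction of sites is
rendered with quality-control-failing frames (mostly-defocused field of view)
to exercise the QC stage.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .frame import Frame, Movie, disc_mask, save_frame
from .labels import DIAGNOSES, category_of, is_neoplastic


# --------------------------------------------------------------------------
# fiber bundle geometry and honeycomb pattern
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberBundleSpec:
    """Geometry of the imaging fiber bundle and the sampled pixel grid.

    Defaults model a bundle with a 720 µm circular field of view and ~4 µm
    core-to-core spacing (the lateral resolution limit), sampled at 1 µm per
    pixel so the FOV disc is 720 px across.

    ``pattern_amplitude`` is the peak fractional modulation of the honeycomb
    core pattern (0 disables it).
    """

    fov_diameter_um: float = 720.0
    pixel_size_um: float = 1.0
    core_spacing_um: float = 4.0
    core_diameter_um: float = 2.5
    pattern_amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.fov_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("fov_diameter_um and pixel_size_um must be positive")
        if self.core_diameter_um > self.core_spacing_um:
            raise ValueError("core_diameter_um must not exceed core_spacing_um")
        if not 0 <= self.pattern_amplitude <= 1:
            raise ValueError("pattern_amplitude must be in [0, 1]")

    @property
    def fov_diameter_px(self) -> float:
        return self.fov_diameter_um / self.pixel_size_um

    @property
    def core_spacing_px(self) -> float:
        return self.core_spacing_um / self.pixel_size_um

    @property
    def shape(self) -> tuple[int, int]:
        n = int(round(self.fov_diameter_px))
        return (n, n)

    def fov_mask(self) -> np.ndarray:
        return disc_mask(self.shape, self.fov_diameter_px)


def core_centers(spec: FiberBundleSpec) -> np.ndarray:
    """Fiber-core centers on a triangular lattice inside the FOV disc.

    Returns an ``(n, 2)`` array of (row, col) pixel coordinates.  The lattice
    has nearest-neighbor spacing ``core_spacing_px`` with alternate rows
    offset by half a spacing (row pitch ``spacing * sqrt(3)/2``).
    """
    s = spec.core_spacing_px
    n = spec.shape[0]
    cy = cx = (n - 1) / 2.0
    radius = spec.fov_diameter_px / 2.0
    row_pitch = s * math.sqrt(3) / 2.0
    n_rows = int(math.ceil(radius / row_pitch)) + 1
    pts = []
    for i in range(-n_rows, n_rows + 1):
        y = cy + i * row_pitch
        x_off = (s / 2.0) if (i % 2) else 0.0
        n_cols = int(math.ceil(radius / s)) + 1
        for j in range(-n_cols, n_cols + 1):
            x = cx + j * s + x_off
            if (y - cy) ** 2 + (x - cx) ** 2 <= radius ** 2:
                pts.append((y, x))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def make_fiber_pattern(spec: FiberBundleSpec) -> np.ndarray:
    """Honeycomb modulation image: unity mean inside the FOV, zero outside.

    Cores are rendered as Gaussian bumps at the triangular-lattice centers;
    the bump field is rescaled so the peak deviation from the mean equals
    ``pattern_amplitude`` and renormalized to exactly unit mean in the FOV.
    """
    if spec.core_spacing_px < 1.0:
        raise ValueError("core spacing below one pixel: pattern unresolvable at this sampling")
    fov = spec.fov_mask()
    if spec.pattern_amplitude == 0:
        return np.where(fov, 1.0, 0.0)
    shape = spec.shape
    impulses = np.zeros(shape)
    centers = core_centers(spec)
    # bilinear splat so subpixel core positions render smoothly
    for y, x in centers:
        iy, ix = int(math.floor(y)), int(math.floor(x))
        fy, fx = y - iy, x - ix
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                yy, xx = iy + dy, ix + dx
                if 0 <= yy < shape[0] and 0 <= xx < shape[1]:
                    impulses[yy, xx] += wy * wx
    sigma = (spec.core_diameter_um / spec.pixel_size_um) / 2.0
    bumps = ndimage.gaussian_filter(impulses, sigma, mode="constant")
    mu = bumps[fov].mean()
    dev = bumps - mu
    peak = np.abs(dev[fov]).max()
    pattern = 1.0 + spec.pattern_amplitude * dev / peak
    pattern[~fov] = 0.0
    pattern[fov] /= pattern[fov].mean()
    return pattern


# --------------------------------------------------------------------------
# single-frame rendering with ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusSpec:
    """One rendered nucleus: an ellipse of a given pixel area.

    ``radius`` is the equivalent circular radius (the ellipse has the same
    area); ``eccentricity`` in [0, 1) sets the axis ratio.
    """

    center: tuple[float, float]
    radius: float
    peak_intensity: float = 0.75
    eccentricity: float = 0.0
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("nucleus radius must be positive")
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must be in [0, 1)")

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(major, minor) semi-axes preserving area pi * radius**2."""
        q = (1 - self.eccentricity ** 2) ** 0.25
        return self.radius / q, self.radius * q


@dataclass
class SyntheticTruth:
    """Ground truth for a rendered frame.

    ``true_nc_ratio`` is exactly nuclear-pixel count over (ROI pixel count
    minus nuclear-pixel count), both within ``roi_mask``.
    """

    nuclear_mask: np.ndarray
    roi_mask: np.ndarray
    true_nc_ratio: float

    def recompute_nc(self) -> float:
        n = int(np.count_nonzero(self.nuclear_mask & self.roi_mask))
        r = int(np.count_nonzero(self.roi_mask))
        return n / (r - n)


@dataclass(frozen=True)
class NoiseModel:
    """Shot (Poisson) plus Gaussian read noise, both optional.

    ``shot_scale`` is the photon count corresponding to full-scale intensity
    (0 disables shot noise); ``read_sd`` is the read-noise standard deviation
    as a fraction of the dynamic range.
    """

    shot_scale: float = 2000.0
    read_sd: float = 0.01

    @staticmethod
    def off() -> "NoiseModel":
        return NoiseModel(shot_scale=0.0, read_sd=0.0)


def _ellipse_footprint(shape, center, a, b, angle) -> np.ndarray:
    """Boolean mask of an ellipse, evaluated at pixel centers."""
    cy, cx = center
    r = max(a, b) + 1.5
    y0, y1 = max(0, int(cy - r)), min(shape[0], int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r)), min(shape[1], int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = local
    return out


def _place_nuclei(target_nc: float, roi: np.ndarray, rng: np.random.Generator,
                  radius_range: tuple[float, float], eccentricity_max: float,
                  peak_intensity: float, tol: float = 0.002,
                  max_attempts: int = 300) -> tuple[np.ndarray, list[NucleusSpec]]:
    """Place non-overlapping elliptical nuclei until the pixel-counted N/C
    ratio is within ``tol`` of ``target_nc``.  Raises if the target exceeds
    what rejection sampling can pack."""
    roi_area = int(np.count_nonzero(roi))
    if roi_area == 0:
        raise ValueError("empty ROI")
    target_px = target_nc / (1.0 + target_nc) * roi_area
    if target_px / roi_area > 0.45:
        raise ValueError(
            f"requested N/C {target_nc} exceeds the packing limit of non-overlapping nuclei")
    mask = np.zeros(roi.shape, dtype=bool)
    nuclei: list[NucleusSpec] = []
    centers: list[tuple[float, float]] = []
    bound_radii: list[float] = []
    rmin, rmax = radius_range
    ys, xs = np.nonzero(roi)
    placed = 0

    def nc_of(npx: int) -> float:
        return npx / (roi_area - npx)

    while True:
        remaining = target_px - placed
        if abs(nc_of(placed) - target_nc) <= tol or remaining <= 0:
            break
        r = float(rng.uniform(rmin, rmax))
        if math.pi * r * r > remaining:
            r = max(rmin, math.sqrt(remaining / math.pi))
        ecc = float(rng.uniform(0.0, eccentricity_max))
        angle = float(rng.uniform(0.0, math.pi))
        q = (1 - ecc ** 2) ** 0.25
        a, b = r / q, r * q
        placed_this = False
        for _ in range(max_attempts):
            k = int(rng.integers(len(ys)))
            cy, cx = float(ys[k]), float(xs[k])
            if centers:
                d2 = (np.asarray(centers) - [cy, cx]) ** 2
                min_ok = np.asarray(bound_radii) + a + 1.0
                if np.any(d2.sum(axis=1) < min_ok ** 2):
                    continue
            fp = _ellipse_footprint(roi.shape, (cy, cx), a, b, angle)
            if not np.array_equal(fp & roi, fp):
                continue  # nucleus would cross the ROI / FOV boundary
            mask |= fp
            nuclei.append(NucleusSpec((cy, cx), r, peak_intensity, ecc, angle))
            centers.append((cy, cx))
            bound_radii.append(a)
            placed += int(fp.sum())
            placed_this = True
            break
        if not placed_this:
            if abs(nc_of(placed) - target_nc) <= tol:
                break
            raise ValueError(
                f"could not place nuclei to reach N/C {target_nc} "
                f"(stuck at {nc_of(placed):.4f}); target may exceed the packing limit")
    return mask, nuclei


def render_frame(target_nc: float, spec: FiberBundleSpec = FiberBundleSpec(), *,
                 noise: NoiseModel = NoiseModel(), seed: int | np.random.Generator = 0,
                 roi: np.ndarray | None = None,
                 radius_range: tuple[float, float] = (5.0, 9.0),
                 eccentricity_max: float = 0.4,
                 background: float = 0.25, nucleus_peak: float = 0.75,
                 blur_sigma: float = 0.0, blur_mask: np.ndarray | None = None,
                 debris_area_px: int = 0,
                 pattern: np.ndarray | None = None,
                 ) -> tuple[Frame, SyntheticTruth]:
    """Render one frame at a requested true N/C ratio.

    The returned truth's ``true_nc_ratio`` is the exact pixel-counted ratio,
    guaranteed within 0.005 (absolute) of ``target_nc``.  ``blur_mask`` (or a
    global ``blur_sigma`` with no mask) applies Gaussian defocus;
    ``debris_area_px`` adds one saturated elliptical blob of roughly that
    area, outside the nuclei.

    frame = (background + nuclei) * fiber_pattern + noise, clipped to [0, 1].
    """
    if target_nc < 0:
        raise ValueError("target N/C must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fov = spec.fov_mask()
    if roi is None:
        roi = fov
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != fov.shape:
        raise ValueError("roi shape must match the rendered frame shape")
    if np.any(roi & ~fov):
        raise ValueError("roi must lie inside the FOV mask")

    if target_nc == 0:
        nuc_mask = np.zeros(spec.shape, dtype=bool)
        nuclei: list[NucleusSpec] = []
    else:
        nuc_mask, nuclei = _place_nuclei(
            target_nc, roi, rng, radius_range, eccentricity_max, nucleus_peak)

    scene = np.where(fov, background, 0.0)
    scene[nuc_mask] = nucleus_peak

    if debris_area_px > 0:
        r_deb = math.sqrt(debris_area_px / math.pi)
        for _ in range(500):
            k_y = rng.uniform(r_deb, spec.shape[0] - r_deb)
            k_x = rng.uniform(r_deb, spec.shape[1] - r_deb)
            fp = _ellipse_footprint(spec.shape, (k_y, k_x), r_deb * 1.2, r_deb / 1.2,
                                    float(rng.uniform(0, math.pi)))
            fp &= fov
            if not np.any(fp & nuc_mask) and fp.sum() > debris_area_px * 0.5:
                scene[fp] = 1.0
                break

    if pattern is None:
        pattern = make_fiber_pattern(spec)
    img = scene * pattern

    if blur_mask is not None:
        sig = blur_sigma if blur_sigma > 0 else 6.0
        blurred = ndimage.gaussian_filter(img, sig)
        img = np.where(blur_mask, blurred, img)
    elif blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)

    if noise.shot_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * noise.shot_scale) / noise.shot_scale
    if noise.read_sd > 0:
        img = img + rng.normal(0.0, noise.read_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    img[~fov] = 0.0

    frame = Frame(img, pixel_size_um=spec.pixel_size_um, fov_mask=fov)
    n = int(np.count_nonzero(nuc_mask & roi))
    r_area = int(np.count_nonzero(roi))
    truth = SyntheticTruth(nuclear_mask=nuc_mask, roi_mask=roi,
                           true_nc_ratio=n / (r_area - n))
    return frame, truth


def render_movie(target_nc: float, spec: FiberBundleSpec = FiberBundleSpec(), *,
                 n_frames: int = 5, noise: NoiseModel = NoiseModel(),
                 seed: int | np.random.Generator = 0,
                 motion_schedule: list[tuple[int, int]] | None = None,
                 blur_schedule: list[float] | None = None,
                 blur_fraction: float = 0.0,
                 site_id: str = "", **render_kw,
                 ) -> tuple[Movie, SyntheticTruth]:
    """Render a short movie of one site.

    The underlying tissue scene is fixed; ``motion_schedule`` gives a per-frame
    integer (dy, dx) translation of the tissue under the (static) fiber
    bundle, and ``blur_schedule`` a per-frame defocus sigma.  When
    ``blur_fraction`` > 0 the blur is confined to a region covering that
    fraction of the FOV (same region in every frame), otherwise it is global.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if motion_schedule is None:
        motion_schedule = [(0, 0)] * n_frames
    if blur_schedule is None:
        blur_schedule = [0.0] * n_frames
    if len(motion_schedule) != n_frames or len(blur_schedule) != n_frames:
        raise ValueError("schedules must have one entry per frame")

    fov = spec.fov_mask()
    # noiseless pattern-free tissue scene; the bundle pattern is static and is
    # applied after per-frame motion of the tissue underneath it
    unit_pattern = np.where(fov, 1.0, 0.0)
    base_frame, truth = render_frame(target_nc, spec, noise=NoiseModel.off(),
                                     seed=rng, pattern=unit_pattern, **render_kw)
    scene = base_frame.pixels.astype(float)
    pattern = make_fiber_pattern(spec)

    blur_region = None
    if blur_fraction > 0:
        blur_region = disc_mask(spec.shape, spec.fov_diameter_px * math.sqrt(blur_fraction))
        blur_region &= fov

    frames = []
    for (dy, dx), sig in zip(motion_schedule, blur_schedule):
        sc = np.roll(scene, (dy, dx), axis=(0, 1))
        sc[~fov] = 0.0
        img = sc * pattern
        if sig > 0:
            blurred = ndimage.gaussian_filter(img, sig)
            img = np.where(blur_region, blurred, img) if blur_region is not None else blurred
        if noise.shot_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * noise.shot_scale) / noise.shot_scale
        if noise.read_sd > 0:
            img = img + rng.normal(0.0, noise.read_sd, img.shape)
        img = np.clip(img, 0.0, 1.0)
        img[~fov] = 0.0
        frames.append(Frame(img, pixel_size_um=spec.pixel_size_um, fov_mask=fov))
    return Movie(frames, site_id=site_id), truth


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------

#: per-diagnosis site counts of the study cohort (44 analyzable sites)
DEFAULT_SITE_COUNTS = {
    "Normal": 5, "Inflammation": 7, "HPV effect": 11,
    "CIN 1": 7, "CIN 2": 2, "CIN 3": 12,
}

#: per-diagnosis true N/C distribution means, anchored at the printed
#: exemplars (HPV-effect-like ~0.08, CIN 3-like ~0.22)
DEFAULT_NC_MEANS = {
    "Normal": 0.06, "Inflammation": 0.07, "HPV effect": 0.08,
    "CIN 1": 0.10, "CIN 2": 0.19, "CIN 3": 0.22,
}

DEFAULT_NC_SDS = {
    "Normal": 0.015, "Inflammation": 0.015, "HPV effect": 0.02,
    "CIN 1": 0.025, "CIN 2": 0.03, "CIN 3": 0.03,
}


@dataclass
class CohortSimConfig:
    """Configuration of a simulated study cohort.

    ``site_counts`` are the analyzable (QC-passing) sites per diagnosis.
    ``artifact_fraction`` is the fraction of *all rendered* sites that are
    rendered with QC-failing frames; the corresponding number of extra sites
    is added on top of ``site_counts`` so the analyzable mix is preserved.
    True N/C per site is drawn from a Beta distribution with the per-diagnosis
    mean and sd (sd 0 means every site sits exactly at the mean).
    """

    site_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SITE_COUNTS))
    nc_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NC_MEANS))
    nc_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NC_SDS))
    artifact_fraction: float = 0.0
    sites_per_patient: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for d, c in self.site_counts.items():
            if d not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {d!r}")
            if c < 0:
                raise ValueError("site counts must be non-negative")
        for d, m in self.nc_means.items():
            if not 0 < m < 1:
                raise ValueError(f"nc mean for {d!r} must be in (0, 1)")
        if not 0 <= self.artifact_fraction < 1:
            raise ValueError("artifact_fraction must be in [0, 1)")

    @property
    def n_clean(self) -> int:
        return sum(self.site_counts.values())

    @property
    def n_artifact(self) -> int:
        f = self.artifact_fraction
        return int(round(f / (1.0 - f) * self.n_clean)) if f > 0 else 0


def _draw_nc(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    var = sd * sd
    max_var = mean * (1 - mean)
    if var >= max_var:
        raise ValueError(f"sd {sd} too large for Beta with mean {mean}")
    kappa = max_var / var - 1.0
    return float(rng.beta(mean * kappa, (1 - mean) * kappa))


def sample_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Sample the cohort ledger: one row per imaged site.

    Columns: site_id, patient_id, histopath_diagnosis, category, neoplastic,
    true_nc, artifact, render_seed.  Fully determined by ``config.seed``.
    """
    if config.n_clean == 0:
        raise ValueError("empty cohort: all site counts are zero")
    rng = np.random.default_rng(config.seed)
    rows = []
    for diag in DIAGNOSES:
        for _ in range(config.site_counts.get(diag, 0)):
            rows.append({"histopath_diagnosis": diag, "artifact": False})
    # extra sites rendered to fail QC; diagnoses drawn from the clean mix
    diags = list(config.site_counts)
    weights = np.array([config.site_counts[d] for d in diags], dtype=float)
    weights /= weights.sum()
    for _ in range(config.n_artifact):
        rows.append({"histopath_diagnosis": str(rng.choice(diags, p=weights)),
                     "artifact": True})
    df = pd.DataFrame(rows)
    df["category"] = df["histopath_diagnosis"].map(category_of)
    df["neoplastic"] = df["category"].map(is_neoplastic)
    df["true_nc"] = [
        _draw_nc(rng, config.nc_means[d], config.nc_sds.get(d, 0.0))
        for d in df["histopath_diagnosis"]
    ]
    df["site_id"] = [f"site{i:03d}" for i in range(len(df))]
    df["patient_id"] = [f"pt{i // config.sites_per_patient:03d}" for i in range(len(df))]
    df["render_seed"] = rng.integers(0, 2 ** 31 - 1, size=len(df))
    cols = ["site_id", "patient_id", "histopath_diagnosis", "category",
            "neoplastic", "true_nc", "artifact", "render_seed"]
    return df[cols].reset_index(drop=True)


def render_site(row: pd.Series | dict, spec: FiberBundleSpec = FiberBundleSpec(), *,
                noise: NoiseModel = NoiseModel(), n_frames: int = 5,
                pattern: np.ndarray | None = None,
                ) -> tuple[Movie, SyntheticTruth]:
    """Render the movie for one ledger row.

    Artifact sites are rendered with ~70% of the FOV defocused in every frame
    plus inter-frame motion, so they fail downstream quality control.
    """
    seed = int(row["render_seed"])
    if bool(row.get("artifact", False)):
        rng = np.random.default_rng(seed)
        motion = [(0, 0)] + [tuple(rng.integers(-8, 9, 2)) for _ in range(n_frames - 1)]
        motion = [(int(a), int(b)) for a, b in motion]
        return render_movie(float(row["true_nc"]), spec, n_frames=n_frames,
                            noise=noise, seed=seed, motion_schedule=motion,
                            blur_schedule=[6.0] * n_frames, blur_fraction=0.72,
                            site_id=str(row["site_id"]))
    if pattern is not None and n_frames == 1:
        frame, truth = render_frame(float(row["true_nc"]), spec, noise=noise,
                                    seed=seed, pattern=pattern)
        return Movie([frame], site_id=str(row["site_id"])), truth
    return render_movie(float(row["true_nc"]), spec, n_frames=n_frames,
                        noise=noise, seed=seed, site_id=str(row["site_id"]))


def simulate_cohort_to_disk(config: CohortSimConfig, outdir: str | os.PathLike,
                            spec: FiberBundleSpec = FiberBundleSpec(), *,
                            noise: NoiseModel = NoiseModel(), n_frames: int = 5,
                            ) -> pd.DataFrame:
    """Render a whole cohort to TIFF sequences plus a ledger CSV.

    Returns the ledger (also written to ``<outdir>/ledger.csv``) with a
    ``movie_path`` column pointing at each site's frame directory.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    ledger = sample_cohort(config)
    paths = []
    for _, row in ledger.iterrows():
        site_dir = os.path.join(outdir, str(row["site_id"]))
        os.makedirs(site_dir, exist_ok=True)
        movie, _ = render_site(row, spec, noise=noise, n_frames=n_frames)
        for i, fr in enumerate(movie.frames):
            save_frame(fr, os.path.join(site_dir, f"frame{i:03d}.tif"))
        paths.append(site_dir)
    ledger = ledger.copy()
    ledger["movie_path"] = paths
    ledger["pixel_size_um"] = spec.pixel_size_um
    ledger.to_csv(os.path.join(outdir, "ledger.csv"), index=False)
    return ledger
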