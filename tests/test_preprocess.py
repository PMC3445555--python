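"""Preprocessing: ROI semantics, CLAHE, fiber-pattern median removal."""

import numpy as np
import pytest
from scipy import ndimage

from hrme.frame import Frame
from hrme.preprocess import (ROIMask, apply_roi, default_median_radius,
                             equalize_contrast, preprocess,
                             remove_fiber_pattern)
from hrme.segment import binarize, segment_frame
from hrme.metrics import nc_ratio
from hrme.synthetic import (FiberBundleSpec, NoiseModel, make_fiber_pattern,
                            render_frame)


# ---------------------------------------------------------------- ROI

def test_full_fov_roi_matches_unmasked_analysis(clean_frame):
    frame, truth = clean_frame
    seg_full = segment_frame(frame, ROIMask.full_fov(frame))
    seg_same = segment_frame(frame, ROIMask(frame.fov_mask.copy()))
    assert np.array_equal(seg_full.binary_mask, seg_same.binary_mask)


def test_half_roi_of_uniform_frame_leaves_nc_unchanged(flat_spec):
    # uniform nucleus density: restricting to half the FOV moves the measured
    # N/C by less than 0.01 (pixel-count oracle on the ground-truth masks)
    frame, truth = render_frame(0.15, flat_spec, seed=21, noise=NoiseModel.off())
    half = truth.roi_mask.copy()
    half[:, half.shape[1] // 2:] = False
    n_half = int((truth.nuclear_mask & half).sum())
    nc_half = n_half / (half.sum() - n_half)
    assert nc_half == pytest.approx(truth.true_nc_ratio, abs=0.01)
    # and the pipeline agrees with the oracle on that half
    seg = segment_frame(frame, ROIMask(half))
    res = nc_ratio(seg, ROIMask(half))
    assert res.nc_ratio == pytest.approx(nc_half, abs=1e-12)


def test_roi_excludes_saturated_blob(flat_spec):
    frame, truth = render_frame(0.1, flat_spec, seed=22, noise=NoiseModel.off(),
                                debris_area_px=2000)
    blob = (frame.pixels >= 0.99) & frame.fov_mask
    assert blob.sum() > 1000
    roi = ROIMask(truth.roi_mask & ~blob)
    seg = segment_frame(frame, roi, threshold=0.5)
    assert not np.any(seg.binary_mask & blob)


def test_empty_roi_rejected(clean_frame):
    frame, _ = clean_frame
    with pytest.raises(ValueError):
        ROIMask(np.zeros(frame.shape, dtype=bool))
    outside = np.zeros(frame.shape, dtype=bool)
    outside[0, 0] = True  # corner: outside the FOV disc
    with pytest.raises(ValueError, match="field of view"):
        apply_roi(frame, ROIMask(outside))


def test_roi_shape_mismatch_rejected(clean_frame):
    frame, _ = clean_frame
    with pytest.raises(ValueError, match="shape"):
        apply_roi(frame, ROIMask(np.ones((10, 10), dtype=bool)))


def test_polygon_roi_pixel_convention():
    # x rightward, y downward, 0-based: a right-triangle polygon covers the
    # expected half of its bounding box
    roi = ROIMask.from_polygon([(0, 0), (40, 0), (0, 40)], shape=(50, 50))
    assert roi.mask[5, 5]
    assert not roi.mask[35, 35]


# ---------------------------------------------------------------- CLAHE

def test_clahe_constant_image_unchanged():
    frame = Frame(np.full((64, 64), 0.4))
    out = equalize_contrast(frame)
    inside = frame.fov_mask
    assert np.allclose(out.pixels[inside], frame.pixels[inside])


def test_clahe_output_within_dynamic_range(noisy_frame):
    frame, _ = noisy_frame
    out = equalize_contrast(frame)
    assert out.pixels.min() >= 0.0
    assert out.pixels.max() <= 1.0
    assert out.shape == frame.shape


def test_clahe_increases_two_class_separation(flat_spec):
    # low-contrast frame: nuclei only 10% above background; CLAHE must widen
    # the between-class variance (ground-truth classes as the oracle)
    frame, truth = render_frame(0.12, flat_spec, seed=4,
                                noise=NoiseModel(shot_scale=0, read_sd=0.005),
                                background=0.5, nucleus_peak=0.55)

    def between_class_variance(f):
        nuc = f.pixels[truth.nuclear_mask]
        cyt = f.pixels[truth.roi_mask & ~truth.nuclear_mask]
        p = nuc.size / (nuc.size + cyt.size)
        return p * (1 - p) * (nuc.mean() - cyt.mean()) ** 2

    out = equalize_contrast(frame)
    assert between_class_variance(out) > between_class_variance(frame)


def test_clahe_tile_larger_than_image_rejected():
    frame = Frame(np.random.default_rng(0).random((32, 32)))
    with pytest.raises(ValueError):
        equalize_contrast(frame, tile_grid=(64, 64))


def test_clahe_ignores_pixels_outside_fov(small_spec):
    # intensities recorded outside the FOV must not influence the result
    frame, _ = render_frame(0.1, small_spec, seed=30)
    tampered = frame.pixels.copy()
    tampered[~frame.fov_mask] = 0.9
    out_a = equalize_contrast(frame)
    out_b = equalize_contrast(Frame(tampered, fov_mask=frame.fov_mask))
    assert np.array_equal(out_a.pixels[frame.fov_mask],
                          out_b.pixels[frame.fov_mask])


# ---------------------------------------------------------------- median

def test_median_constant_image_unchanged():
    frame = Frame(np.full((64, 64), 0.3))
    out = remove_fiber_pattern(frame, 3)
    assert np.allclose(out.pixels[frame.fov_mask], 0.3)


@pytest.mark.parametrize("radius,max_ratio", [(3, 0.35), (4, 0.10)])
def test_median_suppresses_fiber_pattern(radius, max_ratio):
    # oracle: peak-to-trough of the periodic (high-pass) component of the
    # filtered pure-pattern image, away from the FOV rim.  The default
    # radius-3 disc spans ~1 lattice cell and leaves ~0.25 of the modulation;
    # a radius-4 disc spans two cells and reaches the 10% level.
    spec = FiberBundleSpec(fov_diameter_um=240, pattern_amplitude=0.3)
    img = np.clip(make_fiber_pattern(spec) * 0.5, 0, 1)
    frame = Frame(img, fov_mask=spec.fov_mask())
    out = remove_fiber_pattern(frame, radius)
    interior = ((np.arange(240)[:, None] - 119.5) ** 2
                + (np.arange(240)[None, :] - 119.5) ** 2) <= 80 ** 2

    def periodic_ptp(x):
        hp = x - ndimage.gaussian_filter(x, 4.0)
        return np.ptp(hp[interior])

    assert periodic_ptp(out.pixels) <= max_ratio * periodic_ptp(img)


def test_median_preserves_nucleus_mask_area(flat_spec):
    # radius-6 nuclei keep >= 90% of their area after the default filter
    frame, truth = render_frame(0.1, flat_spec, seed=3, noise=NoiseModel.off(),
                                radius_range=(6.0, 6.0))
    out = remove_fiber_pattern(frame, 3)
    mask = binarize(out, ROIMask(truth.roi_mask), 0.5)
    retained = (mask & truth.nuclear_mask).sum() / truth.nuclear_mask.sum()
    assert retained >= 0.90


def test_median_radius_default_spans_a_core():
    assert default_median_radius(4.0) == 3
    assert default_median_radius(2.0) == 2


def test_median_requires_positive_radius(clean_frame):
    frame, _ = clean_frame
    with pytest.raises(ValueError):
        remove_fiber_pattern(frame, 0)


# ---------------------------------------------------------------- pipeline

def test_preprocess_order_is_roi_clahe_median(noisy_frame):
    frame, truth = noisy_frame
    roi = ROIMask(truth.roi_mask)
    out, _ = preprocess(frame, roi)
    staged = remove_fiber_pattern(equalize_contrast(apply_roi(frame, roi)[0]), 3)
    assert np.array_equal(out.pixels, staged.pixels)
    # the reorder flag changes the result and defaults off
    swapped, _ = preprocess(frame, roi, median_before_clahe=True)
    assert not np.array_equal(out.pixels, swapped.pixels)


def test_preprocess_rerun_is_deterministic(noisy_frame):
    frame, truth = noisy_frame
    roi = ROIMask(truth.roi_mask)
    a, _ = preprocess(frame, roi)
    b, _ = preprocess(frame, roi)
    assert np.array_equal(a.pixels, b.pixels)
    # re-running each stage on its own output is safe (not idempotent)
    again = remove_fiber_pattern(equalize_contrast(a), 3)
    assert again.shape == frame.shape
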