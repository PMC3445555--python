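"""Synthetic generator: fiber pattern geometry, cohort sampling, rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from hrme.frame import disc_mask
from hrme.synthetic import (CohortSimConfig, DEFAULT_SITE_COUNTS, FiberBundleSpec,
                            NoiseModel, SyntheticTruth, core_centers,
                            make_fiber_pattern, render_frame, render_movie,
                            sample_cohort)


# ---------------------------------------------------------------- pattern

def test_zero_amplitude_pattern_is_unity_inside_fov(small_spec):
    spec = FiberBundleSpec(fov_diameter_um=small_spec.fov_diameter_um,
                           pattern_amplitude=0.0)
    pat = make_fiber_pattern(spec)
    fov = spec.fov_mask()
    assert np.all(pat[fov] == 1.0)
    assert np.all(pat[~fov] == 0.0)


def test_fov_disc_diameter_matches_physical_size():
    # 720 um FOV sampled at 1 um/px: the mask spans 720 px in both axes
    spec = FiberBundleSpec(fov_diameter_um=720.0, pixel_size_um=1.0)
    fov = spec.fov_mask()
    rows = np.nonzero(fov.any(axis=1))[0]
    cols = np.nonzero(fov.any(axis=0))[0]
    assert rows[-1] - rows[0] + 1 == 720
    assert cols[-1] - cols[0] + 1 == 720


def test_core_count_matches_lattice_density(small_spec):
    # brute-force enumeration vs FOV area / triangular-lattice cell area
    centers = core_centers(small_spec)
    s = small_spec.core_spacing_px
    cell_area = s * s * math.sqrt(3.0) / 2.0
    expected = math.pi * (small_spec.fov_diameter_px / 2.0) ** 2 / cell_area
    assert abs(len(centers) - expected) / expected < 0.05


def test_pattern_has_unit_mean_and_bounded_modulation(small_spec):
    pat = make_fiber_pattern(small_spec)
    fov = small_spec.fov_mask()
    assert pat[fov].mean() == pytest.approx(1.0, abs=1e-12)
    assert np.all(pat[~fov] == 0.0)
    assert pat[fov].min() > 0


def test_unresolvable_core_spacing_rejected():
    spec = FiberBundleSpec(fov_diameter_um=64, pixel_size_um=8.0,
                           core_spacing_um=4.0, core_diameter_um=2.0)
    with pytest.raises(ValueError, match="unresolvable"):
        make_fiber_pattern(spec)


# ---------------------------------------------------------------- cohort

def test_default_cohort_matches_study_site_counts():
    ledger = sample_cohort(CohortSimConfig(seed=3))
    assert len(ledger) == 44
    counts = ledger["histopath_diagnosis"].value_counts().to_dict()
    assert counts == DEFAULT_SITE_COUNTS
    # category grouping and neoplastic flag follow the label map
    high = ledger[ledger["category"] == "High Grade"]
    assert len(high) == 14
    assert high["neoplastic"].all()
    assert not ledger[ledger["category"] != "High Grade"]["neoplastic"].any()


def test_zero_dispersion_draws_sit_at_category_means():
    cfg = CohortSimConfig(nc_sds={d: 0.0 for d in DEFAULT_SITE_COUNTS}, seed=1)
    ledger = sample_cohort(cfg)
    for _, row in ledger.iterrows():
        assert row["true_nc"] == cfg.nc_means[row["histopath_diagnosis"]]


def test_cohort_determinism_and_seed_sensitivity():
    a = sample_cohort(CohortSimConfig(seed=7))
    b = sample_cohort(CohortSimConfig(seed=7))
    c = sample_cohort(CohortSimConfig(seed=8))
    pd.testing.assert_frame_equal(a, b)
    # same diagnosis mix, different N/C draws
    assert (a["histopath_diagnosis"] == c["histopath_diagnosis"]).all()
    assert not np.allclose(a["true_nc"], c["true_nc"])


def test_empty_cohort_rejected():
    with pytest.raises(ValueError, match="empty cohort"):
        sample_cohort(CohortSimConfig(
            site_counts={d: 0 for d in DEFAULT_SITE_COUNTS}))


def test_artifact_fraction_adds_extra_sites():
    cfg = CohortSimConfig(artifact_fraction=8 / 52, seed=2)
    ledger = sample_cohort(cfg)
    assert len(ledger) == 52
    assert int(ledger["artifact"].sum()) == 8


# ---------------------------------------------------------------- frames

def test_zero_nc_renders_no_nuclei(flat_spec):
    frame, truth = render_frame(0.0, flat_spec, seed=1, noise=NoiseModel.off())
    assert not truth.nuclear_mask.any()
    assert truth.true_nc_ratio == 0.0
    assert frame.pixels[frame.fov_mask].std() == 0.0


@pytest.mark.parametrize("target", [0.08, 0.22])
def test_exemplar_nc_values_renderable_within_tolerance(small_spec, target):
    # the two printed exemplar ratios must render within 0.005 absolute
    _, truth = render_frame(target, small_spec, seed=int(target * 100))
    assert truth.true_nc_ratio == pytest.approx(target, abs=0.005)


def test_truth_nc_is_exact_pixel_count(noisy_frame):
    _, truth = noisy_frame
    assert truth.true_nc_ratio == truth.recompute_nc()


def test_midpoint_threshold_recovers_mask_exactly(clean_frame):
    # noiseless, pattern-free, flat-top nuclei: thresholding at the midpoint
    # between background and peak reproduces the ground-truth mask pixel-wise
    frame, truth = clean_frame
    mask = (frame.pixels > 0.5) & frame.fov_mask
    assert np.array_equal(mask, truth.nuclear_mask)


def test_nuclei_confined_to_fov_and_roi(noisy_frame, small_spec):
    _, truth = noisy_frame
    fov = small_spec.fov_mask()
    assert not np.any(truth.nuclear_mask & ~truth.roi_mask)
    assert not np.any(truth.roi_mask & ~fov)


def test_packing_limit_raises():
    spec = FiberBundleSpec(fov_diameter_um=120)
    with pytest.raises(ValueError, match="packing limit"):
        render_frame(0.9, spec, seed=0)


def test_render_determinism(small_spec):
    f1, t1 = render_frame(0.1, small_spec, seed=9)
    f2, t2 = render_frame(0.1, small_spec, seed=9)
    assert np.array_equal(f1.pixels, f2.pixels)
    assert np.array_equal(t1.nuclear_mask, t2.nuclear_mask)


def test_halving_pixel_size_preserves_nc_and_scales_areas():
    coarse = FiberBundleSpec(fov_diameter_um=160, pixel_size_um=1.0)
    fine = FiberBundleSpec(fov_diameter_um=160, pixel_size_um=0.5)
    _, t_c = render_frame(0.12, coarse, seed=4, noise=NoiseModel.off(),
                          radius_range=(5.0, 8.0))
    _, t_f = render_frame(0.12, fine, seed=4, noise=NoiseModel.off(),
                          radius_range=(10.0, 16.0))
    assert t_f.roi_mask.sum() / t_c.roi_mask.sum() == pytest.approx(4.0, rel=0.02)
    assert t_f.true_nc_ratio == pytest.approx(t_c.true_nc_ratio, abs=0.005)


# ---------------------------------------------------------------- movies

def test_static_movie_frames_identical_up_to_noise(small_spec):
    movie, _ = render_movie(0.1, small_spec, n_frames=3, seed=2,
                            noise=NoiseModel.off())
    assert np.array_equal(movie[0].pixels, movie[1].pixels)
    assert np.array_equal(movie[1].pixels, movie[2].pixels)


def test_motion_schedule_translates_scene_under_static_pattern(small_spec):
    movie, _ = render_movie(0.15, small_spec, n_frames=2, seed=3,
                            noise=NoiseModel.off(),
                            motion_schedule=[(0, 0), (5, 0)])
    a, b = movie[0].pixels, movie[1].pixels
    assert not np.array_equal(a, b)
    # the tissue scene moves under the static bundle pattern: dividing the
    # pattern back out, the first frame shifted by (5, 0) matches the second
    pat = make_fiber_pattern(small_spec)
    fov = movie[0].fov_mask
    interior = disc_mask(a.shape, small_spec.fov_diameter_px * 0.5) & fov
    scene_a = np.where(pat > 0, a / np.where(pat > 0, pat, 1.0), 0.0)
    scene_b = np.where(pat > 0, b / np.where(pat > 0, pat, 1.0), 0.0)
    diff = np.abs(np.roll(scene_a, (5, 0), axis=(0, 1)) - scene_b)[interior]
    assert np.median(diff) < 1e-9


def test_movie_needs_at_least_one_frame(small_spec):
    with pytest.raises(ValueError):
        render_movie(0.1, small_spec, n_frames=0)
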