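"""Shared fixtures: small fiber-bundle geometries and pre-rendered frames.

Most tests run on a 240 µm field of view (240 px at the default 1 µm
sampling) so the whole suite stays fast; geometry-independent behavior is
identical to the full 720 µm bundle.
"""

from __future__ import annotations

import numpy as np
import pytest

from hrme.synthetic import FiberBundleSpec, NoiseModel, render_frame
from hrme.preprocess import ROIMask


@pytest.fixture(scope="session")
def small_spec() -> FiberBundleSpec:
    """240 µm FOV bundle with the default honeycomb pattern."""
    return FiberBundleSpec(fov_diameter_um=240.0)


@pytest.fixture(scope="session")
def flat_spec() -> FiberBundleSpec:
    """240 µm FOV bundle with the honeycomb pattern disabled."""
    return FiberBundleSpec(fov_diameter_um=240.0, pattern_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_frame(flat_spec):
    """Noiseless, pattern-free frame at true N/C 0.15 with ground truth."""
    frame, truth = render_frame(0.15, flat_spec, seed=5, noise=NoiseModel.off())
    return frame, truth


@pytest.fixture(scope="session")
def noisy_frame(small_spec):
    """Default-noise patterned frame at true N/C 0.12 with ground truth."""
    frame, truth = render_frame(0.12, small_spec, seed=12)
    return frame, truth


@pytest.fixture()
def full_roi(clean_frame) -> ROIMask:
    frame, _ = clean_frame
    return ROIMask.full_fov(frame)
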