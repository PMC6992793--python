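"""Shared fixtures: small synthetic slides and cohorts, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from wsitile.preprocess import detect_tissue
from wsitile.synthetic import SyntheticSpec, generate_slide


def small_spec(**overrides) -> SyntheticSpec:
    """A compact slide spec for fast unit tests."""
    base = dict(
        slide_width_px=1792,
        slide_height_px=1536,
        region_radius_px=(280, 340),
        false_positive_speck_rate=0.0,
        seed=7,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def small_slide(tmp_path_factory):
    """One small slide carrying all three labelled regions."""
    spec = small_spec(
        slide_width_px=2048,
        slide_height_px=1792,
        region_radius_px=(240, 300),
    )
    record = generate_slide(spec, "trilabel", tmp_path_factory.mktemp("slide"))
    return spec, record


@pytest.fixture(scope="session")
def small_slide_image(small_slide):
    _, record = small_slide
    return np.asarray(record.load_image())


@pytest.fixture(scope="session")
def small_slide_mask(small_slide_image):
    return detect_tissue(small_slide_image)
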