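"""Shared fixtures: synthetic slides are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from psrmorph import (
    ClassMap,
    SlideSpec,
    classify_pixels,
    detect_fat,
    generate_slide,
)


@pytest.fixture(scope="session")
def rv_slide():
    """A vessel- and fat-bearing free-wall slide with ground truth."""
    spec = SlideSpec(
        width_px=512,
        height_px=512,
        collagen_frac=0.15,
        fat_frac=0.12,
        n_vessels=3,
        rng_seed=7,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def rv_classified(rv_slide):
    """Classified + fat-detected map for the session slide."""
    slide, _ = rv_slide
    return detect_fat(classify_pixels(slide))


def toy_map(labels: np.ndarray, um_per_px: float = 1.0) -> ClassMap:
    return ClassMap(np.asarray(labels, dtype=np.uint8), um_per_px)
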