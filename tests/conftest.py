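"""Shared fixtures: small synthetic datasets and reference table excerpts."""

from __future__ import annotations

import numpy as np
import pytest

from posefall import GeneratorConfig, generate_dataset, prepare_features

# Reference excerpt of a keypoint table: raw and min-max-normalized nose
# coordinates for the first three frames of a fall clip.  The first two
# (raw, normalized) pairs per axis pin down the affine map; the third pair is
# the held-out check value.
REFERENCE_NOSE_ROWS = {
    "x": {"raw": (0.379765, 0.362753, 0.362748), "norm": (0.374411, 0.353146, 0.353140)},
    "y": {"raw": (0.553287, 0.185408, 0.185095), "norm": (0.569179, 0.244493, 0.244216)},
    "z": {"raw": (0.208805, -0.32835, -0.30977), "norm": (0.685071, 0.346481, 0.358191)},
}


@pytest.fixture(scope="session")
def small_dataset():
    """4 clips per class, enough to exercise every pipeline stage."""
    return generate_dataset(GeneratorConfig(clips_per_class=4, seed=11))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return prepare_features(small_dataset, seed=7)


@pytest.fixture(scope="session")
def tiny_features():
    """10 clips per class: big enough for a meaningful train/val/test split."""
    ds = generate_dataset(GeneratorConfig(clips_per_class=10, seed=5))
    return prepare_features(ds, seed=6)
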