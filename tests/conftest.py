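"""Shared fixtures: small structured operators and seeded generators."""

import numpy as np
import pytest

from auxgibbs.linops import (
    CirculantMap2D,
    DenseMap,
    DiagonalMap,
    build_wavelet_frame,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_circulant():
    kernel = np.array([[0.0, 1.0, 0.0], [1.0, 4.0, 1.0], [0.0, 1.0, 0.0]]) / 8.0
    return CirculantMap2D(kernel, (8, 8))


@pytest.fixture
def small_frame():
    return build_wavelet_frame("sym3", 2, (16, 16))


@pytest.fixture
def dense_8x8(rng):
    return DenseMap(0.4 * rng.standard_normal((8, 8)))


@pytest.fixture
def diag_8(rng):
    return DiagonalMap(rng.uniform(0.2, 1.5, 8))
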