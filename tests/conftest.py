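"""Shared fixtures: small deterministic phantoms and landmark sets."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from probeloc.phantom import make_phantom, presets
from probeloc.warp import LandmarkSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def affine_landmarks():
    """Landmark pairs generated by a known affine map, plus the map itself."""
    rng = np.random.default_rng(7)
    mov = rng.uniform(0, 1000, (10, 3))
    A = np.array([[1.1, 0.02, 0.0], [0.0, 0.95, 0.01], [0.03, 0.0, 1.05]])
    b = np.array([10.0, -5.0, 3.0])
    fix = mov @ A.T + b
    lm = LandmarkSet(mov, fix, moving_space="subject", fixed_space="atlas")
    return lm, A, b


from probeloc.phantom import BlobSpec

SMALL_GEOM = dict(
    shape=(60, 150, 60),  # 1.2 x 3.0 x 1.2 mm at 20 um
    n_penetrations=2,
    n_landmarks=120,
    n_stims=40,
    insertion_depth_um=(1600.0, 1800.0),
    blobs=(
        BlobSpec(dv_um=1300.0, sigma_um=110.0, latency_ms=2.0),
        BlobSpec(dv_um=1900.0, sigma_um=90.0, latency_ms=6.0),
    ),
    anchor_labels=("CTX/cc", "cc/HPF"),
    seed=5,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A miniature phantom brain: fast enough for per-test use."""
    spec = dataclasses.replace(presets()["realistic"], **SMALL_GEOM)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def exact_small_phantom():
    """Noise-free miniature phantom (affine deformation, no jitter)."""
    spec = dataclasses.replace(presets()["exact"], **SMALL_GEOM, )
    return make_phantom(spec)
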