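"""Shared fixtures: geometries and cached system matrices at three scales."""

from __future__ import annotations

import numpy as np
import pytest

from epdmct import (
    ProjectionGeometry,
    build_system_matrix,
    shepp_logan_phantom,
    simulate_sinogram,
)


@pytest.fixture(scope="session")
def small_problem():
    """16x16 consistent problem (24 views x 24 bins): phantom, A, sinogram."""
    geom = ProjectionGeometry(n_views=24, n_bins=24, image_size=16)
    A = build_system_matrix(geom)
    phantom = shepp_logan_phantom(16)
    sino = simulate_sinogram(A, phantom)
    return phantom, A, sino


@pytest.fixture(scope="session")
def mid_problem():
    """64x64 consistent problem (90 views x 92 bins), half the standard scale."""
    geom = ProjectionGeometry(n_views=90, n_bins=92, image_size=64)
    A = build_system_matrix(geom)
    phantom = shepp_logan_phantom(64)
    sino = simulate_sinogram(A, phantom)
    return phantom, A, sino


@pytest.fixture(scope="session")
def full_problem():
    """The standard 128x128 geometry: 180 views x 184 bins, 33,120 rays."""
    geom = ProjectionGeometry(n_views=180, n_bins=184, image_size=128)
    A = build_system_matrix(geom)
    phantom = shepp_logan_phantom(128)
    sino = simulate_sinogram(A, phantom)
    return phantom, A, sino


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
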