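"""Shared fixtures: small grids and cases so the suite stays fast."""

import numpy as np
import pytest

from lgequant import GridSpec, ImageStack, ScarSpec, make_sa_case


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """Compact short-axis grid for unit tests."""
    return GridSpec(n_slices=3, shape=(96, 96), endo_radius_px=14.0, epi_radius_px=22.0)


@pytest.fixture(scope="session")
def clean_wedge_case(small_grid):
    """Noise-free, blur-free, heterogeneity-free transmural wedge case."""
    spec = ScarSpec(
        pattern="ischemic_wedge",
        angular_extent_deg=60.0,
        transmurality_fraction=1.0,
        slices_involved=(0, 1, 2),
        psf_sigma_px=0.0,
        texture_sigma=0.0,
        scar_texture_sigma=0.0,
        shading_amplitude=0.0,
    )
    return make_sa_case(small_grid, spec, seed=0)


@pytest.fixture(scope="session")
def default_case(small_grid):
    """A realistic small case with blur, texture and shading at defaults."""
    spec = ScarSpec(slices_involved=(0, 1, 2))
    return make_sa_case(small_grid, spec, seed=3)


@pytest.fixture()
def flat_stack() -> ImageStack:
    """Uniform single-slice stack for metric arithmetic tests."""
    return ImageStack(voxels=np.full((1, 64, 64), 100.0))
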