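"""Shared fixtures: coarse channel-flow solves and small synthetic scenes.

Solver fixtures use a shortened domain and coarser mesh than the analysis
defaults so the suite stays fast; the acceptance tests run the default-sized
problems.
"""

import numpy as np
import pytest

from perfushear.fluids import (
    ChannelGeometry,
    FluidProperties,
    MeshSpec,
    NoduleGeometry,
    PorousProperties,
    solve_channel_flow,
)
from perfushear.quant import calibrate_threshold
from perfushear.synth import (
    SceneSpec,
    ZStackMosaic,
    plant_nodules,
    render_calibration_pair,
)


@pytest.fixture(scope="session")
def geom_short():
    return ChannelGeometry(height_h=250e-6, domain_length_x=1.2e-3)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def empty_field(geom_short, fluid):
    return solve_channel_flow(geom_short, fluid,
                              mesh=MeshSpec(target_cell_size=5e-6))


@pytest.fixture(scope="session")
def nodule_sphere():
    """Spherical nodule: a = b = 40 µm, 60 µm protrusion (centre z0=20 µm)."""
    return NoduleGeometry()


@pytest.fixture(scope="session")
def solid_field(geom_short, fluid, nodule_sphere):
    return solve_channel_flow(geom_short, fluid, nodule_sphere,
                              PorousProperties.solid(),
                              MeshSpec(target_cell_size=4e-6))


@pytest.fixture(scope="session")
def porous_field(geom_short, fluid, nodule_sphere):
    return solve_channel_flow(geom_short, fluid, nodule_sphere,
                              PorousProperties(),
                              MeshSpec(target_cell_size=4e-6))


# --------------------------------------------------------------------------
# synthetic imaging fixtures (small acquisition grids)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_spec():
    """A 4x2 grid of 256-pixel tiles, 4 planes: seconds to quantify."""
    return SceneSpec(tile_size=256, grid_cols=4, grid_rows=2, z_planes=4,
                     nodule_count=14, area_min_um2=900.0, area_max_um2=6000.0,
                     seed=11)


@pytest.fixture(scope="session")
def small_spec_noiseless(small_spec):
    from dataclasses import replace
    return replace(small_spec, poisson_scale=0.0, gaussian_sd=0.0)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    scene, ledger = plant_nodules(small_spec)
    return scene, ledger


@pytest.fixture(scope="session")
def small_mosaic(small_scene):
    return ZStackMosaic(small_scene[0])


@pytest.fixture(scope="session")
def calib(small_spec):
    live, dead = render_calibration_pair(small_spec)
    return calibrate_threshold(live, dead)


def boundary_ring_um2(nodules, pixel_size_um):
    """Total one-pixel boundary-ring area budget for a set of ellipses.

    Uses Ramanujan's ellipse perimeter approximation; the ring is one pixel
    wide on each side of the rasterised boundary.
    """
    total = 0.0
    for n in nodules:
        a, b = n.semi_x_um, n.semi_y_um
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        total += 2.0 * perim * pixel_size_um
    return total
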