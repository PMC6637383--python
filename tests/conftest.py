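import numpy as np
import pytest

import myowalk as mw


@pytest.fixture(scope="session")
def cuboid_block():
    return mw.make_cuboid_block(target_ecv=0.25)


@pytest.fixture(scope="session")
def cuboid_lattice(cuboid_block):
    return mw.assemble_lattice(cuboid_block)


@pytest.fixture(scope="session")
def small_histology():
    """Reduced-size synthetic histology raster (fast tests)."""
    return mw.synthesize_histology(target_ecs=0.38, roi_um=(150.0, 120.0),
                                   n_sheetlets=3, seed=1)


@pytest.fixture(scope="session")
def small_block(small_histology):
    r = small_histology
    return mw.extrude_block(
        mw.polygonize(r), seed=2, axial_margin=5.0, side_segment=15.0,
        extent_xy=(r.shape[1] * r.pixel_size, r.shape[0] * r.pixel_size))


@pytest.fixture(scope="session")
def small_lattice(small_block):
    return mw.assemble_lattice(mw.apply_sinusoid(small_block, 5.0))


@pytest.fixture(scope="session")
def three_cell_block():
    """Tiny three-prism block for oracle comparisons."""
    footprints = [
        mw.Footprint(np.array([[6.0, 6.0], [14.0, 7.0], [10.0, 14.0]]), 1, 0),
        mw.Footprint(np.array([[20.0, 6.0], [30.0, 6.0], [30.0, 16.0],
                               [20.0, 16.0]]), 2, 0),
        mw.Footprint(np.array([[8.0, 22.0], [16.0, 20.0], [20.0, 27.0],
                               [14.0, 34.0], [7.0, 30.0]]), 3, 0),
    ]
    return mw.extrude_block(footprints, length_range=(18.0, 24.0), seed=5,
                            extent_xy=(40.0, 40.0), depth=30.0)


def fit_from_runs(lattice, kind, g_max, d_ic, d_ec, n_particles, seed,
                  compartments=("all",)):
    """Convenience wrapper used across tests."""
    return mw.simulate_tensors(lattice, kind, g_max, d_ic, d_ec,
                               n_particles, seed, compartments=compartments)
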