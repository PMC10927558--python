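"""Shared fixtures: one default desk-scale scene, generated once per session."""
import numpy as np
import pytest

import wetch4 as w


@pytest.fixture(scope="session")
def grid():
    return w.GridSpec()


@pytest.fixture(scope="session")
def cfg():
    return w.TruthConfig(seed=1)


@pytest.fixture(scope="session")
def scene(grid, cfg):
    """Default-noise scene: (drivers, wetlands, truth, sites)."""
    drivers = w.generate_drivers(grid, cfg)
    wetlands = w.generate_wetlands(grid, cfg)
    truth = w.generate_truth_flux(drivers, wetlands, cfg)
    sites = w.sample_sites(truth, wetlands, n_ec=30, n_chamber=40, cfg=cfg)
    return drivers, wetlands, truth, sites


@pytest.fixture(scope="session")
def tiny_grid():
    """Small fast grid for pipeline-level tests: 4 x 6 cells, 4 years."""
    return w.GridSpec(lat_min=60, lat_max=62, lon_min=60, lon_max=63,
                      time_start="2002-01-01", time_end="2006-01-01")


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (keeps tests order-independent)."""
    return np.random.default_rng(12345)
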