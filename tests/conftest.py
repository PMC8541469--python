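"""Shared fixtures: geometry and session-scoped simulated acquisitions.

The simulations are the expensive part of the suite, so the acquisitions
several test modules need are produced once per session at reduced but
statistically sufficient counts.
"""

import numpy as np
import pytest

from petew.config import PipelineConfig
from petew.evaluate import simulate_cylinder_series
from petew.geometry import LORBinner, ScannerGeometry, VirtualPixelGrid
from petew.simulator import (Phantom, SourceComponent, SourceDistribution,
                             cylinder_fixture, out_of_fov_fixture,
                             simulate_acquisition)


@pytest.fixture(scope="session")
def geom() -> ScannerGeometry:
    return ScannerGeometry()


@pytest.fixture(scope="session")
def binner(geom) -> LORBinner:
    return LORBinner(geom, VirtualPixelGrid(2.0, geom.block_width,
                                            geom.block_height))


@pytest.fixture(scope="session")
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def cylinder_sets(pipeline_cfg):
    """Seven-radius water-cylinder ensemble, ~12k accepted events each."""
    return simulate_cylinder_series(pipeline_cfg, seed=1234,
                                    target_accepted=12_000,
                                    max_decays=10_000_000)


@pytest.fixture(scope="session")
def cyl160_large(pipeline_cfg):
    """160 mm cylinder at the count level the window purities need."""
    phantom, source = cylinder_fixture(160.0)
    return simulate_acquisition(phantom, source, pipeline_cfg.geometry,
                                n_decays=40_000_000, seed=4321,
                                target_accepted=100_000,
                                max_decays=40_000_000)


@pytest.fixture(scope="session")
def oof_set(pipeline_cfg):
    """Out-of-FOV fixture acquisition (tall source and phantom)."""
    phantom, source = out_of_fov_fixture()
    return simulate_acquisition(phantom, source, pipeline_cfg.geometry,
                                n_decays=20_000_000, seed=999,
                                target_accepted=30_000,
                                max_decays=20_000_000)


@pytest.fixture(scope="session")
def air_point_source_full_absorption(geom):
    """Point source at the isocentre, no phantom, ideal full-energy deposit."""
    phantom = Phantom(())
    source = SourceDistribution((SourceComponent((0, 0, 0), 0.01, 0.01), ))
    return simulate_acquisition(phantom, source, geom, n_decays=300_000,
                                seed=7, detector_model="full_absorption")


def make_random_listmode(geom, n=500, seed=0, with_truth=True,
                         energy_range=(350.0, 650.0)):
    """Synthetic list-mode set with uniformly random valid fields."""
    from petew.listmode import ListModeSet
    rng = np.random.default_rng(seed)
    block = np.stack([rng.integers(0, geom.n_blocks, n),
                      rng.integers(0, geom.n_blocks, n)], axis=1)
    u = rng.uniform(-geom.block_width / 2, geom.block_width / 2, (n, 2))
    v = rng.uniform(-geom.block_height / 2, geom.block_height / 2, (n, 2))
    doi = rng.uniform(0, geom.block_depth, (n, 2))
    energy = rng.uniform(*energy_range, (n, 2))
    kw = {}
    if with_truth:
        nscat = rng.integers(0, 3, (n, 2))
        kw = dict(scattered=nscat > 0, n_scatters=nscat,
                  origin_in_fov=rng.uniform(size=n) < 0.7,
                  source_id=rng.integers(0, 2, n),
                  origin_z=rng.uniform(-80, 80, n).astype(np.float32))
    return ListModeSet(geom, block=block,
                       u=u.astype(np.float32), v=v.astype(np.float32),
                       doi=doi.astype(np.float32),
                       energy=energy.astype(np.float32),
                       time=np.arange(n, dtype=float), **kw)
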