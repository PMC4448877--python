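"""Shared fixtures: one small synthetic world reused across test modules."""

import pytest

from ballastrisk.synthetic import (
    FleetConfig,
    GroundTruth,
    TrafficConfig,
    WorldConfig,
    ballast_voyage_table,
    gen_ballast_census,
    gen_fleet,
    gen_voyages,
    gen_world,
)


@pytest.fixture(scope="session")
def small_world():
    return gen_world(WorldConfig(n_ecoregions=6, ports_per_ecoregion=2, n_islands=3, seed=11))


@pytest.fixture(scope="session")
def small_fleet():
    return gen_fleet(FleetConfig(n_vessels=150), seed=12)


@pytest.fixture(scope="session")
def small_voyages(small_world, small_fleet):
    cfg = TrafficConfig(years=(1999, 2004), base_intensity=1.5)
    return gen_voyages(small_world, small_fleet, cfg, seed=13)


@pytest.fixture(scope="session")
def clean_truth():
    """Ground truth with no corruption and no provenance mismatches."""
    return GroundTruth(corruption_rate=0.0, provenance_mismatch_rate=0.0)


@pytest.fixture(scope="session")
def small_census(small_voyages, small_fleet, small_world, clean_truth):
    _, ports, _ = small_world
    return gen_ballast_census(small_voyages, small_fleet, clean_truth, seed=14, ports=ports)


@pytest.fixture(scope="session")
def small_ballast_voyages(small_census, small_voyages):
    return ballast_voyage_table(small_census, small_voyages)
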