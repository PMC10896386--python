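"""Shared fixtures: one small simulated dataset + its on-disk bundle.

The simulation is session-scoped; tests that need different parameters
build their own configs.
"""

import numpy as np
import pytest

from mozpopgen import io
from mozpopgen.simulate import (
    PANEL_GAMB_VS_COLU,
    PANEL_GC_VS_ARAB,
    CohortSpec,
    SimulationConfig,
    simulate_genotype_dataset,
    write_fixture_bundle,
)


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        cohorts=[
            CohortSpec("Turkana", 2019, 1, 3.717, 34.857,
                       {"arabiensis": 30, "gambiae": 20, "coluzzii": 50}),
            CohortSpec("Bamako", 2014, 7, 12.64, -8.0, {"coluzzii": 20}),
        ],
        n_variants=4000,
        n_aim_sites={PANEL_GC_VS_ARAB: 400, PANEL_GAMB_VS_COLU: 300},
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim():
    return simulate_genotype_dataset(small_config())


@pytest.fixture(scope="session")
def bundle(sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(sim, out)


@pytest.fixture(scope="session")
def dataset(bundle):
    return io.read_genotype_dataset(bundle.vcf, bundle.metadata, bundle.mask)


@pytest.fixture(scope="session")
def panels(bundle):
    return io.read_aim_panels(bundle.aims)


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: deterministic regardless
    # of which subset of the suite runs
    return np.random.default_rng(20240215)
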