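"""Shared fixtures: small phantoms and the paper-scale dictionary.

Expensive objects (the full-resolution dictionary, replicate pipelines,
the reduced error sweep) are session-scoped so acceptance tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from srcsep import RunConfig, build_dictionary, generate_phantom
from srcsep.evaluation import run_replicate, sweep_curves
from srcsep.sequences import TSEParams


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    """A 40x40x32 grid config for fast unit tests."""
    return RunConfig(grid_shape=(40, 40, 32), voxel_size=(1.5, 1.5, 2.5),
                     n_replicates=2)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_phantom(small_config, seed=7)


@pytest.fixture(scope="session")
def noiseless_config() -> RunConfig:
    """Default-size phantom with no texture and no noise."""
    return RunConfig(texture_sd_chi=0.0, texture_sd_r2=0.0,
                     noise_sd_tse=0.0, noise_sd_mege=0.0)


@pytest.fixture(scope="session")
def full_dictionary():
    """Dictionary at the reference grids (T2 step 0.1 ms, B1 step 0.005)."""
    return build_dictionary(TSEParams())


@pytest.fixture(scope="session")
def sweep_config() -> RunConfig:
    """Reduced sweep: 3 replicates, 5 scaling factors, both Dr modes."""
    return RunConfig(n_replicates=3,
                     error_factors=(0.75, 0.85, 1.05, 1.15, 1.25),
                     dr_modes=("default", "regressed"))


@pytest.fixture(scope="session")
def sweep_replicates(sweep_config, full_dictionary):
    return [run_replicate(sweep_config, sweep_config.seed + i, full_dictionary)
            for i in range(sweep_config.n_replicates)]


@pytest.fixture(scope="session")
def sweep_result(sweep_config, sweep_replicates):
    """Per-replicate MPE curves for the reduced sweep (global scaling,
    exponential-fit and R2*-based conditions, both Dr modes)."""
    return sweep_curves(sweep_replicates, sweep_config)
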