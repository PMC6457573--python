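"""Shared small fixtures: a fast design/population pair for unit tests."""

import numpy as np
import pytest

from cuefuse import ExperimentDesign, PopulationSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_design() -> ExperimentDesign:
    """4 runs of 8 blocks (one per stimulus label) — the smallest balanced
    design with enough runs for cross-validated inference."""
    return ExperimentDesign(n_runs=4, blocks_per_run=8)


@pytest.fixture(scope="session")
def tiny_spec() -> PopulationSpec:
    """Small, low-noise population so tiny datasets decode well above chance."""
    return PopulationSpec(
        n_units=24, n_voxels=30, unit_noise_sd=1.0, voxel_noise_sd=1.0
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec, tiny_design):
    return generate_dataset(tiny_spec, tiny_design, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
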