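"""Shared fixtures: tiny grids and datasets small enough for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from portaldose.core import GridSpec
from portaldose.synthetic_beams import SimulatorConfig, generate_dataset
from portaldose.training import prepare_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SimulatorConfig:
    """32-px grid preserving the 24.5 cm field of view; light noise."""
    return SimulatorConfig(
        grid=GridSpec(32, 7.68),
        noise_sd=20.0,
        rng_seed=7,
        n_leaf_pairs=16,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    """8 clinical pairs plus the calibration squares on the tiny grid."""
    return generate_dataset(8, tiny_config, seed=3)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_dataset):
    pairs, calibration = tiny_dataset
    return prepare_dataset(pairs, calibration)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
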