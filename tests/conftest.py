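"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from llnet.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic cohort, shared read-only."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A light configuration for fast unit tests."""
    return SimulationConfig(
        n_samples=150,
        n_probes=200,
        n_modules=2,
        module_sizes=(20, 15),
        n_snps=60,
        n_cis_eqtls=2,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_expression(n_probes: int, n_samples: int, seed: int = 0) -> pd.DataFrame:
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        r.standard_normal((n_probes, n_samples)) + 8.0,
        index=[f"P{i:04d}" for i in range(n_probes)],
        columns=[f"S{i:04d}" for i in range(n_samples)],
    )
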