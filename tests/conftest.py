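"""Shared fixtures for the dfikit test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dfikit.simulate import GeneratorConfig, generate_dataset, make_worked_fixtures


@pytest.fixture(scope="session")
def worked():
    """Deterministic worked fixtures (Kunitz scenario + boundary triples)."""
    return make_worked_fixtures()


@pytest.fixture(scope="session")
def kunitz(worked):
    return worked["kunitz"]


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded synthetic dataset used by several integration tests."""
    return generate_dataset(GeneratorConfig(seed=42, n_families=120, n_dfis=180))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
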