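"""Shared fixtures: small synthetic datasets and cached fits."""

from __future__ import annotations

import numpy as np
import pytest

from gwbzigpr.estimation import fit_bzigpr
from gwbzigpr.synthetic import SimulationDesign, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """40 locations, 2 predictors — fast enough for repeated fitting."""
    dataset, truths = generate_dataset(SimulationDesign(n=40, q=2, seed=7))
    return dataset, truths


@pytest.fixture(scope="session")
def medium_dataset():
    """120 locations, 2 predictors — used where 40 is too noisy."""
    dataset, truths = generate_dataset(SimulationDesign(n=120, q=2, seed=11))
    return dataset, truths


@pytest.fixture(scope="session")
def small_global_fit(small_dataset):
    dataset, _ = small_dataset
    return fit_bzigpr(dataset)


@pytest.fixture(scope="session")
def medium_global_fit(medium_dataset):
    dataset, _ = medium_dataset
    return fit_bzigpr(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
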