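"""Shared fixtures: small synthetic truths and a reusable K=5 fit."""

import numpy as np
import pytest

from mertree.inference import SamplerConfig
from mertree.model import ContextTreeModel
from mertree.simulate import make_totals, make_truth

FAST_CONFIG = SamplerConfig(iterations=2000, thin=5)


@pytest.fixture(scope="session")
def k5_truth():
    """Default-generator truth at K=5 with ample, even occurrence totals."""
    totals = make_totals(21, 5, 10_000_000, dispersion=0.0)
    return make_truth(20, K=5, totals=totals)


@pytest.fixture(scope="session")
def k5_counts(k5_truth):
    return k5_truth.simulate_counts(22)


@pytest.fixture(scope="session")
def k5_fit(k5_counts):
    """One two-chain fit of the K=5 simulation, reused across tests."""
    cfg = SamplerConfig(iterations=3000, thin=5)
    return ContextTreeModel(k5_counts, config=cfg).fit(seed=23)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
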