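"""Shared fixtures: one synthetic herd and one fitted model reused by the
prediction/evaluation tests (session scope keeps the suite fast)."""

import numpy as np
import pytest

from herdsurv import (
    MCMCConfig,
    SyntheticConfig,
    build_design,
    fit_mcmc,
    generate_herd,
    make_knots,
    preprocess,
)
from herdsurv.io import OUTCOME_KINDS


@pytest.fixture(scope="session")
def herd120():
    """120-cow herd under the default generating parameters."""
    cfg = SyntheticConfig(n_cows=120, seed=42)
    dataset, truth = generate_herd(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def clean120(herd120):
    _, dataset, _ = herd120
    clean, report, quart = preprocess(dataset)
    return clean, report, quart


@pytest.fixture(scope="session")
def design120(clean120):
    clean, _, quart = clean120
    specs = {k: make_knots(clean.sensor["dim"].to_numpy(), k) for k in OUTCOME_KINDS}
    return build_design(clean, specs, obs_thin=3, afc_quartiles=quart)


@pytest.fixture(scope="session")
def fit120(design120):
    """A modest-length fit; enough draws for prediction plumbing tests."""
    return fit_mcmc(design120, MCMCConfig(chains=1, burn=250, keep=300), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
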