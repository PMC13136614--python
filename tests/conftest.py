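"""Shared fixtures: small synthetic cohorts and toy networks.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive cohort generation and model training shared across
tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chotwin.network import MetabolicNetwork
from chotwin.records import GROWTH_RATE_NAME
from chotwin.synthetic import SyntheticConfig, generate_batch, generate_cohort
from chotwin.toynet import ToyNetworkSpec, generate_toy_network

ALL_PATHOLOGIES = ("dead_end", "blocked", "redundant_transport", "two_cycle")


@pytest.fixture(scope="session")
def clean_config():
    return SyntheticConfig(n_batches=6, n_media_groups=2, noise_cv=0.0)


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def noisy_batch():
    return generate_batch(SyntheticConfig(), 0, seed=3)


@pytest.fixture(scope="session")
def toy_model():
    return generate_toy_network(ToyNetworkSpec())


@pytest.fixture(scope="session")
def toy_network(toy_model):
    return MetabolicNetwork(toy_model)


@pytest.fixture(scope="session")
def pathological_model():
    return generate_toy_network(ToyNetworkSpec(pathologies=ALL_PATHOLOGIES))


@pytest.fixture(scope="session")
def toy_panel(toy_model):
    """Measured-rate panel of the toy network: growth plus its exchanges."""
    return tuple([GROWTH_RATE_NAME] + [r.id[3:-2] for r in toy_model.exchanges])


def rate_table_for(truth, panel, step=0.25):
    sr = truth.specific_rates
    grid = np.arange(0.0, float(sr.index.max()) + 1e-9, step)
    return pd.DataFrame(
        {a: np.interp(grid, sr.index.values, sr[a].values) for a in panel},
        index=pd.Index(grid, name="time_d"))


@pytest.fixture(scope="session")
def toy_rate_tables(clean_cohort, toy_panel):
    return {rec.batch_id: (rec.media_group, rate_table_for(tr, toy_panel))
            for rec, tr in clean_cohort}


@pytest.fixture(scope="session")
def measured_constraints(toy_model):
    """Realistic per-exchange flux bounds (uptake for nutrients, secretion
    for products) used as the reference condition in reduction tests."""
    cons = {}
    for r in toy_model.exchanges:
        analyte = r.id[3:-2]
        if analyte in ("ammonium", "lactate", "titer"):
            cons[r.id] = (0.01, 5.0)
        else:
            cons[r.id] = (-5.0, -0.01)
    return cons
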