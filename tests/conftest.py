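"""Shared fixtures: small arms/populations and session-scoped trained networks.

Training fixtures are session-scoped because CD-1 training is the expensive
step; every test that needs a trained harmonium shares the same one.
"""

from __future__ import annotations

import numpy as np
import pytest

from multisense._rng import seed_stream
from multisense.config import merge_config
from multisense.experiments import (
    evaluate_integration,
    integration_setup,
    train_integration_network,
)

SEED = 20130418  # fixed master seed for the whole suite


def scaled_overrides(**extra):
    """The reduced 'scaled' configuration: two 12x12 inputs, 144 hidden."""
    base = {
        "populations": {"units_per_dim": 12},
        "training": {"n_vectors": 10_000},
        "testing": {"n_test": 4_000},
    }
    for key, sub in extra.items():
        base.setdefault(key, {}).update(sub)
    return base


@pytest.fixture(scope="session")
def scaled_cfg():
    return merge_config(scaled_overrides())


@pytest.fixture(scope="session")
def scaled_net(scaled_cfg):
    """Trained scaled integration network (flat stimulus prior)."""
    model, trace, layout, setup = train_integration_network(scaled_cfg, SEED)
    return {
        "model": model,
        "trace": trace,
        "layout": layout,
        "setup": setup,
        "cfg": scaled_cfg,
    }


@pytest.fixture(scope="session")
def scaled_report(scaled_net):
    return evaluate_integration(
        scaled_net["model"],
        scaled_net["layout"],
        scaled_net["setup"],
        scaled_net["cfg"],
        SEED,
        with_calibrator=True,
    )


@pytest.fixture(scope="session")
def standard_setup():
    """Standard-scale (30x30) populations without any training."""
    return integration_setup(merge_config(None))


@pytest.fixture()
def rng():
    return seed_stream(SEED, "test-data")
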