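"""Shared fixtures: seeded synthetic record families.

Session-scoped so the heavier dataset fixtures are generated once and
reused by the unit and acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ppgpeaks import generate_dataset, preset
from ppgpeaks.synth import SynthConfig


@pytest.fixture(scope="session")
def clean_rest_config() -> SynthConfig:
    """Rest preset with additive noise switched off (clean study condition)."""
    return dataclasses.replace(preset("rest"), noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_records(clean_rest_config):
    """20 seed-fixed clean rest records with construction ground truth."""
    return generate_dataset(clean_rest_config, 20, seed=101)


@pytest.fixture(scope="session")
def stress_records():
    """50 seed-fixed after-exercise records (tachycardia, noise, artifacts)."""
    return generate_dataset(preset("after_exercise"), 50, seed=202)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
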