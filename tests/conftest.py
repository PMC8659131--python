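"""Shared fixtures: synthetic samples and calibrated gates.

Session scope keeps the expensive sample generation (rendering +
feature extraction) to one pass per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

import aggrecyto as ag
from aggrecyto import gating


@pytest.fixture(scope="session")
def default_model():
    return ag.default_intensity_model()


@pytest.fixture(scope="session")
def small_sample():
    """120-event default-mix sample with truths and feature table."""
    cfg = ag.SampleConfig(n_events=120)
    events, truths = ag.generate_sample(cfg, 3)
    table = ag.extract_feature_table(events)
    return events, truths, table


@pytest.fixture(scope="session")
def default_sample_1000():
    """The reference study sample: 1000 events, default mixture, seed 7."""
    cfg = ag.SampleConfig(n_events=1000)
    events, truths = ag.generate_sample(cfg, 7)
    table = ag.extract_feature_table(events)
    return events, truths, table


@pytest.fixture(scope="session")
def calibrated_gates():
    return gating.calibrate_gates(seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
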