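"""Shared fixtures: synthetic recordings processed once per session.

The pipeline stages (denoise + wavelet-packet separation) cost a couple
of seconds per 25 s recording, so recordings that several test modules
inspect are rendered and separated once.
"""

import numpy as np
import pytest

from calsa.preprocess import denoise, separate_stationary_nonstationary
from calsa.synthetic import SimulationSpec, make_validation_suite, simulate_recording


@pytest.fixture(scope="session")
def default_recording():
    """Default-condition recording with a moderate crackle load."""
    spec = SimulationSpec(seed=7, crackles_per_insp=3.0, crackles_per_exp=2.0)
    return simulate_recording(spec)


@pytest.fixture(scope="session")
def default_pair(default_recording):
    rec, truth = default_recording
    den = denoise(rec)
    return separate_stationary_nonstationary(den), truth


@pytest.fixture(scope="session")
def clean_recording():
    """Crackle-free, wheeze-free breath sound at default ambient noise."""
    return simulate_recording(SimulationSpec(seed=3))


@pytest.fixture(scope="session")
def clean_pair(clean_recording):
    rec, truth = clean_recording
    den = denoise(rec)
    return separate_stationary_nonstationary(den), truth


@pytest.fixture(scope="session")
def validation_suite():
    """The standard 20-recording validation suite (fixed seed)."""
    return make_validation_suite(20, seed=12345)


@pytest.fixture(scope="session")
def suite_report(validation_suite):
    from calsa.validation import evaluate_suite

    return evaluate_suite(validation_suite)
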