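"""Shared fixtures: small synthetic recordings at reduced sampling rate.

Signal fixtures run at 500 Hz (Nyquist 250 Hz comfortably covers the
1–100 Hz analysis range) and short durations so the whole suite stays
fast; hypnogram-only fixtures use full-length (48 h) state sequences,
which are cheap.
"""

import datetime as dt

import numpy as np
import pytest

from psgpheno.simulate import (
    SimConfig,
    simulate_hypnogram,
    synthesize_signals,
)

FS = 500.0
START = dt.datetime(2023, 1, 2, 0, 0, 0)


@pytest.fixture(scope="session")
def wt_config() -> SimConfig:
    return SimConfig(sampling_rate=FS, duration_h=0.5, seed=42,
                     protein_level=1.0, artifact_rate=0.0)


@pytest.fixture(scope="session")
def mutant_config() -> SimConfig:
    return SimConfig(sampling_rate=FS, duration_h=0.5, seed=42,
                     protein_level=0.0, artifact_rate=0.0)


@pytest.fixture(scope="session")
def wt_recording(wt_config):
    hyp = simulate_hypnogram(wt_config)
    rec, truth = synthesize_signals(hyp, wt_config)
    return rec, truth


@pytest.fixture(scope="session")
def mutant_recording(mutant_config):
    hyp = simulate_hypnogram(mutant_config)
    rec, truth = synthesize_signals(hyp, mutant_config)
    return rec, truth


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """No line noise, no artifacts: for spectral-shape checks."""
    return SimConfig(sampling_rate=FS, duration_h=0.25, seed=7,
                     line_noise_amp=0.0, artifact_rate=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
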