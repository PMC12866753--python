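import numpy as np
import pytest

from sleepgeom.config import SessionConfig
from sleepgeom.responses import extract_responses
from sleepgeom.synthetic import generate_physio, generate_session


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small two-state session used across modules."""
    return SessionConfig(
        n_neurons=40, n_sounds=6, presentations_per_sound_per_state=8,
        block_duration=30.0, n_silence_blocks=2, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_cfg):
    return generate_session(tiny_cfg)


@pytest.fixture(scope="session")
def noisefree_cfg():
    """Deterministic session: no gating, no noise, no spontaneous latents."""
    return SessionConfig(
        n_neurons=25, n_sounds=4, presentations_per_sound_per_state=4,
        block_duration=30.0, n_silence_blocks=1, seed=3,
        gate_prob_nrem=0.0, gate_prob_wake=0.0, noise_sd=0.0,
        spont_rank=0, burst_rate=0.0,
    )


@pytest.fixture(scope="session")
def noisefree_session(noisefree_cfg):
    return generate_session(noisefree_cfg)


@pytest.fixture(scope="session")
def scoring_session():
    """Session with REM blocks and physio, for sleep scoring and spindles."""
    cfg = SessionConfig(
        n_neurons=30, n_sounds=4, presentations_per_sound_per_state=8,
        block_duration=60.0, n_rem_blocks=2, spindle_rate=0.05, seed=3,
    )
    raster, trials, truth = generate_session(cfg)
    physio = generate_physio(cfg, truth)
    return cfg, raster, trials, truth, physio


@pytest.fixture(scope="session")
def wake_session():
    """Single-state wake session with trial noise, for RSA and decoding."""
    cfg = SessionConfig(
        n_neurons=60, n_sounds=10, presentations_per_sound_per_state=12,
        states=("wake",), gate_prob_wake=0.0, noise_sd=2.0,
        n_silence_blocks=1, block_duration=60.0, seed=13,
    )
    raster, trials, truth = generate_session(cfg)
    resp = extract_responses(raster, trials)
    return cfg, raster, trials, truth, resp


def make_rng(seed=0):
    return np.random.default_rng(seed)
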