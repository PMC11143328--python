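import numpy as np
import pytest

from calplast import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pf_config():
    """Small electrical parallel-fibre session configuration."""
    return synth.SimConfig(n_trials=8, noise_sd=0.02, seed=7)


@pytest.fixture
def clean_config():
    """Deterministic degenerate limit: evoked only, no noise, no jitter."""
    cfg = synth.SimConfig(
        n_trials=6, spont_rate=0.0, noise_sd=0.0, latency_jitter_sd=0.0, seed=11
    )
    return cfg.replace(
        evoked_prob_by_intensity={k: 1.0 for k in cfg.evoked_prob_by_intensity}
    )


def random_bumpy_trace(rng: np.random.Generator, n: int = 150, frame_rate: float = 31.0):
    """A ΔF/F-like test trace: smooth noise plus a few calcium transients."""
    t = np.arange(n) / frame_rate
    sig = np.convolve(rng.standard_normal(n) * 0.05, np.ones(5) / 5, mode="same")
    for _ in range(rng.integers(0, 4)):
        t0 = rng.uniform(0, t[-1])
        sig += rng.uniform(0.1, 1.0) * synth.event_kernel(t - t0)
    return sig
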