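import numpy as np
import pytest

from pvrkit.wavesim import MORPHOLOGY_PRESETS, TraceConfig, generate_trace


@pytest.fixture(scope="session")
def clean_trace():
    """Factory: noise-free, jitter-free 10 s trace for a preset or params."""

    def make(morphology="normal", duration=10.0, seed=1):
        cfg = TraceConfig(
            duration=duration, noise_sd=0.0, period_jitter_sd=0.0, seed=seed
        )
        return generate_trace(cfg, morphology)

    return make


@pytest.fixture(scope="session")
def noisy_trace():
    """Factory: default-condition trace (2% period jitter, given noise)."""

    def make(morphology="normal", noise_sd=0.02, seed=0, duration=10.0):
        cfg = TraceConfig(duration=duration, noise_sd=noise_sd, seed=seed)
        return generate_trace(cfg, morphology)

    return make


@pytest.fixture(scope="session")
def presets():
    return MORPHOLOGY_PRESETS


def pairwise_auc(scores, labels) -> float:
    """Brute-force all-pairs AUC oracle: P(pos > neg) + 0.5 P(pos == neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
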