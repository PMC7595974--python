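"""Shared fixtures: synthetic series and a pretrained desk-scale prior.

Everything is generated programmatically with fixed seeds; no data
files are read.  The prior model is session-scoped because pretraining
is the most expensive step of the suite.
"""

import pytest

from analogscope.generative import GenerativeConfig, pretrain, transfer_learn
from analogscope.synthetic import (
    SeriesGeneratorSpec,
    generate_corpus,
    generate_series,
    generate_va_pool,
)


@pytest.fixture(scope="session")
def additive_series():
    """Strictly additive, noiseless series: FW predictions must be exact."""
    spec = SeriesGeneratorSpec(
        n_sites=3, substituents_per_site=6, n_eas=30, seed=101
    )
    return generate_series(spec)


@pytest.fixture(scope="session")
def noisy_series():
    spec = SeriesGeneratorSpec(
        n_sites=3,
        substituents_per_site=6,
        n_eas=30,
        noise_sd=0.2,
        seed=7,
    )
    return generate_series(spec)


@pytest.fixture(scope="session")
def va_pool(noisy_series):
    return generate_va_pool(noisy_series, 200, "recombination", seed=11)


@pytest.fixture(scope="session")
def corpus():
    return generate_corpus(600, complexity="varied", seed=3)


@pytest.fixture(scope="session")
def prior_model(corpus):
    model, history = pretrain(corpus, GenerativeConfig(epochs=20, seed=0))
    return model, history


@pytest.fixture(scope="session")
def tl_result(prior_model, noisy_series):
    prior, _ = prior_model
    cfg = GenerativeConfig(
        epochs=15, sample_per_epoch=256, learning_rate=1e-3, seed=5
    )
    model, metrics, samples = transfer_learn(prior, noisy_series.series, cfg)
    return model, metrics, samples
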