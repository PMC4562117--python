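"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from neurothesaurus.raster import BinnedRaster
from neurothesaurus.synthgen import GeneratorConfig, generate_codebook_dataset


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-codebook dataset for fast pipeline-level tests.

    4 clusters over 24 stimuli, 8 neurons, 120 repeats: enough structure
    for clustering/decoding behavior without the cost of the full default
    configuration.
    """
    cfg = GeneratorConfig(n_neurons=8, n_stimuli=24, n_repeats=120,
                          n_clusters=4, n_precise_on=2, n_noisy=3,
                          event_fraction=0.26, min_off_overlap=1, seed=7)
    raster, truth, waveform = generate_codebook_dataset(cfg)
    return cfg, raster, truth, waveform


@pytest.fixture(scope="session")
def small_results(small_planted):
    """Fitted thesaurus on the small planted dataset."""
    from neurothesaurus.model import ThesaurusModel

    _, raster, _, _ = small_planted
    return ThesaurusModel(raster).fit(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_raster():
    """Deterministic 3-neuron raster: 4 repeats, 5 bins."""
    rng = np.random.default_rng(42)
    words = (rng.random((4, 5, 3)) < 0.4).astype(np.uint8)
    return BinnedRaster(words, 0.02)
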