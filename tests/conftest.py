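import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hner.synthcorpus import SynthSpec, gen_corpus, gen_dictionary

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

# the BIO repair warning is exercised deliberately in several tests
logging.getLogger("hner.annotate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_synth():
    """A small clean synthetic corpus with its dictionary (no misspellings)."""
    spec = SynthSpec(n_docs=12, misspell_rate=0.0, seed=42)
    dictionary = gen_dictionary(spec)
    return spec, dictionary, gen_corpus(dictionary, spec)
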