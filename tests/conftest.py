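import numpy as np
import pytest

from chaoswolf.synthetic_data import SynthSpec, generate_dtm
from chaoswolf.text_pipeline import LabeledCorpus


@pytest.fixture
def rng():
    return np.random.default_rng(20231114)


@pytest.fixture
def toy_corpus():
    """Four hand-enumerable documents (two per class)."""
    return LabeledCorpus(
        texts=[
            "feeling empty and hopeless today",
            "hopeless nights, empty days",
            "great hike with sunshine today",
            "sunshine and a great breakfast",
        ],
        labels=np.array([1, 1, 0, 0]),
    )


@pytest.fixture
def small_dtm():
    """Planted-feature matrix small enough for fast wrapper searches."""
    dtm, truth = generate_dtm(
        SynthSpec(n_docs=120, vocab_size=20, n_informative=5, seed=7)
    )
    return dtm, truth
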