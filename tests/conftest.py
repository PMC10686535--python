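import numpy as np
import pytest

from radstruct.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """30 synthetic reports shared by read-only tests."""
    return generate_corpus(GeneratorConfig(n_reports=30, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
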