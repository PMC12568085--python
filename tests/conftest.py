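import numpy as np
import pytest

from eyewrite import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """3 subjects x 10 numeral patterns x 2 trials, webcam-style."""
    return generate_dataset(GeneratorConfig(n_subjects=3, trials_per_pattern=2,
                                            seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
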