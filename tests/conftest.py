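import numpy as np
import pytest

import ecgmultirate as em


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset: 4 classes x 3 subjects x 170 beats."""
    return em.synthesize_dataset(em.SynthConfig(seed=0))


@pytest.fixture(scope="session")
def frontend_outputs(default_dataset):
    """Front-end run over the default dataset: (windows, denoised, stats)."""
    return em.process_dataset(default_dataset)


@pytest.fixture(scope="session")
def features_p2(frontend_outputs):
    _, denoised, _ = frontend_outputs
    return em.build_feature_matrix(denoised, "P2")


@pytest.fixture(scope="session")
def features_p1(frontend_outputs):
    _, denoised, _ = frontend_outputs
    return em.build_feature_matrix(denoised, "P1")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
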