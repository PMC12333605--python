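import numpy as np
import pytest

from cnnbrf.brf import BRFConfig
from cnnbrf.cnn_encoder import EncoderConfig
from cnnbrf.model import MicrobeDrugModel
from cnnbrf.similarity import apply_structure_cutoff, integrate, jaccard_similarity
from cnnbrf.synthetic_data import SyntheticSpec, generate, generate_worked_micro


@pytest.fixture(scope="session")
def micro():
    """Hand-written 4-drug x 3-microbe miniature."""
    return generate_worked_micro()


@pytest.fixture(scope="session")
def micro_sims(micro):
    dataset, ss2_raw, profiles, mv = micro
    ss1 = jaccard_similarity(profiles, dataset.drugs)
    ss2 = apply_structure_cutoff(ss2_raw, 0.5)
    return integrate(ss1, ss2, mv)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced planted-block spec for fast pipeline tests."""
    return SyntheticSpec(nd=30, nm=12, n_blocks=3, seed=5)


@pytest.fixture(scope="session")
def small_data(small_spec):
    """(dataset, sims) for the reduced planted-block problem."""
    dataset, drug_sim, profiles, microbe_sim = generate(small_spec)
    ss1 = jaccard_similarity(profiles, dataset.drugs)
    ss2 = apply_structure_cutoff(drug_sim, 0.5)
    return dataset, integrate(ss1, ss2, microbe_sim)


@pytest.fixture(scope="session")
def default_model():
    """Model on the default planted-block conditions (nd=120, nm=40)."""
    return MicrobeDrugModel.from_synthetic()


@pytest.fixture()
def tiny_encoder_cfg():
    return EncoderConfig(epochs=3, seed=0)


@pytest.fixture()
def tiny_brf_cfg():
    return BRFConfig(n_trees=15, min_split=5, seed=0)


@pytest.fixture()
def blobs():
    """Two separable Gaussian blobs in [0,1]^24 for encoder/forest sanity."""
    rng = np.random.default_rng(42)
    n = 120
    a = np.clip(rng.normal(0.25, 0.08, (n, 24)), 0, 1)
    b = np.clip(rng.normal(0.75, 0.08, (n, 24)), 0, 1)
    X = np.vstack([a, b])
    y = np.concatenate([np.zeros(n), np.ones(n)])
    return X, y
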