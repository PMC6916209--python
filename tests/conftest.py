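import numpy as np
import pytest
from hypothesis import settings

from ehrdae import dae, synthetic
from ehrdae.schema import build_schema, split_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_schema():
    """3 diagnosis codes, 2 medication groups, 4 lab tests -> d = 17."""
    return build_schema(
        ["D1", "D2", "D3"],
        ["M1", "M2"],
        [("L1", 1.0, 2.0), ("L2", 0.0, 10.0), ("L3", 5.0, 6.0), ("L4", -1.0, 1.0)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """500-patient synthetic cohort under default study conditions."""
    return synthetic.generate_cohort(synthetic.CohortConfig(n_patients=500, seed=42))


@pytest.fixture(scope="session")
def small_samples(small_cohort):
    return split_cohort(small_cohort.patients, small_cohort.schema)


@pytest.fixture(scope="session")
def trained_small(small_cohort, small_samples):
    """Denoising autoencoder trained on the 500-patient cohort (small latent)."""
    return dae.train(
        [s.tensor for s in small_samples],
        dae.DaeConfig(latent_dim=16, epochs=15, seed=0),
        schema_fingerprint=small_cohort.schema.fingerprint(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
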