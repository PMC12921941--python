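import numpy as np
import pytest

from fibrovae import CohortSimConfig, VAEConfig, generate_cohort
from fibrovae.vae import MultimodalVAE


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (41 patients, 512-dim embeddings), seed 0."""
    return generate_cohort(CohortSimConfig(seed=0))


@pytest.fixture(scope="session")
def short_fit(default_cohort):
    """A quickly trained model on the default cohort (40 epochs) for tests
    that need a fitted VAE but not full convergence."""
    clinical, embeddings, _ = default_cohort
    model = MultimodalVAE.from_dataframes(
        clinical, embeddings, config=VAEConfig(epochs=40, seed=0)
    )
    return model, model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
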