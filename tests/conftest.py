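import numpy as np
import pytest

from mvnmf import Hyperparameters, MultiViewNMF
from mvnmf.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small dense-enough synthetic dataset shared across tests."""
    return generate(
        SyntheticSpec(
            n_drugs=20,
            n_diseases=12,
            feature_dims=(15, 20, 25),
            latent_rank=3,
            association_density=0.1,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A converged fit on the small dataset (shared, read-only)."""
    ds = small_dataset
    hp = Hyperparameters(seed=11, k_neighbors=3, max_iter=300)
    model = MultiViewNMF(ds.views[:3], ds.assoc, ds.D, hp)
    return model, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
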