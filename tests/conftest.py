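import numpy as np
import pytest

from mregger import MRDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture
def random_dataset_factory(rng):
    """Random but well-conditioned summary datasets (all gamma positive)."""

    def make(n_variants: int, oriented: bool = True, with_eaf: bool = True):
        gamma = rng.uniform(0.1, 0.6, n_variants)
        se_x = rng.uniform(0.01, 0.05, n_variants)
        big_gamma = rng.normal(0.5 * gamma, 0.05)
        sigma = rng.uniform(0.02, 0.10, n_variants)
        eaf = rng.uniform(0.05, 0.95, n_variants) if with_eaf else None
        return MRDataset.from_arrays(
            beta_exposure=gamma,
            se_exposure=se_x,
            beta_outcome=big_gamma,
            se_outcome=sigma,
            eaf=eaf,
            oriented=oriented,
        )

    return make


@pytest.fixture
def affine_dataset():
    """Noise-free data with outcome = 0.1 + 2 * exposure exactly."""
    gamma = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    return MRDataset.from_arrays(
        beta_exposure=gamma,
        se_exposure=np.full(5, 0.02),
        beta_outcome=0.1 + 2.0 * gamma,
        se_outcome=np.array([0.03, 0.05, 0.04, 0.06, 0.05]),
        oriented=True,
    )
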