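import numpy as np
import pytest

import imputequal as iq


@pytest.fixture
def small_dataset():
    """200 x 5 continuous two-class dataset, fixed seed."""
    return iq.generate_numeric(200, 5, class_sep=1.0, seed=11)


@pytest.fixture
def masked_small(small_dataset):
    mask = iq.induce_mcar(small_dataset, 0.25, seed=12)
    return small_dataset, mask, iq.apply_mask(small_dataset, mask)


@pytest.fixture
def correlated_bivariate():
    """Factory for N x 2 Gaussian data with correlation rho."""

    def make(n=500, rho=0.9, seed=0):
        rng = np.random.default_rng(seed)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        values = rng.multivariate_normal([0, 0], cov, size=n)
        schema = [iq.FeatureSchema("a", "continuous"),
                  iq.FeatureSchema("b", "continuous")]
        labels = np.tile([0, 1], n // 2 + 1)[:n]
        return iq.Dataset(values, schema, labels, seed)

    return make
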