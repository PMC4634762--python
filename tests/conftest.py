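import numpy as np
import pytest

from cviim import GeneratorSpec, LabeledDataset, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable():
    """Two well-separated Gaussian classes (n=40, p=10, large effect)."""
    return generate(
        GeneratorSpec(
            n_per_class=20, p=10, n_informative=10, effect_size=5.0,
            block_size=1, rho=0.0, seed=7,
        )
    )


@pytest.fixture
def small_null():
    """Label-independent data at a desk scale (n=24, p=30)."""
    return generate(
        GeneratorSpec(n_per_class=12, p=30, n_informative=0, effect_size=0.0, seed=11)
    )


def make_dataset(X, y, dataset_id="toy"):
    return LabeledDataset(X=np.asarray(X, float), y=np.asarray(y, int),
                          dataset_id=dataset_id)
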