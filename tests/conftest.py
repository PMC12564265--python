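import numpy as np
import pytest

from dooit import SyntheticSpec, generate, split_train_test


@pytest.fixture(scope="session")
def tiny_spec():
    """Small emulation profile: 3 informative + 3 nuisance + anchor."""
    return SyntheticSpec(
        n_samples=160, n_informative=3, n_nuisance=3,
        feature_correlation=0.3, noise_sd=0.2, anchor_bias=0.5,
        anchor_noise_sd=0.2, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_table(tiny_spec):
    table, _ = generate(tiny_spec)
    return split_train_test(table, 0.8, seed=0)


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    from dooit import ground_truth

    return ground_truth(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
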