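import numpy as np
import pytest

import rxclassify as rx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_small():
    """200 prescriptions, 11 classes, disjoint homogeneous signatures, no
    noise: every class is recoverable from any training subset that
    contains it, so exact-recovery assertions are safe at this size."""
    import dataclasses

    cfg = dataclasses.replace(rx.separable_config(200, seed=7), other_subsignatures=1)
    return rx.generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_Xy(separable_small):
    return separable_small.features.to_numpy(float), separable_small.labels


def random_prediction_problem(rng, n_max=50, n_classifiers_max=8, n_classes_max=11):
    """A random prediction matrix with labels, for vote/weight tests."""
    n = int(rng.integers(2, n_max + 1))
    N = int(rng.integers(1, n_classifiers_max + 1))
    K = int(rng.integers(2, n_classes_max + 1))
    P = rng.integers(1, K + 1, size=(n, N))
    y = rng.integers(1, K + 1, size=n)
    return P, y, K
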