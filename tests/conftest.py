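import numpy as np
import pytest

from mevax.dataio import Dataset
from mevax.fixtures import FixtureSpec, generate
from mevax.genome import HyperparamBounds


@pytest.fixture(scope="session")
def bounds():
    return HyperparamBounds()


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 samples x 12 features, 3 planted informative features, balanced-ish."""
    fx = generate(FixtureSpec(n_samples=40, n_features=12, n_informative=3,
                              effect_size=1.5, class_balance=0.5, seed=11))
    return fx.to_dataset(), fx.informative


@pytest.fixture(scope="session")
def planted_dataset():
    """100 samples x 50 features with a clear 5-feature signal."""
    fx = generate(FixtureSpec(n_samples=100, n_features=50, n_informative=5,
                              effect_size=1.2, class_balance=0.4, seed=7))
    return fx.to_dataset(), fx.informative


def make_dataset(X, y, prefix="f"):
    X = np.asarray(X, float)
    names = [f"{prefix}{j}" for j in range(X.shape[1])]
    return Dataset(X=X, y=np.asarray(y, int), feature_names=names,
                   positive_label=1)
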