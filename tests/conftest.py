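import numpy as np
import pytest

from smmsn.preprocess import OmicsView


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_view(rng):
    """A 12-sample, 6-feature view with mild structure, no missingness."""
    X = rng.standard_normal((12, 6))
    return OmicsView(
        name="toy",
        samples=[f"S{i}" for i in range(12)],
        features=[f"f{j}" for j in range(6)],
        X=X,
    )


def make_view(X, name="v"):
    X = np.asarray(X, dtype=float)
    return OmicsView(
        name=name,
        samples=[f"S{i}" for i in range(X.shape[0])],
        features=[f"f{j}" for j in range(X.shape[1])],
        X=X,
    )
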