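import pytest

from sverad import KernelParams, SparseBinaryVector, generate_toy_svm


@pytest.fixture
def worked_pair():
    """The 5-bit example pair: x = [1 0 0 1 0], y = [1 0 1 1 1] (I=2, D=2)."""
    x = SparseBinaryVector.from_dense([1, 0, 0, 1, 0])
    y = SparseBinaryVector.from_dense([1, 0, 1, 1, 1])
    return x, y


@pytest.fixture
def sigma1():
    """Kernel parameters for sigma = 1, i.e. gamma = 0.5."""
    return KernelParams.from_sigma(1.0)


@pytest.fixture
def toy_model():
    return generate_toy_svm(n_support=6, universe_size=20, seed=42)
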