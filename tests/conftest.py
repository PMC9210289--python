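import numpy as np
import pytest

from gapcom import ExpressionMatrix, sample_gaussian, simulate_family


@pytest.fixture(scope="session")
def star_small():
    """A 100-node, 10-star ground truth with n=80 samples."""
    model, X = simulate_family("star", p=100, n=80, seed=11)
    return model, X


@pytest.fixture()
def tiny_expression():
    rng = np.random.default_rng(5)
    return ExpressionMatrix.from_values(rng.standard_normal((30, 8)))
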