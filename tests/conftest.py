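import numpy as np
import pytest

from fundusfuse import FundusConfig, generate_dataset


def make_planted_matrix(seed: int, n: int = 200, d: int = 50, effect: float = 2.5):
    """5-class matrix with 5 planted informative columns (0..4).

    Column j is shifted by ``effect`` for samples of class j; the remaining
    columns are pure N(0,1) noise. The planted set is the ground truth for
    selection-recovery tests.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(5), n // 5)
    x = rng.normal(0, 1, (n, d))
    for j in range(5):
        x[:, j] += effect * (y == j)
    return x, y


@pytest.fixture(scope="session")
def tiny_dataset():
    """20 synthetic fundus images (4 per grade) at 64 px with ground truth."""
    cfg = FundusConfig(image_size=64, seed=0)
    images, manifest, inventories = generate_dataset(cfg, 4, 0)
    return images, manifest, inventories


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
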