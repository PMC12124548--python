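import numpy as np
import pytest

import mdann as M


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny biased cohort shared by read-only tests."""
    spec = M.BiasSpec(
        n=80,
        image_size=(16, 16),
        attributes=[M.AttributeSpec("sex", 3.0, 0.5)],
        seed=7,
    )
    return M.generate_cohort(spec)


def random_scored_batch(rng, n_max=20):
    """A random score batch guaranteed to contain both classes."""
    n = int(rng.integers(2, n_max + 1))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return M.ScoredBatch(rng.uniform(0, 1, n), labels)


def random_prediction_table(rng, n_max=50):
    """A random prediction table with non-empty groups."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        y = rng.integers(0, 2, n)
        y_hat = rng.integers(0, 2, n)
        score = rng.uniform(0, 1, n)
        d = rng.integers(0, 2, n)
        if 0 < d.sum() < n:
            return M.prediction_table(y, y_hat, score, {"grp": d})
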