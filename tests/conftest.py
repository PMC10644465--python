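import numpy as np
import pytest

from carbosite.containers import FeatureMatrix
from carbosite.seq_features import ALPHABET


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_windows(rng):
    """100 random 21-mers with a K centre."""
    aas = np.array(list(ALPHABET))
    out = []
    for _ in range(100):
        chars = aas[rng.integers(0, 20, size=21)]
        chars[10] = "K"
        out.append("".join(chars))
    return out


@pytest.fixture
def gaussian_minority(rng):
    """200 points from N((0.5, 0.5), 0.05^2 I), clipped to the unit square."""
    return np.clip(rng.normal(0.5, 0.05, size=(200, 2)), 0.0, 1.0)


@pytest.fixture
def small_imbalanced(rng):
    """Separable 2-D cloud: 60 negatives around 0.3, 12 positives around 0.75."""
    Xn = np.clip(rng.normal(0.30, 0.06, size=(60, 2)), 0, 1)
    Xp = np.clip(rng.normal(0.75, 0.06, size=(12, 2)), 0, 1)
    return FeatureMatrix(
        X=np.vstack([Xn, Xp]),
        y=np.r_[np.zeros(60, int), np.ones(12, int)],
        scaling_state="minmax",
    )
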