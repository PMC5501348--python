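import numpy as np
import pytest

from eegfc.montage import CHANNELS_58
from eegfc.preprocess import TrialSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_trialset(rng):
    """Eight 58-channel trials of band-limited noise at 200 Hz."""
    trials = [rng.standard_normal((58, 400)) for _ in range(8)]
    return TrialSet(subject_id="T01", session="pre", labels=CHANNELS_58,
                    fs=200.0, trials=trials)


def brute_force_gma_directed(x, y):
    """Literal enumeration of the directed GMA procedure.

    Kept deliberately naive and independent of the package implementation:
    explicit loops, explicit nearest-neighbor search with index-order tie
    breaking, explicit midranks over groups of tied Y-distances, and the
    rank-distribution sum evaluated term by term.  Distances are compared
    as squared Euclidean (a strictly monotone rescaling, so neighbor
    choices and rank ties are unchanged), matching the package's metric
    convention.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = len(x)
    ranks = []
    for i in range(n):
        best, best_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            d = ((x[i] - x[j]) ** 2).sum()
            if d < best_d:  # strict: earlier index wins ties
                best, best_d = j, d
        d_star = ((y[best] - y[i]) ** 2).sum()
        others = [((y[j] - y[i]) ** 2).sum() for j in range(n) if j != i]
        less = sum(1 for d in others if d < d_star)
        tied = sum(1 for d in others if d == d_star)
        ranks.append(less + (tied + 1) / 2.0)  # midrank within the tied group
    counts = {}
    for r in ranks:
        counts[r] = counts.get(r, 0) + 1
    return sum((n - r) * (c / n) for r, c in counts.items()) / (n - 1)


@pytest.fixture
def gma_oracle():
    return brute_force_gma_directed
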