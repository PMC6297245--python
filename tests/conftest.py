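import numpy as np
import pytest

from reconradiomics import FeatureTable, ImageVolume, LesionMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """8x8x3 noisy volume with unit spacing, small enough for exhaustive oracles."""
    return ImageVolume(values=rng.normal(0, 10, size=(8, 8, 3)), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def small_mask():
    m = np.zeros((8, 8, 3), dtype=bool)
    m[1:7, 1:7, :] = True
    return LesionMask(values=m, spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def toy_table(rng):
    """n=40 table: one perfectly separating feature plus 9 noise features."""
    n = 40
    labels = np.array([0] * 20 + [1] * 20)
    values = rng.normal(size=(n, 10))
    values[:, 0] = labels * 10.0 + rng.normal(0, 0.1, size=n)  # near-perfect separator
    names = ["separator"] + [f"noise{i}" for i in range(1, 10)]
    return FeatureTable(
        patient_ids=[f"P{i:03d}" for i in range(n)],
        feature_names=names,
        values=values,
        labels=labels,
    )


def brute_force_auc(scores, labels):
    """Exhaustive pair-counting AUC oracle (ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
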