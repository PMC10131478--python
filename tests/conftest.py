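import numpy as np
import pytest

from methsubtype.matrix import BetaMatrix, LabeledDataset, SubtypeVocabulary


@pytest.fixture
def toy_matrix():
    """3 probes x 2 samples with one missing cell."""
    values = np.array([[0.1, 0.9], [0.5, np.nan], [0.25, 0.75]])
    return BetaMatrix(["cgA", "cgB", "cgC"], ["S1", "S2"], values)


@pytest.fixture
def vocab():
    return SubtypeVocabulary(("LumA", "Basal"))


@pytest.fixture
def separable_2class():
    """200 samples x 50 features, two well-separated classes.

    Class 0 is hypermethylated on the first 15 features, class 1 on the
    next 15; the remainder is shared background.
    """
    rng = np.random.default_rng(42)
    n, k = 200, 50
    y = rng.integers(0, 2, size=n)
    X = rng.beta(2, 2, size=(n, k))
    X[y == 0, :15] = rng.beta(8, 2, size=((y == 0).sum(), 15))
    X[y == 1, 15:30] = rng.beta(8, 2, size=((y == 1).sum(), 15))
    return X, y


def nearest_centroid_accuracy(X_train, y_train, X_test, y_test):
    """Independent separability oracle: classify by the closest class mean."""
    classes = np.unique(y_train)
    centroids = np.stack([X_train[y_train == c].mean(axis=0) for c in classes])
    d = ((X_test[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float((classes[np.argmin(d, axis=1)] == y_test).mean())
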