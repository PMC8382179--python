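"""Train/test splitting, centroid readout, and accuracy estimation.

The readout mirrors the study's evaluation rules: a fresh LDA projection is
fit on the *non-standardized* training features restricted to the selected
sensors; two-class decisions use a boundary at the midpoint of the projected
class centroids, multi-class decisions use the nearest projected centroid.
The pooled covariance gets a small ridge because first-spike features are
frequently constant (many zeros), making it singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .encoding import FirstSpikeMatrix

__all__ = ["ClassifierModel", "AccuracyResult", "split_data", "fit_and_score",
           "replicate_accuracy"]


@dataclass
class ClassifierModel:
    """Centroid classifier on the selected sensors' projected features."""

    w_c: np.ndarray               # (k, n_classes - 1) projection
    centroids: np.ndarray         # (n_classes, n_classes - 1)
    classes: np.ndarray
    selected: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = X[:, self.selected] @ self.w_c
        if len(self.classes) == 2:
            mid = self.centroids.mean(axis=0)
            direction = self.centroids[1] - self.centroids[0]
            side = (Z - mid) @ direction
            return np.where(side > 0, self.classes[1], self.classes[0])
        d2 = ((Z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return self.classes[np.argmin(d2, axis=1)]


@dataclass
class AccuracyResult:
    accuracy: float
    n_test: int
    replicate_sd: float = 0.0
    replicate_accuracies: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def split_data(features: FirstSpikeMatrix, train_frac: float = 0.9,
               seed: int | None = 0):
    """Stratified, seeded train/test split of the observation rows.

    Returns two :class:`FirstSpikeMatrix` objects.  Errors if either side
    would miss a class.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    if features.labels is None:
        raise ValueError("features must carry class labels")
    idx = np.arange(features.n_observations)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=features.labels,
        random_state=np.random.SeedSequence(seed).generate_state(1)[0] % (2**32 - 1))
    train = FirstSpikeMatrix(features.data[train_idx], features.labels[train_idx])
    test = FirstSpikeMatrix(features.data[test_idx], features.labels[test_idx])
    for part, name in ((train, "training"), (test, "test")):
        if len(np.unique(part.labels)) < len(np.unique(features.labels)):
            raise ValueError(f"a class is absent from the {name} split")
    return train, test


def _fit_classifier(train: FirstSpikeMatrix, selected: np.ndarray,
                    ridge: float = 1e-6) -> ClassifierModel:
    X = train.data[:, selected].astype(float)
    y = train.labels
    classes = np.unique(y)
    k = X.shape[1]
    mu = np.array([X[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((k, k))
    for c, mc in zip(classes, mu):
        d = X[y == c] - mc
        Sw += d.T @ d
    Sw /= max(X.shape[0] - len(classes), 1)
    Sw += ridge * (np.trace(Sw) / max(k, 1) + 1.0) * np.eye(k)
    if len(classes) == 2:
        W = np.linalg.solve(Sw, mu[1] - mu[0])[:, None]
    else:
        grand = X.mean(axis=0)
        Sb = np.zeros((k, k))
        for c, mc in zip(classes, mu):
            d = (mc - grand)[:, None]
            Sb += np.sum(y == c) * d @ d.T
        from scipy.linalg import eigh
        vals, vecs = eigh(Sb, Sw)
        W = vecs[:, np.argsort(vals)[::-1][: len(classes) - 1]]
    centroids = mu @ W
    return ClassifierModel(w_c=W, centroids=centroids, classes=classes,
                           selected=np.asarray(selected))


def fit_and_score(train: FirstSpikeMatrix, test: FirstSpikeMatrix,
                  selected, rule: str | None = None,
                  metadata: dict | None = None) -> AccuracyResult:
    """Fit the centroid readout on the training split and score the test split.

    ``rule`` is inferred from the class count when omitted ("midpoint" for
    two classes, "nearest-centroid" otherwise); passing it is a consistency
    check only.
    """
    selected = np.atleast_1d(np.asarray(selected, int))
    if selected.size < 1:
        raise ValueError("at least one selected sensor is required")
    model = _fit_classifier(train, selected)
    inferred = "midpoint" if len(model.classes) == 2 else "nearest-centroid"
    if rule is not None and rule != inferred:
        raise ValueError(f"rule {rule!r} does not match {len(model.classes)} classes")
    pred = model.predict(test.data.astype(float))
    acc = float(np.mean(pred == test.labels))
    return AccuracyResult(accuracy=acc, n_test=test.n_observations,
                          metadata=metadata or {})


def replicate_accuracy(pipeline, n_replicates: int = 20,
                       seed: int | None = 0,
                       metadata: dict | None = None) -> AccuracyResult:
    """Repeat a full pipeline with fresh seeds and report mean +/- sd accuracy.

    ``pipeline`` is a callable ``pipeline(seed) -> AccuracyResult`` (fresh
    simulation + spiking per call).  Requires at least two replicates.
    """
    if n_replicates < 2:
        raise ValueError("at least two replicates are required")
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    accs = np.array([pipeline(int(s % (2**31))).accuracy for s in seeds])
    n_test = 0
    return AccuracyResult(accuracy=float(accs.mean()), n_test=n_test,
                          replicate_sd=float(accs.std(ddof=1)),
                          replicate_accuracies=accs, metadata=metadata or {})
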