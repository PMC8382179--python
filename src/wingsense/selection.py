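"""SSPOC: sparse sensor placement optimization for classification.

Given the (observations x sensors) matrix of first-spike times, the method

1. standardizes features and finds an m-dimensional PCA basis Psi,
2. fits LDA in the reduced space to get the discriminating projection w
   (one column per discriminant direction; classes - 1 columns),
3. recovers a sparse sensor-weight vector s from the convex program
   min lam ||s||_1 + (1 - lam) ||s||_2 subject to Psi^T s = w (two classes)
   or |Psi^T s - w| <= eps columnwise (multi-class),
4. keeps the k sensors with the largest aggregated |weight|.

Defaults follow the study conditions: m = 3, lam = 0.9, eps = 1e-6, k = 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from ._elastic_net import solve_constrained_elastic_net
from .encoding import FirstSpikeMatrix

__all__ = ["SSPOCParams", "SubspaceModel", "SensorWeights", "fit_subspace",
           "solve_sensors_2class", "solve_sensors_multiclass", "top_k"]


@dataclass(frozen=True)
class SSPOCParams:
    m: int = 3                 # PCA subspace dimension
    lam: float = 0.9           # elastic-net mixing (L1 weight)
    eps: float = 1e-6          # multi-class constraint slack
    k: int = 10                # sensors kept
    squared_l2: bool = False   # use ||s||_2^2 instead of ||s||_2 in the objective

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.k < 1:
            raise ValueError("k must be at least 1")


@dataclass
class SubspaceModel:
    """Standardization + PCA basis + LDA directions fit on training data."""

    Psi: np.ndarray          # (n_sensors, m), orthonormal columns
    w: np.ndarray            # (m, n_classes - 1) discriminant directions
    center: np.ndarray       # per-sensor mean used for standardization
    scale: np.ndarray        # per-sensor sd (zero-variance sensors get 1)
    classes: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class SensorWeights:
    """Sensor weight vector/matrix from the sparse recovery, plus top-k picks."""

    s: np.ndarray            # (n_sensors,) or (n_sensors, n_cols)
    selected: np.ndarray     # indices of the k largest aggregated weights
    solver_info: dict = field(default_factory=dict)

    def aggregated(self) -> np.ndarray:
        s = np.atleast_2d(self.s.T).T
        return np.linalg.norm(s, axis=1)


def _lda_directions(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """LDA discriminant directions for low-dimensional X (m columns).

    Two classes: the classic w = Sw^-1 (mu1 - mu0), unit-normalized.
    Multi-class: top (C-1) generalized eigenvectors of (Sb, Sw).
    Deterministic sign: largest-magnitude component positive.
    """
    classes = np.unique(y)
    m = X.shape[1]
    mu = np.array([X[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((m, m))
    for c, mc in zip(classes, mu):
        d = X[y == c] - mc
        Sw += d.T @ d
    Sw += ridge * np.trace(Sw) / max(m, 1) * np.eye(m) + 1e-12 * np.eye(m)
    if len(classes) == 2:
        w = np.linalg.solve(Sw, mu[1] - mu[0])
        W = w[:, None]
    else:
        grand = X.mean(axis=0)
        Sb = np.zeros((m, m))
        for c, mc in zip(classes, mu):
            n_c = np.sum(y == c)
            d = (mc - grand)[:, None]
            Sb += n_c * d @ d.T
        from scipy.linalg import eigh
        vals, vecs = eigh(Sb, Sw)
        order = np.argsort(vals)[::-1]
        W = vecs[:, order[: len(classes) - 1]]
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    for j in range(W.shape[1]):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def fit_subspace(features: FirstSpikeMatrix | np.ndarray,
                 params: SSPOCParams | None = None,
                 labels=None) -> SubspaceModel:
    """Standardize, reduce with PCA to m dimensions, and fit LDA directions.

    Features are z-scored per sensor (zero-variance sensors get unit scale —
    they carry no class information and end up with near-zero weight).
    """
    params = params or SSPOCParams()
    if isinstance(features, FirstSpikeMatrix):
        X, y = features.data, features.labels
    else:
        X, y = np.asarray(features), None
    if labels is not None:
        y = np.asarray(labels)
    if y is None:
        raise ValueError("class labels are required")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("at least two classes are required")
    if X.shape[0] < params.m:
        raise ValueError("fewer observations than subspace dimensions")

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - center) / scale

    # randomized SVD for the large (observations x 1326 sensors) matrices;
    # exact for small problems where tests compare against closed forms
    solver = "full" if min(X.shape) <= 200 else "randomized"
    pca = PCA(n_components=params.m, svd_solver=solver, random_state=0)
    T = pca.fit_transform(Xs)
    Psi = pca.components_.T  # (n_sensors, m), orthonormal
    W = _lda_directions(T, y)
    if not np.isfinite(W).all() or np.linalg.norm(W) == 0:
        raise ValueError("degenerate LDA projection (no class separation)")
    return SubspaceModel(Psi=Psi, w=W, center=center, scale=scale,
                         classes=classes)


def solve_sensors_2class(model: SubspaceModel,
                         params: SSPOCParams | None = None) -> SensorWeights:
    """Exact-constraint elastic-net recovery of sensor weights (two classes)."""
    params = params or SSPOCParams()
    if model.w.shape[1] != 1:
        raise ValueError("two-class solve requires a single discriminant direction")
    s, info = solve_constrained_elastic_net(
        model.Psi, model.w[:, 0], lam=params.lam, eps=0.0,
        squared_l2=params.squared_l2)
    if info["constraint_violation"] > 1e-6:
        raise RuntimeError(
            f"elastic-net solve infeasible: constraint violation "
            f"{info['constraint_violation']:.2e}")
    weights = SensorWeights(s=s, selected=np.empty(0, int), solver_info=info)
    weights.selected = top_k(weights, params.k)
    return weights


def solve_sensors_multiclass(model: SubspaceModel,
                             params: SSPOCParams | None = None) -> SensorWeights:
    """Relaxed-constraint recovery, |Psi^T s - w| <= eps columnwise."""
    params = params or SSPOCParams()
    s, info = solve_constrained_elastic_net(
        model.Psi, model.w, lam=params.lam, eps=params.eps,
        squared_l2=params.squared_l2)
    if info["constraint_violation"] > 1e-6:
        raise RuntimeError(
            f"elastic-net solve infeasible: constraint violation "
            f"{info['constraint_violation']:.2e}")
    weights = SensorWeights(s=s, selected=np.empty(0, int), solver_info=info)
    weights.selected = top_k(weights, params.k)
    return weights


def top_k(weights: SensorWeights | np.ndarray, k: int = 10) -> np.ndarray:
    """Indices of the k largest aggregated |weights|, largest first.

    Ties break toward the lower grid index.  Raises if every weight is zero
    (no informative sensors).
    """
    agg = weights.aggregated() if isinstance(weights, SensorWeights) \
        else np.linalg.norm(np.atleast_2d(np.asarray(weights).T).T, axis=1)
    if k > agg.size:
        raise ValueError("k exceeds the number of sensors")
    if not np.any(agg > 0):
        raise ValueError("all sensor weights are zero; nothing to select")
    order = np.lexsort((np.arange(agg.size), -agg))
    return order[:k]
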