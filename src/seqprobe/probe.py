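"""KNN probing of embedding traces into a learning-curve surface.

The probe measures how locally separable the classes are in the hidden-state
space at each (epoch, timestep): a k-nearest-neighbor classifier on
(embedding, label) pairs under Euclidean distance.  Stacking its accuracy
over all timesteps (the information-processing trajectory) and all epochs
(the developmental trajectory) yields the epoch x timestep surface that is
this package's central object.

The evaluation protocol is configurable: stratified k-fold cross-validation
(default — in-sample 1-NN accuracy is degenerately 1.0), leave-one-out, or
in-sample.  Vote ties are broken by the tied classes' summed inverse
neighbor distance, then by the lower class index, so results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .model import EmbeddingTrace

__all__ = ["ProbeConfig", "LearningCurveSurface", "knn_accuracy", "map_learning_surface"]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class ProbeConfig:
    k: int = 5
    eval_protocol: str = "stratified_cv"
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.eval_protocol not in ("stratified_cv", "loocv", "insample"):
            raise ValueError(f"unknown eval_protocol {self.eval_protocol!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class LearningCurveSurface:
    """Epoch x timestep matrix of probe performance, with provenance."""

    performance: np.ndarray  # (E, T) in [0, 1]
    epochs: np.ndarray       # (E,) epoch ids (1-based)
    timesteps: np.ndarray    # (T,) time-slice ids (0-based)
    probe: ProbeConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.performance = np.asarray(self.performance, dtype=np.float64)
        if self.performance.ndim != 2:
            raise ValueError("performance must be 2-d (epochs x timesteps)")
        E, T = self.performance.shape
        if len(self.epochs) != E or len(self.timesteps) != T:
            raise ValueError("epoch/timestep ids must match the matrix")
        if np.any(self.performance < 0) or np.any(self.performance > 1):
            raise ValueError("performance entries must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return self.performance.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.performance.shape[1]


# ---------------------------------------------------------------------------
# KNN with the documented tie-break
# ---------------------------------------------------------------------------

def _vote(dist: np.ndarray, neigh_labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Majority vote per query row with deterministic tie-breaking.

    Ties on vote count are broken by the tied classes' summed inverse
    neighbor distance (larger wins — the nearer neighbor set), then by the
    lower class index.
    """
    n = dist.shape[0]
    votes = np.zeros((n, n_classes))
    weight = np.zeros((n, n_classes))
    inv = 1.0 / (dist + _TIE_EPS)
    for c in range(n_classes):
        is_c = neigh_labels == c
        votes[:, c] = is_c.sum(axis=1)
        weight[:, c] = np.where(is_c, inv, 0.0).sum(axis=1)
    top = votes.max(axis=1, keepdims=True)
    tied = votes == top
    # among tied classes pick the largest summed inverse distance; argmax's
    # first-occurrence rule supplies the lower-class-index fallback
    score = np.where(tied, weight, -np.inf)
    return score.argmax(axis=1)


def _predict(train_x, train_y, query_x, k, n_classes, exclude_self=False):
    nn = NearestNeighbors(n_neighbors=k + (1 if exclude_self else 0), metric="euclidean")
    nn.fit(train_x)
    dist, idx = nn.kneighbors(query_x)
    if exclude_self:
        # leave-one-out: each query is its own nearest point at distance 0;
        # drop one occurrence of the query itself per row
        keep = np.ones_like(idx, dtype=bool)
        for r in range(idx.shape[0]):
            self_cols = np.flatnonzero(idx[r] == r)
            drop = self_cols[0] if len(self_cols) else 0
            keep[r, drop] = False
        dist = dist[keep].reshape(len(query_x), k)
        idx = idx[keep].reshape(len(query_x), k)
    return _vote(dist, train_y[idx], n_classes)


def knn_accuracy(embeddings: np.ndarray, labels: np.ndarray, cfg: ProbeConfig) -> float:
    """Classification accuracy of the KNN probe on (embedding, label) pairs.

    Under ``stratified_cv`` the items are split into ``cfg.folds`` seeded
    stratified folds; each fold is predicted from the others.  ``loocv``
    predicts each item from all the rest; ``insample`` fits and scores on the
    full set (the item itself participates in its own neighborhood).
    """
    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if X.ndim != 2 or len(y) != len(X):
        raise ValueError("embeddings must be (n, d) with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present to probe")
    n_classes = int(classes.max()) + 1
    n = len(y)

    if cfg.eval_protocol == "insample":
        if n < cfg.k:
            raise ValueError(f"n={n} too small for k={cfg.k}")
        pred = _predict(X, y, X, cfg.k, n_classes)
        return float((pred == y).mean())

    if cfg.eval_protocol == "loocv":
        if n < cfg.k + 1:
            raise ValueError(f"n={n} too small for leave-one-out with k={cfg.k}")
        pred = _predict(X, y, X, cfg.k, n_classes, exclude_self=True)
        return float((pred == y).mean())

    # stratified cross-validation
    min_class = np.bincount(y, minlength=n_classes)[classes].min()
    if min_class < cfg.folds:
        raise ValueError(
            f"smallest class has {min_class} items; needs >= folds ({cfg.folds})"
        )
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        if len(train_idx) < cfg.k:
            raise ValueError(f"fold training size {len(train_idx)} < k={cfg.k}")
        pred = _predict(X[train_idx], y[train_idx], X[test_idx], cfg.k, n_classes)
        correct += int((pred == y[test_idx]).sum())
    return float(correct / n)


def map_learning_surface(
    traces: list[EmbeddingTrace], cfg: ProbeConfig, provenance: dict | None = None
) -> LearningCurveSurface:
    """Probe every (epoch, timestep) cell of a run's embedding traces."""
    if not traces:
        raise ValueError("no traces supplied")
    T = traces[0].T
    n_eval = traces[0].n_eval
    labels = traces[0].labels
    for tr in traces:
        if tr.T != T or tr.n_eval != n_eval or not np.array_equal(tr.labels, labels):
            raise ValueError("traces disagree on T, n_eval or labels")
    perf = np.empty((len(traces), T))
    for e, tr in enumerate(traces):
        for t in range(T):
            perf[e, t] = knn_accuracy(tr.hidden[t], labels, cfg)
    return LearningCurveSurface(
        performance=perf,
        epochs=np.array([tr.epoch for tr in traces]),
        timesteps=np.arange(T),
        probe=cfg,
        provenance=dict(provenance or {}),
    )
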