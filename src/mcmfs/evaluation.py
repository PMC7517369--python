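"""Experimental harness: feature selection followed by multi-label classification.

Mirrors the standard filter-method protocol: discretized features are
ranked on the training portion only, classifiers are trained on the top-b
features for an increasing grid of b, and the four multi-label metrics are
computed on held-out data.  Because every selector is a sequential forward
procedure, selection runs once at the largest b and the grid is served by
prefix slicing.

Three classifier adapters are provided: ML-kNN (the multi-label k-nearest
neighbour classifier with label-wise Bayesian posteriors and Laplace
smoothing), a per-label kNN vote, and a per-label (binary relevance)
linear SVM.  All three expose binary predictions plus a real-valued
confidence per label so that every metric applies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import LinearSVC

from .metrics import PredictionSet, compute_all
from .preprocessing import DiscreteDataset, TrainTestPair
from .selectors import select

__all__ = [
    "ExperimentConfig",
    "EvaluationReport",
    "MLkNN",
    "BinaryRelevanceKNN",
    "BinaryRelevanceLinearSVM",
    "CLASSIFIERS",
    "run_holdout_experiment",
    "run_cv_experiment",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# classifier adapters


class MLkNN:
    """Multi-label k-nearest-neighbour classifier.

    For each label, the classifier estimates the prior probability of the
    label and the likelihood of observing c neighbours carrying it among
    the k nearest training neighbours, with Laplace smoothing s; a test
    instance receives the label when the smoothed posterior favours it.
    The posterior probability doubles as the confidence score.
    """

    def __init__(self, k: int = 10, s: float = 1.0):
        self.k = k
        self.s = s

    def fit(self, X: NDArray, Y: NDArray) -> "MLkNN":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=np.int64)
        n, q = Y.shape
        k = min(self.k, n - 1) if n > 1 else 1
        if k < self.k:
            logger.warning("MLkNN: k clamped from %d to %d (only %d training instances)",
                           self.k, k, n)
        self.k_eff_ = k
        self.X_, self.Y_ = X, Y
        s = self.s
        self.prior_ = (s + Y.sum(axis=0)) / (2 * s + n)

        self._nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
        # leave-one-out neighbour label counts on the training set
        idx = self._nn.kneighbors(X, return_distance=False)
        counts = np.empty((n, q), dtype=np.int64)
        for i in range(n):
            neigh = [j for j in idx[i] if j != i][:k]
            counts[i] = Y[neigh].sum(axis=0)

        c1 = np.zeros((q, k + 1))
        c0 = np.zeros((q, k + 1))
        for l in range(q):
            for i in range(n):
                if Y[i, l]:
                    c1[l, counts[i, l]] += 1
                else:
                    c0[l, counts[i, l]] += 1
        self.like1_ = (s + c1) / (s * (k + 1) + c1.sum(axis=1, keepdims=True))
        self.like0_ = (s + c0) / (s * (k + 1) + c0.sum(axis=1, keepdims=True))
        return self

    def _posteriors(self, X: NDArray) -> NDArray[np.float64]:
        X = np.asarray(X, dtype=float)
        n_train = len(self.X_)
        idx = NearestNeighbors(n_neighbors=min(self.k_eff_, n_train)).fit(self.X_).kneighbors(
            X, return_distance=False
        )
        counts = self.Y_[idx].sum(axis=1)  # (n_test, q)
        q = self.Y_.shape[1]
        post = np.empty((len(X), q))
        for l in range(q):
            c = counts[:, l]
            p1 = self.prior_[l] * self.like1_[l, c]
            p0 = (1 - self.prior_[l]) * self.like0_[l, c]
            post[:, l] = p1 / (p1 + p0)
        return post

    def predict(self, X: NDArray) -> NDArray[np.int64]:
        return (self._posteriors(X) > 0.5).astype(np.int64)

    def confidence(self, X: NDArray) -> NDArray[np.float64]:
        return self._posteriors(X)


class BinaryRelevanceKNN:
    """Per-label k-nearest-neighbour vote; confidence is the vote fraction."""

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X: NDArray, Y: NDArray) -> "BinaryRelevanceKNN":
        X = np.asarray(X, dtype=float)
        self.Y_ = np.asarray(Y, dtype=np.int64)
        k = min(self.k, len(X))
        if k < self.k:
            logger.warning("kNN: k clamped from %d to %d", self.k, k)
        self.k_eff_ = k
        self._nn = NearestNeighbors(n_neighbors=k).fit(X)
        return self

    def confidence(self, X: NDArray) -> NDArray[np.float64]:
        idx = self._nn.kneighbors(np.asarray(X, dtype=float), return_distance=False)
        return self.Y_[idx].mean(axis=1)

    def predict(self, X: NDArray) -> NDArray[np.int64]:
        return (self.confidence(X) > 0.5).astype(np.int64)


class BinaryRelevanceLinearSVM:
    """One linear SVM per label; confidence is the signed decision value.

    A label that is constant in the training data gets a constant
    predictor with confidence +/-1.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X: NDArray, Y: NDArray) -> "BinaryRelevanceLinearSVM":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=np.int64)
        self.models_: list = []
        for l in range(Y.shape[1]):
            y = Y[:, l]
            if len(np.unique(y)) < 2:
                self.models_.append(int(y[0]))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence on tiny folds
                clf = LinearSVC(C=self.C).fit(X, y)
            self.models_.append(clf)
        return self

    def confidence(self, X: NDArray) -> NDArray[np.float64]:
        X = np.asarray(X, dtype=float)
        cols = []
        for m in self.models_:
            if isinstance(m, int):
                cols.append(np.full(len(X), 1.0 if m else -1.0))
            else:
                cols.append(m.decision_function(X))
        return np.column_stack(cols)

    def predict(self, X: NDArray) -> NDArray[np.int64]:
        return (self.confidence(X) > 0).astype(np.int64)


CLASSIFIERS: dict[str, Callable[..., object]] = {
    "mlknn": MLkNN,
    "knn": BinaryRelevanceKNN,
    "svm": BinaryRelevanceLinearSVM,
}


# ---------------------------------------------------------------------------
# experiment driver


def default_b_grid(d: int, fraction: float = 0.20) -> list[int]:
    """1..ceil(fraction * d): the number-of-features grid used in evaluation."""
    return list(range(1, max(1, int(np.ceil(fraction * d))) + 1))


@dataclass
class ExperimentConfig:
    """Settings for a selection-plus-classification experiment."""

    methods: list[str] = field(default_factory=lambda: ["mcmfs"])
    b_grid: list[int] | None = None  # default: 1..ceil(0.2 d)
    classifiers: list[str] = field(default_factory=lambda: ["mlknn", "knn", "svm"])
    classifier_params: dict[str, dict] = field(default_factory=dict)
    selector_params: dict[str, dict] = field(default_factory=dict)
    cv_folds: int | None = None
    seed: int = 0

    def resolve_b_grid(self, d: int) -> list[int]:
        grid = self.b_grid if self.b_grid is not None else default_b_grid(d)
        if any(not 1 <= b <= d for b in grid):
            raise ValueError(f"b grid {grid} outside [1, {d}]")
        return sorted(set(grid))


@dataclass
class EvaluationReport:
    """Long-format metric table: (method, classifier, b, metric, value)."""

    table: pd.DataFrame

    def mean_metric(
        self, metric: str, method: str | None = None, classifier: str | None = None
    ) -> float:
        t = self.table[self.table.metric == metric]
        if method is not None:
            t = t[t.method == method]
        if classifier is not None:
            t = t[t.classifier == classifier]
        if t.empty:
            raise ValueError(f"no rows for metric={metric}, method={method}")
        return float(t.value.mean())

    def to_tsv(self, path: str | Path | None = None) -> str:
        text = self.table.to_csv(sep="\t", index=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        text = self.table.to_json(orient="records", indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _make_classifier(name: str, cfg: ExperimentConfig):
    params = cfg.classifier_params.get(name, {})
    return CLASSIFIERS[name](**params)


def _evaluate_split(
    train: DiscreteDataset,
    test: DiscreteDataset,
    cfg: ExperimentConfig,
    b_grid: list[int],
) -> list[dict]:
    rows: list[dict] = []
    b_max = max(b_grid)
    for method in cfg.methods:
        result = select(train, method, b_max, **cfg.selector_params.get(method, {}))
        for b in b_grid:
            keep = result.order[:b]
            Xtr, Xte = train.features[:, keep], test.features[:, keep]
            for clf_name in cfg.classifiers:
                try:
                    clf = _make_classifier(clf_name, cfg).fit(Xtr, train.labels)
                    pred = PredictionSet(
                        test.labels, clf.predict(Xte), clf.confidence(Xte)
                    )
                    values = compute_all(pred)
                except Exception as exc:  # record and continue with the grid
                    logger.error("classifier %s failed at method=%s b=%d: %s",
                                 clf_name, method, b, exc)
                    rows.append({"method": method, "classifier": clf_name, "b": b,
                                 "metric": "error", "value": np.nan})
                    continue
                for metric, value in values.items():
                    rows.append({"method": method, "classifier": clf_name, "b": b,
                                 "metric": metric, "value": value})
    return rows


def run_holdout_experiment(pair: TrainTestPair, cfg: ExperimentConfig) -> EvaluationReport:
    """Select on the training set, evaluate classifiers on the test set."""
    b_grid = cfg.resolve_b_grid(pair.train.d)
    rows = _evaluate_split(pair.train, pair.test, cfg, b_grid)
    return EvaluationReport(pd.DataFrame(rows))


def run_cv_experiment(data: DiscreteDataset, cfg: ExperimentConfig) -> EvaluationReport:
    """Seeded shuffled k-fold cross-validation with selection inside each fold.

    Reported values are means over folds for each (method, classifier, b,
    metric) cell.
    """
    folds = cfg.cv_folds or 5
    if folds > data.n:
        raise ValueError(f"cv_folds={folds} exceeds n={data.n}")
    b_grid = cfg.resolve_b_grid(data.d)
    kf = KFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    rows: list[dict] = []
    for fold, (tr, te) in enumerate(kf.split(data.features)):
        fold_rows = _evaluate_split(
            data.subset_rows(tr), data.subset_rows(te), cfg, b_grid
        )
        for r in fold_rows:
            r["fold"] = fold
        rows.extend(fold_rows)
    frame = pd.DataFrame(rows)
    mean = (
        frame[frame.metric != "error"]
        .groupby(["method", "classifier", "b", "metric"], as_index=False)
        .value.mean()
    )
    return EvaluationReport(mean)
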