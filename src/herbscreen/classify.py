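"""Ensemble activity classification and evaluation.

Seven base learners plus an unweighted soft-voting meta-learner, evaluated
by stratified k-fold cross-validation with a single confusion matrix pooled
over out-of-fold predictions (the convention behind ACC/SE/SP tables in
QSAR work), and AUC as the Mann-Whitney pair statistic on pooled
out-of-fold scores.

The learners are functional analogues of the classic WEKA set: a Gaussian
naive Bayes, a CART-style pruned tree, plain k-NN, a distance-weighted k-NN
with an exponential kernel (an entropy-motivated nearest-neighbour
analogue), a random forest, bagged k-NN, and AdaBoost over shallow trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .io import ConfigurationError, DataError

LEARNER_NAMES = (
    "naive_bayes",
    "decision_tree",
    "knn_entropic",
    "knn",
    "random_forest",
    "bagging_knn",
    "adaboost_tree",
    "voting",
)


@dataclass(frozen=True)
class LearnerSpec:
    """A named learner with its parameter map."""

    name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise ConfigurationError(
                f"unknown learner {self.name!r}; choose from {LEARNER_NAMES}"
            )


@dataclass(frozen=True)
class ModelMetrics:
    """Pooled confusion counts and the derived ACC / SE / SP / AUC."""

    tp: int
    fn: int
    tn: int
    fp: int
    auc: float | None = None

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ModelMetrics:
    """Exact ACC/SE/SP from confusion counts (no internal rounding)."""
    if min(tp, fn, tn, fp) < 0:
        raise DataError("confusion counts must be non-negative")
    if tp + fn < 1 or tn + fp < 1:
        raise DataError("both classes must be represented (undefined metric)")
    return ModelMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney pair statistic.

    Fraction of (active, inactive) pairs whose active member scores strictly
    higher, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise DataError("AUC undefined: one class absent")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _exp_kernel_weights(dist: np.ndarray) -> np.ndarray:
    # entropy-motivated kernel: weight decays exponentially with distance,
    # scaled by the mean neighbour distance per query point
    scale = dist.mean(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return np.exp(-dist / scale)


def build_learner(spec: LearnerSpec, seed: int = 0):
    """Instantiate the sklearn estimator for a learner spec.

    Distance-based learners are wrapped with feature standardization.
    ``decision_tree`` exposes ``confidence`` (pruning strength mapped to
    cost-complexity alpha) and the k-NN variants ``n_neighbors``.
    """
    p = dict(spec.params)
    name = spec.name
    if name == "naive_bayes":
        return GaussianNB(**p)
    if name == "decision_tree":
        conf = p.pop("confidence", 0.25)
        # lower pruning confidence -> heavier pruning (larger ccp_alpha)
        return DecisionTreeClassifier(
            ccp_alpha=p.pop("ccp_alpha", 0.01 * (0.5 - min(conf, 0.5))),
            random_state=seed,
            **p,
        )
    if name == "knn":
        return _scaled(KNeighborsClassifier(n_neighbors=p.pop("n_neighbors", 5), **p))
    if name == "knn_entropic":
        return _scaled(
            KNeighborsClassifier(
                n_neighbors=p.pop("n_neighbors", 15),
                weights=_exp_kernel_weights,
                **p,
            )
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 200), random_state=seed, n_jobs=1, **p
        )
    if name == "bagging_knn":
        return _scaled(
            BaggingClassifier(
                KNeighborsClassifier(n_neighbors=p.pop("n_neighbors", 5)),
                n_estimators=p.pop("n_estimators", 10),
                random_state=seed,
                **p,
            )
        )
    if name == "adaboost_tree":
        return AdaBoostClassifier(
            DecisionTreeClassifier(max_depth=p.pop("max_depth", 3)),
            n_estimators=p.pop("n_estimators", 50),
            random_state=seed,
            **p,
        )
    if name == "voting":
        base = p.pop("base_learners", None)
        if base is None:
            base = [LearnerSpec(n, {}) for n in LEARNER_NAMES[:-1]]
        return _VotingModel([build_learner(s, seed) for s in base])
    raise ConfigurationError(f"unknown learner {name!r}")


def _scaled(est):
    return Pipeline([("scale", StandardScaler()), ("model", est)])


class _VotingModel:
    """Unweighted mean of base-model active-class probabilities."""

    def __init__(self, models):
        if len(models) < 2:
            raise ConfigurationError("voting needs at least 2 base models")
        self.models = models

    def fit(self, X, y):
        for m in self.models:
            m.fit(X, y)
        self.classes_ = self.models[0].classes_
        return self

    def predict_proba(self, X):
        probs = [m.predict_proba(X) for m in self.models]
        return np.mean(probs, axis=0)

    def predict(self, X):
        # boundary rule: score >= 0.5 -> active
        active_col = int(np.flatnonzero(self.classes_ == 1)[0])
        return (self.predict_proba(X)[:, active_col] >= 0.5).astype(int)

    def get_params(self, deep=False):
        return {"models": self.models}

    def __sklearn_clone__(self):
        return _VotingModel([clone(m) for m in self.models])


def voting_predict(base_models, x) -> float:
    """Voting score for one sample: mean active-class probability."""
    if len(base_models) < 2:
        raise ConfigurationError("voting needs at least 2 fitted base models")
    x = np.atleast_2d(x)
    scores = []
    for m in base_models:
        if not hasattr(m, "predict_proba"):
            raise ConfigurationError(
                f"base model {m!r} lacks probability output"
            )
        active_col = int(np.flatnonzero(m.classes_ == 1)[0])
        scores.append(float(m.predict_proba(x)[0, active_col]))
    return float(np.mean(scores))


def _active_proba(model, X) -> np.ndarray:
    proba = model.predict_proba(X)
    active_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return proba[:, active_col]


def crossvalidate(
    X, y, spec: LearnerSpec, k: int = 5, seed: int = 0
) -> ModelMetrics:
    """Stratified k-fold CV with metrics pooled over out-of-fold predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DataError("labels must be binary with both classes present")
    if counts.min() < k:
        raise DataError(f"smallest class ({counts.min()}) has fewer members than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_score = np.empty(len(y))
    oof_pred = np.empty(len(y), dtype=int)
    for train, test in skf.split(X, y):
        model = build_learner(spec, seed=seed)
        model.fit(X[train], y[train])
        s = _active_proba(model, X[test])
        oof_score[test] = s
        oof_pred[test] = (s >= 0.5).astype(int)
    tp = int(((oof_pred == 1) & (y == 1)).sum())
    fn = int(((oof_pred == 0) & (y == 1)).sum())
    tn = int(((oof_pred == 0) & (y == 0)).sum())
    fp = int(((oof_pred == 1) & (y == 0)).sum())
    return ModelMetrics(tp=tp, fn=fn, tn=tn, fp=fp, auc=auc_score(oof_score, y))


def _complexity(name: str, point: dict[str, Any]) -> tuple:
    # ties broken toward simpler models: fewer neighbours / shallower trees
    return (
        point.get("n_neighbors", 0),
        point.get("max_depth", 0),
        point.get("n_estimators", 0),
    )


def parameter_search(
    X, y, spec: LearnerSpec, grid: dict[str, Sequence[Any]], k: int = 5, seed: int = 0
) -> LearnerSpec:
    """Grid CV parameter selection maximizing pooled CV accuracy.

    Ties go to the simpler model (fewer neighbours, shallower/smaller
    ensembles), then to grid order.
    """
    keys = list(grid.keys())
    points = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k_] for k_ in keys))]
    if not points:
        raise ConfigurationError("empty parameter grid")
    best = None
    for gi, point in enumerate(points):
        cand = LearnerSpec(spec.name, {**spec.params, **point})
        acc = crossvalidate(X, y, cand, k=k, seed=seed).acc
        key = (-acc, _complexity(spec.name, point), gi)
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]
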