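"""Random forest with per-node weighted candidate-feature sampling.

A from-scratch binary random-forest classifier in which the ``mtry``
candidate features examined at every tree node are drawn *without
replacement* with probabilities proportional to a user-supplied feature
weight vector (an *enriched* random forest).  With uniform probabilities it
reduces to a standard random forest.  The forest exposes normalized Gini
variable importance and the tree-versus-ensemble error decomposition used
to quantify ensemble diversity.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) and composes with sklearn model
selection; it is restricted to binary classification and non-negative
feature values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _tree
from .errors import DegenerateWeightsError, ValidationError


@dataclass
class ForestParams:
    """Forest hyper-parameters.

    ``mtry=None`` means ⌊√p⌋ (at least 1).  Trees are fully grown by default
    (``min_node_size=1``) and each tree is built on a bootstrap replicate of
    the training instances.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 1
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1")


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Gini impurity ``1 − Σ_k (n_k/n)²`` of a two-class count pair."""
    n0, n1 = class_counts
    if n0 < 0 or n1 < 0:
        raise ValidationError("class counts must be non-negative")
    n = n0 + n1
    if n == 0:
        raise ValidationError("gini impurity of an empty node is undefined")
    return 1.0 - (n0 / n) ** 2 - (n1 / n) ** 2


def _prepare_probs(probs: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, int]:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (p,):
        raise ValidationError(f"probability vector has shape {probs.shape}, expected ({p},)")
    if (probs < 0).any():
        raise ValidationError("sampling probabilities must be non-negative")
    total = probs.sum()
    if total <= 0:
        raise DegenerateWeightsError("all feature sampling probabilities are zero")
    probs = probs / total
    cumsum = np.cumsum(probs)
    cumsum[-1] = 1.0
    nnz = int(np.count_nonzero(probs))
    return probs, cumsum, nnz


def sample_candidates(probs: np.ndarray, mtry: int, rng_state: int) -> np.ndarray:
    """Draw ``min(mtry, #nonzero)`` distinct column indices.

    Successive draws without replacement, each proportional to the remaining
    probabilities; zero-probability columns are never returned.  Deterministic
    given ``rng_state``.
    """
    if mtry < 1:
        raise ValidationError("mtry must be >= 1")
    probs, cumsum, nnz = _prepare_probs(probs, len(np.asarray(probs)))
    chosen = np.empty(len(probs), dtype=np.int64)
    taken = np.zeros(len(probs), dtype=np.bool_)
    state = np.uint64(
        _tree.derive_substream(np.uint64(rng_state & 0xFFFFFFFFFFFFFFFF), np.uint64(0))
    )
    count, _ = _tree.sample_candidates_kernel(probs, cumsum, nnz, mtry, state, chosen, taken)
    return chosen[:count].copy()


class WeightedRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Binary random forest with weighted per-node feature sampling.

    Parameters
    ----------
    n_trees : int, default 500
        Number of trees in the ensemble.
    mtry : int or None, default None
        Candidate features examined per node; ``None`` means ⌊√p⌋ (min 1).
        When fewer columns have nonzero sampling probability, all of them
        are used.
    min_node_size : int, default 1
        Minimum samples per child node; 1 grows trees fully.
    bootstrap : bool, default True
        Build each tree on a size-*n* bootstrap replicate.
    feature_probabilities : array-like of shape (p,) or None, default None
        Per-feature candidate sampling weights (need not be normalized);
        ``None`` means uniform.  Columns with probability zero never appear
        in any tree.
    random_state : int, default 0
        Seed; per-tree substreams are derived from (seed, tree index), so a
        refit with identical inputs reproduces the forest exactly.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is the positive (ADE) class.
    feature_importances_ : ndarray of shape (p,)
        Normalized Gini importance (sums to 1 unless no split was ever made).
    trees_ : list of per-tree node-array tuples.
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int | None = None,
        min_node_size: int = 1,
        bootstrap: bool = True,
        feature_probabilities=None,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.bootstrap = bootstrap
        self.feature_probabilities = feature_probabilities
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _as_dense(X) -> np.ndarray:
        if sp.issparse(X):
            X = X.toarray()
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        if X.ndim != 2:
            raise ValidationError("X must be a 2-d matrix")
        return X

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = self._as_dense(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y have inconsistent lengths")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError(
                f"exactly two classes are required, got {list(self.classes_)}"
            )
        y01 = np.ascontiguousarray((y == self.classes_[1]).astype(np.int64))
        n, p = X.shape
        if p == 0:
            raise ValidationError("X has no feature columns")
        self.n_features_in_ = p

        if self.feature_probabilities is None:
            probs = np.full(p, 1.0 / p)
        else:
            probs = np.asarray(self.feature_probabilities, dtype=np.float64)
        probs, cumsum, nnz = _prepare_probs(probs, p)

        mtry = self.mtry
        if mtry is None:
            mtry = max(1, int(np.floor(np.sqrt(p))))
        if mtry > p:
            raise ValidationError(f"mtry={mtry} exceeds the number of features p={p}")
        params = ForestParams(
            self.n_trees, mtry, self.min_node_size, self.bootstrap, int(self.random_state)
        )

        trees = []
        imp = np.zeros(p, dtype=np.float64)
        base = np.uint64(params.seed & 0xFFFFFFFFFFFFFFFF)
        for t in range(params.n_trees):
            tree_seed = np.uint64(_tree.derive_substream(base, np.uint64(t + 1)))
            feature, thr, left, right, n0, n1, tree_imp, _ = _tree.grow_tree(
                X,
                y01,
                probs,
                cumsum,
                nnz,
                mtry,
                params.min_node_size,
                params.bootstrap,
                tree_seed,
            )
            trees.append((feature, thr, left, right, n0, n1))
            imp += tree_imp

        imp /= params.n_trees
        total = imp.sum()
        self.feature_importances_ = imp / total if total > 0 else imp
        self.trees_ = trees
        self._params_ = params
        self._probs_ = probs
        return self

    def _vote_matrix(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = self._as_dense(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} columns, forest manifest has {self.n_features_in_}"
            )
        votes = np.empty((len(self.trees_), X.shape[0]), dtype=np.int64)
        for t, (feature, thr, left, right, n0, n1) in enumerate(self.trees_):
            votes[t] = _tree.tree_votes(feature, thr, left, right, n0, n1, X)
        return votes

    def predict_proba(self, X) -> np.ndarray:
        """Fraction of trees voting for each class (positive = classes_[1])."""
        votes = self._vote_matrix(X)
        pos = votes.mean(axis=0)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X) -> np.ndarray:
        """Majority vote; an exact tie goes to the negative class."""
        scores = self.predict_proba(X)[:, 1]
        return self.classes_[(scores > 0.5).astype(np.int64)]

    # -- diagnostics -------------------------------------------------------

    def decompose_error(self, X, y) -> tuple[float, float, float]:
        """(average tree error, ensemble error, diversity) on a labelled set.

        Diversity is the average individual-tree 0-1 error minus the voted
        ensemble 0-1 error; a positive value means the ensemble beats its
        average member.
        """
        y = np.asarray(y)
        if y.shape[0] == 0:
            raise ValidationError("empty evaluation set")
        y01 = (y == self.classes_[1]).astype(np.int64)
        votes = self._vote_matrix(X)
        tree_errors = (votes != y01[None, :]).mean(axis=1)
        ens = (votes.mean(axis=0) > 0.5).astype(np.int64)
        ensemble_error = float((ens != y01).mean())
        avg_tree_error = float(tree_errors.mean())
        return avg_tree_error, ensemble_error, avg_tree_error - ensemble_error

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Self-describing text serialization with exact threshold round-trip."""
        check_is_fitted(self, "trees_")
        payload = {
            "format": "ehrweights-forest/1",
            "params": {
                "n_trees": self._params_.n_trees,
                "mtry": self._params_.mtry,
                "min_node_size": self._params_.min_node_size,
                "bootstrap": self._params_.bootstrap,
                "seed": self._params_.seed,
            },
            "classes": [int(c) if np.issubdtype(type(c), np.integer) else c
                        for c in self.classes_.tolist()],
            "n_features": self.n_features_in_,
            "trees": [
                {
                    "feature": f.tolist(),
                    "threshold": [v.hex() for v in thr.tolist()],
                    "left": l.tolist(),
                    "right": r.tolist(),
                    "n0": n0.tolist(),
                    "n1": n1.tolist(),
                }
                for f, thr, l, r, n0, n1 in self.trees_
            ],
            "feature_importances": self.feature_importances_.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "WeightedRandomForestClassifier":
        payload = json.loads(text)
        if payload.get("format") != "ehrweights-forest/1":
            raise ValidationError("unrecognized forest serialization format")
        prm = payload["params"]
        est = cls(
            n_trees=prm["n_trees"],
            mtry=prm["mtry"],
            min_node_size=prm["min_node_size"],
            bootstrap=prm["bootstrap"],
            random_state=prm["seed"],
        )
        est.classes_ = np.asarray(payload["classes"])
        est.n_features_in_ = payload["n_features"]
        est.trees_ = [
            (
                np.asarray(t["feature"], dtype=np.int64),
                np.asarray([float.fromhex(h) for h in t["threshold"]], dtype=np.float64),
                np.asarray(t["left"], dtype=np.int64),
                np.asarray(t["right"], dtype=np.int64),
                np.asarray(t["n0"], dtype=np.int64),
                np.asarray(t["n1"], dtype=np.int64),
            )
            for t in payload["trees"]
        ]
        est.feature_importances_ = np.asarray(payload["feature_importances"])
        est._params_ = ForestParams(
            prm["n_trees"], prm["mtry"], prm["min_node_size"], prm["bootstrap"], prm["seed"]
        )
        return est


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_forest(X, y, probs, params: ForestParams) -> WeightedRandomForestClassifier:
    """Fit a weighted-sampling forest; ``probs=None`` means uniform."""
    est = WeightedRandomForestClassifier(
        n_trees=params.n_trees,
        mtry=params.mtry,
        min_node_size=params.min_node_size,
        bootstrap=params.bootstrap,
        feature_probabilities=probs,
        random_state=params.seed,
    )
    return est.fit(X, y)


def predict(forest: WeightedRandomForestClassifier, X) -> np.ndarray:
    return forest.predict(X)


def predict_proba(forest: WeightedRandomForestClassifier, X) -> np.ndarray:
    return forest.predict_proba(X)[:, 1]


def gini_importance(forest: WeightedRandomForestClassifier) -> np.ndarray:
    """Normalized Gini importance vector of a fitted forest."""
    check_is_fitted(forest, "feature_importances_")
    return forest.feature_importances_


def error_decomposition(forest: WeightedRandomForestClassifier, X, y):
    return forest.decompose_error(X, y)


def forest_feature_usage(forest: WeightedRandomForestClassifier) -> set[int]:
    """Set of feature indices appearing in any internal node of any tree."""
    used: set[int] = set()
    for feature, *_ in forest.trees_:
        used.update(int(f) for f in feature[feature >= 0])
    return used
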