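"""Random-forest backbone and the per-tree output transform.

The forest is a standard CART regression ensemble: M trees, each fit with a
random feature subset considered at every node.  Once fitted, tree
parameters are frozen.  Instead of collapsing the ensemble by averaging,
each reaction x is mapped to the M-vector of per-tree predictions

    x' = (h_1(x), h_2(x), ..., h_M(x))

which is the input the attention head re-weights.  The classic
random-forest prediction is exactly the uniform column average of this
matrix, so the baseline method is recoverable from this module alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the regression forest.

    max_features follows the d/3 regression heuristic by default; any value
    accepted by scikit-learn (int, float fraction, "sqrt", ...) may be given.
    """

    m_trees: int = 100
    max_features: float | int | str = 1 / 3
    min_leaf: int = 1
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.m_trees < 1:
            raise ValueError("m_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class TreeOutputMatrix:
    """N x M matrix of per-tree predictions; row i is x_i'."""

    values: np.ndarray
    row_index: np.ndarray

    def ensemble_mean(self) -> np.ndarray:
        """The plain random-forest prediction: uniform average over trees."""
        return self.values.mean(axis=1)


class Forest:
    """M fitted regression trees plus bookkeeping.

    Thin wrapper around a fitted scikit-learn ``RandomForestRegressor``:
    exposes per-tree predictions, the ensemble mean, and a portable JSON
    dump of the tree structures (split feature, threshold, children, leaf
    value) so a model can be reloaded without refitting.
    """

    def __init__(self, trees: list, config: ForestConfig, feature_dim: int):
        self.trees = trees
        self.config = config
        self.feature_dim = feature_dim
        if len(trees) != config.m_trees:
            raise ValueError("tree count does not match config.m_trees")

    @property
    def m_trees(self) -> int:
        return len(self.trees)

    def _check_dim(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature dimension {X.shape[1]} != expected {self.feature_dim}"
            )
        return X

    def predict_trees(self, features: np.ndarray) -> np.ndarray:
        """N x M matrix; entry (i, m) = h_m(x_i)."""
        X = self._check_dim(features)
        return np.column_stack([t.predict(X) for t in self.trees])

    def predict_mean(self, features: np.ndarray) -> np.ndarray:
        return self.predict_trees(features).mean(axis=1)

    def to_dict(self) -> dict:
        """Versioned portable dump of every tree."""
        return {
            "format": "metarf-forest",
            "version": 1,
            "feature_dim": self.feature_dim,
            "config": {
                "m_trees": self.config.m_trees,
                "max_features": self.config.max_features,
                "min_leaf": self.config.min_leaf,
                "bootstrap": self.config.bootstrap,
                "seed": self.config.seed,
            },
            "trees": [_dump_tree(t) for t in self.trees],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "Forest":
        if d.get("format") != "metarf-forest":
            raise ValueError("not a forest dump")
        cfg = ForestConfig(**d["config"])
        trees = [_DumpedTree(t) for t in d["trees"]]
        return cls(trees, cfg, d["feature_dim"])

    @classmethod
    def from_json(cls, s: str) -> "Forest":
        return cls.from_dict(json.loads(s))


def _dump_tree(tree) -> dict:
    t = tree.tree_ if hasattr(tree, "tree_") else tree._raw
    if isinstance(t, dict):
        return t
    return {
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "value": t.value.reshape(-1).tolist(),
    }


class _DumpedTree:
    """A regression tree rebuilt from its JSON dump; predict only."""

    def __init__(self, d: dict):
        self._raw = d
        self.feature = np.asarray(d["feature"], dtype=int)
        self.threshold = np.asarray(d["threshold"], dtype=float)
        self.left = np.asarray(d["children_left"], dtype=int)
        self.right = np.asarray(d["children_right"], dtype=int)
        self.value = np.asarray(d["value"], dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        for i, x in enumerate(X):
            node = 0
            while self.left[node] != -1:
                if x[self.feature[node]] <= self.threshold[node]:
                    node = self.left[node]
                else:
                    node = self.right[node]
            out[i] = self.value[node]
        return out


def fit_forest(
    train_features: np.ndarray,
    train_yields: np.ndarray,
    config: ForestConfig = ForestConfig(),
    max_depth: int | None = None,
) -> Forest:
    """Fit M regression trees with per-node random feature subsetting.

    Deterministic for a fixed ``config.seed``.  Tree parameters are frozen
    after fitting; downstream meta-learning never touches them.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_yields, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] == 0:
        raise ValueError("need an N x d matrix with N >= 2 and d >= 1")
    if y.shape != (X.shape[0],):
        raise ValueError("train_yields length must match train_features rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in training data")

    rf = RandomForestRegressor(
        n_estimators=config.m_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_leaf,
        bootstrap=config.bootstrap,
        max_depth=max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return Forest(list(rf.estimators_), config, X.shape[1])


def tree_transform(forest: Forest, features: np.ndarray) -> TreeOutputMatrix:
    """Map each row to its per-tree prediction vector x' (shape N x M)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return TreeOutputMatrix(
        values=forest.predict_trees(X),
        row_index=np.arange(X.shape[0]),
    )
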