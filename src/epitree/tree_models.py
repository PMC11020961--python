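"""Epistasis and no-epistasis tree models on the penetrance scale.

The alternative ("epistasis") model for an interaction I = {A1..Ad} is a
single CART fit to all d features; the null ("no epistasis") model is an
additive combination of two regression trees over a bipartition (I1, I2)
of I, combined by backfitting:

    H1: P(y=1 | a1..ad) = CART(A1,...,Ad)
    H0: P(y=1 | a1..ad) = mu + CART1(I1) + CART2(I2)

Both operate directly on the probability (penetrance) scale; predictions
are clipped to [eps, 1-eps] before any likelihood evaluation.  Tree depth
is tuned per interaction to the shallowest tree that still uses every
feature of I, which keeps the alternative and null models of comparable
complexity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from epitree.core_data import EPS, FeatureMatrix, ValidationError

DEPTH_CEILING = 8
MAX_BACKFIT_ROUNDS = 20
BACKFIT_TOL = 1e-6


@dataclass(frozen=True)
class Interaction:
    """Ordered set of interacting feature ids; order d = len."""

    feature_ids: tuple

    def __init__(self, feature_ids):
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in feature_ids))
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError(f"duplicate features in interaction {self.feature_ids}")

    @property
    def order(self) -> int:
        return len(self.feature_ids)

    @property
    def key(self) -> tuple:
        return tuple(sorted(self.feature_ids))

    def __str__(self) -> str:
        return ";".join(self.feature_ids)


@dataclass(frozen=True)
class Partition:
    """Bipartition (I1, I2) of an interaction's features for the null model."""

    group1: tuple
    group2: tuple

    def __init__(self, group1, group2):
        object.__setattr__(self, "group1", tuple(str(f) for f in group1))
        object.__setattr__(self, "group2", tuple(str(f) for f in group2))
        if not self.group1 or not self.group2:
            raise ValidationError("both partition groups must be non-empty")
        if set(self.group1) & set(self.group2):
            raise ValidationError("partition groups overlap")

    def validate_for(self, interaction: Interaction) -> None:
        if set(self.group1) | set(self.group2) != set(interaction.feature_ids):
            raise ValidationError("partition does not cover the interaction")

    def __str__(self) -> str:
        return ",".join(self.group1) + "|" + ",".join(self.group2)


@dataclass(frozen=True)
class TuningParams:
    max_depth: int
    min_leaf: int
    all_features_used: bool = True

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")


def default_min_leaf(n: int) -> int:
    """Leaf-size floor shared by alternative and null component trees."""
    return max(25, n // 500)


@dataclass
class TreeModel:
    """Flat-array binary tree (CART) over named features.

    ``feature[i] == -1`` marks a leaf; ``value[i]`` is then the prediction
    (a class-1 probability for classification trees, a real offset for
    regression trees).  Internal nodes route x[feature] <= threshold to
    ``left``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_samples: np.ndarray
    feature_ids: list
    tuning: TuningParams | None = None
    kind: str = "classification"
    n_pos: np.ndarray | None = None  # class-1 training count per node

    def __post_init__(self):
        if self.kind == "classification":
            leaves = self.feature < 0
            v = self.value[leaves]
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValidationError("leaf probabilities outside [0,1]")

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def features_used(self) -> set:
        return {self.feature_ids[f] for f in self.feature if f >= 0}

    def leaf_ids(self) -> np.ndarray:
        return np.nonzero(self.feature < 0)[0]

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index for every row of X (columns ordered as feature_ids)."""
        X = np.asarray(X, dtype=float)
        node = np.zeros(len(X), dtype=np.int64)
        while True:
            f = self.feature[node]
            active = f >= 0
            if not active.any():
                return node
            idx = np.nonzero(active)[0]
            fa = f[idx]
            go_left = X[idx, fa] <= self.threshold[node[idx]]
            node[idx] = np.where(
                go_left, self.left[node[idx]], self.right[node[idx]]
            )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw leaf values (no clipping)."""
        return self.value[self.apply(X)]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_ids": list(self.feature_ids),
            "tuning": None if self.tuning is None else {
                "max_depth": self.tuning.max_depth,
                "min_leaf": self.tuning.min_leaf,
                "all_features_used": self.tuning.all_features_used,
            },
            "nodes": [
                {
                    "feature": None if self.feature[i] < 0
                    else self.feature_ids[self.feature[i]],
                    "threshold": None if self.feature[i] < 0
                    else float(self.threshold[i]),
                    "left": int(self.left[i]),
                    "right": int(self.right[i]),
                    "value": float(self.value[i]),
                    "n_samples": int(self.n_samples[i]),
                }
                for i in range(self.n_nodes)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        fids = [str(f) for f in d["feature_ids"]]
        pos = {f: j for j, f in enumerate(fids)}
        nodes = d["nodes"]
        n = len(nodes)
        feature = np.array(
            [-1 if nd["feature"] is None else pos[nd["feature"]] for nd in nodes],
            dtype=np.int64,
        )
        threshold = np.array(
            [np.nan if nd["threshold"] is None else nd["threshold"] for nd in nodes]
        )
        tun = d.get("tuning")
        return cls(
            feature=feature,
            threshold=threshold,
            left=np.array([nd["left"] for nd in nodes], dtype=np.int64),
            right=np.array([nd["right"] for nd in nodes], dtype=np.int64),
            value=np.array([nd["value"] for nd in nodes], dtype=float),
            n_samples=np.array([nd["n_samples"] for nd in nodes], dtype=np.int64),
            feature_ids=fids,
            tuning=None if tun is None else TuningParams(**tun),
            kind=d["kind"],
        )

    @classmethod
    def constant(cls, value: float, n: int, feature_ids: Sequence[str],
                 kind: str = "regression") -> "TreeModel":
        return cls(
            feature=np.array([-1], dtype=np.int64),
            threshold=np.array([np.nan]),
            left=np.array([-1], dtype=np.int64),
            right=np.array([-1], dtype=np.int64),
            value=np.array([float(value)]),
            n_samples=np.array([n], dtype=np.int64),
            feature_ids=list(feature_ids),
            kind=kind,
        )


def _from_sklearn(est, feature_ids, tuning, kind) -> TreeModel:
    t = est.tree_
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(est.n_features_in_)]
    if kind == "classification":
        counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
        if counts.shape[1] == 2:
            value = counts[:, 1] / counts.sum(axis=1)
            n_pos = counts[:, 1]
        else:  # single class present in training data
            only = float(est.classes_[0])
            value = np.full(t.node_count, only)
            n_pos = counts[:, 0] * only
    else:
        value = t.value[:, 0, 0].copy()
        n_pos = None
    return TreeModel(
        feature=t.feature.astype(np.int64),
        threshold=t.threshold.copy(),
        left=t.children_left.astype(np.int64),
        right=t.children_right.astype(np.int64),
        value=np.asarray(value, dtype=float),
        n_samples=t.n_node_samples.astype(np.int64),
        feature_ids=list(feature_ids),
        tuning=tuning,
        kind=kind,
        n_pos=None if n_pos is None else np.asarray(n_pos, dtype=np.int64),
    )


def _as_array(X, feature_ids=None):
    if isinstance(X, FeatureMatrix):
        X.require_complete()
        if feature_ids is not None:
            X = X.restrict(list(feature_ids))
        return X.values, list(X.feature_ids)
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("missing values in feature matrix")
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]
    return X, list(feature_ids)


def fit_probability_tree(X, y, tuning: TuningParams,
                         feature_ids=None) -> TreeModel:
    """Single CART on all features of the interaction (Gini splits); leaf
    prediction is the class-1 fraction of the training samples it holds."""
    Xa, fids = _as_array(X, feature_ids)
    y = np.asarray(y)
    if len(Xa) < 2 * tuning.min_leaf:
        raise ValidationError(
            f"need n >= 2*min_leaf = {2 * tuning.min_leaf}, got {len(Xa)}"
        )
    est = DecisionTreeClassifier(
        criterion="gini",
        max_depth=tuning.max_depth,
        min_samples_leaf=tuning.min_leaf,
        random_state=0,
    ).fit(Xa, y.astype(int))
    return _from_sklearn(est, fids, tuning, "classification")


def _fit_regression_tree(Xa, resid, tuning) -> TreeModel:
    est = DecisionTreeRegressor(
        criterion="squared_error",
        max_depth=tuning.max_depth,
        min_samples_leaf=tuning.min_leaf,
        random_state=0,
    ).fit(Xa, resid)
    return _from_sklearn(est, None, tuning, "regression")


@dataclass
class AdditiveTreeModel:
    """No-epistasis model: mu + CART1(I1) + CART2(I2), backfitted.

    Each component's fitted training offsets are centered to mean zero
    (identifiability); the summed prediction is clipped to [eps, 1-eps]
    before entering any likelihood.  A component that never helps collapses
    to a constant-zero offset, which covers responses depending on only one
    group or on neither.
    """

    intercept: float
    partition: Partition
    component1: TreeModel
    component2: TreeModel
    tuning: TuningParams
    feature_ids: list
    train_mse_path: list = field(default_factory=list)

    def predict(self, X, feature_ids=None) -> np.ndarray:
        Xa, fids = _as_array(X, feature_ids)
        pos = {f: j for j, f in enumerate(fids)}
        missing = [f for f in self.feature_ids if f not in pos]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        c1 = [pos[f] for f in self.partition.group1]
        c2 = [pos[f] for f in self.partition.group2]
        raw = (
            self.intercept
            + self.component1.predict(Xa[:, c1])
            + self.component2.predict(Xa[:, c2])
        )
        return np.clip(raw, EPS, 1 - EPS)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "group1": list(self.partition.group1),
            "group2": list(self.partition.group2),
            "component1": self.component1.to_dict(),
            "component2": self.component2.to_dict(),
        }


def fit_additive_trees(X, y, partition: Partition, tuning: TuningParams,
                       feature_ids=None) -> AdditiveTreeModel:
    """Backfit the additive no-epistasis model on the penetrance scale.

    mu = mean(y); alternately fit each component as a regression tree
    (variance-reduction splits) to the residual of the other, re-centering
    after every fit, until the training MSE improves by < 1e-6 or 20
    rounds.
    """
    Xa, fids = _as_array(X, feature_ids)
    y = np.asarray(y, dtype=float)
    interaction = Interaction(fids)
    partition.validate_for(interaction)
    pos = {f: j for j, f in enumerate(fids)}
    c1 = [pos[f] for f in partition.group1]
    c2 = [pos[f] for f in partition.group2]
    X1, X2 = Xa[:, c1], Xa[:, c2]
    mu = float(y.mean())
    f1 = np.zeros(len(y))
    f2 = np.zeros(len(y))
    t1 = TreeModel.constant(0.0, len(y), partition.group1)
    t2 = TreeModel.constant(0.0, len(y), partition.group2)
    mse_path = [float(np.mean((y - mu) ** 2))]
    for _ in range(MAX_BACKFIT_ROUNDS):
        prev = (t1, t2, f1, f2)
        t1 = _fit_regression_tree(X1, y - mu - f2, tuning)
        f1 = t1.predict(X1)
        center = float(f1.mean())
        t1.value = t1.value - center
        t1.feature_ids = list(partition.group1)
        f1 = f1 - center

        t2 = _fit_regression_tree(X2, y - mu - f1, tuning)
        f2 = t2.predict(X2)
        center = float(f2.mean())
        t2.value = t2.value - center
        t2.feature_ids = list(partition.group2)
        f2 = f2 - center

        mse = float(np.mean((y - mu - f1 - f2) ** 2))
        improvement = mse_path[-1] - mse
        if improvement < 0:
            # greedy refits are not guaranteed to help; keep the better state
            t1, t2, f1, f2 = prev
            break
        mse_path.append(mse)
        if improvement < BACKFIT_TOL:
            break
    return AdditiveTreeModel(
        intercept=mu,
        partition=partition,
        component1=t1,
        component2=t2,
        tuning=tuning,
        feature_ids=fids,
        train_mse_path=mse_path,
    )


def select_tuning(X, y, depth_grid=None, min_leaf=None,
                  feature_ids=None) -> TuningParams:
    """Shallowest depth at which the single CART uses every feature of I.

    If no depth in the grid achieves this, the grid ceiling is returned
    with ``all_features_used=False`` (the interaction will typically screen
    to p = 1 downstream).  The selected parameters are shared with the null
    model's component trees so model complexity stays comparable.
    """
    Xa, fids = _as_array(X, feature_ids)
    y = np.asarray(y)
    if depth_grid is None:
        depth_grid = list(range(2, DEPTH_CEILING + 1))
    depth_grid = list(depth_grid)
    if not depth_grid:
        raise ValueError("empty depth grid")
    if list(depth_grid) != sorted(depth_grid):
        raise ValueError("depth grid must be ascending")
    if min_leaf is None:
        min_leaf = default_min_leaf(len(Xa))
    needed = set(fids)
    for depth in depth_grid:
        tuning = TuningParams(max_depth=depth, min_leaf=min_leaf)
        tree = fit_probability_tree(Xa, y, tuning, feature_ids=fids)
        if needed <= tree.features_used():
            return tuning
    return TuningParams(
        max_depth=depth_grid[-1], min_leaf=min_leaf, all_features_used=False
    )


def enumerate_bipartitions(feature_ids: Sequence[str]):
    """All 2^(d-1) - 1 unordered bipartitions of the feature set."""
    fids = [str(f) for f in feature_ids]
    first, rest = fids[0], fids[1:]
    parts = []
    for r in range(len(rest) + 1):
        for combo in combinations(rest, r):
            g1 = (first,) + combo
            g2 = tuple(f for f in rest if f not in combo)
            if g2:
                parts.append(Partition(g1, g2))
    return parts


def best_null_partition(X, y_train, test_X, test_y, tuning: TuningParams,
                        feature_ids=None) -> Partition:
    """For d >= 3: the bipartition whose additive model has the lowest
    cross-entropy on the test data; ties broken by smaller |I1| then
    lexicographic feature order."""
    Xa, fids = _as_array(X, feature_ids)
    d = len(fids)
    if d < 3:
        raise ValidationError("partition search needs interaction order >= 3")
    if d > 8:
        raise ValidationError("enumeration bound exceeded (d > 8)")
    Xt, _ = _as_array(test_X, fids)
    test_y = np.asarray(test_y)
    best = None
    for part in enumerate_bipartitions(fids):
        model = fit_additive_trees(Xa, y_train, part, tuning, feature_ids=fids)
        ce = cross_entropy(model.predict(Xt, feature_ids=fids), test_y)
        key = (ce, min(len(part.group1), len(part.group2)),
               tuple(sorted(min(part.group1, part.group2))))
        if best is None or key < best[0]:
            best = (key, part)
    return best[1]


def predict_proba(model, X, feature_ids=None) -> np.ndarray:
    """Predicted P(y=1), clipped to [eps, 1-eps]."""
    if isinstance(model, AdditiveTreeModel):
        return model.predict(X, feature_ids=feature_ids)
    Xa, fids = _as_array(X, feature_ids)
    if set(model.feature_ids) - set(fids):
        missing = sorted(set(model.feature_ids) - set(fids))
        raise KeyError(f"missing feature columns: {missing}")
    pos = {f: j for j, f in enumerate(fids)}
    cols = [pos[f] for f in model.feature_ids]
    return np.clip(model.predict(Xa[:, cols]), EPS, 1 - EPS)


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Negative average Bernoulli log-likelihood (natural log), computed
    after clipping probabilities to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=float), EPS, 1 - EPS)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValidationError("probability and response lengths differ")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def save_model_json(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
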