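"""Multiclass gradient-boosted regression trees, from first principles.

Friedman's multiclass algorithm with softmax deviance: the model keeps one
score function per class, initialised at the log class proportions; each
boosting round computes pseudo-residuals ``r_ik = y_ik - p_k(x_i)`` (the
negative gradient of the deviance) and fits one regression tree per class to
them by greedy CART on squared error. Leaf values take the one-step Newton
approximation of the per-leaf line search,
``gamma = ((K-1)/K) * sum(r) / sum(|r| (1-|r|))``, and scores update as
``F <- F + nu * gamma(x)`` with shrinkage ``0 < nu < 1``.

Everything is deterministic given the seed: per-node candidate features are
a seeded uniform subset consumed in depth-first order, thresholds sit at
midpoints of consecutive distinct sorted values, and split ties break toward
the lowest (feature index, threshold).

A squared-loss regression mode (``loss="squared"``, exact leaf means) exists
as a self-test target where the line search has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_LEAF = -1


@dataclass
class DecisionTree:
    """Flat-array binary regression tree.

    ``feature[i] == -1`` marks a leaf with value ``value[i]``; internal nodes
    route ``x[feature] <= threshold`` left.
    """

    feature: list[int] = field(default_factory=list)
    threshold: list[float] = field(default_factory=list)
    left: list[int] = field(default_factory=list)
    right: list[int] = field(default_factory=list)
    value: list[float] = field(default_factory=list)

    def _add_node(self) -> int:
        self.feature.append(_LEAF)
        self.threshold.append(0.0)
        self.left.append(_LEAF)
        self.right.append(_LEAF)
        self.value.append(0.0)
        return len(self.feature) - 1

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index for each row."""
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=int)
        feature = np.asarray(self.feature)
        threshold = np.asarray(self.threshold)
        left = np.asarray(self.left)
        right = np.asarray(self.right)
        active = feature[node] != _LEAF
        while np.any(active):
            idx = np.nonzero(active)[0]
            f = feature[node[idx]]
            go_left = X[idx, f] <= threshold[node[idx]]
            node[idx] = np.where(go_left, left[node[idx]], right[node[idx]])
            active = feature[node] != _LEAF
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.value)[self.apply(X)]

    def to_dict(self) -> dict:
        return {"feature": self.feature, "threshold": self.threshold,
                "left": self.left, "right": self.right, "value": self.value}

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(feature=list(d["feature"]), threshold=list(d["threshold"]),
                   left=list(d["left"]), right=list(d["right"]),
                   value=[float(v) for v in d["value"]])


def _best_split(X: np.ndarray, r: np.ndarray, rows: np.ndarray,
                candidates: np.ndarray, min_samples_leaf: int):
    """Best (feature, threshold) by squared-error reduction over candidates.

    Candidates are scanned in ascending feature order and thresholds in
    ascending value order, with strict improvement required, so ties resolve
    to the lowest (feature index, threshold). Returns None if no valid split.
    """
    rsub = r[rows]
    n = rows.size
    total = rsub.sum()
    base = total * total / n
    best = None
    best_gain = 0.0
    for f in candidates:
        col = X[rows, f]
        order = np.argsort(col, kind="stable")
        xs = col[order]
        rs = rsub[order]
        csum = np.cumsum(rs)
        pos = np.arange(1, n)  # left sizes
        valid = xs[1:] > xs[:-1]
        if min_samples_leaf > 1:
            valid &= (pos >= min_samples_leaf) & (n - pos >= min_samples_leaf)
        if not np.any(valid):
            continue
        sl = csum[:-1]
        gain = sl * sl / pos + (total - sl) ** 2 / (n - pos) - base
        gain = np.where(valid, gain, -np.inf)
        i = int(np.argmax(gain))  # first occurrence -> lowest threshold
        if gain[i] > best_gain + 1e-12 * max(1.0, abs(best_gain)):
            best_gain = float(gain[i])
            best = (int(f), float((xs[i] + xs[i + 1]) / 2.0))
    return best


def fit_tree(X: np.ndarray, r: np.ndarray, max_depth: int = 4,
             max_features: int | None = None, min_samples_leaf: int = 1,
             seed: int | np.random.Generator = 0) -> DecisionTree:
    """Greedy CART regression tree on residuals ``r``.

    At each node a size-``max_features`` uniform random feature subset
    (without replacement, seeded) is considered; leaves hold the mean
    residual. Depth 0 forces a single leaf.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    n, d = X.shape
    if max_features is None:
        max_features = d
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    max_features = min(max_features, d)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = DecisionTree()

    def build(rows: np.ndarray, depth: int) -> int:
        node = tree._add_node()
        tree.value[node] = float(r[rows].mean())
        if depth >= max_depth or rows.size < 2 * min_samples_leaf or rows.size < 2:
            return node
        if max_features < d:
            candidates = np.sort(rng.choice(d, size=max_features, replace=False))
        else:
            candidates = np.arange(d)
        split = _best_split(X, r, rows, candidates, min_samples_leaf)
        if split is None:
            return node
        f, thr = split
        go_left = X[rows, f] <= thr
        tree.feature[node] = f
        tree.threshold[node] = thr
        tree.left[node] = build(rows[go_left], depth + 1)
        tree.right[node] = build(rows[~go_left], depth + 1)
        return node

    build(np.arange(n), 0)
    return tree


def init_scores(y: np.ndarray, K: int, eps: float = 1e-12) -> np.ndarray:
    """Per-class constant initial scores: log empirical class proportions."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=K).astype(float)
    p = np.clip(counts / counts.sum(), eps, None)
    return np.log(p)


def softmax(F: np.ndarray) -> np.ndarray:
    Z = F - F.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def pseudo_residuals(y_onehot: np.ndarray, probabilities: np.ndarray) -> np.ndarray:
    """Negative gradient of the multiclass deviance: y - p (rows sum to 0)."""
    return np.asarray(y_onehot, dtype=float) - np.asarray(probabilities, dtype=float)


def leaf_values(tree: DecisionTree, X: np.ndarray, r: np.ndarray, K: int) -> None:
    """Replace leaf means with the one-step Newton gamma for the deviance.

    ``gamma = ((K-1)/K) * sum(r) / sum(|r| (1 - |r|))`` per leaf, with a
    guarded denominator (gamma = 0 for an empty/degenerate leaf).
    """
    leaf = tree.apply(X)
    absr = np.abs(r)
    num = np.bincount(leaf, weights=r, minlength=len(tree.value))
    den = np.bincount(leaf, weights=absr * (1.0 - absr), minlength=len(tree.value))
    scale = (K - 1.0) / K
    for i in range(len(tree.value)):
        if tree.feature[i] == _LEAF:
            tree.value[i] = float(scale * num[i] / den[i]) if den[i] > 1e-12 else 0.0


def deviance(y: np.ndarray, proba: np.ndarray, eps: float = 1e-15) -> float:
    """Mean multiclass negative log-likelihood."""
    p = np.clip(proba[np.arange(len(y)), y], eps, None)
    return float(-np.mean(np.log(p)))


@dataclass
class GBDTModel:
    classes: np.ndarray
    F0: np.ndarray
    trees: list[list[DecisionTree]]   # trees[m][k]
    learning_rate: float
    seed: int
    loss: str = "deviance"
    train_deviance: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return int(self.classes.size)

    def _scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        F = np.tile(self.F0, (X.shape[0], 1))
        for round_trees in self.trees:
            for k, tree in enumerate(round_trees):
                F[:, k] += self.learning_rate * tree.predict(X)
        return F

    def to_dict(self) -> dict:
        return {
            "kind": "gbdt",
            "classes": [str(c) for c in self.classes],
            "F0": self.F0.tolist(),
            "trees": [[t.to_dict() for t in round_trees] for round_trees in self.trees],
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "loss": self.loss,
            "train_deviance": list(self.train_deviance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GBDTModel":
        return cls(
            classes=np.asarray(d["classes"]),
            F0=np.asarray(d["F0"], dtype=float),
            trees=[[DecisionTree.from_dict(t) for t in rt] for rt in d["trees"]],
            learning_rate=float(d["learning_rate"]),
            seed=int(d["seed"]),
            loss=d.get("loss", "deviance"),
            train_deviance=[float(v) for v in d.get("train_deviance", [])],
        )


def fit(X, y, learning_rate: float = 0.1, n_estimators: int = 200,
        max_depth: int = 4, max_features: int | None = 30,
        min_samples_leaf: int = 1, seed: int = 0) -> GBDTModel:
    """Fit the multiclass ensemble: one tree per class per round."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    if not 0.0 < learning_rate < 1.0:
        raise ValueError("learning_rate must lie in (0, 1)")
    classes, y_idx = np.unique(y, return_inverse=True)
    K = classes.size
    if K < 2:
        raise ValueError("need at least 2 classes")
    n = X.shape[0]
    Y = np.zeros((n, K))
    Y[np.arange(n), y_idx] = 1.0
    F0 = init_scores(y_idx, K)
    F = np.tile(F0, (n, 1))
    rng = np.random.default_rng(seed)
    trees: list[list[DecisionTree]] = []
    dev_path: list[float] = []
    for _ in range(n_estimators):
        P = softmax(F)
        R = pseudo_residuals(Y, P)
        round_trees: list[DecisionTree] = []
        for k in range(K):
            tree = fit_tree(X, R[:, k], max_depth=max_depth,
                            max_features=max_features,
                            min_samples_leaf=min_samples_leaf, seed=rng)
            leaf_values(tree, X, R[:, k], K)
            F[:, k] += learning_rate * tree.predict(X)
            round_trees.append(tree)
        trees.append(round_trees)
        dev_path.append(deviance(y_idx, softmax(F)))
    return GBDTModel(classes=classes, F0=F0, trees=trees,
                     learning_rate=learning_rate, seed=seed,
                     train_deviance=dev_path)


def predict_proba(model: GBDTModel, X) -> np.ndarray:
    """Class probabilities by softmax over the additive scores."""
    return softmax(model._scores(np.atleast_2d(np.asarray(X, dtype=float))))


def predict(model: GBDTModel, X):
    """argmax class; ties resolve to the lowest class index."""
    proba = predict_proba(model, X)
    return model.classes[np.argmax(proba, axis=1)]
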