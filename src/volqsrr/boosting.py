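"""Stochastic gradient-boosted regression trees for retention-index QSRR.

The learner follows the classic least-squares boosting recipe as used by
desktop statistics packages for QSRR work: an internal random holdout
("test proportion") is split off before boosting; the model starts from the
training mean; each iteration draws a random subsample of the training rows,
fits a small binary regression tree to the current residuals, and adds it
with a shrinkage factor (the learning rate).  Boosting stops at the
requested number of trees or when the holdout least-square error has not
improved for ``patience`` iterations, and the ensemble is truncated at the
holdout-optimal iteration.

Everything here is implemented directly on numpy arrays; scikit-learn is
used only for the estimator interface (``get_params``/``set_params``,
pipeline compatibility), never for the learning itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RegressionTree",
    "TreeNode",
    "BRTConfig",
    "BoostedTreesRegressor",
    "fit_tree",
    "fit_brt",
    "predict",
    "grid_search",
    "predictor_importance",
]

#: hyperparameter ranges explored when tuning the fit
N_TREES_RANGE = (100, 1000)
LEARNING_RATE_RANGE = (0.0005, 0.1)
TEST_PROPORTION_RANGE = (0.1, 0.9)
SUBSAMPLE_RANGE = (0.1, 0.9)


@dataclass
class TreeNode:
    """Binary split node; a leaf when ``feature`` is None."""

    value: float
    feature: int | None = None
    threshold: float | None = None
    gain: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    """Greedy least-squares binary regression tree."""

    root: TreeNode
    max_depth: int
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        self._predict_into(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, node: TreeNode, X, idx, out) -> None:
        if node.is_leaf:
            out[idx] = node.value
            return
        mask = X[idx, node.feature] <= node.threshold
        self._predict_into(node.left, X, idx[mask], out)
        self._predict_into(node.right, X, idx[~mask], out)

    def split_gains(self) -> np.ndarray:
        """Total SSE reduction attributed to each feature."""
        gains = np.zeros(self.n_features)
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                gains[node.feature] += node.gain
                stack.extend([node.left, node.right])
        return gains

    def to_dict(self) -> dict:
        def enc(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"value": node.value}
            return {
                "value": node.value, "feature": node.feature,
                "threshold": node.threshold, "gain": node.gain,
                "left": enc(node.left), "right": enc(node.right),
            }
        return {"max_depth": self.max_depth, "n_features": self.n_features,
                "root": enc(self.root)}

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        def dec(nd: dict) -> TreeNode:
            if "feature" not in nd:
                return TreeNode(value=nd["value"])
            return TreeNode(
                value=nd["value"], feature=nd["feature"],
                threshold=nd["threshold"], gain=nd.get("gain", 0.0),
                left=dec(nd["left"]), right=dec(nd["right"]))
        return cls(root=dec(d["root"]), max_depth=d["max_depth"],
                   n_features=d["n_features"])


def _best_split(X: np.ndarray, r: np.ndarray, idx: np.ndarray,
                min_leaf: int) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) for the rows ``idx``; ties resolved
    toward the lowest feature index, then the lowest threshold."""
    n = idx.size
    if n < 2 * min_leaf:
        return None
    y = r[idx]
    sse_parent = float(((y - y.mean()) ** 2).sum())
    # gains below rounding noise (relative to the sum-of-squares scale used
    # in the prefix-sum score) are treated as no improvement
    eps = 1e-12 * max(1.0, float((y ** 2).sum()))
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        v = X[idx, j]
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], y[order]
        # candidate cut after position i (1-based count on the left)
        csum = np.cumsum(ys)
        total = csum[-1]
        counts = np.arange(1, n)
        left_sum = csum[:-1]
        right_sum = total - left_sum
        with np.errstate(invalid="ignore"):
            score = left_sum ** 2 / counts + right_sum ** 2 / (n - counts)
        valid = (vs[:-1] < vs[1:]) & (counts >= min_leaf) & (n - counts >= min_leaf)
        if not valid.any():
            continue
        score = np.where(valid, score, -np.inf)
        i = int(np.argmax(score))  # first occurrence = lowest threshold
        gain = float(score[i] - total ** 2 / n)
        if gain <= eps:
            continue
        if best is None or gain > best[2] + 1e-12:
            thr = 0.5 * (vs[i] + vs[i + 1])
            best = (j, float(thr), gain)
    return best


def _grow(X, r, idx, depth, max_depth, min_leaf) -> TreeNode:
    node = TreeNode(value=float(r[idx].mean()))
    if depth >= max_depth:
        return node
    found = _best_split(X, r, idx, min_leaf)
    if found is None:
        return node
    j, thr, gain = found
    mask = X[idx, j] <= thr
    node.feature, node.threshold, node.gain = j, thr, gain
    node.left = _grow(X, r, idx[mask], depth + 1, max_depth, min_leaf)
    node.right = _grow(X, r, idx[~mask], depth + 1, max_depth, min_leaf)
    return node


def fit_tree(X: np.ndarray, residuals: np.ndarray, max_depth: int = 3,
             min_leaf: int = 2) -> RegressionTree:
    """Fit one greedy least-squares tree to residuals.

    Leaf values are mean residuals; each split maximizes the SSE reduction.
    Constant residuals produce a single-leaf tree.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if X.ndim != 2 or r.shape != (X.shape[0],):
        raise ValueError("X must be 2-D and residuals aligned to its rows")
    root = _grow(X, r, np.arange(X.shape[0]), 0, max_depth, min_leaf)
    return RegressionTree(root=root, max_depth=max_depth, n_features=X.shape[1])


@dataclass
class BRTConfig:
    """Boosting configuration restricted to the tuned hyperparameter ranges:
    100-1000 trees, learning rate 0.0005-0.1, random holdout proportion
    0.1-0.9 and subsample proportion 0.1-0.9."""

    n_trees: int = 500
    learning_rate: float = 0.1
    test_proportion: float = 0.2
    subsample: float = 0.5
    max_depth: int = 3
    min_leaf: int = 2
    patience: int = 50
    seed: int = 0

    def validate(self) -> "BRTConfig":
        checks = [
            ("n_trees", self.n_trees, N_TREES_RANGE),
            ("learning_rate", self.learning_rate, LEARNING_RATE_RANGE),
            ("test_proportion", self.test_proportion, TEST_PROPORTION_RANGE),
            ("subsample", self.subsample, SUBSAMPLE_RANGE),
        ]
        for name, v, (lo, hi) in checks:
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside allowed range [{lo}, {hi}]")
        if self.max_depth < 1 or self.min_leaf < 1 or self.patience < 1:
            raise ValueError("max_depth, min_leaf and patience must be >= 1")
        return self


class BoostedTreesRegressor(RegressorMixin, BaseEstimator):
    """Stochastic gradient-boosted least-squares regression trees.

    Parameters mirror :class:`BRTConfig`.  ``test_fraction`` rows are held
    out before boosting to monitor the holdout least-square error (LSE); the
    ensemble is truncated at the holdout-optimal iteration.  Set
    ``test_fraction=0`` to boost on all rows without early stopping (used
    for small inner learners, e.g. feature-selection fitness).

    Attributes set by :meth:`fit` (scikit-learn convention):

    ``init_value_``
        constant initial prediction, the training mean.
    ``trees_``
        list of :class:`RegressionTree`, truncated at ``n_iter_``.
    ``train_history_``, ``test_history_``
        per-iteration mean squared error on the boosting rows and holdout.
    ``feature_importances_``
        per-feature split-gain totals rescaled so the maximum is 1.
    """

    def __init__(self, n_estimators: int = 500, learning_rate: float = 0.1,
                 test_fraction: float = 0.2, subsample: float = 0.5,
                 max_depth: int = 3, min_samples_leaf: int = 2,
                 patience: int = 50, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.test_fraction = test_fraction
        self.subsample = subsample
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.patience = patience
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _coerce_X(self, X, fitting: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if fitting:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            else:
                have = list(X.columns)
                want = list(getattr(self, "feature_names_in_", have))
                missing = [c for c in want if c not in have]
                if missing:
                    raise ValueError(f"missing features at predict time: {missing}")
                X = X[want]
            return np.asarray(X, dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be a 2-D array or DataFrame")
        return arr

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y) -> "BoostedTreesRegressor":
        Xa = self._coerce_X(X, fitting=True)
        ya = np.asarray(y, dtype=float).ravel()
        if ya.shape[0] != Xa.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if not np.all(np.isfinite(Xa)) or not np.all(np.isfinite(ya)):
            raise ValueError("X and y must be finite")
        n = Xa.shape[0]
        rng = np.random.default_rng(self.random_state)

        if self.test_fraction > 0:
            n_test = int(round(n * self.test_fraction))
            if n_test == 0 or n_test == n:
                raise ValueError(
                    f"test_fraction={self.test_fraction} leaves an empty "
                    f"train or test partition for n={n}")
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
        else:
            train_idx = np.arange(n)
            test_idx = np.empty(0, dtype=int)
        Xtr, ytr = Xa[train_idx], ya[train_idx]
        Xte, yte = Xa[test_idx], ya[test_idx]
        self.train_indices_, self.test_indices_ = train_idx, test_idx

        self.init_value_ = float(ytr.mean())
        f_tr = np.full(ytr.shape, self.init_value_)
        f_te = np.full(yte.shape, self.init_value_)
        nu = self.learning_rate
        n_sub = max(1, int(round(self.subsample * ytr.size)))

        trees: list[RegressionTree] = []
        train_hist: list[float] = []
        test_hist: list[float] = []
        best_lse = np.inf
        best_iter = 0
        for m in range(self.n_estimators):
            sub = rng.choice(ytr.size, size=n_sub, replace=False) \
                if n_sub < ytr.size else np.arange(ytr.size)
            resid = ytr - f_tr
            tree = fit_tree(Xtr[sub], resid[sub],
                            max_depth=self.max_depth,
                            min_leaf=self.min_samples_leaf)
            f_tr += nu * tree.predict(Xtr)
            trees.append(tree)
            train_hist.append(float(np.mean((ytr - f_tr) ** 2)))
            if yte.size:
                f_te += nu * tree.predict(Xte)
                lse = float(np.mean((yte - f_te) ** 2))
                test_hist.append(lse)
                if lse < best_lse - 1e-12:
                    best_lse, best_iter = lse, m + 1
                elif m + 1 - best_iter >= self.patience:
                    break
            else:
                best_iter = m + 1

        self.n_iter_ = best_iter if yte.size else len(trees)
        self.n_grown_ = len(trees)
        self.trees_ = trees[: self.n_iter_]
        # histories are truncated with the ensemble: one entry per kept tree
        self.train_history_ = np.asarray(train_hist[: self.n_iter_])
        self.test_history_ = np.asarray(test_hist[: self.n_iter_])
        self.best_test_lse_ = best_lse if yte.size else None
        gains = np.zeros(Xa.shape[1])
        for t in self.trees_:
            gains += t.split_gains()
        top = gains.max()
        self.feature_importances_ = gains / top if top > 0 else gains
        self.n_features_in_ = Xa.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "trees_"):
            raise ValueError("estimator is not fitted")
        Xa = self._coerce_X(X, fitting=False)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xa.shape[1]} features, expected {self.n_features_in_}")
        out = np.full(Xa.shape[0], self.init_value_)
        for tree in self.trees_:
            out += self.learning_rate * tree.predict(Xa)
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "init_value": self.init_value_,
            "n_iter": self.n_iter_,
            "trees": [t.to_dict() for t in self.trees_],
            "train_history": self.train_history_.tolist(),
            "test_history": self.test_history_.tolist(),
            "feature_names": list(getattr(self, "feature_names_in_", [])) or None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedTreesRegressor":
        est = cls(**d["params"])
        est.init_value_ = d["init_value"]
        est.n_iter_ = d["n_iter"]
        est.trees_ = [RegressionTree.from_dict(t) for t in d["trees"]]
        est.train_history_ = np.asarray(d["train_history"])
        est.test_history_ = np.asarray(d["test_history"])
        est.n_features_in_ = est.trees_[0].n_features if est.trees_ else 0
        if d.get("feature_names"):
            est.feature_names_in_ = np.asarray(d["feature_names"], dtype=object)
        return est


def fit_brt(X, y, cfg: BRTConfig) -> BoostedTreesRegressor:
    """Fit a boosted-trees model under a validated configuration."""
    cfg.validate()
    est = BoostedTreesRegressor(
        n_estimators=cfg.n_trees, learning_rate=cfg.learning_rate,
        test_fraction=cfg.test_proportion, subsample=cfg.subsample,
        max_depth=cfg.max_depth, min_samples_leaf=cfg.min_leaf,
        patience=cfg.patience, random_state=cfg.seed)
    return est.fit(X, y)


def predict(model: BoostedTreesRegressor, X) -> np.ndarray:
    return model.predict(X)


def grid_search(
    X, y, grid: Iterable[BRTConfig | Mapping], seed: int | None = None,
) -> tuple[BoostedTreesRegressor, pd.DataFrame]:
    """Refit one model per configuration (shared seed) and pick the one with
    the lowest holdout LSE; ties go to fewer trees, then smaller learning
    rate.  Configurations outside the allowed ranges are rejected."""
    configs: list[BRTConfig] = []
    for c in grid:
        cfg = c if isinstance(c, BRTConfig) else BRTConfig(**dict(c))
        if seed is not None:
            cfg = BRTConfig(**{**asdict(cfg), "seed": seed})
        configs.append(cfg.validate())
    if not configs:
        raise ValueError("empty grid")
    rows = []
    best = None  # (lse, n_trees, lr, order, model)
    for order, cfg in enumerate(configs):
        model = fit_brt(X, y, cfg)
        lse = model.best_test_lse_
        rows.append({**asdict(cfg), "test_lse": lse, "n_iter": model.n_iter_})
        key = (lse, cfg.n_trees, cfg.learning_rate, order)
        if best is None or key < best[0]:
            best = (key, model)
    return best[1], pd.DataFrame(rows)


def predictor_importance(model: BoostedTreesRegressor) -> pd.Series:
    """Per-feature total split-gain importance, rescaled to max 1 and sorted
    descending."""
    imp = model.feature_importances_
    names = getattr(model, "feature_names_in_", None)
    index = list(names) if names is not None else list(range(len(imp)))
    return pd.Series(imp, index=index).sort_values(ascending=False)
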