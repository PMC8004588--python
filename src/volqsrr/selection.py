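"""Descriptor selection: correlation pre-filter and genetic-algorithm
wrapper selection of a fixed-size subset.

The pre-filter removes collinear descriptors before the wrapper search: for
every pair above the |r| threshold the member with the larger mean absolute
correlation to all remaining descriptors is dropped, until no pair exceeds
the threshold.

The genetic algorithm encodes a fixed-cardinality descriptor subset as a
chromosome and scores it by cross-validated r2 of a small boosted-trees
learner.  Selection is by tournament, crossover is uniform with repair back
to the fixed cardinality, mutation swaps a selected descriptor for an
unselected one, and elitism makes the best fitness trace monotone
non-decreasing.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .boosting import BoostedTreesRegressor

__all__ = [
    "GAConfig",
    "pearson_matrix",
    "correlation_prefilter",
    "CorrelationPrefilter",
    "GeneticDescriptorSelector",
    "ga_select",
]


def pearson_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of descriptor columns.

    Requires at least 3 rows; constant columns get r = 0 off-diagonal with
    a warning (their correlation is undefined).
    """
    if len(features) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    X = features.to_numpy(dtype=float)
    constant = X.std(axis=0) == 0
    if constant.any():
        names = list(features.columns[constant])
        warnings.warn(f"constant columns, correlation set to 0: {names}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=features.columns, columns=features.columns)


def correlation_prefilter(
    features: pd.DataFrame, threshold: float = 0.95
) -> pd.DataFrame:
    """Greedy removal of collinear descriptors; no surviving pair has
    |r| > threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    cols = list(features.columns)
    if len(cols) < 2:
        return features.copy()
    corr = pearson_matrix(features).abs().to_numpy()
    keep = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(keep, keep)]
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        # drop the member more correlated with everything else on average
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        drop = i if mean_i >= mean_j else j
        keep.pop(drop)
    return features.iloc[:, keep].copy()


class CorrelationPrefilter(BaseEstimator):
    """Transformer wrapper around :func:`correlation_prefilter`."""

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationPrefilter":
        reduced = correlation_prefilter(pd.DataFrame(X), self.threshold)
        self.selected_features_ = list(reduced.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    The inner fitness learner is a small fixed boosted-trees model; its
    settings are exposed so that desk-scale runs can shrink it.
    """

    subset_size: int = 7
    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    fitness: str = "cv_r2"
    cv_folds: int = 5
    seed: int = 0
    tournament: int = 3
    elitism: int = 1
    inner_n_trees: int = 100
    inner_max_depth: int = 3
    inner_learning_rate: float = 0.1

    def validate(self, n_features: int) -> "GAConfig":
        if self.subset_size > n_features:
            raise ValueError(
                f"subset_size={self.subset_size} exceeds feature count {n_features}")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} not a probability")
        if self.fitness != "cv_r2":
            raise ValueError(f"unknown fitness {self.fitness!r}")
        return self


class GeneticDescriptorSelector(BaseEstimator):
    """Fixed-size descriptor-subset selection by a genetic algorithm.

    fit(X, y) searches subsets of ``subset_size`` columns maximizing the
    ``cv_folds``-fold cross-validated r2 of a small boosted-trees learner.
    With elitism the per-generation best fitness is monotone non-decreasing.

    Attributes after fitting: ``selected_features_`` (column names),
    ``support_`` (boolean mask), ``fitness_trace_`` (best fitness per
    generation), ``best_fitness_``.
    """

    def __init__(self, subset_size: int = 7, population: int = 50,
                 generations: int = 100, crossover_rate: float = 0.8,
                 mutation_rate: float = 0.05, cv_folds: int = 5,
                 tournament: int = 3, elitism: int = 1,
                 inner_n_trees: int = 100, inner_max_depth: int = 3,
                 inner_learning_rate: float = 0.1,
                 random_state: int | None = 0):
        self.subset_size = subset_size
        self.population = population
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.cv_folds = cv_folds
        self.tournament = tournament
        self.elitism = elitism
        self.inner_n_trees = inner_n_trees
        self.inner_max_depth = inner_max_depth
        self.inner_learning_rate = inner_learning_rate
        self.random_state = random_state

    # -- fitness -----------------------------------------------------------
    def _cv_r2(self, X: np.ndarray, y: np.ndarray, cols: tuple[int, ...],
               fold_ids: np.ndarray) -> float:
        Xs = X[:, cols]
        scores = []
        for f in range(self.cv_folds):
            te = fold_ids == f
            tr = ~te
            if te.sum() == 0 or tr.sum() < 2:
                continue
            est = BoostedTreesRegressor(
                n_estimators=self.inner_n_trees,
                learning_rate=self.inner_learning_rate,
                test_fraction=0.0, subsample=1.0,
                max_depth=self.inner_max_depth, min_samples_leaf=2,
                random_state=0)
            est.fit(Xs[tr], y[tr])
            pred = est.predict(Xs[te])
            sst = float(((y[te] - y[tr].mean()) ** 2).sum())
            ssr = float(((y[te] - pred) ** 2).sum())
            scores.append(1.0 - ssr / sst if sst > 0 else 0.0)
        return float(np.mean(scores)) if scores else -np.inf

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y) -> "GeneticDescriptorSelector":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            if X.isna().any().any():
                raise ValueError("feature table contains missing cells")
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = list(range(Xa.shape[1]))
        ya = np.asarray(y, dtype=float).ravel()
        if ya.shape[0] != Xa.shape[0]:
            raise ValueError("target not aligned to feature rows")
        n_feat = Xa.shape[1]
        k = self.subset_size
        if k > n_feat:
            raise ValueError(
                f"subset_size={k} exceeds feature count {n_feat}")
        rng = np.random.default_rng(self.random_state)
        fold_ids = rng.permutation(Xa.shape[0]) % self.cv_folds

        if k == n_feat:  # nothing to search
            self.support_ = np.ones(n_feat, dtype=bool)
            self.selected_features_ = list(names)
            self.fitness_trace_ = [self._cv_r2(Xa, ya, tuple(range(n_feat)),
                                               fold_ids)]
            self.best_fitness_ = self.fitness_trace_[0]
            return self

        cache: dict[tuple[int, ...], float] = {}

        def fitness(cols: tuple[int, ...]) -> float:
            if cols not in cache:
                cache[cols] = self._cv_r2(Xa, ya, cols, fold_ids)
            return cache[cols]

        def random_subset() -> tuple[int, ...]:
            return tuple(sorted(rng.choice(n_feat, size=k, replace=False)))

        def repair(genes: set[int]) -> tuple[int, ...]:
            genes = set(genes)
            pool = [g for g in range(n_feat) if g not in genes]
            while len(genes) > k:
                genes.remove(rng.choice(sorted(genes)))
            while len(genes) < k:
                pick = pool[rng.integers(len(pool))]
                genes.add(pick)
                pool.remove(pick)
            return tuple(sorted(genes))

        def mutate(cols: tuple[int, ...]) -> tuple[int, ...]:
            genes = set(cols)
            for g in list(genes):
                if rng.random() < self.mutation_rate:
                    outside = [j for j in range(n_feat) if j not in genes]
                    genes.remove(g)
                    genes.add(outside[rng.integers(len(outside))])
            return tuple(sorted(genes))

        pop = [random_subset() for _ in range(self.population)]
        scores = np.array([fitness(c) for c in pop])
        trace: list[float] = []
        for _ in range(self.generations):
            order = np.argsort(-scores, kind="stable")
            pop = [pop[i] for i in order]
            scores = scores[order]
            trace.append(float(scores[0]))
            nxt = pop[: self.elitism]
            while len(nxt) < self.population:
                def pick() -> tuple[int, ...]:
                    idx = rng.integers(len(pop), size=self.tournament)
                    return pop[int(idx[np.argmax(scores[idx])])]
                a, b = pick(), pick()
                if rng.random() < self.crossover_rate:
                    sa, sb = set(a), set(b)
                    common = sa & sb
                    diff = sorted(sa ^ sb)
                    child = set(common)
                    for g in diff:  # uniform: each differing gene 50/50
                        if rng.random() < 0.5:
                            child.add(g)
                    child = repair(child)
                else:
                    child = a
                nxt.append(mutate(child))
            pop = nxt
            scores = np.array([fitness(c) for c in pop])
        order = np.argsort(-scores, kind="stable")
        best = pop[int(order[0])]
        trace.append(float(scores[order[0]]))

        self.support_ = np.zeros(n_feat, dtype=bool)
        self.support_[list(best)] = True
        self.selected_features_ = [names[j] for j in best]
        self.fitness_trace_ = trace
        self.best_fitness_ = trace[-1]
        self.n_features_in_ = n_feat
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features_]
        return np.asarray(X)[:, self.support_]


def ga_select(
    features: pd.DataFrame, target: Sequence[float], cfg: GAConfig
) -> tuple[list[str], list[float]]:
    """Functional wrapper: best descriptor subset and the per-generation
    best-fitness trace under ``cfg``."""
    cfg.validate(features.shape[1])
    sel = GeneticDescriptorSelector(
        subset_size=cfg.subset_size, population=cfg.population,
        generations=cfg.generations, crossover_rate=cfg.crossover_rate,
        mutation_rate=cfg.mutation_rate, cv_folds=cfg.cv_folds,
        tournament=cfg.tournament, elitism=cfg.elitism,
        inner_n_trees=cfg.inner_n_trees, inner_max_depth=cfg.inner_max_depth,
        inner_learning_rate=cfg.inner_learning_rate,
        random_state=cfg.seed)
    sel.fit(features, np.asarray(target, dtype=float))
    return sel.selected_features_, sel.fitness_trace_
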