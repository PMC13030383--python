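"""Genotype-stratified temperature classifiers and importance consistency.

Each genotype gets its own bagged decision-tree ensemble predicting the
temperature class (25/30/35 degC) from all metabolic features, with
sqrt(p) candidate variables per split.  Feature importance is Mean Decrease
Accuracy (MDA): the average out-of-bag accuracy lost when one feature's
values are permuted.  Cross-genotype agreement is summarized by Spearman
rank concordance, a per-feature consistency score in [0, 1], and a four-way
categorization (shared / A-favored / B-favored / uninformative).

The ensemble is built tree-by-tree over scikit-learn decision trees rather
than through ``RandomForestClassifier`` so that the bootstrap (and hence the
out-of-bag sets) is explicit: MDA only needs to re-predict the trees whose
split set contains the permuted feature, which makes exact out-of-bag
permutation importance cheap even at 1000 trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .containers import OmicsMatrix

__all__ = [
    "ForestConfig",
    "TemperatureForest",
    "ImportanceProfile",
    "ConsistencyReport",
    "fit_temperature_classifier",
    "mda_importance",
    "rank_concordance",
    "consistency_scores",
    "categorize_features",
]


@dataclass
class ForestConfig:
    n_trees: int = 1000
    n_importance_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_importance_repeats < 1:
            raise ValueError("n_importance_repeats must be >= 1")


@dataclass
class TemperatureForest:
    """Bagged ensemble of temperature classifiers for one genotype."""

    trees: list
    bootstrap_indices: list[np.ndarray]
    classes: np.ndarray
    feature_ids: list[str]
    genotype: str
    oob_accuracy: float
    X: np.ndarray  # samples x features (training data, kept for OOB MDA)
    y: np.ndarray  # integer class codes


def _oob_votes(trees, boots, X, n_classes) -> np.ndarray:
    votes = np.zeros((X.shape[0], n_classes))
    n = X.shape[0]
    for tree, idx in zip(trees, boots):
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if len(oob) == 0:
            continue
        pred = tree.predict(X[oob]).astype(int)
        votes[oob, pred] += 1
    return votes


def fit_temperature_classifier(
    matrix: OmicsMatrix, config: ForestConfig
) -> TemperatureForest:
    """Fit the per-genotype temperature classifier.

    The input must contain a single genotype (the two cultivars get
    independent models); every temperature class needs >= 2 samples.
    Per-split candidate-variable count is floor(sqrt(p)).
    """
    genotypes = matrix.metadata["genotype"].unique()
    if len(genotypes) != 1:
        raise ValueError(
            f"mixed genotypes {sorted(genotypes)}: fit one model per cultivar"
        )
    labels = matrix.metadata["temperature_C"].to_numpy()
    classes, y = np.unique(labels, return_inverse=True)
    if np.bincount(y).min() < 2:
        raise ValueError("every temperature class needs at least 2 samples")

    X = matrix.values.to_numpy(dtype=float).T
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    trees, boots = [], []
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2 ** 31 - 1))
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)

    votes = _oob_votes(trees, boots, X, len(classes))
    covered = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)
    oob_acc = float(np.mean(pred[covered] == y[covered])) if covered.any() else float("nan")
    return TemperatureForest(
        trees=trees,
        bootstrap_indices=boots,
        classes=classes,
        feature_ids=matrix.feature_ids,
        genotype=str(genotypes[0]),
        oob_accuracy=oob_acc,
        X=X,
        y=y,
    )


@dataclass
class ImportanceProfile:
    """Per-feature MDA with ranks (1 = most important) for one genotype."""

    mda: pd.Series
    rank: pd.Series  # average ranks for ties; permutation of 1..p when no ties
    oob_accuracy: float
    genotype: str

    def top(self, k: int) -> list[str]:
        order = self.mda.sort_values(ascending=False, kind="mergesort")
        return list(order.index[:k])


def mda_importance(
    forest: TemperatureForest, n_repeats: int = 10, seed: int = 0
) -> ImportanceProfile:
    """Out-of-bag permutation importance (Mean Decrease Accuracy).

    For every tree and every feature appearing in its splits, the feature's
    values are permuted within the tree's out-of-bag samples and the drop in
    that tree's out-of-bag accuracy recorded; trees not using the feature
    contribute zero.  The per-feature MDA is the drop summed over trees,
    divided by the number of trees, averaged over ``n_repeats`` permutation
    draws.  Ranks are by descending MDA with average ranks for ties.
    """
    rng = np.random.default_rng(seed)
    X, y = forest.X, forest.y
    n, p = X.shape
    decrease = np.zeros(p)

    per_tree = []
    for tree, idx in zip(forest.trees, forest.bootstrap_indices):
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0:
            continue
        Xoob = X[oob]
        y_oob = y[oob]
        base_acc = float(np.mean(tree.predict(Xoob).astype(int) == y_oob))
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        per_tree.append((tree, Xoob, y_oob, base_acc, used))

    for _ in range(n_repeats):
        for tree, Xoob, y_oob, base_acc, used in per_tree:
            m = len(y_oob)
            Xp = Xoob.copy()
            for f in used:
                perm = rng.permutation(m)
                saved = Xp[:, f].copy()
                Xp[:, f] = saved[perm]
                acc = float(np.mean(tree.predict(Xp).astype(int) == y_oob))
                decrease[f] += base_acc - acc
                Xp[:, f] = saved

    # average over repeats and all trees (unused trees contribute zero)
    mda_vals = decrease / (n_repeats * len(forest.trees))
    mda = pd.Series(mda_vals, index=forest.feature_ids, name="mda")
    rank = mda.rank(ascending=False, method="average")
    return ImportanceProfile(
        mda=mda, rank=rank, oob_accuracy=forest.oob_accuracy, genotype=forest.genotype
    )


def rank_concordance(
    prof_a: ImportanceProfile, prof_b: ImportanceProfile
) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation of two importance profiles.

    Computed over the common feature set; two-sided p via the t
    approximation on n - 2 degrees of freedom.
    """
    common = prof_a.mda.index.intersection(prof_b.mda.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common features")
    rho, p = stats.spearmanr(prof_a.mda[common], prof_b.mda[common])
    return float(rho), float(p)


def _normalized_importance(prof: ImportanceProfile) -> pd.Series:
    """Min-max normalized importance with negative MDA clipped to zero."""
    v = prof.mda.clip(lower=0.0)
    span = v.max() - v.min()
    if span == 0:
        return pd.Series(0.0, index=v.index)
    return (v - v.min()) / span


def consistency_scores(
    prof_a: ImportanceProfile, prof_b: ImportanceProfile
) -> pd.Series:
    """Per-feature agreement of min-max-normalized importances, in [0, 1].

    consistency_j = 1 - |n_A(j) - n_B(j)| where n is each model's importance
    min-max normalized to [0, 1] (negatives clipped to 0 first).
    """
    na = _normalized_importance(prof_a)
    nb = _normalized_importance(prof_b)
    common = na.index.intersection(nb.index)
    return (1.0 - (na[common] - nb[common]).abs()).rename("consistency")


@dataclass
class ConsistencyReport:
    spearman_rho: float
    spearman_p: float
    consistency: pd.Series
    normalized_importance_a: pd.Series
    normalized_importance_b: pd.Series
    category: pd.Series  # shared / a_favored / b_favored / uninformative
    genotype_a: str
    genotype_b: str
    importance_a: pd.Series | None = None
    importance_b: pd.Series | None = None

    @property
    def category_counts(self) -> dict[str, int]:
        counts = self.category.value_counts().to_dict()
        for cat in ("shared", "a_favored", "b_favored", "uninformative"):
            counts.setdefault(cat, 0)
        return counts


def categorize_features(
    prof_a: ImportanceProfile,
    prof_b: ImportanceProfile,
    importance_quantile: float = 0.8,
    consistency_threshold: float = 0.8,
) -> ConsistencyReport:
    """Partition features into shared / A-favored / B-favored / uninformative.

    "High importance" means MDA at or above the given within-model quantile.
    shared = high in both models AND consistency >= threshold; a_favored /
    b_favored = high in exactly one; uninformative = the rest.  Thresholds
    are inclusive (>=).
    """
    cons = consistency_scores(prof_a, prof_b)
    common = cons.index
    qa = prof_a.mda[common].quantile(importance_quantile)
    qb = prof_b.mda[common].quantile(importance_quantile)
    high_a = prof_a.mda[common] >= qa
    high_b = prof_b.mda[common] >= qb
    category = pd.Series("uninformative", index=common, name="category")
    category[high_a & ~high_b] = "a_favored"
    category[~high_a & high_b] = "b_favored"
    category[high_a & high_b & (cons >= consistency_threshold)] = "shared"
    rho, p = rank_concordance(prof_a, prof_b)
    return ConsistencyReport(
        spearman_rho=rho,
        spearman_p=p,
        consistency=cons,
        normalized_importance_a=_normalized_importance(prof_a)[common],
        normalized_importance_b=_normalized_importance(prof_b)[common],
        category=category,
        genotype_a=prof_a.genotype,
        genotype_b=prof_b.genotype,
        importance_a=prof_a.mda[common],
        importance_b=prof_b.mda[common],
    )
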