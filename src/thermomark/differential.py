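"""Multivariate and univariate differential screening.

PCA variance summaries, PLS-DA with VIP scoring (7-fold cross-validated Q2
and label-permutation validation), per-feature two-sample t tests, the
differential-metabolite rule (VIP > 1 and p < 0.05), a differential-gene
caller on normalized counts, Venn region counting, K-means expression
patterns and 2^-ddCt arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix

__all__ = [
    "PcaSummary",
    "VIPResult",
    "PLSDAModel",
    "DifferentialSet",
    "ClusterAssignment",
    "pca_summary",
    "fit_plsda",
    "validate_model",
    "univariate_tests",
    "select_dams",
    "select_degs",
    "venn_overlap",
    "kmeans_patterns",
    "ddct",
]


# --------------------------------------------------------------------------- PCA


@dataclass
class PcaSummary:
    variance_fraction: np.ndarray  # per component, non-increasing
    scores: pd.DataFrame  # samples x components
    degenerate: bool = False  # constant input matrix

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if not self.degenerate:
            if np.any(np.diff(vf) > 1e-10):
                raise ValueError("variance fractions must be non-increasing")
            if vf.sum() > 1 + 1e-8:
                raise ValueError("variance fractions must sum to <= 1")


def pca_summary(
    matrix: OmicsMatrix, n_components: int = 2, scale: bool = True
) -> PcaSummary:
    """Principal-component variance shares of the sample distribution.

    Samples are observations, features are variables.  With ``scale=True``
    (the metabolome convention here) features are standardized to unit
    variance first; for log-count transcriptome summaries pass
    ``scale=False``.
    """
    X = matrix.values.to_numpy(dtype=float).T
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
    if X.size == 0 or not np.any(X):
        k = min(n_components, X.shape[0])
        return PcaSummary(
            variance_fraction=np.zeros(k),
            scores=pd.DataFrame(
                np.zeros((matrix.values.shape[1], k)),
                index=matrix.sample_ids,
                columns=[f"PC{i + 1}" for i in range(k)],
            ),
            degenerate=True,
        )
    k = min(n_components, min(X.shape) - 0, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    return PcaSummary(
        variance_fraction=pca.explained_variance_ratio_,
        scores=pd.DataFrame(
            scores, index=matrix.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
        ),
    )


# ----------------------------------------------------------------------- PLS-DA


@dataclass
class VIPResult:
    """Variable importance in projection with model-quality statistics.

    The VIP normalization identity mean(vip^2) = 1 holds for every fitted
    model and is enforced as a postcondition.
    """

    vip: pd.Series  # per retained feature, >= 0
    n_components: int
    r2y: float
    q2: float = float("nan")
    permutation_p_r2y: float = float("nan")
    permutation_p_q2: float = float("nan")
    excluded_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        msq = float(np.mean(np.asarray(self.vip, dtype=float) ** 2))
        if abs(msq - 1.0) > 1e-8:
            raise ValueError(f"VIP normalization violated: mean(vip^2) = {msq}")


@dataclass
class PLSDAModel:
    """Fitted PLS discriminant model (latent variables against one-hot classes)."""

    pls: PLSRegression
    classes: np.ndarray
    feature_ids: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray

    def transform_X(self, values: pd.DataFrame) -> np.ndarray:
        X = values.loc[self.feature_ids].to_numpy(dtype=float).T
        return (X - self.scaler_mean) / self.scaler_sd


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    Y = (labels[:, None] == classes[None, :]).astype(float)
    if Y.shape[1] == 2:  # binary: a single +-1-style response column suffices
        Y = Y[:, [0]]
    return Y


def _vip_from_model(pls: PLSRegression) -> np.ndarray:
    W = pls.x_weights_  # p x A, unit-norm columns
    T = pls.x_scores_  # n x A
    Q = pls.y_loadings_  # m x A
    ss = np.sum(T ** 2, axis=0) * np.sum(Q ** 2, axis=0)  # Y-variance per component
    p = W.shape[0]
    wnorm2 = W ** 2 / np.sum(W ** 2, axis=0, keepdims=True)
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


def fit_plsda(
    matrix: OmicsMatrix,
    class_labels,
    n_components: int = 2,
) -> tuple[PLSDAModel, VIPResult]:
    """Fit PLS-DA on column-standardized features against one-hot classes.

    ``class_labels`` aligns with the matrix samples.  Zero-variance features
    are excluded with a warning and reported in the result.  VIP_j =
    sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a) with SS_a the
    Y-variance captured by component a.
    """
    labels = np.asarray(list(class_labels))
    if len(labels) != len(matrix.sample_ids):
        raise ValueError("class_labels length must match number of samples")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("PLS-DA requires at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")

    X = matrix.values.to_numpy(dtype=float).T
    sd = X.std(axis=0, ddof=1)
    excluded = [f for f, s in zip(matrix.feature_ids, sd) if s == 0]
    if excluded:
        warnings.warn(f"excluding {len(excluded)} zero-variance features")
    keep = sd > 0
    feature_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    X = X[:, keep]
    mean, sdk = X.mean(axis=0), X.std(axis=0, ddof=1)
    Xs = (X - mean) / sdk
    Y = _one_hot(labels, classes)
    Yc = Y - Y.mean(axis=0)

    n_components = int(min(n_components, Xs.shape[0] - 1, Xs.shape[1]))
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Yc)

    resid = Yc - pls.predict(Xs)
    r2y = 1.0 - np.sum(resid ** 2) / np.sum(Yc ** 2)
    vip = pd.Series(_vip_from_model(pls), index=feature_ids, name="vip")
    model = PLSDAModel(
        pls=pls, classes=classes, feature_ids=feature_ids,
        scaler_mean=mean, scaler_sd=sdk,
    )
    return model, VIPResult(
        vip=vip, n_components=n_components, r2y=r2y, excluded_features=excluded
    )


def _fit_stats(Xs, Yc, n_components, folds) -> tuple[float, float]:
    """(R2Y, Q2) of a PLS fit on already standardized/centered data."""
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Yc)
    r2y = 1.0 - np.sum((Yc - pls.predict(Xs)) ** 2) / np.sum(Yc ** 2)
    press = 0.0
    for train, test in folds:
        sub = PLSRegression(
            n_components=min(n_components, len(train) - 1), scale=False
        )
        sub.fit(Xs[train], Yc[train])
        press += np.sum((Yc[test] - sub.predict(Xs[test])) ** 2)
    q2 = 1.0 - press / np.sum(Yc ** 2)
    return float(r2y), float(q2)


def validate_model(
    model: PLSDAModel,
    matrix: OmicsMatrix,
    class_labels,
    n_folds: int = 7,
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Cross-validated Q2 and label-permutation p-values for R2Y and Q2.

    Q2 comes from stratified ``n_folds``-fold cross-validation; each
    permutation shuffles the class labels, refits, and the p-value is the
    plus-one-corrected fraction of permuted statistics >= the observed one,
    bounded below by 1/(n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = np.asarray(list(class_labels))
    if n_folds > len(labels):
        raise ValueError("n_folds cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    Xs = model.transform_X(matrix.values)
    A = model.pls.n_components

    def stats_for(lab, shuffle_seed):
        Y = _one_hot(lab, model.classes)
        Yc = Y - Y.mean(axis=0)
        skf = StratifiedKFold(
            n_splits=min(n_folds, np.bincount(pd.factorize(lab)[0]).min()),
            shuffle=True,
            random_state=shuffle_seed,
        )
        folds = list(skf.split(Xs, lab))
        return _fit_stats(Xs, Yc, A, folds)

    obs_r2y, obs_q2 = stats_for(labels, int(rng.integers(2 ** 31 - 1)))
    ge_r2y = ge_q2 = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        r2y_p, q2_p = stats_for(perm, int(rng.integers(2 ** 31 - 1)))
        ge_r2y += r2y_p >= obs_r2y
        ge_q2 += q2_p >= obs_q2
    p_r2y = (ge_r2y + 1) / (n_permutations + 1)
    p_q2 = (ge_q2 + 1) / (n_permutations + 1)
    return obs_q2, float(p_r2y), float(p_q2)


# ------------------------------------------------------------------- univariate


def univariate_tests(
    matrix: OmicsMatrix, group_a_ids, group_b_ids, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sided two-sample t test and log2 fold change per feature.

    log2FC = log2(mean_B / mean_A) on the raw abundance scale; zero means are
    guarded with a pseudo-count of half the smallest positive value in the
    matrix.  Returns a DataFrame with columns t, p_value, log2_fold_change.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = matrix.values[a_ids].to_numpy(dtype=float)
    B = matrix.values[b_ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=equal_var)
    # identical groups: zero pooled variance -> no evidence of difference
    same = ~np.isfinite(t)
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    positive = matrix.values.to_numpy()
    positive = positive[positive > 0]
    pseudo = 0.5 * positive.min() if positive.size else 0.5
    mean_a = np.where(A.mean(axis=1) > 0, A.mean(axis=1), pseudo)
    mean_b = np.where(B.mean(axis=1) > 0, B.mean(axis=1), pseudo)
    lfc = np.log2(mean_b / mean_a)
    return pd.DataFrame(
        {"t": t, "p_value": p, "log2_fold_change": lfc}, index=matrix.feature_ids
    )


@dataclass
class DifferentialSet:
    """Features surviving a recorded selection rule, with direction calls."""

    table: pd.DataFrame  # full per-feature table incl. 'selected' flag
    rule: str

    def __post_init__(self) -> None:
        if not len(self.table):
            return
        sel = self.table[self.table["selected"].astype(bool)]
        bad = sel[
            (sel["log2_fold_change"] > 0) & (sel["direction"] != "up")
            | (sel["log2_fold_change"] < 0) & (sel["direction"] != "down")
        ]
        if len(bad):
            raise ValueError("direction inconsistent with log2 fold change sign")

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def n_up(self) -> int:
        sel = self.table[self.table["selected"]]
        return int((sel["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        sel = self.table[self.table["selected"]]
        return int((sel["direction"] == "down").sum())


def select_dams(
    vip: VIPResult,
    tests: pd.DataFrame,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> DifferentialSet:
    """Differentially accumulated metabolites: VIP > 1.0 and p < 0.05.

    Both inequalities are strict.  Features without a VIP (excluded as
    zero-variance) are never selected.
    """
    table = tests.copy()
    table["vip"] = vip.vip.reindex(table.index)
    table["selected"] = (table["vip"] > vip_threshold) & (
        table["p_value"] < p_threshold
    )
    table["selected"] &= table["vip"].notna()
    table["direction"] = np.where(table["log2_fold_change"] >= 0, "up", "down")
    rule = f"VIP > {vip_threshold} and p < {p_threshold} (strict)"
    return DifferentialSet(table=table, rule=rule)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors (geometric-mean reference)."""
    log_counts = np.log(counts, where=counts > 0, out=np.full_like(counts, np.nan, dtype=float))
    ref = np.nanmean(np.where(np.all(counts > 0, axis=1)[:, None], log_counts, np.nan), axis=0)
    if np.all(np.isnan(ref)):
        totals = counts.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    usable = np.all(counts > 0, axis=1)
    ratios = log_counts[usable] - np.mean(log_counts[usable], axis=1, keepdims=True)
    return np.exp(np.median(ratios, axis=0))


def select_degs(
    counts: OmicsMatrix,
    group_a_ids,
    group_b_ids,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> DifferentialSet:
    """Differentially expressed genes between two sample groups.

    Counts are normalized by median-of-ratios size factors; a Welch test on
    log2(normalized + 1) with a normal approximation for the p-value, then
    Benjamini-Hochberg adjustment.  Rule: |log2FC| >= lfc_threshold and
    FDR < fdr_threshold.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    raw = counts.values.to_numpy(dtype=float)
    if raw.size == 0:
        table = pd.DataFrame(
            columns=["log2_fold_change", "p_value", "padj", "direction", "selected"]
        )
        return DifferentialSet(
            table=table, rule=f"|log2FC| >= {lfc_threshold} and FDR < {fdr_threshold}"
        )
    sf = size_factors(raw)
    norm = pd.DataFrame(
        raw / sf[None, :], index=counts.feature_ids, columns=counts.sample_ids
    )
    log_norm = np.log2(norm + 1.0)
    A = log_norm[a_ids].to_numpy()
    B = log_norm[b_ids].to_numpy()
    diff = B.mean(axis=1) - A.mean(axis=1)
    se = np.sqrt(
        A.var(axis=1, ddof=1) / A.shape[1] + B.var(axis=1, ddof=1) / B.shape[1]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = diff / se
    z = np.where(np.isfinite(z), z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2_fold_change": diff,
            "p_value": p,
            "padj": padj,
            "direction": np.where(diff >= 0, "up", "down"),
            "selected": (np.abs(diff) >= lfc_threshold) & (padj < fdr_threshold),
        },
        index=counts.feature_ids,
    )
    return DifferentialSet(
        table=table,
        rule=(
            f"median-of-ratios normalization, normal-approx test on log2 counts, "
            f"|log2FC| >= {lfc_threshold} and BH FDR < {fdr_threshold}"
        ),
    )


# ----------------------------------------------------------- sets and patterns


def venn_overlap(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every exclusive intersection region of the named sets.

    The region key is the sorted tuple of set names an element belongs to;
    region counts sum to the size of the union.
    """
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for element in set().union(*sets.values()) if sets else set():
        key = tuple(n for n in names if element in sets[n])
        regions[key] = regions.get(key, 0) + 1
    return regions


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene id -> cluster index in 1..k
    k: int
    inertia: float

    def __post_init__(self) -> None:
        lab = self.labels.to_numpy()
        if len(lab) and (lab.min() < 1 or lab.max() > self.k):
            raise ValueError("cluster indices must lie in 1..k")


def kmeans_patterns(
    profiles: OmicsMatrix, k: int = 12, seed: int = 0, n_init: int = 10
) -> ClusterAssignment:
    """K-means expression patterns on per-gene z-scored profiles.

    k-means++ (furthest-point-style) seeding with ``n_init`` restarts keeping
    the lowest inertia; deterministic given ``seed``.
    """
    X = profiles.values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z) + 1
    return ClusterAssignment(
        labels=pd.Series(labels, index=profiles.feature_ids, name="cluster"),
        k=k,
        inertia=float(km.inertia_),
    )


# ----------------------------------------------------------------------- qPCR


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_calibrator.
    """
    delta_treated = ct_target_treated - ct_ref_treated
    delta_calibrator = ct_target_calibrator - ct_ref_calibrator
    return float(2.0 ** -(delta_treated - delta_calibrator))
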