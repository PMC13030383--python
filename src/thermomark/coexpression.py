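"""From-formula weighted co-expression network analysis.

Unsigned weighted network: adjacency a_ij = |cor(x_i, x_j)|^beta, soft
threshold chosen by scale-free topology fit, topological overlap similarity

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage hierarchical module detection with a minimum module size
(small clusters fall into the reserved "grey" label), first-principal-
component module eigengenes, eigengene-similarity module merging, and
Pearson module-trait correlation with Student-t p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkParams",
    "ModuleSet",
    "correlation_matrix",
    "adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "align_traits",
]

GREY = "grey"


@dataclass
class NetworkParams:
    power: float = 9.0
    min_module_size: int = 50
    merge_cut_height: float = 0.25
    tom_type: str = "unsigned"
    # static branch cut: explicit height, or None for the largest-gap rule
    cut_height: float | None = None

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must lie in (0, 1)")
        if self.tom_type != "unsigned":
            raise ValueError("only the unsigned convention is implemented")


@dataclass
class ModuleSet:
    labels: pd.Series  # gene -> module label, "grey" = unassigned
    eigengenes: pd.DataFrame  # module x sample, unit norm
    module_trait_r: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None
    scale_free_r2: float | None = None
    power: float | None = None


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Pearson gene-gene correlation; near-constant profiles correlate 0."""
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    degenerate = sd < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} near-constant profiles: correlations set to 0"
        )
    Xs = X - X.mean(axis=1, keepdims=True)
    denom = np.where(degenerate, 1.0, sd * np.sqrt(X.shape[1]))
    Xs = Xs / denom[:, None]
    cor = Xs @ Xs.T
    cor[degenerate, :] = 0.0
    cor[:, degenerate] = 0.0
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def adjacency(expr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta with zero diagonal (for connectivity sums)."""
    a = np.abs(correlation_matrix(expr)) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 frequency vs log10 connectivity regression.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    and zero connectivities are dropped.  Returns the squared correlation of
    log10(freq(k)) against log10(mean k) over the bins.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or k.max() == k.min():
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(len(members) / len(k)))
    if len(log_k) < 3:
        return 0.0
    r = np.corrcoef(log_k, log_f)[0, 1]
    return float(r ** 2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    r2_target: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Scan candidate powers for scale-free topology.

    Returns the recommended power (smallest with fit R^2 >= ``r2_target``,
    else the maximizer) and a table of (power, scale_free_r2,
    mean_connectivity).
    """
    cor_abs = np.abs(correlation_matrix(expr))
    np.fill_diagonal(cor_abs, 0.0)
    rows = []
    for beta in candidate_powers:
        a = cor_abs ** beta
        k = a.sum(axis=1)
        rows.append(
            {
                "power": float(beta),
                "scale_free_r2": scale_free_fit(k),
                "mean_connectivity": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows)
    good = table[table["scale_free_r2"] >= r2_target]
    if len(good):
        beta = float(good["power"].iloc[0])
    else:
        beta = float(table.loc[table["scale_free_r2"].idxmax(), "power"])
    return beta, table


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal, TOM_ii = 1.  The adjacency must be symmetric with entries in
    [0, 1] (diagonal ignored).
    """
    a = np.asarray(adj, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _gap_cut_height(merge_heights: np.ndarray, lower_quantile: float = 0.5) -> float:
    """Midpoint of the largest gap among the upper merge heights.

    Tight within-module merges happen low in the dendrogram and the
    unstructured background merges in a dense plateau near the top; the
    largest gap between consecutive merge heights (restricted to heights at
    or above the ``lower_quantile`` quantile, ignoring sparse early merges)
    separates the two regimes.
    """
    hs = np.sort(np.asarray(merge_heights, dtype=float))
    hs = hs[hs >= np.quantile(hs, lower_quantile)]
    if len(hs) < 2:
        return float(hs[-1]) if len(hs) else 1.0
    gaps = np.diff(hs)
    i = int(np.argmax(gaps))
    return float((hs[i] + hs[i + 1]) / 2)


def detect_modules(
    tom_dissimilarity: np.ndarray,
    gene_ids,
    min_module_size: int = 50,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage module detection with a static branch cut.

    The dendrogram on 1 - TOM is cut at ``cut_height`` (default: the
    largest-gap rule of :func:`_gap_cut_height`); clusters smaller than
    ``min_module_size`` are assigned the reserved "grey" label.  Surviving
    modules are renamed M1, M2, ... by decreasing size.
    """
    d = np.asarray(tom_dissimilarity, dtype=float)
    gene_ids = list(gene_ids)
    condensed = squareform(np.round((d + d.T) / 2, 12), checks=False)
    Z = linkage(condensed, method="average")
    if cut_height is None:
        cut_height = _gap_cut_height(Z[:, 2])
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=gene_ids)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    # stable rename by decreasing size, ties by first occurrence
    ordered = sorted(keep, key=lambda c: (-sizes[c], c))
    mapping = {c: f"M{i + 1}" for i, c in enumerate(ordered)}
    return labels.map(lambda c: mapping.get(c, GREY)).rename("module")


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Eigengenes are unit-norm over samples and sign-oriented to correlate
    positively with the module's mean standardized profile; grey genes get
    no eigengene.
    """
    modules = [m for m in labels.unique() if m != GREY]
    modules.sort(key=lambda m: (len(m), m))  # M2 < M10
    rows = {}
    for m in modules:
        sub = expr.loc[labels.index[labels == m]].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (sub - mu) / sd
        # first right-singular vector = PC1 across samples
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        eig = vt[0]
        ref = Z.mean(axis=0)
        if np.dot(eig, ref) < 0:
            eig = -eig
        rows[m] = eig / np.linalg.norm(eig)
    return pd.DataFrame(rows, index=expr.columns).T


def merge_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    cut_height: float = 0.25,
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge modules whose eigengenes are closer than ``cut_height``.

    Eigengene dissimilarity is 1 - Pearson correlation; average-linkage
    groups below the cut are merged, eigengenes recomputed, and the process
    repeated to a fixed point.  Merged modules are renamed by decreasing
    size.
    """
    labels = labels.copy()
    while True:
        eig = module_eigengenes(expr, labels)
        if len(eig) <= 1 or cut_height <= 0:
            return _rename_by_size(labels), module_eigengenes(expr, _rename_by_size(labels))
        diss = 1.0 - np.corrcoef(eig.to_numpy())
        np.fill_diagonal(diss, 0.0)
        Z = linkage(squareform(np.clip(diss, 0, None), checks=False), method="average")
        groups = fcluster(Z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(eig):
            renamed = _rename_by_size(labels)
            return renamed, module_eigengenes(expr, renamed)
        mapping = {}
        for module, grp in zip(eig.index, groups):
            mapping.setdefault(grp, []).append(module)
        for grp, members in mapping.items():
            target = members[0]
            for m in members[1:]:
                labels[labels == m] = target


def _rename_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    ordered = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    mapping = {m: f"M{i + 1}" for i, m in enumerate(ordered)}
    mapping[GREY] = GREY
    return labels.map(mapping).rename("module")


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson module-trait correlations with two-sided Student-t p-values.

    Rows of ``traits`` are trait vectors (e.g. biomarker metabolite
    abundances); columns must share sample ids with the eigengenes.  Pairs
    are aligned on the shared samples; p-values use n - 2 degrees of
    freedom.  Near-constant vectors correlate 0 with a warning.
    """
    common = eigengenes.columns.intersection(traits.columns)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    E = eigengenes[common].to_numpy(dtype=float)
    T = traits[common].to_numpy(dtype=float)
    n = len(common)
    r = np.zeros((E.shape[0], T.shape[0]))
    p = np.ones_like(r)
    for i in range(E.shape[0]):
        for j in range(T.shape[0]):
            if E[i].std() < 1e-12 or T[j].std() < 1e-12:
                warnings.warn("near-constant profile in module-trait correlation")
                r[i, j], p[i, j] = 0.0, 1.0
                continue
            rij, pij = stats.pearsonr(E[i], T[j])
            r[i, j], p[i, j] = rij, pij
    return (
        pd.DataFrame(r, index=eigengenes.index, columns=traits.index),
        pd.DataFrame(p, index=eigengenes.index, columns=traits.index),
    )


def align_traits(
    traits: pd.DataFrame,
    trait_metadata: pd.DataFrame,
    target_metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Align trait measurements onto another assay's sample grid.

    Matches samples by (genotype, temperature_C, replicate); where replicate
    counts differ (e.g. 6 metabolome vs 3 transcriptome replicates) the
    trait values are averaged within (genotype, temperature_C) and broadcast
    to the target samples of that cell.
    """
    key_cols = ["genotype", "temperature_C"]
    full_key = key_cols + ["replicate"]
    src_keys = {
        tuple(row[c] for c in full_key): sid for sid, row in trait_metadata.iterrows()
    }
    out = {}
    for sid, row in target_metadata.iterrows():
        key = tuple(row[c] for c in full_key)
        if key in src_keys:
            out[sid] = traits[src_keys[key]]
        else:
            cell = trait_metadata[
                (trait_metadata["genotype"] == row["genotype"])
                & (trait_metadata["temperature_C"] == row["temperature_C"])
            ].index
            if len(cell) == 0:
                raise ValueError(f"no trait samples for cell {key[:2]}")
            out[sid] = traits[list(cell)].mean(axis=1)
    return pd.DataFrame(out)
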