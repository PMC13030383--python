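"""Synthetic multi-omics generator with planted, recoverable ground truth.

Emulates a two-cultivar (heat-tolerant vs heat-sensitive) graded heat-stress
design: three temperatures (25/30/35 degC, encoded as ordinal doses 0/1/2),
six metabolome replicates and three transcriptome replicates per
genotype x temperature cell.

The metabolome is log-normal: each feature's log2 abundance is a feature
baseline plus marker shifts plus Gaussian noise.  *Shared* markers respond to
temperature in both genotypes, *genotype-specific* markers only in theirs;
the response is linear in dose with slope ``marker_effect`` (log2-fold-change
per temperature step).

The transcriptome is negative-binomial around module-driven means: each
planted co-expression module has a latent per-sample factor, its member genes
respond affinely to that factor on the log scale, and background genes are
independent noise.  Designated metabolite "traits" are constructed jointly
with the latent factors (bivariate-normal construction) so that the planted
module-trait Pearson correlation equals ``module_trait_r`` in population.

Everything is deterministic given ``config.seed``; seeds are explicit and
never global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import GENOTYPES, TEMPERATURES, OmicsMatrix

# log2 abundance scale constants (arbitrary units typical of LC-MS intensities)
_MET_BASELINE_MEAN = 10.0
_MET_BASELINE_SD = 2.0
_TRAIT_BASELINE = 10.0
# transcriptome: log2 base mean ~ 7.6 -> ~200 counts
_GENE_BASE_MEAN = 7.6
_GENE_BASE_SD = 1.0


@dataclass
class SimulationConfig:
    """Study-design constants and planted effect sizes for one simulation."""

    n_features_metabolome: int = 500
    n_genes: int = 1000
    n_reps_metabolome: int = 6
    n_reps_transcriptome: int = 3
    n_shared_markers: int = 10
    n_specific_markers_per_genotype: int = 5
    marker_effect: float = 2.0  # log2-fold-change per temperature step
    n_modules: int = 4
    module_sizes: tuple[int, ...] = (60, 80, 100, 120)
    module_trait_r: float = 0.7
    noise_sd: float = 0.5  # log2-scale metabolite noise
    nb_dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_features_metabolome=self.n_features_metabolome,
            n_genes=self.n_genes,
            n_reps_metabolome=self.n_reps_metabolome,
            n_reps_transcriptome=self.n_reps_transcriptome,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_shared_markers < 0 or self.n_specific_markers_per_genotype < 0:
            raise ValueError("marker counts must be non-negative")
        n_markers = self.n_shared_markers + 2 * self.n_specific_markers_per_genotype
        if n_markers > self.n_features_metabolome:
            raise ValueError(
                f"{n_markers} markers exceed {self.n_features_metabolome} features"
            )
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if not abs(self.module_trait_r) < 1:
            raise ValueError("|module_trait_r| must be < 1")
        if self.marker_effect < 0:
            raise ValueError("marker_effect must be >= 0")
        if self.noise_sd <= 0 or self.nb_dispersion <= 0:
            raise ValueError("noise_sd and nb_dispersion must be positive")


@dataclass
class SyntheticTruth:
    """Planted structure: the recovery oracle for every downstream stage."""

    shared_marker_ids: list[str]
    tolerant_marker_ids: list[str]
    sensitive_marker_ids: list[str]
    # gene id -> module index, 0 = background
    module_membership: dict[str, int] = field(default_factory=dict)
    # module index (1-based) x transcriptome sample
    module_latent_factors: pd.DataFrame | None = None
    # metabolite id -> (module index, signed target r)
    trait_assignments: dict[str, tuple[int, float]] = field(default_factory=dict)
    # trait metabolite x transcriptome sample, abundance scale
    trait_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sets = [
            set(self.shared_marker_ids),
            set(self.tolerant_marker_ids),
            set(self.sensitive_marker_ids),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("marker id sets must be pairwise disjoint")

    @property
    def all_marker_ids(self) -> list[str]:
        return (
            list(self.shared_marker_ids)
            + list(self.tolerant_marker_ids)
            + list(self.sensitive_marker_ids)
        )

    def to_json(self, path) -> None:
        payload = {
            "shared_marker_ids": self.shared_marker_ids,
            "tolerant_marker_ids": self.tolerant_marker_ids,
            "sensitive_marker_ids": self.sensitive_marker_ids,
            "module_membership": self.module_membership,
            "module_latent_factors": (
                None
                if self.module_latent_factors is None
                else self.module_latent_factors.to_dict(orient="split")
            ),
            "trait_assignments": {
                k: list(v) for k, v in self.trait_assignments.items()
            },
            "trait_values": (
                None
                if self.trait_values is None
                else self.trait_values.to_dict(orient="split")
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)

        def _df(entry):
            if entry is None:
                return None
            return pd.DataFrame(
                entry["data"], index=entry["index"], columns=entry["columns"]
            )

        return cls(
            shared_marker_ids=payload["shared_marker_ids"],
            tolerant_marker_ids=payload["tolerant_marker_ids"],
            sensitive_marker_ids=payload["sensitive_marker_ids"],
            module_membership={k: int(v) for k, v in payload["module_membership"].items()},
            module_latent_factors=_df(payload["module_latent_factors"]),
            trait_assignments={
                k: (int(v[0]), float(v[1]))
                for k, v in payload["trait_assignments"].items()
            },
            trait_values=_df(payload["trait_values"]),
        )


def _design(genotypes, temperatures, n_reps) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        for t in temperatures:
            for r in range(1, n_reps + 1):
                rows.append((f"{g}_{t}_r{r}", g, t, r))
    df = pd.DataFrame(rows, columns=["sample_id", "genotype", "temperature_C", "replicate"])
    return df.set_index("sample_id")


def temperature_dose(temperature_c) -> np.ndarray:
    """Ordinal dose encoding of the graded stress: 25->0, 30->1, 35->2."""
    mapping = {t: i for i, t in enumerate(TEMPERATURES)}
    return np.asarray([mapping[int(t)] for t in np.atleast_1d(temperature_c)])


def generate_metabolome(config: SimulationConfig) -> tuple[OmicsMatrix, SyntheticTruth]:
    """Simulate the metabolome and allocate the planted marker sets.

    Returns the features x samples abundance matrix (6 replicates per
    genotype x temperature by default) and the ground truth carrying the
    disjoint shared / tolerant-specific / sensitive-specific marker ids.
    """
    rng = np.random.default_rng(config.seed)
    meta = _design(GENOTYPES, TEMPERATURES, config.n_reps_metabolome)
    p = config.n_features_metabolome
    feature_ids = [f"met_{i:04d}" for i in range(1, p + 1)]

    n_markers = config.n_shared_markers + 2 * config.n_specific_markers_per_genotype
    marker_pos = rng.choice(p, size=n_markers, replace=False)
    shared = marker_pos[: config.n_shared_markers]
    tol = marker_pos[
        config.n_shared_markers : config.n_shared_markers
        + config.n_specific_markers_per_genotype
    ]
    sen = marker_pos[config.n_shared_markers + config.n_specific_markers_per_genotype :]

    dose = temperature_dose(meta["temperature_C"].to_numpy())
    is_tol = (meta["genotype"] == "tolerant").to_numpy()

    baseline = rng.normal(_MET_BASELINE_MEAN, _MET_BASELINE_SD, size=p)
    log2 = np.tile(baseline[:, None], (1, len(meta)))
    log2[shared, :] += config.marker_effect * dose[None, :]
    log2[tol[:, None], np.where(is_tol)[0][None, :]] += (
        config.marker_effect * dose[is_tol][None, :]
    )
    log2[sen[:, None], np.where(~is_tol)[0][None, :]] += (
        config.marker_effect * dose[~is_tol][None, :]
    )
    log2 += rng.normal(0.0, config.noise_sd, size=log2.shape)

    values = pd.DataFrame(2.0 ** log2, index=feature_ids, columns=meta.index)
    truth = SyntheticTruth(
        shared_marker_ids=[feature_ids[i] for i in shared],
        tolerant_marker_ids=[feature_ids[i] for i in tol],
        sensitive_marker_ids=[feature_ids[i] for i in sen],
    )
    return OmicsMatrix(values=values, metadata=meta, role="metabolome"), truth


def generate_transcriptome(config: SimulationConfig, truth: SyntheticTruth) -> OmicsMatrix:
    """Simulate module-structured gene counts and plant metabolite traits.

    Mutates ``truth`` in place: fills ``module_membership``,
    ``module_latent_factors``, ``trait_assignments`` and ``trait_values``.
    Member genes respond affinely (slope ~ +-U(0.8, 1.2), 20% negative) to
    their module's standard-normal latent factor on the log2 scale; counts
    are negative-binomial with ``var = mu + dispersion * mu^2``.  For each
    module a non-marker metabolite is designated as its trait and its values
    are drawn so that corr(latent, trait) = ``module_trait_r``.
    """
    # distinct stream from the metabolome so that the two matrices are
    # independently reproducible
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    meta = _design(GENOTYPES, TEMPERATURES, config.n_reps_transcriptome)
    n_samples = len(meta)
    gene_ids = [f"gene_{i:05d}" for i in range(1, config.n_genes + 1)]

    membership = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        membership[start : start + size] = m
        start += size
    # shuffle so module membership is not positional
    order = rng.permutation(config.n_genes)
    membership = membership[order]

    latent = rng.standard_normal((config.n_modules, n_samples))
    if config.n_modules:
        # standardize per module: the planted factor has exactly unit sample
        # variance, so module strength is controlled, not left to n=18 luck
        latent = (latent - latent.mean(axis=1, keepdims=True)) / latent.std(
            axis=1, keepdims=True
        )

    base = rng.normal(_GENE_BASE_MEAN, _GENE_BASE_SD, size=config.n_genes)
    slope_mag = rng.uniform(0.8, 1.2, size=config.n_genes)
    slope_sign = np.where(rng.random(config.n_genes) < 0.2, -1.0, 1.0)
    slopes = slope_mag * slope_sign

    log2_mean = np.tile(base[:, None], (1, n_samples))
    for m in range(1, config.n_modules + 1):
        rows = membership == m
        log2_mean[rows, :] += slopes[rows, None] * latent[m - 1][None, :]

    mu = 2.0 ** log2_mean
    r_shape = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r_shape, r_shape / (r_shape + mu))

    values = pd.DataFrame(counts.astype(float), index=gene_ids, columns=meta.index)

    truth.module_membership = {g: int(m) for g, m in zip(gene_ids, membership)}
    truth.module_latent_factors = pd.DataFrame(
        latent, index=[f"M{m}" for m in range(1, config.n_modules + 1)], columns=meta.index
    )

    # trait metabolites: non-marker features, one per module
    marker_set = set(truth.all_marker_ids)
    candidates = [
        f"met_{i:04d}"
        for i in range(1, config.n_features_metabolome + 1)
        if f"met_{i:04d}" not in marker_set
    ]
    if len(candidates) < config.n_modules:
        raise ValueError("not enough non-marker metabolites to assign traits")
    trait_ids = [str(t) for t in rng.choice(candidates, size=config.n_modules, replace=False)]

    r = config.module_trait_r
    trait_rows = []
    truth.trait_assignments = {}
    for m, trait_id in enumerate(trait_ids, start=1):
        z = latent[m - 1]
        zs = (z - z.mean()) / z.std()
        eps = rng.standard_normal(n_samples)
        eps = eps - eps.mean()
        eps /= eps.std()
        # exact-in-sample bivariate construction: orthogonalize the noise
        eps -= zs * (zs @ eps) / (zs @ zs)
        eps /= np.sqrt((eps ** 2).mean())
        trait_z = r * zs + np.sqrt(1.0 - r ** 2) * eps
        trait_rows.append(2.0 ** (_TRAIT_BASELINE + trait_z))
        truth.trait_assignments[trait_id] = (m, float(r))
    truth.trait_values = pd.DataFrame(trait_rows, index=trait_ids, columns=meta.index)

    return OmicsMatrix(values=values, metadata=meta, role="transcriptome")


def embed_trait_metabolites(
    metabolome: OmicsMatrix,
    truth: SyntheticTruth,
    jitter_sd: float = 0.1,
    seed: int | None = None,
) -> OmicsMatrix:
    """Overwrite the designated trait metabolite rows with planted trait values.

    Metabolome replicates are mapped onto transcriptome replicates cyclically
    (replicate k -> transcriptome replicate ((k-1) mod n)+1) and a small
    log2-scale jitter keeps replicate columns distinct.
    """
    if truth.trait_values is None:
        raise ValueError("truth carries no trait values; run generate_transcriptome first")
    rng = np.random.default_rng(seed)
    values = metabolome.values.copy()
    tx_meta = {}
    for sid in truth.trait_values.columns:
        g, t, r = sid.rsplit("_", 2)
        tx_meta[(g, int(t), int(r[1:]))] = sid
    n_tx_reps = max(k[2] for k in tx_meta)
    for sid in values.columns:
        row = metabolome.metadata.loc[sid]
        key = (
            row["genotype"],
            int(row["temperature_C"]),
            (int(row["replicate"]) - 1) % n_tx_reps + 1,
        )
        src = tx_meta[key]
        jitter = 2.0 ** rng.normal(0.0, jitter_sd, size=len(truth.trait_values))
        values.loc[truth.trait_values.index, sid] = (
            truth.trait_values[src].to_numpy() * jitter
        )
    return OmicsMatrix(values=values, metadata=metabolome.metadata.copy(), role="metabolome")


def synthetic_annotation(truth: SyntheticTruth, config: SimulationConfig) -> dict[str, list[str]]:
    """GMT-style term -> member mapping over the planted structure.

    Terms: one per planted module (its genes), one per biomarker category
    over the planted marker metabolites, and one convergence term joining
    the tolerant-relevant markers with the genes of the first trait-linked
    module (emulating a pathway observable in several evidence streams).
    """
    ann: dict[str, list[str]] = {}
    module_genes: dict[int, list[str]] = {}
    for gene, m in truth.module_membership.items():
        if m > 0:
            module_genes.setdefault(m, []).append(gene)
    for m, genes in sorted(module_genes.items()):
        ann[f"module_{m}_pathway"] = sorted(genes)

    categories = ("hormone_regulation", "secondary_metabolic_defense", "signal_transduction")
    markers = truth.all_marker_ids
    for i, cat in enumerate(categories):
        ann[cat] = sorted(markers[i::len(categories)])

    if truth.trait_assignments:
        first_module = min(m for m, _ in truth.trait_assignments.values())
        ann["flavonoid_like_convergence"] = sorted(
            set(truth.shared_marker_ids)
            | set(truth.tolerant_marker_ids)
            | set(module_genes.get(first_module, []))
        )
    return ann
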