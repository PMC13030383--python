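"""End-to-end orchestration: simulate -> differential -> forest -> cascade ->
modules -> hubs -> enrichment -> convergence.

A single base seed fans out to per-stage seeds through a documented counter
scheme (``SeedSequence([base_seed, stage_index])``), so stages are
reproducible independently of one another.  Every stage writes TSV/JSON
outputs under the run directory and the run manifest records parameters,
seeds and per-stage output paths.  The convergence table joins the three
evidence streams — biomarker panel membership, module-trait correlation and
module enrichment — and counts, per annotation term, how many streams
support it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cascade import annotate_panel, expression_filter, read_annotation, top_candidates, write_gmt
from .coexpression import (
    NetworkParams,
    adjacency,
    align_traits,
    detect_modules,
    merge_modules,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
)
from .containers import OmicsMatrix, read_matrix_tsv, write_matrix_tsv
from .differential import (
    fit_plsda,
    kmeans_patterns,
    pca_summary,
    select_dams,
    select_degs,
    univariate_tests,
    validate_model,
    venn_overlap,
)
from .enrichment import enrich
from .forest import (
    ForestConfig,
    categorize_features,
    fit_temperature_classifier,
    mda_importance,
)
from .hubs import build_graph, degree_rank, intramodular_connectivity
from .simulate import (
    SimulationConfig,
    SyntheticTruth,
    embed_trait_metabolites,
    generate_metabolome,
    generate_transcriptome,
    synthetic_annotation,
)

log = logging.getLogger("thermomark")

# stage indices for the seed fan-out
_STAGES = ("simulate", "differential", "forest", "cascade", "modules", "hubs", "enrich")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([base_seed, idx]).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    outdir: str = "results/run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    forest: ForestConfig = field(default_factory=lambda: ForestConfig(n_trees=300))
    network: NetworkParams = field(default_factory=NetworkParams)
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    kmeans_k: int = 12
    top_k_candidates: int = 100
    hub_top_n: int = 50
    n_permutations: int = 200
    # optional user inputs; when absent, synthetic equivalents are generated
    metabolome_path: str | None = None
    metabolome_metadata_path: str | None = None
    transcriptome_path: str | None = None
    transcriptome_metadata_path: str | None = None
    annotation_path: str | None = None
    edges_path: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        forest = ForestConfig(**raw.pop("forest", {}))
        network = NetworkParams(**raw.pop("network", {}))
        return cls(simulation=sim, forest=forest, network=network, **raw)


def _check_path(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "simulation": asdict(config.simulation),
            "forest": asdict(config.forest),
            "network": asdict(config.network),
            "vip_threshold": config.vip_threshold,
            "p_threshold": config.p_threshold,
            "lfc_threshold": config.lfc_threshold,
            "fdr_threshold": config.fdr_threshold,
            "kmeans_k": config.kmeans_k,
            "top_k_candidates": config.top_k_candidates,
            "hub_top_n": config.hub_top_n,
        },
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "outputs": {},
    }

    stage = "simulate"
    try:
        # ------------------------------------------------------------ inputs
        if config.metabolome_path is not None:
            metab = read_matrix_tsv(
                _check_path(config.metabolome_path, "metabolome matrix"),
                _check_path(config.metabolome_metadata_path, "metabolome metadata"),
                role="metabolome",
            )
            expr = read_matrix_tsv(
                _check_path(config.transcriptome_path, "transcriptome matrix"),
                _check_path(config.transcriptome_metadata_path, "transcriptome metadata"),
                role="transcriptome",
            )
            truth = None
        else:
            sim = SimulationConfig(**{**asdict(config.simulation), "seed": stage_seed(config.seed, "simulate")})
            metab, truth = generate_metabolome(sim)
            expr = generate_transcriptome(sim, truth)
            metab = embed_trait_metabolites(
                metab, truth, seed=stage_seed(config.seed, "simulate") + 1
            )
            write_matrix_tsv(metab, outdir / "metabolome.tsv", outdir / "metabolome_metadata.tsv")
            write_matrix_tsv(expr, outdir / "transcriptome.tsv", outdir / "transcriptome_metadata.tsv")
            truth.to_json(outdir / "truth.json")
            manifest["outputs"]["simulate"] = [
                str(outdir / f) for f in (
                    "metabolome.tsv", "metabolome_metadata.tsv",
                    "transcriptome.tsv", "transcriptome_metadata.tsv", "truth.json",
                )
            ]
        if config.annotation_path is not None:
            annotation = read_annotation(_check_path(config.annotation_path, "annotation"))
        elif truth is not None:
            annotation = synthetic_annotation(truth, config.simulation)
            write_gmt(annotation, outdir / "annotation.gmt")
        else:
            annotation = {}

        # ------------------------------------------------------ differential
        stage = "differential"
        dseed = stage_seed(config.seed, stage)
        pca = pca_summary(metab, n_components=2)
        dam_sets = {}
        plsda_quality = {}
        for genotype in ("tolerant", "sensitive"):
            base = metab.samples_where(genotype=genotype, temperature_C=25)
            stressed = metab.samples_where(genotype=genotype, temperature_C=35)
            sub = metab.subset_samples(base + stressed)
            labels = ["25"] * len(base) + ["35"] * len(stressed)
            model, vip = fit_plsda(sub, labels, n_components=2)
            q2, p_r2y, p_q2 = validate_model(
                model, sub, labels, n_permutations=config.n_permutations, seed=dseed
            )
            tests = univariate_tests(metab, base, stressed)
            dams = select_dams(vip, tests, config.vip_threshold, config.p_threshold)
            dam_sets[genotype] = dams
            plsda_quality[genotype] = {
                "r2y": vip.r2y, "q2": q2,
                "permutation_p_r2y": p_r2y, "permutation_p_q2": p_q2,
            }
            dams.table.to_csv(outdir / f"dams_{genotype}_25v35.tsv", sep="\t")

        deg_sets = {}
        for genotype in ("tolerant", "sensitive"):
            base = expr.samples_where(genotype=genotype, temperature_C=25)
            stressed = expr.samples_where(genotype=genotype, temperature_C=35)
            degs = select_degs(expr, base, stressed, config.lfc_threshold, config.fdr_threshold)
            deg_sets[genotype] = degs
            degs.table.to_csv(outdir / f"degs_{genotype}_25v35.tsv", sep="\t")

        venn = venn_overlap({g: set(d.selected_ids) for g, d in deg_sets.items()})
        with open(outdir / "deg_venn.json", "w") as fh:
            json.dump({"&".join(k): v for k, v in venn.items()}, fh, indent=1)

        deg_union = sorted(set().union(*(d.selected_ids for d in deg_sets.values())))
        clusters = None
        if len(deg_union) >= config.kmeans_k:
            clusters = kmeans_patterns(
                expr.subset_features(deg_union), k=config.kmeans_k, seed=dseed
            )
            clusters.labels.to_csv(outdir / "deg_kmeans_clusters.tsv", sep="\t")
        manifest["outputs"]["differential"] = {
            "pca_variance_fraction": [float(v) for v in pca.variance_fraction],
            "plsda_quality": plsda_quality,
            "dam_counts": {g: len(d.selected_ids) for g, d in dam_sets.items()},
            "deg_counts": {g: len(d.selected_ids) for g, d in deg_sets.items()},
            "kmeans": None if clusters is None else f"k={clusters.k}",
        }

        # ------------------------------------------------------------ forest
        stage = "forest"
        fseed = stage_seed(config.seed, stage)
        profiles = {}
        for i, genotype in enumerate(("tolerant", "sensitive")):
            sub = metab.subset_samples(metab.samples_where(genotype=genotype))
            fc = ForestConfig(
                n_trees=config.forest.n_trees,
                n_importance_repeats=config.forest.n_importance_repeats,
                seed=fseed + i,
            )
            forest_model = fit_temperature_classifier(sub, fc)
            prof = mda_importance(
                forest_model, n_repeats=fc.n_importance_repeats, seed=fseed + 10 + i
            )
            profiles[genotype] = prof
            pd.DataFrame(
                {"mda": prof.mda, "rank": prof.rank, "genotype": genotype}
            ).to_csv(outdir / f"importance_{genotype}.tsv", sep="\t")
        report = categorize_features(profiles["tolerant"], profiles["sensitive"])
        pd.DataFrame(
            {
                "consistency": report.consistency,
                "normalized_importance_tolerant": report.normalized_importance_a,
                "normalized_importance_sensitive": report.normalized_importance_b,
                "category": report.category,
            }
        ).to_csv(outdir / "consistency.tsv", sep="\t")
        with open(outdir / "consistency_summary.json", "w") as fh:
            json.dump(
                {
                    "spearman_rho": report.spearman_rho,
                    "spearman_p": report.spearman_p,
                    "category_counts": report.category_counts,
                    "oob_accuracy": {g: p.oob_accuracy for g, p in profiles.items()},
                },
                fh,
                indent=1,
            )
        manifest["outputs"]["forest"] = {
            "spearman_rho": report.spearman_rho,
            "category_counts": report.category_counts,
        }

        # ----------------------------------------------------------- cascade
        stage = "cascade"
        candidates = top_candidates(report, k=config.top_k_candidates, model="tolerant")
        panel = expression_filter(candidates, metab, p_threshold=config.p_threshold)
        panel = annotate_panel(panel, annotation)
        panel.table.to_csv(outdir / "biomarker_panel.tsv", sep="\t")
        manifest["outputs"]["cascade"] = {"panel_size": len(panel.table)}

        # ----------------------------------------------------------- modules
        stage = "modules"
        log_expr = np.log2(expr.values + 1.0)
        beta, sft = pick_soft_threshold(log_expr)
        power = config.network.power
        adj = adjacency(log_expr, power)
        tom = tom_similarity(adj)
        labels = detect_modules(
            1.0 - tom,
            log_expr.index,
            min_module_size=config.network.min_module_size,
            cut_height=config.network.cut_height,
        )
        labels, eigengenes = merge_modules(
            log_expr, labels, cut_height=config.network.merge_cut_height
        )
        labels.to_csv(outdir / "module_labels.tsv", sep="\t")
        eigengenes.to_csv(outdir / "module_eigengenes.tsv", sep="\t")
        sft.to_csv(outdir / "soft_threshold_scan.tsv", sep="\t", index=False)

        trait_ids = list(panel.marker_ids)
        if truth is not None:
            trait_ids += [t for t in truth.trait_assignments if t not in trait_ids]
        mt_r = mt_p = None
        if trait_ids and len(eigengenes):
            traits = align_traits(
                metab.values.loc[[t for t in trait_ids if t in metab.values.index]],
                metab.metadata,
                expr.metadata,
            )
            mt_r, mt_p = module_trait_correlation(eigengenes, traits)
            mt_r.to_csv(outdir / "module_trait_r.tsv", sep="\t")
            mt_p.to_csv(outdir / "module_trait_p.tsv", sep="\t")
        manifest["outputs"]["modules"] = {
            "n_modules": int((labels != "grey").sum() and labels[labels != "grey"].nunique()),
            "recommended_power": beta,
            "power_used": power,
        }

        # -------------------------------------------------------------- hubs
        stage = "hubs"
        if config.edges_path is not None:
            edges = pd.read_csv(_check_path(config.edges_path, "edge list"), sep="\t")
        else:
            # synthetic interaction list: strongest co-expression edges
            a = adj.to_numpy().copy()
            iu = np.triu_indices_from(a, k=1)
            w = a[iu]
            keep = w >= np.quantile(w, 0.999) if len(w) else np.array([], bool)
            edges = pd.DataFrame(
                {
                    "gene_a": adj.index[iu[0][keep]],
                    "gene_b": adj.index[iu[1][keep]],
                    "weight": w[keep],
                }
            )
            edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        graph = build_graph(edges)
        kim = intramodular_connectivity(adj, labels)
        hub_tables = []
        for module in sorted(m for m in labels.unique() if m != "grey"):
            members = labels.index[labels == module]
            tab = degree_rank(graph, top_n=config.hub_top_n, module_genes=members)
            tab["module"] = module
            tab["kIM"] = kim.loc[tab["gene_id"], "kIM"].to_numpy()
            hub_tables.append(tab)
        hubs = (
            pd.concat(hub_tables, ignore_index=True)
            if hub_tables
            else pd.DataFrame(columns=["rank", "gene_id", "degree", "weighted_degree", "module", "kIM"])
        )
        hubs.to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        manifest["outputs"]["hubs"] = {"n_hubs": len(hubs)}

        # ------------------------------------------------------------ enrich
        stage = "enrich"
        universe = set(expr.feature_ids) | set(metab.feature_ids)
        enrich_tables = {}
        for module in sorted(m for m in labels.unique() if m != "grey"):
            members = list(labels.index[labels == module])
            tab = enrich(members, annotation, universe)
            tab.to_csv(outdir / f"enrichment_{module}.tsv", sep="\t", index=False)
            enrich_tables[module] = tab
        manifest["outputs"]["enrich"] = {
            m: int((t["padj"] < 0.05).sum()) for m, t in enrich_tables.items()
        }

        # ------------------------------------------------------- convergence
        convergence = _convergence_table(
            annotation, panel.marker_ids, labels, mt_r, mt_p, enrich_tables
        )
        convergence.to_csv(outdir / "convergence.tsv", sep="\t", index=False)
        manifest["outputs"]["convergence"] = str(outdir / "convergence.tsv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _convergence_table(
    annotation, panel_ids, labels, mt_r, mt_p, enrich_tables
) -> pd.DataFrame:
    """Score each annotation term by the number of supporting evidence streams.

    Streams: (1) the term covers a final biomarker; (2) the term is
    significantly enriched (BH FDR < 0.05) in at least one module; (3) that
    module's eigengene significantly correlates (p < 0.05) with at least one
    panel trait.
    """
    panel_set = set(panel_ids)
    correlated_modules = set()
    if mt_r is not None and mt_p is not None:
        for module in mt_p.index:
            if (mt_p.loc[module] < 0.05).any():
                correlated_modules.add(module)
    rows = []
    for term, members in annotation.items():
        members = set(members)
        has_biomarker = bool(members & panel_set)
        enriched_in = [
            m for m, t in enrich_tables.items()
            if term in set(t.loc[t["padj"] < 0.05, "term"])
        ]
        module_correlated = bool(set(enriched_in) & correlated_modules)
        n_streams = int(has_biomarker) + int(bool(enriched_in)) + int(module_correlated)
        rows.append(
            {
                "term": term,
                "covers_biomarker": has_biomarker,
                "enriched_modules": ";".join(enriched_in),
                "module_trait_support": module_correlated,
                "evidence_streams": n_streams,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            ["evidence_streams", "term"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return table
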