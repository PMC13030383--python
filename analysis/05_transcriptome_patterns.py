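#!/usr/bin/env python
"""Transcriptome differential expression and expression patterns.

Per genotype: DEG calling (25 vs 35 degC) on size-factor-normalized counts
with BH FDR; Venn overlap of the two DEG sets; K-means (k=12) expression
patterns of the DEG union.  Writes tables under results/transcriptome/.
"""

import json
from pathlib import Path

import numpy as np

from thermomark.containers import OmicsMatrix, read_matrix_tsv
from thermomark.differential import kmeans_patterns, pca_summary, select_degs, venn_overlap

DATA = Path("results/data")
OUT = Path("results/transcriptome")
SEED = 20250921


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = read_matrix_tsv(
        DATA / "transcriptome.tsv", DATA / "transcriptome_metadata.tsv",
        role="transcriptome",
    )
    log_counts = OmicsMatrix(
        values=np.log2(expr.values + 1), metadata=expr.metadata
    )
    pca = pca_summary(log_counts, n_components=2, scale=False)
    print(
        "transcriptome PCA (log2 counts): PC1 %.1f%%, PC2 %.1f%%"
        % tuple(100 * v for v in pca.variance_fraction[:2])
    )

    deg_sets = {}
    for genotype in ("tolerant", "sensitive"):
        base = expr.samples_where(genotype=genotype, temperature_C=25)
        stressed = expr.samples_where(genotype=genotype, temperature_C=35)
        degs = select_degs(expr, base, stressed)
        degs.table.to_csv(OUT / f"degs_{genotype}_25v35.tsv", sep="\t")
        deg_sets[genotype] = set(degs.selected_ids)
        print(
            f"{genotype} 25v35: {len(degs.selected_ids)} DEGs "
            f"({degs.n_up} up, {degs.n_down} down)"
        )

    venn = venn_overlap(deg_sets)
    with open(OUT / "deg_venn.json", "w") as fh:
        json.dump({"&".join(k): v for k, v in venn.items()}, fh, indent=1)
    print(f"DEG Venn regions: { {'&'.join(k): v for k, v in venn.items()} }")

    union = sorted(set().union(*deg_sets.values()))
    if len(union) >= 12:
        clusters = kmeans_patterns(expr.subset_features(union), k=12, seed=SEED)
        clusters.labels.to_csv(OUT / "deg_kmeans_clusters.tsv", sep="\t")
        print(f"k-means: {clusters.k} expression patterns over {len(union)} DEGs")
    else:
        print(f"k-means skipped: only {len(union)} DEGs (planted modules are "
              "temperature-independent, so few genes respond to heat)")


if __name__ == "__main__":
    main()
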