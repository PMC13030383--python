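#!/usr/bin/env python
"""Hub genes and module over-representation.

Builds an interaction edge list from the strongest co-expression adjacency
weights (a stand-in for an external interaction database, which this
analysis never fetches), ranks intra-module hub genes by degree (top 50),
computes intramodular connectivity, and runs hypergeometric enrichment of
each module against the annotation.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from thermomark.cascade import read_annotation
from thermomark.containers import read_matrix_tsv
from thermomark.coexpression import adjacency
from thermomark.enrichment import enrich
from thermomark.hubs import build_graph, degree_rank, intramodular_connectivity

DATA = Path("results/data")
MODULES = Path("results/modules")
OUT = Path("results/hubs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = read_matrix_tsv(
        DATA / "transcriptome.tsv", DATA / "transcriptome_metadata.tsv",
        role="transcriptome",
    )
    labels = pd.read_csv(MODULES / "module_labels.tsv", sep="\t", index_col=0)["module"]
    annotation = read_annotation(DATA / "annotation.gmt")
    log_expr = np.log2(expr.values + 1.0)
    adj = adjacency(log_expr, 9.0)

    # synthetic interaction list: top 0.1% strongest adjacency edges
    a = adj.to_numpy()
    iu = np.triu_indices_from(a, k=1)
    w = a[iu]
    keep = w >= np.quantile(w, 0.999)
    edges = pd.DataFrame(
        {"gene_a": adj.index[iu[0][keep]], "gene_b": adj.index[iu[1][keep]],
         "weight": w[keep]}
    )
    edges.to_csv(OUT / "edges.tsv", sep="\t", index=False)
    graph = build_graph(edges)
    print(f"interaction list: {len(edges)} edges over {graph.number_of_nodes()} genes")

    kim = intramodular_connectivity(adj, labels)
    hub_tables = []
    for module in sorted(m for m in labels.unique() if m != "grey"):
        members = labels.index[labels == module]
        tab = degree_rank(graph, top_n=50, module_genes=members)
        tab["module"] = module
        tab["kIM"] = kim.loc[tab["gene_id"], "kIM"].to_numpy()
        hub_tables.append(tab)
        if len(tab):
            top = tab.iloc[0]
            print(
                f"{module}: {len(tab)} hubs; top {top['gene_id']} "
                f"(degree {top['degree']}, kIM {top['kIM']:.1f})"
            )
    pd.concat(hub_tables, ignore_index=True).to_csv(
        OUT / "hubs.tsv", sep="\t", index=False
    )

    universe = list(expr.feature_ids)
    for module in sorted(m for m in labels.unique() if m != "grey"):
        members = list(labels.index[labels == module])
        tab = enrich(members, annotation, universe)
        tab.to_csv(OUT / f"enrichment_{module}.tsv", sep="\t", index=False)
        sig = tab[tab["padj"] < 0.05]
        if len(sig):
            print(f"{module} enriched in: {', '.join(sig['term'])}")


if __name__ == "__main__":
    main()
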