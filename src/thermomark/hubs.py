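"""Hub-gene identification.

Degree ranking on a supplied protein-interaction edge list (top-50 by
number of interacting edges is the hub convention) and intramodular
connectivity kIM from the co-expression adjacency.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_edge_list",
    "build_graph",
    "degree_rank",
    "intramodular_connectivity",
]


def build_graph(edges: pd.DataFrame) -> nx.Graph:
    """Undirected weighted graph from (gene_a, gene_b, weight) rows.

    Self-loops are dropped; duplicate undirected edges keep the maximum
    weight.
    """
    g = nx.Graph()
    for _, row in edges.iterrows():
        a, b = str(row.iloc[0]), str(row.iloc[1])
        w = float(row.iloc[2]) if len(row) > 2 else 1.0
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    return g


def read_edge_list(path) -> nx.Graph:
    edges = pd.read_csv(path, sep="\t")
    return build_graph(edges)


def degree_rank(
    graph: nx.Graph,
    top_n: int = 50,
    module_genes=None,
) -> pd.DataFrame:
    """Top-n nodes by interaction degree within an optional module.

    Ties break by weighted degree (descending), then gene id.  Returns a
    table with rank, degree and weighted degree.
    """
    nodes = list(graph.nodes)
    if module_genes is not None:
        members = set(module_genes)
        nodes = [n for n in nodes if n in members]
        sub = graph.subgraph(nodes)
    else:
        sub = graph
    rows = [
        {
            "gene_id": n,
            "degree": sub.degree(n),
            "weighted_degree": sub.degree(n, weight="weight"),
        }
        for n in nodes
    ]
    if not rows:
        return pd.DataFrame(columns=["rank", "gene_id", "degree", "weighted_degree"])
    table = pd.DataFrame(rows).sort_values(
        by=["degree", "weighted_degree", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    table = table.head(top_n).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def intramodular_connectivity(
    adjacency: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """kIM(i) = sum of adjacency weights to genes sharing i's module label.

    Grey (unassigned) genes get their sum over grey peers but are flagged
    ``in_module = False``.
    """
    genes = adjacency.index
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    lab = labels.reindex(genes)
    kim = np.zeros(len(genes))
    for module in lab.unique():
        idx = np.where((lab == module).to_numpy())[0]
        kim[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    return pd.DataFrame(
        {"kIM": kim, "module": lab.to_numpy(), "in_module": (lab != "grey").to_numpy()},
        index=genes,
    )
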