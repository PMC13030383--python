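"""Over-representation analysis against user-supplied annotation sets.

Hypergeometric upper-tail test per term with Benjamini-Hochberg adjustment:
for a query list of n genes drawn from a universe of N, a term of size K
overlapping the list in k genes has p = P[X >= k], X ~ Hypergeom(N, K, n).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["enrich"]


def enrich(
    gene_list,
    annotation: dict[str, list[str]],
    universe,
    max_terms: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each annotation term.

    Query genes outside the universe are excluded with a warning; term
    memberships are intersected with the universe.  Results are sorted by
    p-value; ``max_terms`` optionally truncates the output (display limit
    only, applied after adjustment).
    """
    universe = set(universe)
    query = set(gene_list)
    outside = sorted(query - universe)
    if outside:
        warnings.warn(f"{len(outside)} query ids outside the universe: {outside[:5]}...")
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for term, members in annotation.items():
        term_set = set(members) & universe
        K = len(term_set)
        if K == 0:
            continue
        overlap = sorted(query & term_set)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "list_size": n,
                "term_size": K,
                "universe_size": N,
                "p_value": min(p, 1.0),
                "overlap_genes": ";".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term", "overlap", "list_size", "term_size", "universe_size",
                "p_value", "padj", "overlap_genes",
            ]
        )
    table = pd.DataFrame(rows)
    table["padj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    table = table[
        ["term", "overlap", "list_size", "term_size", "universe_size",
         "p_value", "padj", "overlap_genes"]
    ]
    if max_terms is not None:
        table = table.head(max_terms)
    return table
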