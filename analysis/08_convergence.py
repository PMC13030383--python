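#!/usr/bin/env python
"""Join the three evidence streams into the convergence table.

A term converges when (1) it covers a final biomarker, (2) it is enriched in
a co-expression module, and (3) that module's eigengene correlates with a
biomarker trait.  With the synthetic annotation the planted
"flavonoid_like_convergence" term (markers + trait-linked module genes)
should top the table — the synthetic analogue of a pathway recovered
independently by metabolome screening, module enrichment and module-trait
correlation.
"""

from pathlib import Path

import pandas as pd

from thermomark.cascade import read_annotation
from thermomark.pipeline import _convergence_table

DATA = Path("results/data")
MODULES = Path("results/modules")
HUBS = Path("results/hubs")
CASCADE = Path("results/cascade")
OUT = Path("results")


def main() -> None:
    annotation = read_annotation(DATA / "annotation.gmt")
    panel = pd.read_csv(CASCADE / "biomarker_panel.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(MODULES / "module_labels.tsv", sep="\t", index_col=0)["module"]
    mt_r = pd.read_csv(MODULES / "module_trait_r.tsv", sep="\t", index_col=0)
    mt_p = pd.read_csv(MODULES / "module_trait_p.tsv", sep="\t", index_col=0)
    enrich_tables = {
        m: pd.read_csv(HUBS / f"enrichment_{m}.tsv", sep="\t")
        for m in sorted(set(labels) - {"grey"})
    }
    table = _convergence_table(
        annotation, list(panel.index), labels, mt_r, mt_p, enrich_tables
    )
    table.to_csv(OUT / "convergence.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    top = table.iloc[0]
    print(
        f"\ntop term: {top['term']} with {top['evidence_streams']}/3 evidence streams"
    )


if __name__ == "__main__":
    main()
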