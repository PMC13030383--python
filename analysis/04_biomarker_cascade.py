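#!/usr/bin/env python
"""Biomarker selection cascade.

Top-100 features by the tolerant-cultivar importance score, filtered to
those either more abundant under stress in the tolerant cultivar or
significantly up-regulated in it at 35 degC, then categorized from the
annotation.  Reports planted tolerant-relevant marker retention.
"""

from pathlib import Path

import pandas as pd

from thermomark.cascade import annotate_panel, expression_filter, read_annotation
from thermomark.containers import read_matrix_tsv
from thermomark.simulate import SyntheticTruth

DATA = Path("results/data")
FOREST = Path("results/forest")
OUT = Path("results/cascade")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    metab = read_matrix_tsv(DATA / "metabolome.tsv", DATA / "metabolome_metadata.tsv")
    truth = SyntheticTruth.from_json(DATA / "truth.json")
    imp = pd.read_csv(FOREST / "importance_tolerant.tsv", sep="\t", index_col=0)["mda"]

    candidates = list(
        imp.sort_index().sort_values(ascending=False, kind="mergesort").index[:100]
    )
    panel = expression_filter(candidates, metab)
    panel = annotate_panel(panel, read_annotation(DATA / "annotation.gmt"))
    panel.table.to_csv(OUT / "biomarker_panel.tsv", sep="\t")

    kept = set(panel.marker_ids)
    tol = set(truth.tolerant_marker_ids)
    sen = set(truth.sensitive_marker_ids)
    print(f"panel: {len(kept)} biomarkers from {len(candidates)} candidates")
    print(
        f"tolerant-specific planted markers retained: {len(kept & tol)}/{len(tol)}; "
        f"sensitive-specific rejected: {len(sen) - len(kept & sen)}/{len(sen)}"
    )
    print(panel.table["category"].value_counts().to_string())


if __name__ == "__main__":
    main()
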