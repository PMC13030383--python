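"""Biomarker selection cascade.

The screening funnel from importance tables to named biomarkers:
take the top-k features by the designated (by default heat-tolerant) model's
importance, keep the ones that are either more abundant in the tolerant
cultivar under stress or significantly up-regulated in it at 35 degC, then
assign categories from a user-supplied annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix
from .forest import ConsistencyReport

__all__ = [
    "BiomarkerPanel",
    "top_candidates",
    "expression_filter",
    "annotate_panel",
    "read_annotation",
]


@dataclass
class BiomarkerPanel:
    """Ordered biomarker table with filter evidence and annotation labels."""

    table: pd.DataFrame
    candidate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.table) and self.candidate_ids:
            outside = set(self.table.index) - set(self.candidate_ids)
            if outside:
                raise ValueError(f"panel members outside candidate set: {sorted(outside)}")
        if len(self.table) and {"higher_abundance", "upregulated"} <= set(self.table.columns):
            no_clause = ~(self.table["higher_abundance"] | self.table["upregulated"])
            if no_clause.any():
                raise ValueError("panel member passed no expression-filter clause")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)


def top_candidates(
    report: ConsistencyReport, k: int = 100, model: str = "tolerant"
) -> list[str]:
    """Top-k candidate features by one model's importance score.

    ``model`` selects which genotype's importances to rank by ("tolerant"
    maps to whichever of the report's two models carries that genotype
    label; "a"/"b" address them positionally).  Ties break by feature id
    for a stable ordering.
    """
    if model in ("a", report.genotype_a):
        imp = report.importance_a
    elif model in ("b", report.genotype_b):
        imp = report.importance_b
    elif model == "tolerant":
        imp = (
            report.importance_a
            if report.genotype_a == "tolerant"
            else report.importance_b
        )
    else:
        raise ValueError(f"unknown model selector {model!r}")
    if imp is None:
        raise ValueError("report carries no raw importances")
    if k <= 0:
        return []
    order = imp.sort_index().sort_values(ascending=False, kind="mergesort")
    return list(order.index[:k])


def expression_filter(
    candidates,
    matrix: OmicsMatrix,
    p_threshold: float = 0.05,
    stress_temperatures=(30, 35),
    test_temperature: int = 35,
) -> BiomarkerPanel:
    """Keep candidates favoring the heat-tolerant cultivar.

    A candidate survives if EITHER its mean abundance across stressed
    samples is strictly higher in the tolerant genotype than the sensitive
    one, OR a one-sided Welch test (tolerant > sensitive) at the top stress
    temperature rejects at ``p_threshold``.  Both clauses are recorded per
    marker.
    """
    candidates = [c for c in candidates if c in matrix.values.index]
    tol_stress = matrix.samples_where(genotype="tolerant", temperature_C=stress_temperatures)
    sen_stress = matrix.samples_where(genotype="sensitive", temperature_C=stress_temperatures)
    tol_top = matrix.samples_where(genotype="tolerant", temperature_C=test_temperature)
    sen_top = matrix.samples_where(genotype="sensitive", temperature_C=test_temperature)

    rows = []
    for fid in candidates:
        tol_mean = matrix.values.loc[fid, tol_stress].mean()
        sen_mean = matrix.values.loc[fid, sen_stress].mean()
        higher = bool(tol_mean > sen_mean)
        a = matrix.values.loc[fid, tol_top].to_numpy(dtype=float)
        b = matrix.values.loc[fid, sen_top].to_numpy(dtype=float)
        if len(a) >= 2 and len(b) >= 2 and (a.std() > 0 or b.std() > 0):
            p = stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
        else:
            p = 1.0
        up = bool(p < p_threshold)
        if higher or up:
            rows.append(
                {
                    "feature_id": fid,
                    "tolerant_stress_mean": tol_mean,
                    "sensitive_stress_mean": sen_mean,
                    "higher_abundance": higher,
                    "upregulated": up,
                    "p_one_sided": float(p),
                }
            )
    table = pd.DataFrame(rows).set_index("feature_id") if rows else pd.DataFrame(
        columns=[
            "tolerant_stress_mean",
            "sensitive_stress_mean",
            "higher_abundance",
            "upregulated",
            "p_one_sided",
        ]
    )
    return BiomarkerPanel(table=table, candidate_ids=list(candidates))


def annotate_panel(panel: BiomarkerPanel, annotation: dict[str, list[str]]) -> BiomarkerPanel:
    """Attach annotation categories; unannotated members become "unclassified".

    A member mapped by several terms reports all of them; the primary
    category is the lexicographically first.
    """
    feature_terms: dict[str, list[str]] = {}
    for term, members in annotation.items():
        for fid in members:
            feature_terms.setdefault(fid, []).append(term)
    table = panel.table.copy()
    cats, primaries = [], []
    for fid in table.index:
        terms = sorted(feature_terms.get(fid, []))
        cats.append(";".join(terms) if terms else "unclassified")
        primaries.append(terms[0] if terms else "unclassified")
    table["categories"] = cats
    table["category"] = primaries
    return BiomarkerPanel(table=table, candidate_ids=panel.candidate_ids)


def read_annotation(path) -> dict[str, list[str]]:
    """Read a term -> members mapping from GMT or two-column TSV.

    GMT lines are ``term<TAB>description<TAB>member...``; a two-column file
    is interpreted as (member, term) pairs.
    """
    ann: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    two_col = all(len(ln.split("\t")) == 2 for ln in lines) if lines else False
    for ln in lines:
        parts = ln.split("\t")
        if two_col:
            member, term = parts
            ann.setdefault(term, []).append(member)
        else:
            term, _desc, *members = parts
            ann.setdefault(term, []).extend(members)
    return ann


def write_gmt(annotation: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            fh.write("\t".join([term, term] + sorted(annotation[term])) + "\n")
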