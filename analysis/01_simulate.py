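#!/usr/bin/env python
"""Generate the synthetic two-cultivar heat-stress dataset.

Emulates the study design: heat-tolerant and heat-sensitive wheat cultivars
at 25/30/35 degC, six metabolome and three transcriptome replicates per
cell, with 10 shared + 5/5 genotype-specific temperature-responsive
metabolite markers (log2FC 2.0 per temperature step), four co-expressed gene
modules (60-120 genes) and one trait metabolite per module planted at
r = 0.7.  Writes the matrices, metadata, ground truth and a synthetic
annotation under results/data/.
"""

from pathlib import Path

from thermomark.cascade import write_gmt
from thermomark.containers import write_matrix_tsv
from thermomark.simulate import (
    SimulationConfig,
    embed_trait_metabolites,
    generate_metabolome,
    generate_transcriptome,
    synthetic_annotation,
)

OUT = Path("results/data")
SEED = 20250921


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    metab, truth = generate_metabolome(config)
    expr = generate_transcriptome(config, truth)
    metab = embed_trait_metabolites(metab, truth, seed=SEED + 1)

    write_matrix_tsv(metab, OUT / "metabolome.tsv", OUT / "metabolome_metadata.tsv")
    write_matrix_tsv(expr, OUT / "transcriptome.tsv", OUT / "transcriptome_metadata.tsv")
    truth.to_json(OUT / "truth.json")
    write_gmt(synthetic_annotation(truth, config), OUT / "annotation.gmt")

    print(f"metabolome: {metab.values.shape[0]} features x {metab.values.shape[1]} samples")
    print(f"transcriptome: {expr.values.shape[0]} genes x {expr.values.shape[1]} samples")
    print(
        f"planted markers: {len(truth.shared_marker_ids)} shared, "
        f"{len(truth.tolerant_marker_ids)} tolerant-specific, "
        f"{len(truth.sensitive_marker_ids)} sensitive-specific"
    )
    print(f"planted traits: {list(truth.trait_assignments)}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
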