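#!/usr/bin/env python
"""Multivariate and univariate metabolome screening (25 vs 35 degC).

Per genotype: PCA variance summary, PLS-DA with 7-fold cross-validated Q2
and 200 label-permutation tests, per-feature t-tests, and the differential
metabolite rule VIP > 1 and p < 0.05.  Writes DAM tables under
results/differential/ and prints the model-quality numbers.
"""

from pathlib import Path

from thermomark.containers import read_matrix_tsv
from thermomark.differential import (
    fit_plsda,
    pca_summary,
    select_dams,
    univariate_tests,
    validate_model,
)

DATA = Path("results/data")
OUT = Path("results/differential")
SEED = 20250921


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    metab = read_matrix_tsv(DATA / "metabolome.tsv", DATA / "metabolome_metadata.tsv")

    pca = pca_summary(metab, n_components=2)
    print(
        "metabolome PCA: PC1 %.1f%%, PC2 %.1f%% of variance"
        % tuple(100 * v for v in pca.variance_fraction[:2])
    )

    for genotype in ("tolerant", "sensitive"):
        base = metab.samples_where(genotype=genotype, temperature_C=25)
        stressed = metab.samples_where(genotype=genotype, temperature_C=35)
        sub = metab.subset_samples(base + stressed)
        labels = ["25"] * len(base) + ["35"] * len(stressed)
        model, vip = fit_plsda(sub, labels, n_components=2)
        q2, p_r2y, p_q2 = validate_model(
            model, sub, labels, n_folds=7, n_permutations=200, seed=SEED
        )
        dams = select_dams(vip, univariate_tests(metab, base, stressed))
        dams.table.to_csv(OUT / f"dams_{genotype}_25v35.tsv", sep="\t")
        print(
            f"{genotype} 25v35: R2Y={vip.r2y:.3f} Q2={q2:.3f} "
            f"perm p(R2Y)={p_r2y:.3f} p(Q2)={p_q2:.3f}; "
            f"{len(dams.selected_ids)} DAMs ({dams.n_up} up, {dams.n_down} down)"
        )


if __name__ == "__main__":
    main()
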