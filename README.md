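# thermomark

Multi-omics screening of heat-tolerance biomarkers in a two-cultivar,
graded heat-stress design — a tested reimplementation of the analysis stack
used to dissect wheat root thermotolerance: dual-genotype random-forest
feature importance with cross-genotype consistency categorization,
PLS-DA/VIP differential-metabolite screening, a biomarker selection
cascade, weighted gene co-expression modules with metabolite traits, hub
genes and over-representation analysis.

## Who this is for

Researchers integrating a metabolome (features × samples, e.g. LC-MS
intensities) and a transcriptome (gene counts) measured on two genotypes
(a stress-tolerant and a stress-sensitive cultivar) across graded stress
levels, who want to separate *shared* stress responses from
*genotype-specific* ones and to connect candidate metabolite biomarkers to
gene modules. Because studies of this kind rarely deposit desk-scale
matrices, the package ships a first-class synthetic-data generator that
plants recoverable ground truth (markers, modules, module–trait
correlations), so every stage is testable end to end.

## The methods at the core

- **Temperature forests + MDA.** Per cultivar, a bagged ensemble of 1000
  decision trees classifies temperature (25/30/35 °C) from all metabolic
  features (√p candidate variables per split). Importance is Mean Decrease
  Accuracy: the out-of-bag accuracy lost when a feature's values are
  permuted. Cross-cultivar agreement is summarized by Spearman's ρ on the
  importance ranks, a per-feature consistency score
  `1 − |ñ_A − ñ_B|` over min-max-normalized importances, and a four-way
  partition (shared / A-favored / B-favored / uninformative).
- **PLS-DA with VIP.** NIPALS partial least squares against one-hot classes
  on unit-variance-scaled features;
  `VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a)` with the identity
  `mean(VIP²) = 1` enforced as a postcondition. Model quality: 7-fold
  cross-validated Q² and 200 response-permutation tests. Differential
  metabolites (DAMs): VIP > 1.0 and t-test p < 0.05 (strict).
- **Co-expression modules from formula.** Unsigned adjacency
  `a_ij = |cor(x_i, x_j)|^β` (β = 9), topological overlap
  `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`,
  average-linkage clustering of `1 − TOM` with a static branch cut,
  minimum module size 50 (smaller clusters → "grey"), eigengene (module
  PC1) merging at dissimilarity 0.25, and Pearson module–trait correlation
  with Student-t p-values, using biomarker metabolite abundances as traits.
- **Biomarker cascade.** Top-100 features by the tolerant model's
  importance → keep those either more abundant in the tolerant cultivar
  under stress or significantly up-regulated in it at 35 °C (one-sided
  Welch) → annotate into functional categories.
- **Hubs and enrichment.** Top-50 degree ranking on an interaction edge
  list per module, intramodular connectivity `kIM(i) = Σ_{j∈module} a_ij`,
  and hypergeometric over-representation with Benjamini–Hochberg FDR.
- **qPCR arithmetic.** Relative expression via 2^−ΔΔCt.

## Worked example

Run the numbered analysis drivers in order (each is a thin narrative over
the library and writes tables under `results/`):

```sh
python analysis/01_simulate.py
python analysis/02_differential_metabolome.py
python analysis/03_forest_consistency.py
python analysis/04_biomarker_cascade.py
python analysis/05_transcriptome_patterns.py
python analysis/06_coexpression_modules.py
python analysis/07_hubs_enrichment.py
python analysis/08_convergence.py
```

Representative output (seeds fixed in the scripts):

```
tolerant 25v35: R2Y=1.000 Q2=0.348 perm p(R2Y)=0.040 p(Q2)=0.005; 36 DAMs (24 up, 12 down)
tolerant: OOB accuracy 1.000; 10/10 planted shared markers in top-20 MDA
importance-rank concordance: rho=0.065 (p=1.47e-01) — low rho mirrors divergent cultivar strategies
categories: {'uninformative': 334, 'b_favored': 71, 'a_favored': 71, 'shared': 24}
panel: 54 biomarkers from 100 candidates
tolerant-specific planted markers retained: 5/5; sensitive-specific rejected: 5/5
detected modules: {'M1': 135, 'M2': 115, 'M3': 97, 'M4': 67} (+586 grey)
adjusted Rand index vs planted modules: 0.845
planted trait met_0448 (module 4, target |r|=0.70): best module M1, |r|=0.63, p=4.81e-03
top term: flavonoid_like_convergence with 3/3 evidence streams
```

Reading this: the PLS-DA separates 25 °C from 35 °C far better than
label-permuted refits (permutation p ≪ 0.05); both cultivars' forests
recover all ten planted shared markers; the near-zero rank concordance
(ρ ≈ 0.07) reproduces the analysis' key observation that the two cultivars
rank features very differently while both classify temperature perfectly;
the cascade keeps exactly the planted tolerant-relevant markers; module
detection recovers the four planted modules (ARI 0.85) and the planted
module–trait correlations (target r = 0.7) reappear at |r| ≈ 0.6 with
n = 18; and the planted pathway term is the only one supported by all three
evidence streams.

The same flow is available as a CLI (`thermomark simulate|dam|deg|forest|
cascade|modules|hubs|enrich|run`) and as a single call,
`thermomark.run_pipeline(PipelineConfig(...))`, which writes a manifest and
the convergence table.

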