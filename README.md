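# savbind

Are missense variants depleted at the residues where proteins bind other
proteins, DNA or RNA — and do common and rare variants differ there in
predicted functional effect?

`savbind` is a pipeline for analysts of human variation data who have, for a
set of proteins: a table of single amino-acid variants (SAVs) with allele
frequencies, per-variant functional-effect scores in [−100, +100]
(SNAP2-style), per-residue binding scores for the protein/DNA/RNA substrate
classes (ProNA2020-style) and/or 3D structures of complexes, and optionally
a tissue × protein expression matrix. The predictors themselves are
external; `savbind` consumes their scores.

## What it computes

Variants are classified by linkage-disequilibrium allele frequency as
**common** (LDAF ≥ 0.05) or **rare** (LDAF < 0.01); the uncommon middle band
is discarded. For each binding class the pipeline builds the 2×2 table of
(common/rare) × (binding/other) counts and reports

* the sample odds ratio `OR = (N_cb/N_cn)/(N_rb/N_rn)` with a Woolf 95%
  confidence interval and a two-sided Fisher exact p-value (computed in
  log-space, so tables with millions of counts are exact and finite);
* two-sample Kolmogorov–Smirnov contrasts between the effect-score
  distributions of any two groups, with cumulative
  fraction-above-threshold curves on the −100…100 score grid;
* a **19-non-native background**: the pooled effect scores of all 19
  possible substitutions at every SAV-carrying position, serving as the
  "random" reference distribution;
* interface residues called from structure by the ≤ 6 Å closest-atom rule
  (any atom of a residue vs any atom of a protein/DNA/RNA chain), mapped
  to sequence positions through a SIFTS-like residue-mapping table;
* per-tissue over/under-representation of binding-class SAVs among
  tissue-enriched proteins (expression ≥ 1 and ≥ 4× the mean of the other
  tissues): `(PERC_tissue − PERC_overall)/PERC_overall`;
* bootstrap standard errors throughout (1000 draws of 50% of the data
  without replacement).

A synthetic-data generator produces all input kinds with known planted
structure (binding depletion odds ratio, score shifts, tissue enrichment,
exact interface truth sets), so the whole pipeline is testable offline.
See `docs/methods.md` for the statistical conventions and design choices.

## Worked example

Simulate a 50,000-SAV dataset at the default study conditions and analyze it:

```sh
savbind simulate --out demo --seed 1 --n-savs 50000
savbind analyze \
    --variants demo/variants.tsv \
    --effect-scores demo/effect_scores.tsv \
    --annotations demo/residue_annotations.tsv \
    --background-scores demo/background_scores.tsv \
    --expression demo/expression.tsv \
    --out demo/results --seed 1
```

prints

```
savbind run summary
===================
SAVs read 50000, joined 50000, excluded 0; after dropping the uncommon band: 49776 (229 common, 49547 rare)
binding fraction [any]: 21.6% +/- 0.18 (bootstrap SE)
binding fraction [protein]: 8.9% +/- 0.13 (bootstrap SE)
binding fraction [dna]: 11.9% +/- 0.14 (bootstrap SE)
binding fraction [rna]: 7.7% +/- 0.12 (bootstrap SE)
odds ratio [any]: 1.01 (95% CI 0.74-1.39), Fisher p 0.936
odds ratio [protein]: 0.87 (95% CI 0.54-1.41), Fisher p 0.643
odds ratio [dna]: 1.16 (95% CI 0.79-1.70), Fisher p 0.414
odds ratio [rna]: 1.15 (95% CI 0.72-1.82), Fisher p 0.534
KS common_any vs rare_any: D = 0.108, p 0.605
KS common_any vs background_any: D = 0.208, p 0.0269
KS rare_any vs background_any: D = 0.134, p < 2.2e-16
KS common_non_binding vs rare_non_binding: D = 0.175, p 3.6e-05
KS common_any vs common_non_binding: D = 0.189, p 0.123
KS rare_any vs rare_non_binding: D = 0.251, p < 2.2e-16
```

Reading the output: about 21.6% of SAVs fall on predicted binding residues
(the generator's planted any-class rate is 22.5%; the bootstrap SE of 0.18
covers the draw). The common-vs-rare odds ratios hover near 1 with wide
intervals because only 229 SAVs are common at this problem size — the
planted depletion (OR 0.88) needs larger simulations to resolve, which is
exactly what the wide Woolf intervals say. The KS rows show the planted
score structure: binding SAVs score higher than non-binding ones
(`rare_any vs rare_non_binding`, p < 2.2e-16 — the rendering floor for
p-values below double precision) and the 19-non-native background sits
above the observed rare SAVs.

`demo/results/` contains the tidy tables (`enrichment.tsv`, `ks_tests.tsv`,
`curves.tsv`, `tissue.tsv`), a machine-readable `summary.json` holding every
number in the printed report, and a `manifest.json` with the configuration
echo and input checksums. `savbind annotate-structure` calls interfaces from
a PDB/mmCIF file, and `savbind tissue` lists tissue-enriched
(protein, tissue) pairs.

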