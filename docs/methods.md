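# Methods

## The question and the quantities

`savbind` analyses single amino-acid variants (SAVs: missense changes with a
population allele frequency) at macromolecular binding interfaces. Each SAV
carries a linkage-disequilibrium allele frequency (LDAF) and is classified
**common** (LDAF ≥ 0.05), **uncommon** (0.01 ≤ LDAF < 0.05) or **rare**
(LDAF < 0.01); the uncommon band is always removed before statistics, so the
common/rare contrast never hinges on a single threshold. Both thresholds are
configuration parameters.

Each SAV row carries a functional-effect score in [−100, +100] (higher =
more reliably predicted effect), and each residue carries three binding
scores in [−100, +100], one per substrate class (protein, DNA, RNA); a
predicted score > 0 means binding. Alternatively, binding annotations can be
called from a 3D structure: a residue is an interface residue for class *c*
when the closest pair of atoms between it and any chain of class *c* lies
within 6 Å. The effect and binding predictors themselves are external;
their score tables are inputs, never recomputed here.

Four statistics drive the analysis:

* **Enrichment.** For a binding class, the 2×2 table
  (common/rare × binding/other) gives the sample odds ratio
  OR = (N_cb/N_cn)/(N_rb/N_rn), a Woolf 95% confidence interval
  exp(ln OR ± 1.959964·√(ΣN⁻¹)), and a two-sided Fisher exact p-value.
* **Distribution contrasts.** Two-sample Kolmogorov–Smirnov tests between
  effect-score multisets of groups (common/rare × binding/non-binding ×
  background), with cumulative fraction-at-or-above-threshold curves over
  the integer grid −100…100.
* **The 19-non-native background.** The null pool holds, for every residue
  position carrying at least one observed SAV, the effect scores of all 19
  non-native substitutions at that position. Each position contributes
  exactly 19 entries regardless of its observed-SAV multiplicity
  (position-uniform weighting; weighting by SAV multiplicity is a defensible
  alternative but double-counts recurrently mutated residues in a null that
  is meant to be a property of sequence positions).
* **Tissue enrichment.** A protein is tissue-enriched when its expression is
  ≥ 1 (TPM/FPKM) in a tissue and ≥ 4× the arithmetic mean over all other
  tissues. For one tissue/binding-class/frequency-class cell,
  normalized = (PERC_tissue − PERC_overall)/PERC_overall, where PERC_tissue
  is the percentage of binding-class SAVs among the tissue's enriched SAVs
  and PERC_overall the same over the pooled enriched SAVs of all tissues.

## Statistical conventions

**Fisher's exact test** is two-sided by probability-mass ordering: the
p-value sums the hypergeometric mass of every table with the observed
margins whose point probability is at most that of the observed table, with
a 1 + 10⁻⁷ relative tie tolerance (the convention of the reference R
implementation). The mass function is evaluated in log-space via log-gamma
and renormalized by the total mass, so tables with cells of order 10⁷ remain
finite and small-table results agree with exact integer enumeration to
10⁻¹².

**Odds ratio.** The *sample* odds ratio (the ratio of observed odds), not
the conditional maximum-likelihood estimate that `fisher.test` reports, and
a Woolf log-OR interval rather than the exact conditional interval: the
quantity of interest is defined by the explicit formula above, and Woolf is
closed-form and deterministic. At large counts the two CIs differ only in
the third decimal. A zero cell makes the Woolf interval undefined; the
Haldane–Anscombe +0.5 correction is available as an explicit opt-in, never
silently applied to the odds ratio itself.

**Kolmogorov–Smirnov.** D is the exact supremum of |ECDF_a − ECDF_b|
evaluated at every distinct pooled value — sufficient for right-continuous
step ECDFs, and exact under ties (scores are bounded and discrete). The
p-value uses the asymptotic Kolmogorov distribution at effective size
nm/(n+m): at the sample sizes where the analysis is run (10³–10⁶ per group)
the exact permutation null is unnecessary, and with heavily tied discrete
data the asymptotic p is mildly conservative. p-values below 2.220446×10⁻¹⁶
are reported numerically and flagged; reports render them "< 2.2e-16". A
signed variant of D (the ECDF difference at its extremum) records the
direction of a shift.

**Bootstrap.** Standard errors come from subsampling: 1000 replicates, each
drawing 50% of the items *without replacement*; the SE is the standard
deviation over replicate statistics. For a proportion this matches the
finite-population expression √(p(1−p)/m)·√(1−f). Replicate *i* uses an
independent counter-based substream of the seed, so it is reproducible
regardless of how many replicates are requested. Replicates on which the
metric fails (e.g. an empty subgroup) are dropped and counted; more than 10%
drops aborts. An SE below 10⁻¹³ relative to the point estimate is reported
as exactly 0 (pure summation rounding).

## Interface calling from structures

Structures (PDB or mmCIF) are read with gemmi; author residue numbering is
kept, with insertion codes appended to form the residue key. Waters and
non-polymer heteroatom groups are excluded on both sides of the distance
computation; for alternate locations the highest-occupancy conformer of each
atom name is kept (ties: first in file order); hydrogens are kept when
present. Chains are typed by strict-plurality vote over recognized residue
names (standard amino acids incl. MSE/SEC/PYL; DA/DC/DG/DT/DI; A/C/G/U/I).

"Within 6 Å" is read as ≤ 6.0 inclusive — on real coordinates the boundary
is measure-zero, and inclusivity is pinned by a test. The cutoff is a
parameter; 6.5 Å (the cutoff some binding predictors train against) is
exposed as a named preset. Minimum distances are found with a k-d tree over
the pooled substrate atoms per class; the result is tested to equal the
exhaustive all-atom-pairs scan exactly, and calls are monotone in the
cutoff. Protein substrate chains never include the query chain itself.

Mapping from structure residues to sequence positions goes through an
explicit residue-mapping table (chain, author residue number → protein
accession, 1-based position), the single source of truth — no heuristic
renumbering. Mapped query-chain residues never called for a class get
status "other", which for experimental annotations means *not observed
binding in the examined structure*, not proven non-binding; residues absent
from the structure stay "unknown" and are excluded from counts.

## Filters

* `effect_min`: keep SAVs with effect score ≥ threshold (50 marks highly
  reliable effect predictions). The tissue stage uses a strict > 50 by
  default, matching the convention of that analysis; both the threshold and
  the strictness are parameters.
* `binding_reliability_min`: keep rows whose relevant binding score
  satisfies |score| ≥ threshold — confident binding *and* confident
  non-binding calls both pass; filtering only binding-positive rows would
  bias the "other" group toward ambiguous calls.
* `any` binding is the union over the three classes (a double-binding SAV
  counts once), so per-class counts can sum to more than the union.

A protein enriched in several tissues contributes its SAVs to each such
tissue, and the overall pool counts (SAV, tissue) pairs. This keeps an exact
identity: the enriched-count-weighted mean of PERC_tissue over tissues
equals PERC_overall. With a zero mean over the other tissues, enrichment
reduces to the expression-level gate alone. PERC_overall = 0 yields an
explicitly *undefined* result (never coerced to 0); an empty tissue is
flagged rather than scored.

## Synthetic data: what it emulates, and what it does not

The generator produces all four input kinds with known planted structure.
Defaults are the reference study conditions: the common/uncommon/rare
mixture uses the observed class proportions of the 6.7 M-SAV human exome
reference (34,309 / 25,217 / 6,639,624), per-class binding rates are
9.6% / 12.4% / 8.0% with a 22.5% any-class marginal, and the planted
common-vs-rare binding odds ratio defaults to 0.88 (the worked-example
value).

Mechanics worth knowing:

* SAVs are placed uniformly over (residue, non-native alternate) pairs
  without replacement; every residue has a single native amino acid, so SAV
  keys are unique. Within-class LDAFs are log-uniform over the class
  interval; only class membership matters downstream.
* Binding membership is drawn per residue. The common and rare membership
  probabilities solve the pair (marginal = any-class rate, odds ratio =
  planted OR); a residue carrying any common SAV uses the common
  probability (without this priority, common SAVs sharing residues with
  rare SAVs would dilute the planted odds ratio toward 1). Given
  membership, the three classes fire with probabilities calibrated by a
  fixed-point iteration so the per-class marginals hit their targets
  exactly while every binding residue binds at least one class. Infeasible
  rate combinations (a class rate above the any-class rate, or rates that
  cannot cover the union) raise with the feasible range.
* Effect scores are integers from discretized normals truncated to
  [−100, 100] by resampling (never clamping). Group means default to
  common_binding 20, common_other 0, rare_binding 10, rare_other −15,
  sd 40, with the 19-non-native background shifted +15 above the rare-group
  means and +5 per additional bound class — values chosen once to reproduce
  the qualitative curve ordering of the real analysis (background highest,
  binding above non-binding, common above rare); nothing downstream depends
  on these shapes, and they are configuration, not doctrine.
* Binding scores are sign-consistent with membership, with a configurable
  fraction (default 0.5) of magnitudes ≥ 50.
* The toy complex is a Cα-trace query chain (3.8 Å spacing) with substrate
  chains whose atoms sit at a controlled 5.5 Å from planted residues —
  close enough to call, far enough (√(3.8² + 5.5²) > 6) that neighbours are
  not dragged in — so the ≤ 6 Å truth set is exact by construction.
* Planted tissue enrichment raises a protein's focal-tissue expression to
  1.5 × max(1, 4 × other-tissue mean); planted proteins are distinct across
  tissues because a second planting for the same protein would lift its
  other-tissue mean and break the first planting's four-fold margin.

The generator does **not** mimic a real site-frequency spectrum, real
protein geometry, predictor error structure, or empirical expression
distributions. Passing tests therefore demonstrate that the pipeline's
statistics recover known planted effects under controlled conditions — not
that any biological conclusion transfers to a particular real dataset.

## Problem sizes and numerical choices

Calibration tests run at the sizes where the checks are informative: odds-
ratio CI coverage uses 100 runs of 200,000 SAVs over a 3,000-protein
synthetic proteome (keeping SAV-per-residue multiplicity near 1, since
multiple SAVs on one residue share its binding state and would correlate
counts); KS power uses ~10,000 scores per group; the type-I calibration 200
null runs of 2,000 SAVs. Exhaustive oracles cover every 2×2 table with
grand total ≤ 60 and every sample pair of size ≤ 8 over a 5-point score
alphabet. The acceptance script's synthetic run uses 400,000 SAVs.

Ties in the Fisher tail comparison use the 1 + 10⁻⁷ relative tolerance
noted above. Cumulative curves use the inclusive reading "fraction ≥
threshold" (hence exactly 1.0 at −100); the exclusive variant is available
and differs only at exact grid hits. Degenerate inputs fail loudly: empty
groups, zero margins, single-tissue matrices, unmapped structure residues
(dropped with a count), and conflicting duplicate annotation keys are all
errors, not silent coercions.

## Known limitations

* The Woolf CI and the sample OR differ slightly from the conditional-MLE
  OR and exact conditional CI of R's `fisher.test`; at the counts involved
  the difference is negligible, but CIs are not bit-comparable to R's.
* Raw p-values only; no multiple-testing correction is applied anywhere —
  adjustment is left to the caller.
* The asymptotic KS p-value is conservative for small, heavily tied
  samples; D itself is always exact.
* Experimental "other" annotations are absence of evidence; analyses
  treating them as true negatives inherit that caveat.
* The structure module annotates the asymmetric unit as given: no
  biological-assembly generation, and resolution filtering is a pass-through
  on a metadata column, not computed from the coordinates.
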