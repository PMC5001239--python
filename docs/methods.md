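# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the package.

## Cohort stratification

A variant is *truncating* when its consequence class is nonsense,
frameshift (insertion or deletion), or splice-site; frameshift insertions
are included on the loss-of-function rationale even where a particular
cohort happens to contain only nonsense/splice/frameshift-deletion events,
and the class set is configurable.  Case membership requires at least one
truncating variant in the target gene *and* no variant of any class in any
exclusion gene; controls carry no target- and no exclusion-gene variant.
Samples whose only target-gene variants are non-truncating are excluded
from both groups rather than treated as controls — this keeps the control
group genuinely target-negative.  A sample with both truncating and
non-truncating target variants is a case (any-truncating rule).  Sample ids
are opaque strings compared case-sensitively after whitespace trimming; no
barcode truncation is applied.

## Differential expression

Counts for feature *g* in sample *j* are modelled NB(μ_gj, φ) with
Var = μ + φμ², one common φ for all features.  The workflow is the classic
two-group exact-test chain:

1. **Filter** — keep features with cpm strictly above 1 in at least two
   samples of the combined matrix ("at least two samples" is read over the
   combined case+control set; a per-group mode is available), and always
   drop all-zero features.
2. **TMM** — normalization factors from the weighted trimmed mean of
   M-values against a reference sample (the one with 75th-percentile cpm
   closest to the mean), trimming 30% from each tail of M and 5% from each
   tail of A, with inverse-approximate-variance weights; factors are scaled
   to geometric mean 1.  As with any trimmed-mean normalizer, a very large
   asymmetric differential fraction (≳ 25% of features changed in one
   direction) is only partially corrected.
3. **Dispersion** — counts are equalized to the geometric-mean effective
   library by mean scaling, y′ = rint(y·L*/L_j), rounding ties to even (a
   documented simplification of quantile-based equalization).  φ maximizes
   the conditional NB log-likelihood given the within-group totals
   (per-feature means cancel), by golden-section search on [≈0, 10] to
   tolerance 1e-6; a boundary check returns exactly 0 when the likelihood
   is maximized there.
4. **Exact test** — conditional on a feature's total T across both groups,
   the case-group sum follows a negative hypergeometric law with shapes
   n₁/φ and n₂/φ (the NB success probability cancels); for φ = 0 it is
   Binomial(T, n₁/(n₁+n₂)).  Two-sided p sums the probabilities of all
   outcomes whose conditional probability does not exceed the observed
   one (probability ordering, with a 1e-10 log-space tie tolerance); a
   tail-doubling mode is available.  The pmf is evaluated in log space via
   log-gamma and normalized by log-sum-exp.
5. **Calls** — strict thresholds |log2FC| > 1 and raw p < 0.05.  Raw p is
   used for calls, matching the convention for this design; BH-adjusted
   values are reported in the same table.  log2FC uses mean cpm with a
   0.5-cpm prior offset in both groups (settable to 0).

No GLM/covariate models, tagwise dispersion shrinkage, or precision
weights: the smallest faithful model for a two-group comparison was
preferred, and small numeric differences against other implementations of
the same model family are expected.

## Differential methylation

Probes on chrX/chrY, probes with a SNP within 5 bp of the CpG, and probes
without a reference gene are removed (coordinates are 1-based, matching
standard 450K manifests).  The effect size is the plain beta-difference;
means are pairwise-complete over missing values, and probes with fewer than
two observations in either group are excluded with a warning.

Significance uses a moderated two-class statistic d = (m₁ − m₂)/(s + s0)
where s is the pooled standard error of the mean difference and s0 an
exchangeability constant that prevents small-variance probes from
dominating.  s0 defaults to the median of the per-probe s values; the
original percentile-window coefficient-of-variation tuning is a documented
simplification hook (pass `s0` explicitly to plug in any rule).  The null
is obtained by permuting group labels jointly across probes with s0
recomputed per permutation: p = (1 + #{|d*| ≥ |d|})/(1 + B) for B random
permutations, or the exact enumeration fraction when C(n, n₁) ≤ B (the
observed labelling is one of the enumerated assignments, so the add-one
correction is dropped).  Calls use strict |β-difference| > 0.15 and
p < 0.01; gene summaries take the union of gene symbols of called probes
(multi-gene annotations split on ';'), so gene counts never exceed probe
counts.  Region composition of hyper vs hypo probes is compared per region
label with a two-proportion z-test, BH-adjusted across the seven labels.

## Enrichment

Standard over-representation: P[X ≥ k] for X ~ Hypergeometric(N, K, n)
with the post-filter expressed genes as the default universe (configurable
to the full catalog), BH across terms, retained at adjusted p < 0.05.  This
replaces clustering-based enrichment tools deliberately: a plain upper-tail
test is reproducible and dependency-free, at the cost of not grouping
related terms.  Queries are silently restricted to the universe with the
discarded count reported.

## Co-expression networks

Pearson correlations are computed over all unordered gene pairs on
log2(cpm+1) of the filtered expression matrix, **case samples only** — the
network is specific to the mutated group.  log-cpm was chosen for variance
stabilization; the top 5% of pairs is taken by |r| by default (signed mode
available) with all ties at the cutoff included.  Background edges are the
intersection of those pairs with the PPI edge list (exact symbol match, no
alias resolution).  Projection takes induced subgraphs on the called gene
sets; miRNAs attach to retained targets only.  The core network is the
closed neighborhood of the hyper-down seed genes.  The degree filter is a
single pass on input degrees (a display rule), not a k-core; an iterative
k-core mode exists.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
desk scale, with every planted assignment recorded:

* **Design** — 11 cases, 33 controls, 6 "other" samples (excluded by
  stratification: half carry an exclusion-gene variant, half a
  non-truncating target variant).  Case truncating classes follow a
  5:3:3 nonsense:splice:frameshift-deletion ratio; every sample carries at
  least one somatic variant so the roster is recoverable from the MAF.
* **Counts** — NB with common dispersion 0.1 (Poisson at 0); baseline
  abundances log-normal (σ = 1.2 on the natural log); per-sample library
  sizes uniform on [0.8, 1.2]·10⁶; planted features multiply the case mean
  by 2^(±2) with 75% of planted genes down (mirroring the down-dominant
  regime such cohorts show).  These choices make parameter recovery a fair
  test of the DE engine, which assumes exactly this model.
* **Methylation** — beta values with per-probe baseline mean uniform on
  (0.05, 0.95) and concentration 50; planted probes shift the case mean by
  ±0.3 (baselines drawn away from the boundary; means clipped to
  [0.01, 0.99]); 75% of planted probes are hyper.  Planted probes are
  always autosomal, SNP-free and gene-annotated, so the probe filter
  cannot remove signal; 25% of hyper probes are annotated to planted down
  genes so hyper-down genes exist by construction; hyper probes draw
  region labels from a promoter/body-skewed distribution to exercise the
  region test.
* **Resources** — each miRNA targets ~13 random genes, planted DE miRNAs
  additionally target planted DE genes; the catalog holds 40 random terms
  plus one term with 70% of members from planted down genes; the PPI is a
  uniform random graph of mean degree 6 with the planted module wired in
  as a clique; the TF list holds 15% of planted DE genes plus 20
  background genes.
* **Co-expression module** — module genes share a per-sample log-normal
  latent factor (sd 1.0 on the log scale, mean-corrected), giving pairwise
  log-cpm correlations ≈ 0.9 — reliably inside the top-5% tail at 11 case
  samples.
* **Seeding** — one global seed expands into fixed per-layer substreams
  (sample assignment is drawn before feature-level truth), so regenerating
  or resizing one layer does not perturb the others.

What the generator does **not** emulate: read-level sequencing noise,
intensity-level (M/U) methylation with its type-I/type-II probe chemistry,
GC/length biases, batch effects, correlated null genes, copy-number
contamination, or realistic PPI/target-map topology.  Passing the planted
recovery tests therefore demonstrates correctness of the statistics under
their own model assumptions, not performance on real TCGA-scale data.

## Problem sizes and determinism

Default simulations are desk-scale — 1 500 genes, 150 miRNAs, 1 500
probes, 1 000 permutations — chosen so a complete pipeline run takes well
under a minute while leaving hundreds of null features for calibration
estimates; the test suite uses the same or smaller sizes.  All randomness
flows from explicit seeds (simulation config, permutation seed), stage
order is fixed, report dictionaries are serialized with sorted keys, and
reruns with an identical configuration reproduce `report.json` byte for
byte.  Degenerate inputs are handled explicitly: empty groups, all-zero
matrices, constant probes, empty PPI intersections, and absent seeds
either raise typed errors (input vs configuration) or return empty
results with warnings, as documented per function.

## Known limitations

* The exact test's library equalization is mean scaling with rounding, not
  quantile adjustment; with very unequal libraries the discreteness
  correction is approximate.
* TMM under-corrects when a large asymmetric fraction of features is
  differential (a property of trimmed-mean normalizers); null p-values
  measured inside such a run are mildly inflated even though pure-null
  calibration is nominal.
* The median-s0 rule is a simplification of variance-window tuning.
* Enrichment treats terms independently; no term clustering or redundancy
  reduction.
* Symbol matching everywhere is exact and case-sensitive; no alias tables.
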