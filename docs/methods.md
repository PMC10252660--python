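# Methods

## Scar statistics

All segment coordinates are 1-based, fully closed (SEG convention);
segment length is `end − start + 1`, so ">15 Mb" thresholds are strict
and unambiguous. Event states on a segment with total copy number `t`
and minor-allele copy number `m`:

| event class        | condition          | note |
|--------------------|--------------------|------|
| LOH                | `m = 0` and `t ≥ 1`| homozygous deletions (`t = 0`) are *loss*, not LOH, to avoid double counting |
| loss               | `t < 2`            | |
| gain               | `t > 2`            | |
| allelic imbalance  | `m ≠ t − m`        | includes LOH as a special case |

A *run* is a maximal stretch of contiguous segments (no base-pair gap)
sharing the event state; run length is measured after merging, so
splitting a segment into equal-state pieces never changes any
statistic (a tested invariance). Uncovered intervals break runs.

* **HRD-LOH**: LOH runs > 15 Mb that do not span an entire chromosome.
* **LST**: per chromosome arm (split at the centromere midpoint;
  straddling segments are truncated at the split), adjacent equal-state
  segments are merged, then segments < 3 Mb are removed smallest-first,
  re-merging equal-state flanks across the vacated gap; a transition
  between two consecutive different-state segments counts when both are
  ≥ 10 Mb and the gap between them is < 3 Mb.
* **ntAI**: allelic-imbalance runs > 1 Mb that touch a chromosome end
  and do not overlap the centromere interval.
* **HRD score**: the sum of the three.

The length thresholds (15 / 10 / 3 / 1 Mb) are the literature defaults
for these scores and are keyword arguments throughout. No ploidy
correction is applied to LST; profiles are consumed as given. Whether
run-merging should cross upstream segmentation boundaries is not
uniquely determined by the definitions; merge-then-measure is adopted
and pinned by tests.

The 28-entry GI parameter catalogue is a declared construction:
{count, pct_genome} × {LOH, loss, gain, allelic imbalance} × {>3, >10,
>15 Mb} (24 entries) plus HRD-LOH, LST, ntAI and the HRD sum. It is
fully swappable through `ScarCatalogue`.

Every statistic is verified exactly against an independent brute-force
oracle that rasterizes profiles to per-base-pair state arrays and
enumerates runs from the arrays. The oracle tests run on a
kilobase-rescaled copy of the three-chromosome mini-genome (240 kb
total, thresholds scaled by the same factor): the statistics are
coordinate-scale-free, and this size makes a literal per-bp sweep over
hundreds of random profiles cheap.

## Feature layers

* Response label: responder ⇔ PFI ≥ 12.0 months (boundary inclusive).
* Near-zero-variance filter on SNP coverage: drop a feature when its
  total count < `min_total` (default 10 × samples) or when
  most-frequent/second-most-frequent value ratio ≥ 95/5 with distinct
  fraction ≤ 0.1. The criterion is standard; the thresholds are package
  defaults, exposed as config keys.
* Expression counts are scaled per sample so every sample's median
  equals the grand median of pre-normalization medians — idempotent,
  invariant to per-sample rescaling, and keeps counts interpretable.
* HRR stratification: a sample is HRRmut when any of its mutated genes
  intersects the HRR gene set (default: the DNA-damage-panel genes
  annotated to homologous recombination; config-overridable since any
  specific panel's HRR subset is a curation choice). CCNE1-amplified
  samples form their own subgroup in the three-way stratification,
  taking precedence over HRR status.

## Selection and models

Selectors see training samples only. SNR scores features by
(μ₊ − μ₋)/(σ₊ + σ₋); ANOVA uses the one-way F statistic; logistic
selection keeps features with univariate Wald p < 0.05 (no multiplicity
correction by default, matching common practice in this setting;
complete separation flags the feature and treats it as selected); RFE
eliminates to k features with a linear SVM; Boruta builds one shadow
(permuted copy) per feature each iteration, fits a random forest on the
joint matrix, scores a hit when a feature outranks the best shadow, and
confirms/rejects by a Bonferroni-adjusted two-sided binomial test
against p = 0.5 at α = 0.01, resolving leftover tentative features by
comparing median importance to the median best-shadow importance.
Boruta's false-confirmation control presumes a reasonably large feature
pool (the shadow maximum is the null); on very small panels single
spuriously correlated features can be confirmed — a known property of
the procedure, not an implementation artifact.

Default layer sizes are 8 (SNP), all 28 (GI; the layer is small and is
not selected over), and 7 (expression), giving the 43-attribute union.
Models: RBF-SVM with C ∈ {0.25, 1, 4} and kernel width from the median
pairwise-distance heuristic; random forest with 500 trees and
`max_features` ∈ {√p, p/3}; single-hidden-layer perceptron with size ∈
{3, 5, 7} and L2 α ∈ {0.1, 0.01}. Tuning is 5-fold stratified CV on
accuracy; grids are ordered simple-to-complex and ties resolve to the
first best. SVM/NN inputs are standardized with training-set
statistics inside the pipeline; forests consume raw values.

The ensemble consumes the 43 raw selected features (not the layer
models' predictions) with the same SVM tuning; a
stacking-on-predictions variant exists as `stack_predictions` for
comparison. The bootstrap benchmark resamples the *validation series*
(size preserved, with replacement, B = 500) around fixed predictions;
single-class resamples leave κ undefined and are skipped and counted,
never imputed.

The 70/30 split takes `floor(0.7·n_class)` training samples per class
and assigns the rounding remainder to training: 183 samples → 128/55.

## Evaluation

Published confusion matrices in this setting tally responders in the TP
cell but print sensitivity as tn/(tn+fp) and specificity as tp/(tp+fn);
`metric_report` reproduces that orientation explicitly
(`rates_from_tn=True`) rather than silently. Accuracy CIs are exact
Clopper–Pearson (beta-quantile form); Wilson-style intervals can be had
from `statsmodels` if preferred, but the exact interval is the package
convention. κ uses the 2×2 marginal-product chance term. AUC is the
midrank Mann–Whitney statistic. Survival uses lifelines: product-limit
KM, unweighted log-rank, Cox with Efron tie handling; rank-deficient or
constant covariate matrices are rejected before fitting.

## Synthetic cohort

The generator encodes the study conditions the analysis assumes, all
driven by one latent Bernoulli HRD state per sample (default fraction
0.5, cohort size 183):

* **Profiles**: per chromosome, Poisson breakpoints at 8 (HRD) vs 2
  (stable) per 100 Mb; per segment, LOH with probability 0.40 vs 0.05,
  otherwise total CN in {2, 3, 4} (0.7/0.2/0.1) with the minor allele
  drawn to produce a realistic mix of balanced and imbalanced states.
  The default genome is the 3-chromosome 240 Mb mini-genome, chosen so
  scar computations stay hand-checkable; a GRCh38-scaled autosome
  layout ships with the package but is never required by tests.
* **Matrices**: gamma-Poisson (negative-binomial, dispersion 0.3)
  counts with log-normal baseline means (median ≈ 100); 8 of 1000 SNP
  features and 7 of 600 genes shift their HRD-class mean by ±1.5 on the
  log2 scale, alternating sign. The matrix sizes are scaled down from
  assay dimensions to keep the default analysis interactive; the
  informative-feature counts match the final layer sizes.
* **Outcomes**: PFI is exponential with median 72 months for HRD
  samples vs 4 for stable — the 72 mirrors the reported platinum-free
  survival of HRR-mutated HGSOC, the 4 a platinum-refractory course.
  Censoring (rate 0.15) draws censoring times as 12 + Exp(mean 24)
  months: a minimum-follow-up assumption that keeps the 12-month
  responder label observable, as in a real cohort where response status
  is ascertainable for analyzed patients. OS adds an Exp(median 18)
  post-relapse survival under uniform 24–120-month follow-up; 31% of
  samples receive a PARPi with exponential PFS (median 20 vs 8).
* Stage, HRR-mutation and CCNE1 flags are drawn with class-conditional
  frequencies that reproduce realistic marginals (~36% HRRmut, ~12%
  CCNE1-amplified).

Ground truth (HRD state, informative feature ids) is stored in the
bundle's metadata sidecar and in trailing-`i` feature-id markers; the
pipeline never reads either.

With these defaults the HRD state and the responder label agree for
~87% of samples — exponential PFI scatters some HRD samples below 12
months and vice versa — so ~0.87 is the generative ceiling on
achievable classification accuracy, and observed validation accuracies
of 0.87–0.93 (55 held-out samples) are at that ceiling. The generator
does **not** model FFPE artifacts, tumor purity/ploidy, subclonality,
read-level noise, or correlated features; passing tests demonstrate
correctness and statistical sanity of the pipeline, not clinical
performance on real cohorts.

## Numerical and design notes

* All randomness flows from explicit integer seeds; no global RNG
  state. Identical configs produce bit-identical cohorts, splits, fits
  and bootstrap reports (tested).
* Segment readers correct swapped allele labels (minor > major) with a
  logged warning instead of failing, since upstream tools disagree on
  A/B order; overlapping segments and unknown chromosomes are hard
  errors.
* Cohort components with mismatched sample sets are harmonized to the
  intersection with a logged report, mirroring how multi-assay cohorts
  lose samples per assay.
* Known limitations: no probability calibration; no nested
  cross-validation (selection and tuning share the training series); GI
  catalogue identities are a reconstruction, not a published list; the
  LST smoothing deletes sub-threshold segments smallest-first, which is
  deterministic but one of several defensible orders.
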