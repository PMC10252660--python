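# scarface

Genomic-scar scoring and multi-layer response prediction for high-grade
serous ovarian cancer (HGSOC).

Response of HGSOC to DNA-damaging agents — platinum-based chemotherapy
and PARP inhibitors — tracks deficiencies in homologous recombination
repair (HRD). HRD leaves persistent copy-number footprints ("genomic
scars") that can be read off allele-specific copy-number segment
profiles. This package implements that readout and the classifier built
on top of it, for bioinformaticians and translational researchers who
want an open, testable version of the whole workflow:

* **Scar statistics.** From a segment profile (total and minor-allele
  copy number per interval) it computes HRD-LOH (loss-of-heterozygosity
  runs > 15 Mb not spanning a chromosome), LST (chromosome-arm
  transitions between segments ≥ 10 Mb after 3 Mb smoothing), ntAI
  (allelic-imbalance runs reaching a telomere without crossing the
  centromere), their sum (the HRD score), and a configurable
  28-parameter genomic-instability (GI) catalogue
  ({count, % genome} × {LOH, loss, gain, allelic imbalance} × {>3, >10,
  >15 Mb} plus the four scar scores).
* **Three feature layers and models.** SNP coverage counts
  (near-zero-variance filtered), the GI parameter vector, and
  median-normalized gene-expression counts; per layer, feature selection
  (ANOVA F, signal-to-noise ratio (μ₊ − μ₋)/(σ₊ + σ₋), univariate
  logistic significance, recursive feature elimination, Boruta) and a
  grid-tuned classifier (SVM, random forest, or single-hidden-layer
  neural network), trained on a stratified 70/30 split to discriminate
  responders (platinum-free interval PFI ≥ 12 months) from
  non-responders.
* **The Scarface ensemble.** An SVM over the union of the selected
  features of the three layers (8 SNP + 28 GI + 7 expression = 43
  attributes by default), benchmarked by a 500-iteration bootstrap of
  the validation series (mean accuracy and Cohen's κ = (p₀ − pₑ)/(1 −
  pₑ), with exact Clopper–Pearson intervals on accuracy).
* **Survival evaluation.** Kaplan–Meier curves, log-rank tests and Cox
  proportional-hazards models over PFI, PARP-inhibitor PFS and overall
  survival.
* **A synthetic-cohort generator** that ties everything to a latent
  per-sample HRD state — Poisson breakpoints and class-specific LOH
  rates for the segment profiles, negative-binomial count matrices with
  a few informative features, exponential survival times — so every
  stage is testable end to end without patient data.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1   # writes scratch/cohort/
python analysis/02_score_scars.py                # results/gi_parameters.tsv
python analysis/03_train_models.py --seed 1      # results/model_report.json
python analysis/04_evaluate_survival.py --seed 1 # results/survival_report.json
```

On the default 183-sample cohort at seed 1 this prints:

```
  samples: 183, latent HRD fraction: 0.492
  responders (PFI >= 12 mo): 0.546
  HRD/responder agreement: 0.869
  hrd_sum : HRD mean   7.37   stable mean   1.94
  snp   model validation accuracy: 0.9273
  gi    model validation accuracy: 0.8909
  expr  model validation accuracy: 0.8909
  ensemble validation accuracy: 0.9091
  bootstrap (B=500): accuracy 0.9069, kappa 0.8116
PFI log-rank: chi2 166.61, p 4.07e-38
OS Cox HR (predicted responder): 0.144 [0.092, 0.228], p 8e-17
```

Reading: HRD-class samples carry ~5 more combined scar events than
stable ones; the three single-source models reach ~0.89–0.93 validation
accuracy on 55 held-out samples; the 43-attribute ensemble reaches 0.91
with a bootstrap-mean κ of 0.81; and the predicted responder group has a
far longer platinum-free interval (log-rank χ² 167) and an overall
survival hazard ratio of 0.14. The HRD/responder agreement of 0.87 is
the generative ceiling any classifier can reach on this cohort (see
`docs/methods.md`).

The same steps are available as a CLI (`scarface simulate|scars|train|
evaluate`) for use on external segment profiles and matrices; input
formats are documented in `src/scarface/io.py`.

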