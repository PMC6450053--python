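# Methods

This note documents the statistical machinery of `hurthleseq`: the models
and their assumptions, the parameters that matter, the synthetic study
conditions, and the numerical choices made where the design was open. No
empirical claim is made here beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Expressed LOH statistic (`variant_loh`)

Loss of heterozygosity shifts the variant allele fraction (VAF) of
heterozygous sites away from 0.5. Because RNA-seq variants are confined to
expressed exons, no segment boundaries are estimated; the statistic is the
proportion of putatively heterozygous variants in the loss zones:

* calls with VAF exactly 1 are dropped first (expressed homozygous sites);
* `n_all_het` counts `0 < vaf < 1`; `n_loss_het` counts `0 < vaf < 0.2` or
  `0.8 < vaf < 1`; `LOH = n_loss_het / n_all_het`;
* all inequalities are strict: VAFs exactly 0, 0.2, 0.8 or 1 never count as
  loss, and 0/1 are not heterozygous candidates. VAF-0 records can arise
  from homozygous-reference calls and carry no heterozygosity information;
* the genome-level value pools chromosomes 1–22 only. MT is effectively
  haploid/heteroplasmic and X/Y are hemizygous in males, so their VAF
  spectra are uninformative for LOH;
* `n_all_het = 0` yields an explicit undefined marker (NaN), not 0 and not
  an exception. For classifier feature vectors the marker is imputed as 0
  ("no evidence of loss") with the imputation count logged — absence of
  variants is treated as absence of signal, the conservative choice. The
  per-chromosome `n_all_het` is reported so users can filter thinly covered
  chromosomes; no minimum variant count is imposed.

The neoplasm-index LOH block is the 15 chromosome-level values
(chromosomes 1, 2, 3, 4, 5, 6, 8, 9, 11, 13, 14, 15, 16, 18, 19) plus the
genome-level value — 16 features.

VCF input (via pysam) accepts `chr`-prefixed or bare chromosome names and
`chrM`/`MT`; VAFs come from a per-sample `AF`/`VAF` FORMAT field when
present, else from `AD` as alt/(ref+alt), in that fixed precedence for
reproducibility. Biallelic records only; non-PASS records are skipped by
default with a flag to include them (upstream filter conventions vary).

## Normalization and differential expression (`expression`)

**Size factors** are median-of-ratios: per sample, the median over genes of
count / geometric-mean-across-samples, over genes positive in every sample
(a pseudo-reference fallback uses nonzero entries only).

**VST.** Gene-wise dispersions are estimated by moments on normalized
counts and a parametric mean-dispersion trend `alpha(mu) = a0/mu + a1` is
fitted by trimmed least squares. With `Var = (1 + a0) mu + a1 mu^2`,
integrating `1/sqrt(Var)` gives the closed form

```
vst(q) = log2( (1 + a0 + 2 a1 q + 2 sqrt(a1 q (1 + a0 + a1 q))) / (4 a1) )
```

monotone in the normalized count `q`, constant for all-zero genes, and
`log2(q) + const` at high counts. A parametric trend replaces a local
regression fit deliberately: the classifiers consume only the normalized
values, and the transform is accepted via its measured
variance-stabilization property (transformed variance varying < 2× across
mean-expression bins in NB simulations), not via numeric equality with any
other implementation. Fewer than 10 trend-fittable genes triggers a
`log2(q+1)` fallback with a warning.

**Differential expression** is a two-group negative-binomial exact test on
raw counts:

* library sizes are equalized by scaling counts to the geometric-mean
  effective library and rounding (a linear approximation of quantile
  adjustment — adequate at these depths and checked against the enumeration
  oracle on equal-library instances);
* a common dispersion is estimated by conditional maximum likelihood on a
  log-spaced grid (1e-4 … ~8, 48 points); tagwise dispersions maximize the
  per-gene conditional likelihood plus 10 prior "gene-equivalents" of the
  common curve (weighted-likelihood shrinkage);
* conditioning on a gene's total count, the group sums are NB with means
  `n_k mu` and sizes `n_k / phi`; the two-sided p-value is the total
  conditional probability of all splits no more probable than the observed
  one. A likelihood-ratio backend (chi-square, 1 df, same dispersions) is
  available where speed matters;
* Benjamini–Hochberg adjustment throughout. Log2 fold-changes are computed
  from group means with a prior count of 2 (mild shrinkage at low counts).

Feature selection keeps genes with adjusted p < 0.05 and |log2FC| > 1.5,
both strict. The fold-change filter is two-sided by default (volcano plots
of both contrasts show both tails) with a one-sided option. For the Hürthle
index the 13 mitochondrial protein-coding genes are force-included. DE runs
on raw counts while the SVMs consume VST values — the standard split.

## Index models (`classifiers`)

Both indices are linear SVMs whose *continuous* decision value is the
score; binarization happens only in the cascade. Features are standardized
(center/scale frozen into the model): the cost grid reaches 1e-4, which is
only meaningful on unit-scale features. Cost is selected by nested
cross-validation — stratified 10-fold outer (each fold holds out ~10% for
honest evaluation), 5-fold inner tuning by AUC over the grid
(1e-4, 1e-3, 0.01, 0.05, 0.1, 1, 5, 10); the final cost is the modal
inner-selection across outer folds, ties to the smaller (more regularized)
value, and the final model is refit on all samples. The inner fold count is
a convention (5) as is the vote-based final selection — both deterministic
given the seed, which is a required input to every stochastic operation.

The reported CV AUC is the **mean of per-fold held-out AUCs**, not the AUC
of pooled raw scores: folds whose inner loops selected different costs
produce decision scores on very different scales, and pooling them mixes
incomparable rankings. Pooled scores are retained for plots and for
sensitivity/specificity at cutoff 0 (every fold model's own boundary).
An asymmetric per-class cost multiplier is available for class imbalance;
the shipped defaults use ratio 1.

Models serialize to versioned JSON (feature names, weights, intercept,
standardization parameters) and refuse to score feature frames whose names
mismatch.

## Cascade and threshold optimization (`cascade`)

The three rules are implemented exactly as stated in the README, with the
printed strict/non-strict boundaries
(`BS < t_nominal`; `H > t_H`; `N < t_N`; `t_nominal ≤ BS < t_Hürthle`), and
are property-tested against a literal transcription over randomized lattice
draws that hit every tie. NI scores are computed internally for all samples
so rule 2 is always decidable, but are *reported* only for HI-positive
samples (for HI-negative samples the score is recorded as absent, not
zero). A missing N score for an HI-positive sample is an error.

The **stand-in B/S scorer** replaces the production ensemble, whose
internals are out of scope: 12 linear SVMs on bootstrap resamples of the
cohort over histology-DE-selected genes (FDR < 0.05, no fold-change cut,
top 200 by p-value — the histology contrast is diluted by label noise, so
the index-style |log2FC| > 1.5 cut would often select nothing), one shared
cost chosen by 5-fold CV AUC; the BS score is the mean decision value. It
is interface-compatible with any faithful ensemble (`scores(features)` +
`feature_names`).

**Thresholds are learned, never hard-coded.** `t_BS_nominal` is first fixed
by the B/S scorer's own tuning: the most specific cutoff whose B/S-alone
sensitivity exceeds the floor (ties to the more sensitive). The remaining
three thresholds are then searched exhaustively on 50-point score-quantile
grids (the adjusted-threshold grid spans `[t_nominal, max BS]` and always
contains the degenerate no-rescue point `t_Hürthle = t_nominal`, so the
constrained optimum can never be worse than no rescue). The objective is
maximal overall training specificity subject to overall training
sensitivity > 0.90; ties break toward higher sensitivity, then a smaller
adjusted threshold. If no configuration meets the floor the
maximum-sensitivity configuration is returned with a warning. A flag
extends the search to a full 4-dimensional grid including `t_BS_nominal`.

The optimizer consumes final-model resubstitution scores: the quantity
being optimized (and reported by the acceptance script) is explicitly
*training* sensitivity/specificity, and the bagged B/S stand-in has no
pooled-CV score; this optimism is a known limitation — validation on held
out data is the user's responsibility.

## Synthetic study conditions (`synthdata`)

The generator emulates the structure the classifiers assume, with a
ground-truth ledger sufficient to score every planted signal:

* **Classes.** 318 samples: H+N+ = 71, H+N− = 128, H−N+ = 40, H−N− = 79
  (199 Hürthle-positive / 119 negative). An `ni_labelled` flag marks all 71
  H+N+ plus 27 H+N− samples as the 98-sample neoplasm-index training subset
  — only part of the Hürthle-positive samples carry confident neoplasm
  labels, as in real development cohorts.
* **Counts.** Negative binomial (dispersion 0.15, typical bulk RNA-seq),
  log-normal baseline means (ln-mean 4, ln-sd 1; mitochondrial baselines
  ×10), log-normal library factors (ln-sd 0.25).
* **Expression programs.** Effects enter through sample-level latent
  activities — class indicator plus Gaussian noise — multiplied by per-gene
  loadings with random sign. This is deliberate: independent fixed per-gene
  shifts would let an SVM aggregate a handful of genes into near-perfect
  separation, making the LOH-adds-value and rescue mechanisms untestable;
  correlated programs bound separability by the activity noise, the way
  real co-regulated signatures behave. Group-mean log2FC still equals the
  loading (activity noise is mean-zero), so DE recovery is unaffected.
  Defaults: Hürthle program 60 genes, max |log2FC| 2.0, activity sd 0.25,
  plus +3.0 log2FC on the 13 mitochondrial protein-coding genes (clear
  separation, as mitochondrial abundance gives in practice); neoplasm
  program 15 genes, max |log2FC| 1.0, activity sd 1.0 — deliberately weak,
  since an indirect transcriptional signature of cytological neoplasm
  status is precisely why LOH features are needed; malignancy program 30
  genes, max |log2FC| 1.0, activity sd 0.5, tied to the histology label.
* **Histology labels.** N+ samples are malignant with probability 0.55,
  N− with 0.05 — simulation conventions encoding "neoplasm ≠ malignant",
  not estimates.
* **LOH.** Only H+N+ samples carry planted LOH, on chromosomes
  {1, 2, 3, 8, 9, 13} (a subset of the 15 index chromosomes):
  P(LOH | malignant) = 0.95, P(LOH | benign) = 0.55, so LOH is enriched in,
  but not exclusive to, the malignant neoplasms — which is exactly what
  makes rescuing NI-negative benign neoplasms possible. On affected
  chromosomes a fraction 0.6 of variants is redrawn from the extreme zones;
  baseline VAFs are Beta(6, 6) (≈3% baseline extreme mass), 8% of calls are
  homozygous VAF = 1 to exercise the pre-filter, and read depths are
  Poisson(40) so realized VAFs carry binomial noise and cross the strict
  0.2/0.8 boundaries naturally. 80 variants per chromosome.
* **Determinism.** Everything flows from one seed; rewriting the same spec
  yields byte-identical label and ledger files.

What passing tests on these conditions *do not* show about clinical data:
genes here are conditionally independent given three latent programs,
LOH is chromosome-wide and bimodal, truth labels are clean Bernoulli
functions of class — real cohorts have correlated programs, partial and
mosaic LOH, and noisy histopathology gold standards. The synthetic results
demonstrate that the machinery recovers the signals it is built for, at
desk scale, not that clinical performance is reproduced.

## Problem sizes and numerical choices

Default desk-scale runs use 2000 genes × 318 samples, 80 variants ×
25 chromosomes per sample; end-to-end training (three exact-test DE passes,
two nested CVs, the bagged ensemble and a 125 000-configuration threshold
grid) takes about a minute on one CPU. Exact-test enumeration is vectorized
per gene over the conditional total; dispersion grids use 48 log-spaced
points with grid-argmax (no within-grid refinement — threshold decisions
downstream are insensitive to sub-grid dispersion error). Zero-variance
features standardize with scale 1. Quantile grids use data values, so
strict-inequality thresholds behave identically for any monotone rescaling
of scores. Bootstrap resamples are redrawn (up to 100×) until both classes
are present with ≥ 2 members.

## Known limitations

* Feature selection runs on the full training cohort before
  cross-validation (as in the emulated development process), so CV AUCs
  carry selection optimism; the honest-evaluation machinery (outer folds
  never informing inner tuning) is asserted by a bookkeeping test, but
  selection bias is not removed.
* Threshold optimization uses resubstitution scores (see above).
* The cohort generator's neoplasm expression contrast is weak by design;
  consequently index-style feature selection on the synthetic neoplasm
  contrast typically falls back to the top-25-by-p gene list (a logged
  warning, not an error).
* The stand-in B/S scorer is a placeholder with the correct interface and
  honest desk-scale behavior, not a reimplementation of the production
  ensemble.
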