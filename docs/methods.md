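# Methods

## Problem and model

`gemresponse` implements a small-cohort drug-response classification
pipeline: given per-patient tumor molecular profiles (mRNA FPKM / FPKM-UQ,
miRNA and isomiR log2-RPM, CpG-probe and CpG-island methylation beta
values, per-gene copy number) and a curated binary response label
(responder = best response CR or PR; nonresponder = SD or PD), estimate how
well each (profile, algorithm) pair predicts response, and whether the
predicted groups retain the survival separation of the actual groups.

Three design commitments shape everything else:

1. **Merged cross-validation.** With n ≈ 70 patients, per-fold test sets of
   7 samples make MCC extremely unstable. Instead, each repetition merges
   the n out-of-sample predictions from all K folds and computes one
   confusion matrix, one MCC and one ROC-AUC over all n samples. Per-fold
   metrics are never averaged. Five seeded repetitions are summarised by
   the median (mMCC); the seed drives both the fold assignment and any
   stochastic learner, so a repetition is one reproducible unit.

2. **Undefined MCC is a first-class outcome.** A classifier that predicts
   one class for every sample has a zero in an MCC marginal; the
   coefficient is undefined, not zero. `mcc` returns a typed sentinel,
   summaries exclude undefined repetitions and count them, and a cell whose
   every repetition is undefined renders as a blank, never as 0. This
   distinction matters scientifically: "no better than chance" and
   "degenerate" are different failure modes.

3. **Fully nested OMC feature selection.** For each outer-fold training
   set, features are ranked by a two-group ANOVA F-test and a grid of
   top-k feature counts (k from 2 up to half the training-set size) is
   scored by an *inner* merged-CV MCC; the best k (ties broken toward the
   smallest, for parsimony) is refit on the outer training set. The ANOVA
   ranking is recomputed inside every inner training split, so no selection
   decision ever sees data it is evaluated on. A leakage-guard test
   verifies that permuting held-out labels changes neither the chosen k nor
   the selected features.

## Algorithm panel

Eight classifiers behind one predictor contract: CART, random forest,
XGBoost, LightGBM, logistic regression, linear- and RBF-kernel SVC, and
k-nearest neighbours; each in all-features and OMC modes (16 variants per
profile). Hyperparameters are the libraries' defaults, recorded verbatim
into the run manifest — no tuning is performed anywhere, so reproducibility
rests on recording rather than guessing. Learners exposing class
probabilities are thresholded at 0.5 (above = responder); margin
classifiers (SVC) contribute decision scores thresholded at 0. ROC-AUC is
computed from the ranking scores directly (it is rank-invariant), with the
responder class positive and ties counted one half.

## Synthetic data

The generator replaces the cohort download and defines the study
conditions. Defaults: n = 70 samples with a 41/29 nonresponder/responder
split, 1,000 features of which 5 are informative, effect size Δ = 1.5
(standardized mean shift on a latent Gaussian scale), noise SD 1.

A latent-Gaussian-then-transform scheme gives Δ a uniform meaning across
profile kinds: latent N(0, σ²) values, shifted by Δσ in responders'
informative columns, are mapped by `exp` (FPKM-like: non-negative,
right-skewed), a logistic squash (beta values in (0,1)), identity
(log2-RPM), or an additive offset around the neutral copy number 2.0
(CNV). Informative columns carry an `info_` ID prefix so recovery metrics
need no side table. Segment-level CNV data are generated by tiling a
chromosome with contiguous segments per sample; the generator retains the
per-gene mean/median ground truth computed by direct interval scanning, so
the segment-to-gene aggregator can be checked for exact equality.

Survival: OS is exponential with nonresponder median 20 months and a
responder hazard ratio of 0.3 (echoing observed gemcitabine-cohort medians
of roughly 20 vs 70 months); PFS = OS × Uniform(0.3, 1), which enforces
PFS ≤ OS; censoring is Bernoulli at rate 0.2 with a uniform follow-up cut.
Setting Δ = 0 and HR = 1 yields a fully null dataset, used to check
calibration (ANOVA false-positive rate, log-rank p uniformity, permutation
null centering).

What the generator does *not* emulate: inter-feature correlation, batch
effects, assay-specific missingness, or the empirical distribution shapes
of real tumor data. Passing tests therefore demonstrate correctness of the
machinery and calibrated behaviour under a known truth — not expected
performance on real cohorts.

## Curation and matching rules

Drug names are lower-cased, trimmed and mapped through a synonym
dictionary ("Gemzar", "gemcitabine HCl" → "gemcitabine"); unmapped names
pass through with a warning. Exclusions apply in a fixed order (target-drug
filter → missing response → inconsistent response → treatment before tumor
procurement), with per-rule patient tallies that sum to input minus output.
Inconsistency is judged on the *binarized* label, so CR + PR records are
consistent. Profiles join to the cohort on the patient-level barcode prefix
(12 characters for TCGA-style IDs, configurable); duplicate samples per
patient keep the lexicographically first.

## Survival statistics

Welch's two-tailed unpaired t test (Satterthwaite df) for differential
features, raw p-values by default (Benjamini–Hochberg available but off).
Kaplan–Meier median = first time the product-limit curve is ≤ 0.5,
undefined if never reached. Two-group log-rank with 1 df. Cox
proportional-hazards fits via lifelines (Efron tie handling — the library's
default and the more accurate approximation; synthetic times are continuous
so ties are immaterial), Wald 95% CIs; continuous covariates are
standardized so hazard ratios are per SD, binary covariates stay on their
natural scale; multivariate fits pre-check the covariate matrix rank and
raise a diagnostic on collinearity. The four-group comparison (actual and
predicted responders/nonresponders) takes the predicted split from one
designated repetition's merged out-of-sample classes (default: the first
seed), reported alongside the per-group KM medians and the four pairwise
log-rank tests for OS and PFS.

## Numerical and sizing choices

- OMC k-grid default is exhaustive (step 1) from 2 to ⌊n_train/2⌋; a
  coarser step is a supported configuration. Acceptance-scale runs use
  step 6 (grid {2, 8, 14, 20, 26} at n = 70) for the RF study and a
  reduced inner CV (3-fold, k ≤ 20) for the 51-run permutation study —
  the observed statistic and its null always use the identical
  configuration, so the permutation test stays exact.
- ANOVA p-value ties (duplicated features) break by feature ID; constant
  features get F = 0, p = 1 and rank last.
- If every candidate k has undefined inner MCC, selection falls back to the
  smallest k with a warning.
- Empirical permutation p uses the +1 correction and is never 0; undefined
  null summaries are stored as NaN and never count as exceedances.
- The stratified-fold builder delegates to scikit-learn for K < n and
  implements leave-one-out (K = n) as a seeded permutation of singleton
  folds, where stratification is vacuous.
- Fold-count contract: per-fold class counts deviate from proportional
  allocation by at most 1 (e.g. 41 nonresponders over 10 folds: nine folds
  of 4 and one of 5).

## Known limitations

- The synthetic generator's independence assumptions make feature selection
  easier than on real, correlated omics data; planted-recovery results are
  upper bounds on real-data behaviour.
- Combination-therapy records are attributed to the target drug whenever it
  appears in the record; the curation report notes the rule.
- No methylation array normalization, no FPKM computation from counts, no
  batch correction: matrices are assumed pre-normalized.
- The CGI aggregation uses only explicitly mapped probes (no shore/shelf
  inference).
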