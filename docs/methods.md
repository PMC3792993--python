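# Methods

This note documents the statistical model behind `liporisk`: what the
pipeline computes, what the synthetic cohort generator emulates, the
numerical conventions, and the design choices made where the design was
genuinely open.

## The classification problem

Subjects with fasting plasma glucose < 6.1 mmol/L carry one of three
labels: undiagnosed type 2 diabetes (T2D), impaired glucose tolerance
(IGT), or normal glucose tolerance (NGT). The binary outcome pools T2D and
IGT as the *at-risk* (event) class — the group that would benefit from
intervention — against NGT. The three-way label is retained for
stratification and for per-group accuracy reporting, never for training.

Three feature sets are compared: **A**, the eight standard risk factors
(sex, age in years, systolic blood pressure in mmHg, waist in cm, total
cholesterol, HDL-C and triglycerides in mmol/L, HbA1c in %); **B**, the
lipid species (relative abundances, arbitrary units); **A+B**, their union.

## Preprocessing

1. *Log transform.* Natural log of every observed lipid abundance
   (log10 selectable; risk factors pass through).
2. *Below-LOD imputation.* Missing lipid cells mean "below the limit of
   detection" and are imputed with the constant 0 **on the log scale**
   (raw abundance 1 in measurement units). The alternative reading —
   logging a raw value of 0 — is undefined, so this is the implementable
   interpretation. The imputed constant is configurable. Imputation
   happens before z-scoring, so imputed cells shift the column mean; for a
   species whose typical log abundance is far from 0, imputed cells are
   low outliers, which both sharpens rank-based separation (censoring is
   left-tail) and inflates the column SD.
3. *Z-scoring, per cohort.* Every feature column is standardized to mean 0
   and sample SD 1 (denominator n−1) using statistics of **that cohort
   only**. Because a multiplicative per-species batch factor (or any
   per-species affine distortion of the log values) is absorbed entirely
   by the column mean and SD, separate z-scoring removes such batch
   effects exactly — provided no cells were imputed; imputed cells hold
   the same constant in both cohorts while observed cells shift, so with
   censoring present the removal is only approximate. Zero-variance
   columns become all zeros with a warning. Risk factors are standardized
   too by default (toggleable): the polynomial kernel is scale-sensitive,
   and mixing mmHg with z-scores would let single columns dominate.

## Classifier

C-support vector classification with a polynomial kernel. The
hyperparameters are not dictated by the method, so the defaults are the
common library defaults for polynomial C-SVC: degree 3, C = 1,
gamma = 1/n_features, coef0 = 0, no class reweighting (the 76-vs-170 class
imbalance is left as is, which yields the characteristic low-sensitivity /
high-specificity profile at the native cutoff). All are configurable. The
decision score's sign is arbitrary for a two-class SVM, so orientation is
calibrated after training: if the training-set AUC of the raw decision
values is below 0.5 the scores are negated. Hard at-risk calls use the
native cutoff score ≥ 0, not an ROC-optimized threshold. The classifier
contract (train → opaque model; decision_scores → one real per subject,
higher = more at-risk) is implementation-agnostic; the test suite runs a
trivial centroid-distance classifier through the same contract.

## Cross-validation engine

Stratified 3-fold partitions: within each fold, each three-way label's
count is within 1 of n_label/3. One master seed; the fold RNG for repeat r
is seeded with (seed, r), making runs bitwise reproducible and repeats
independent. Per iteration (one repeat × one held-out fold):

- candidate features are ranked on the training two-thirds by univariate
  AUC of the raw feature value, *folded* above 0.5 as max(a, 1−a) —
  protective features (HDL-C-like) would otherwise never rank. Folding is
  a deliberate reading of "order by highest AUC" and can be disabled.
  Ties break alphabetically.
- the classifier is retrained at each feature count 1..max_features in
  that order, and AUC / sensitivity / specificity are computed on the
  held-out fold only. Nothing from the held-out fold influences ranking
  or training; the suite asserts the feature order is bit-identical after
  randomizing held-out labels.

Defaults: k = 3, 200 repeats (600 iterations); max_features 30 for the
lipid and combined variants (covers the plateau of the mean-AUC curve with
margin) and all 8 for the risk-factor variant.

Aggregation over iterations: arithmetic means per feature count; 95%
bands are empirical 2.5th/97.5th percentiles of the iteration values (the
600-value empirical distribution exists, so a percentile interval makes
the fewest assumptions; a normal-theory interval would be narrower). The
operating point is the smallest feature count attaining the maximum mean
AUC. Incorporation frequency counts, per feature, the percentage of
iterations whose first operating-point inclusions contain it; frequency
ties break by mean inclusion rank (features absent from an iteration's
ranking count as max_features+1), then by name.

## Final models, external validation, comparison

Each variant's final model is trained on every subject of the initial
cohort using its operating-point-many most frequent features, then
evaluated once on the validation cohort, which is preprocessed entirely
on its own. No validation-derived quantity feeds back into any model.

The gain in AUC (A+B minus A) uses, cross-validated: paired per-iteration
AUC differences at each variant's operating point with a two-sided paired
t-test (Wilcoxon signed-rank selectable); externally: the single-pass AUC
difference. The NRI is the standard two-category form,
(up_e − down_e)/n_events + (down_ne − up_ne)/n_nonevents, comparing hard
classifications at the native cutoff; the cross-validated NRI is computed
per iteration on the held-out fold and averaged.

Cohort characteristics tables report median (IQR) per group with
two-sided Mann–Whitney U p-values (exact by exhaustive enumeration of all
group assignments when n+m ≤ 8, doubled smaller tail, midranks for ties;
tie-corrected normal approximation otherwise), a chi-square test of
proportions without continuity correction for binary variables, and joint
Benjamini–Hochberg adjustment.

## Synthetic cohort generator

No subject-level dataset of this design is publicly deposited, so the
generator produces cohorts with the structure the analysis assumes:

- **Sizes.** Defaults: initial cohort 36 T2D / 40 IGT / 170 NGT (246);
  validation cohort 0 T2D / 101 IGT / 384 NGT (485) — the validation
  cohort deliberately contains no T2D subjects, mirroring the common
  situation that undiagnosed-diabetes plasma is unavailable for
  validation; a flag adds them.
- **Risk factors.** Plausible population means/SDs (age 60 ± 12 y, SBP
  135 ± 16 mmHg, waist 91 ± 11 cm, HbA1c 5.15 ± 0.30 %; total
  cholesterol, HDL-C and triglycerides log-normal). Standardized at-risk
  shifts default to triglycerides 0.75, HbA1c 0.70, age 0.40, SBP 0.45,
  and 0 for waist, sex, total cholesterol and HDL-C — the magnitudes are
  back-derived from the group contrasts typical of a BMI- and sex-matched
  case-control design of this size, where waist and sex are null by
  matching. Sex is an independent fair coin in every group.
- **Lipids.** Log-normal abundances: log value = mu_s + sigma_s · z_s with
  mu_s ~ U(−1, 3), sigma_s ~ U(0.3, 0.8) (scales are arbitrary — the
  pipeline z-scores them away). z_s has block covariance by lipid class:
  ~20 classes with species counts echoing targeted plasma lipidomics
  panels (TG 48, PC 45, DG 25, SM 25, CE 22, ...), within-class
  correlation 0.5. This redundancy is what makes forward selection
  non-trivial: whole classes move together, including by chance.
- **Informative species.** The first n_informative species of the DG
  class (named `DG_001`, ...) carry a standardized mean shift of
  effect_size (default 0.8) in at-risk subjects, plus a loading of
  tg_coupling (default 0.3) on the *within-group* part of the
  triglycerides latent — so they correlate with triglycerides as shared
  physiology would suggest, while their group effect is exactly
  effect_size and partially independent of triglycerides.
- **Censoring.** Per species, the lowest lod_quantile fraction of values
  (default 5%) becomes below-LOD missing — left-tail, not random, since
  missingness means "below detection".
- **Batch effect.** Optionally, every species' raw abundances are scaled
  by a per-species factor jittered around batch_scale and all log values
  are shifted by batch_log_shift — the kind of inter-batch distortion the
  separate z-scoring is designed to remove. Applied to the validation
  cohort by default (scale 1.3, shift 0.2).

Generation is a pure function of the spec including its seed; equal specs
give byte-identical TSV serializations.

### What the generator does not emulate

Raw mass-spectrometry signal, internal standards, instrument drift within
a batch, non-Gaussian lipid co-regulation beyond the class blocks,
age/sex/BMI matching algorithms, and any real biological coupling between
the risk factors and the non-informative lipidome. Passing tests on this
generator demonstrate that the *procedure* behaves correctly (no leakage,
correct accounting, calibrated under the null, able to recover planted
signal); they do not certify performance numbers on real plasma data.

## Behavior worth knowing about

Two properties of the procedure, visible in the synthetic runs and
documented here because they shape interpretation:

1. **Single-cohort null runs are noisy.** Under a global null, a single
   246-subject cohort carries chance feature-label associations of AUC
   order 0.04–0.08 after best-of-k selection. Repeated CV on that one
   cohort estimates those faithfully — they are properties of the data,
   not engine optimism — and no number of repeats averages them away.
   Calibration of the engine itself is therefore checked on the average
   over independent null cohorts, which sits near 0.5 (the residual
   +0.02–0.03 is the operating-point argmax bias).
2. **Per-iteration models are noisier than the frequency-selected final
   model.** With few informative species among hundreds, the greedy
   univariate ordering admits iteration-specific noise features whose
   training-fold AUC (a max order statistic over ~287 candidates,
   amplified by the class-block covariance) competes with the true
   effects. The operating-point mean CV AUC of the combined variant can
   therefore sit at or below the risk-factor variant's even when the
   lipid signal is real. The incorporation-frequency aggregation filters
   this noise — informative species recur across iterations, noise picks
   do not — so the externally validated gain of the final models is the
   more reliable indicator of incremental value, and is consistently
   positive on signal-bearing synthetic cohorts.

## Numerical conventions

- AUC via midranks (ties count half); identical to the trapezoidal area
  under the tie-grouped empirical ROC to < 1e-12.
- Sample SD uses the n−1 denominator everywhere.
- z-scored columns are reproducible bit-for-bit; the TSV reader uses
  round-trip float parsing so write→read is the identity.
- Operating-point ties take the smallest count; ranking ties are
  alphabetical; frequency ties use mean inclusion rank then name.
- Degenerate inputs: zero-variance columns z-score to zeros (warning);
  single-class AUC/NRI raise; empty groups report NaN accuracy, not 0;
  constant-in-both-groups variables report p = 1.
- Problem sizes in the shipped tests and the acceptance script are scaled
  down (20 CV repeats rather than 200; some fixtures use fewer lipids or
  subjects); 60 iterations already give sub-0.01 precision on mean AUC
  curves, and every scaled run states its sizes in its config echo.
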