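# Methods

This note documents the statistical procedures the package implements,
the defaults it ships, and the choices made where the design was open.

## Data model and preprocessing

The unit of analysis is a single-batch LC-MS run: study samples injected
in random order, a pooled QC injected at the run start, after every
`qc_every` (default 6) study samples and at the run end, and optional
blanks at the end of the sequence. Blanks are carried through the tables
but never enter any computation.

**Missing values.** Default imputation replaces a missing entry with half
the feature's minimum observed intensity, the conventional surrogate for
values below the detection limit. The `none` strategy leaves gaps and
downstream steps reject them.

**QC-CV filter.** Per feature, CV% = 100·sd/mean over QC replicates,
using the sample (n−1) standard deviation because QC counts are small
(typically 9 per run here). Features are removed when CV is *strictly*
above the threshold (default 30%), so a feature at exactly the threshold
is retained. A zero QC mean makes the CV undefined; such features are
excluded and flagged. Lowering the threshold can only shrink the retained
set, and filtering commutes with ionization-mode merging.

**Drift correction (QC-RLSC).** Per feature, a degree-1 LOESS (tricube
weights, span 0.75 by default, no robustness iterations) of QC intensity
on injection order is fitted via statsmodels' lowess; the fitted trend is
evaluated at every injection by linear interpolation between the QC
anchors and held flat beyond the first/last QC. Intensities are
multiplied by `median(QC)/trend`, which preserves positivity and leaves a
drift-free feature unchanged. If the fitted trend dips to zero or below
anywhere, the feature is left uncorrected and a warning names it —
dividing by a non-positive trend would fabricate signs. The default step
order is filter → correct, with `correct_then_filter` available since
both orders are in field use; whether correction precedes filtering
mainly affects borderline-CV features.

**Scaling.** Study samples are autoscaled: per feature, mean-centered and
divided by the sample SD (ddof = 1). Coefficients of models fitted on
this matrix are therefore "standardized coefficients". No log transform
is applied by default (a flag exists); autoscaling alone already puts
features on a common scale and keeps effect directions interpretable on
raw intensities.

## PLS-DA

The outcome is coded y ∈ {0, 1} (1 = adverse outcome, creatinine
> 1.5 mg/dL) and centered; with a single response the NIPALS weight
update is exact (no inner iteration): per component
w = X'y/‖X'y‖, t = Xw, q = y't/t't, p = X't/t't, then X ← X − tp'.
y-deflation is omitted (mathematically redundant for PLS1). Component
signs follow a fixed convention — the largest-magnitude weight entry is
made positive — so score/loading output is reproducible. Predictions use
b = W(P'W)⁻¹q plus the training class mean, making 0.5 the natural
decision cutoff. Requested component counts beyond the residual rank
raise an error reporting the achievable maximum.

Diagnostics: R²Y = 1 − SS_res/SS_tot on the training fit; per-component
X-variance explained = (t't)(p'p)/‖X₀‖²_F. VIP uses Wold's definition
with unit-norm weights and SSY_a = q_a²·t_a't_a as the component weight;
Σ VIP² = p holds identically and is asserted in tests.

## Component selection and the two-stage design

The component count is selected by leave-one-out cross-validation
minimizing the misclassification count at the 0.5 cutoff; ties resolve
to the smallest count (parsimony, determinism). The stage-1 cap defaults
to 7 and the stage-2 cap to 10. Inside each fold the training set is
re-autoscaled before fitting, and the held-out sample is projected with
the fold's center/scale — the held-out sample influences neither scaling
nor fit, which a corruption test verifies. Folds whose training labels
collapse to one class are skipped with a warning.

VIP selection runs once, on the full data, with a strict VIP > 1.5 rule
(default). The reduced model is then refitted and LOOCV-scored on the
selected columns. This single-selection design mirrors common practice
and is *optimistic*: the features entering stage 2 were chosen for
association with y on the same samples, so stage-2 LOOCV metrics and
per-feature jackknife p-values overstate out-of-sample performance. The
package documents this rather than silently correcting it; the
permutation test's `full_pipeline=True` mode, which re-runs selection
under every permuted labeling, quantifies the selection bias when needed.

## Validation

**Permutation test.** B label permutations (default 1000); for each, the
final model is refitted at fixed features and component count and its
training R²Y recorded. The empirical p-value uses the +1 correction,
p = (1 + #{R²_perm ≥ R²_obs})/(B + 1), so it can never be zero and its
minimum is 1/(B+1). Under pure-noise data this test is calibrated (the
suite checks the rejection rate at p ≤ 0.05 over 200 replicate null
datasets with B = 199, sized to keep the run in seconds).

**Jackknife.** Delete-one refits at fixed features/components (each fold
re-autoscaled) give coefficient vectors b₍ᵢ₎; SE_j = sqrt((n−1)/n ·
Σᵢ(b₍ᵢ₎ⱼ − b̄ⱼ)²), CI = b̄ⱼ ± t₀.₉₇₅,ₙ₋₁·SE_j, and two-sided p-values from
tⱼ = b̄ⱼ/SE_j with n−1 df. The t reference is the standard choice at
moderate n; no reference distribution is canonical for jackknifed PLS
coefficients. Degenerate SE = 0 yields p = 0 (flagged) for a nonzero
coefficient and p = 1 otherwise. Both the full-data coefficient and the
jackknife mean are reported, as published tables may print either.
Significance defaults to raw p < 0.05 without multiplicity correction —
the convention of the panel-style reporting this package targets;
Benjamini–Hochberg can be applied downstream by users who want it.

**Classification metrics.** Continuous LOOCV predictions are thresholded
at the cutoff (ŷ ≥ cutoff ⇒ class 1) for the confusion matrix, accuracy,
sensitivity and specificity. The ROC sweeps all distinct prediction
values; AUC uses the rank (Mann–Whitney) formula with midranks, so ties
count one half, and equals the trapezoidal ROC area exactly.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults matching the motivating study design: 26 + 22 study
samples, 226 features, QC every 6 injections.

* Intensities are log-normal: per feature a baseline natural-log mean
  drawn from U(9, 14) and log-SD from U(0.2, 0.6) (stated assumptions —
  typical orders of magnitude and spreads for polar metabolites; no
  intensity distributions were available to copy). Generation on the log
  scale guarantees positivity.
* 12 planted discriminative features (default) shift the class-1 log-mean
  by ±1.2 feature log-SDs, signs alternating so both protective and
  adverse markers exist. A `within_class_sd` multiplier can switch off
  biological variation, in which case the realized standardized
  difference equals the planted effect exactly (standardized by the
  generator's own log-SD).
* Non-planted features are partitioned into blocks of 8 sharing a latent
  factor with within-block correlation 0.3 (pathway-style covariation);
  planted features stay independent so recovery is unambiguous.
* Drift is multiplicative — matching what ratio-based QC-RLSC corrects —
  via a smooth per-feature sinusoid of injection order with amplitude up
  to `drift_amplitude` (default 0.3).
* Pooled QCs are the per-feature mean of the study samples times a
  unit-mean lognormal with the feature's technical CV, drawn from
  U(0.05, 0.45) so a realistic fraction of features fails the 30% filter.
  Technical noise is placed on QC replicates only; study-sample
  variation is the biological log-normal model.
* A single seed drives all randomness; identical config + seed gives
  bit-identical output.

What the generator does **not** emulate: technical noise on study
samples, adducts/isotopes, retention-time drift, batch effects beyond
one batch, censoring at the detection limit, or informative missingness
(only a missing-at-random mask is available). Recovery results on this
cohort therefore demonstrate that the pipeline finds planted multivariate
signal under drift and correlated noise — not that it is robust to every
artifact of real acquisitions.

Because technical noise lives only on QC rows, the QC-CV filter would
remove planted features whose study-sample signal is intact; recovery
experiments therefore run generation → drift correction → autoscaling →
two-stage pipeline, exercising the filter separately on its own worked
examples.

## Problem sizes used in the shipped experiments

Recovery: 20 cohorts at the default geometry (226 × 48). Permutation
calibration: 200 null datasets (48 × 22) at B = 199. Null p-uniformity of
the jackknife: 120 replicates at n = 40. These sizes give stable
Monte-Carlo estimates while keeping the full suite under a minute on one
CPU.

## Known limitations

* PLS1 only: binary outcomes, single response; no PLS2, O-PLS or sparse
  variants.
* LOOCV is the only cross-validation scheme, matching the target
  workflow; k-fold is not implemented.
* The stage-2 LOOCV metrics inherit VIP-selection optimism (see above).
* LOESS span is global per run; no per-feature span selection.
* Inter-batch normalization is out of scope — the model is a single
  analytical batch.
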