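# Methods

This note records the models, defaults and numerical conventions behind
`cardiocast`, and what the bundled synthetic study can and cannot show.

## Time base and day windows

t = 0 h at differentiation induction (CHIR addition). Preculture occupies
negative times; day labels map to half-open 24 h windows: `d0` = [−48, −24),
`d1` = [−24, 0), `dd k` = [24k, 24k + 24). The dd0…dd9 windows tile
[0, 240) h exactly. Offline samples are timestamped inside their day's
window; online series carry explicit timestamps (no sampling rate is
assumed).

## Feature engineering

* **Difference quotients.** Gradients are first-order difference quotients
  gᵢ = (yᵢ − yᵢ₋₁)/(tᵢ − tᵢ₋₁); second derivatives are difference quotients
  of the gradients, hᵢ = (gᵢ − gᵢ₋₁)/(tᵢ − tᵢ₋₁). They are exact for
  polynomials of degree ≤ 1 and reproduce the constant second difference of
  a quadratic on a unit grid.
* **"Average X gradient ddk"** is the mean of the instantaneous gradient
  series inside window ddk — not the difference of two day means. The
  within-window mean of equally-spaced gradients telescopes to
  (last − first)/span, so these features measure net within-day change per
  hour.
* **Day averages** are arithmetic means of the samples in the window,
  excluding samples inside any flagged media-change interval; an empty
  window yields a missing value, never an error.
* **Density-normalised DO** divides each DO sample by the offline cell
  density piecewise-linearly interpolated in time, with nearest-sample
  extrapolation outside the offline span (flagged in the log). Units:
  % air saturation per 10⁶ cells mL⁻¹.
* **Offline day-to-day gradients** use day midpoints, in days, as Eq.-style
  timestamps, so "dd0–dd1 cell density gradient" has units
  10⁶ cells mL⁻¹ day⁻¹ and "overall" gradients are
  (last − first)/(elapsed days). Overall gradients are cutoff-aware: in a
  Feature Set 2 table they use only samples through dd5.
* **Default schema (101 features).** The full candidate list is
  reconstructed from the printed selection-table vocabulary: DO and pH
  means and mean gradients over {d0, d1, dd0…dd7}; second derivatives for
  DO and density-normalised DO over {dd0…dd5} (every printed acceleration
  feature ends by dd5); density-normalised DO means/gradients over
  {dd0…dd7}; cell density and aggregate size values at the offline
  sampling grid {dd0, dd1, dd2, dd3, dd5, dd7} with
  consecutive-sampling-day and overall gradients; glucose and lactate at
  the medium-exchange days {dd3, dd5, dd7}; and the scalars preculture
  time, IWP2 treatment time and rotation speed. CHIR concentration is
  protocol-constant and therefore excluded from the default schema (it
  would be dropped as zero-variance anyway). pH second derivatives are
  omitted: pH probes quantise coarsely and their second differences are
  numerically uninformative. The 101-column count is asserted as a
  warning-level check; the schema is fully configurable.
* **Feature sets.** FS1 keeps features whose every constituent measurement
  ends by the end of dd7 (192 h); FS2 by the end of dd5 (144 h).
* **Missing data** stay explicit (`NA`) in stored tables. Imputation
  (per-feature training-fold median) happens only at model-fitting time and
  is refit inside every cross-validation fold.

## Feature selection

* Pearson/Spearman screening (|r| ≥ 0.3 by default; constant inputs are an
  error, undefined correlations are skipped).
* PCA on z-scored features; the retained count is the smallest whose
  cumulative explained variance reaches the target (default 0.94).
* Random-forest importance: impurity decrease from a 500-tree seeded
  regression forest (many trees stabilise the ranking; the *predictive*
  forests use the 5-tree protocol below); selected = importance ≥ mean
  importance.
* GP-ARD: anisotropic RBF kernel, one length-scale per z-scored feature,
  optimised by marginal likelihood. Length-scales are initialised at √d —
  at d ≈ 100 a unit initialisation makes the kernel vanish between any two
  points and strands the optimiser — and L-BFGS-B is budgeted to 60
  iterations, past which the relevance ordering is static. Sensitivity of
  feature j is the mean over training points of the squared central
  finite-difference (step 0.1 in z-units) of the posterior mean; selected =
  sensitivity ≥ 10% of the maximum. With an outcome independent of all
  features the marginal-likelihood optimum is typically a mild overfit
  rather than the pure-noise model, so the meaningful null behaviour is a
  near-empty selected set, not literally zero sensitivities.
* MARS membership: features appearing in ≥ 1 retained basis function of an
  additive hinge MARS fit (forward growth to ≤ 21 terms, ≤ 12 candidate
  knots per variable at quantiles, backward pruning by GCV with penalty 3).

Zero-variance features are dropped with a warning before any selection.

## Predictive models and classification

Endpoint CM content (%) is predicted by regression and thresholded:
*sufficient* iff prediction ≥ 90%, with *insufficient* the positive class.
Predictions are clipped to [0, 100].

* Random forests use **5 trees** (the process-protocol setting), seeded;
  the direct `rf_classifier` path votes over trees on binarised labels,
  breaking 0.5 probability ties toward insufficient (conservative: flags
  at-risk runs).
* GPR prediction models use a single isotropic RBF plus a white-noise term,
  features and outcome standardised, hyperparameters by marginal likelihood
  with 5 fixed-seed restarts. (The anisotropic kernel is reserved for ARD
  selection.)
* MARS as above; a `mean` baseline backend (training-mean predictor) is
  available for leakage probes and floors.

## Evaluation

Accuracy, precision, recall and MCC from the confusion matrix. Conventions:
an MCC denominator factor of zero gives MCC = 0 (an uninformative
classifier has zero correlation with truth); undefined precision/recall are
reported as NaN with a warning, never silently zero. LOO CV refits all
preprocessing (imputation, standardisation, optional selection or PCA) per
fold; a fixed feature list reproduces the select-once-outside-CV protocol.
Monte-Carlo CV draws each validation set without replacement within a
trial; the aggregate is the unweighted mean of per-trial metrics
(NaN-skipping), with pooled counts also reported. The hold-out protocol
fits once on the training cohort and scores the disjoint test cohort.

## Synthetic study conditions

Each run draws six standardised latents, one per *plantable* feature:

| latent | manifests in | rendering |
|---|---|---|
| early growth | dd0–dd1 cell-density gradient | linear dd0 gain 0.35·e^{0.45z} 10⁶ mL⁻¹ day⁻¹ |
| inoculum state | dd1 cell density | dd1 level 1.0·e^{0.35z} 10⁶ mL⁻¹ |
| IWP2 timing | IWP2 treatment time | 48 h (60% of runs) or 48 ± U(24) h |
| oxygen kinetics | dd2 mean density-normalised DO gradient | DO/density tilt 6 · z per day on dd2 |
| late growth | dd5–dd7 cell-density gradient | linear dd5–dd7 gain 0.25·e^{0.5z} day⁻¹ |
| preculture | preculture time | U(45, 56) h |

The dd1 density level carries the inoculum latent and the dd0 gain the
early-growth latent (induction density is their difference) so that each
planted feature is the single best observable proxy of its latent — the
property that makes recovery experiments well-posed. Cell density follows
linear-then-saturating growth (ceiling 3.5 ± 0.3 × 10⁶ mL⁻¹); DO is
setpoint − k·density·demand(t) with a sigmoidal metabolic switch near 96 h;
lactate accumulates with density and partially resets at each medium
exchange, dragging pH down; glucose depletes and is restored at exchanges;
aggregate diameter grows as density^(1/3) and never shrinks. Media-change
artefacts are a rectangular excursion plus a missing-data gap inside the
flagged interval. Run-to-run nuisance spreads (DO setpoint and probe
offsets, oxygen coefficient, metabolic-switch magnitude and timing, lactate
rate, aggregate morphology) keep the online families from being pure
density proxies, as in real campaigns where sensor calibration and
metabolism vary between runs.

Outcome: CM = clip(100·logistic(β₀ + Σ βⱼ zⱼ) + ε, 0, 100) with default
coefficients (+1.0, +0.8, −1.0, +0.9, +0.7, −0.6) in the table's order and
ε ~ N(0, 2.5²) %. β₀ is solved by bisection over a fixed quasi-random
latent sample so that P(CM < 90) equals the configured class balance
(default 0.67, the prevalence implied by an all-positive classifier scoring
0.67 accuracy). Optional config knobs (`effect_sharpness`,
`effect_center`, `effect_shapes`) replace the linear per-latent response
with saturating or tolerance-window dose responses; they are off by
default.

**What passing tests show — and don't.** The generator reproduces
trajectory *shapes* and a known causal structure, not the absolute values,
correlation spectrum, or failure modes of any real campaign; recovery and
performance results certify the pipeline's statistical machinery, not
biological claims. Two structural honesty notes: (i) several engineered
features are near-deterministic transforms of the same measurement (e.g.
density-normalised DO at dd1 versus dd1 density), so sparsity-seeking
selectors may legitimately pick a transform instead of the named feature;
(ii) with the protocol-locked 5-tree forests at n = 42, LOO accuracy beats
the majority-class baseline consistently but modestly, while GPR on the
same tables reaches substantially higher accuracy — smooth
multi-factor boundaries at small n favour kernel methods over tiny tree
ensembles. The test suite asserts the direction of the improvement, not a
fixed margin.

## Problem sizes

Stochastic tests use the study-scale protocols: 58-run cohorts with 42/16
splits for evaluation claims, 200-run cohorts for selection recovery,
20 seeds for averaged claims, and 500-run cohorts for the class-balance
calibration check. The acceptance script mirrors the 58-run protocol
end to end.

## Known limitations

* The full 101-feature candidate list is a reconstruction anchored to the
  57 printed feature names; membership beyond those is a design choice.
* GP-ARD selection depends on a local marginal-likelihood optimum; with
  heavily redundant features the retained representative of a correlated
  group can vary between seeds.
* The MARS implementation is additive (degree-1 hinges only).
* No probability calibration, multiclass outcomes, or vendor file parsers.
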