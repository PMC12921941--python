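# Methods

This note documents the modeling and simulation choices behind `fibrovae`:
what is computed, which knobs matter, what the synthetic cohort does and does
not emulate, and the numerical conventions a reader needs to reproduce or
extend the analysis.

## The anomaly model

The unit of analysis is the fused patient vector
`x = [z-scored clinical block | z-scored imaging-embedding block] ∈ ℝᵈ`
(d = 526 at defaults: 10 continuous clinical variables + 4 binary indicators
+ 512 embedding dimensions). A variational autoencoder with a Gaussian
latent (`k = 8`, diagonal posterior covariance) and a Gaussian observation
model with identity covariance is trained on the full cohort by minimizing
the β-weighted ELBO

```
L = E_q ‖x − x̂‖²  +  β · KL(q(z|x) ‖ N(0, I)),     β = 1
```

with the reconstruction term summed over all d components (‖·‖², not a
mean), KL summed over the k latent dimensions per patient, and the batch
objective averaged over patients. β's balance is defined relative to the
summed-reconstruction scale. The anomaly score is the same quantity at
evaluation time, `A(x) = ‖x − x̂‖² + β·KL`, with the deterministic
posterior-mean pass (`z = μ(x)`) by default; an S-sample Monte-Carlo scoring
mode (`score_mode="sampled"`) is config-exposed, seeded, and reproducible.
The additive decomposition `score = recon + β·kl` is an exact identity and
is asserted per patient in the tests.

Assumptions worth stating: a single Gaussian likelihood is used for both
continuous and binary components (a mixed Gaussian/Bernoulli likelihood is a
possible extension, not implemented); no train/validation split exists —
scores are in-sample descriptions of one cohort, not generalizable risk
estimates; the 512 embedding dimensions enter unreduced, so the embedding
block dominates d and, with it, the reconstruction term.

## Training, determinism, and numerical choices

Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8), batch size 8, 200 epochs, one
Monte-Carlo latent sample per input per step, last incomplete batch kept, no
early stopping. One seeded generator drives weight initialization (uniform
fan-in, U(±1/√fan_in) for weights and biases), per-epoch shuffling and
latent sampling in a fixed order, so a shorter run's loss curve is a prefix
of a longer run's and two serial runs are bit-identical. The exact-
reproducibility contract covers serial single-threaded execution only.

Two numerical conventions are this package's own:

* **Gradient clipping.** Batch gradients are clipped to a global L2 norm of
  5.0 (config `grad_clip`, disableable). The synthetic cohort deliberately
  contains extreme multimodal outliers (see below) whose squared-error
  gradients reach ~10⁴ in small batches; without clipping, training shows
  transient loss explosions. Clipping preserves determinism and the
  objective; it only bounds step magnitude.
* **Recorded loss curve.** The per-epoch value is the full-cohort ELBO
  evaluated at the end of the epoch with the posterior-mean reconstruction.
  This tracks optimization progress without the Monte-Carlo noise of the
  running batch losses and consumes no randomness (preserving the prefix
  property).

A residual training behavior should be understood before reading loss
curves: after rapid early convergence (the curve falls by >80% within ~20
epochs), the fixed-rate optimizer keeps taking finite steps, and the fitted
reconstruction of the injected 3-SD outliers intermittently degrades and
recovers, producing late-epoch swings of 10–50% in the epoch-mean ELBO.
Training the identical configuration on a cohort without injected
discordance yields a curve that is flat after epoch 20 to within ~5%. The
swings are therefore a property of the prescribed outlier injection
interacting with a fixed learning rate and one-sample Monte-Carlo gradients,
not of the optimization code; they do not affect score rankings enough to
break ground-truth recovery (below).

## Feature construction

Binary variables use documented codings (female→0/male→1, no→0/yes→1; a
binary column with ≥3 categories is an error naming the column). Continuous
clinical variables and every embedding dimension are z-scored with full-
cohort means and sample SDs (n−1); binaries pass through unscaled.
Zero-variance columns are dropped with a warning rather than ε-inflated. No
imputation is performed anywhere: a missing core value is an error listing
the affected patients. mMRC is ordinal 0–4 but treated as continuous for
scaling, matching its handling among the modeled variables. Rows are ordered
by sorted patient id; the normalizer is serializable to JSON so saved models
score identically from file.

## Imaging pipeline

Series selection keeps the largest non-scout 3D series (slice count, then
in-plane resolution, then lexicographically smallest series id — the last
tie-break is a determinism convention). Scouts are detected by localizer
image-type flags or single-slice series. DICOM reads apply rescale
slope/intercept; NIfTI volumes are assumed already in HU.

Slice sampling takes 32 evenly spaced indices over `[0, n_slices−1]`
inclusive (round-half-to-even of a linspace); endpoint inclusion maximizes
cranio-caudal coverage, and volumes thinner than 32 slices are sampled with
repetition (warning) rather than rejected. Windowing precedes resizing
(window → bilinear resize with anti-aliasing → channel triplication); the
order and interpolation are conventions, as is common when a protocol does
not state them. Channel-standardization constants belong to the extractor
plug-in, not the pipeline.

The shipped extractor is a frozen Gaussian random projection of slices
block-pooled to an 8×8 grid per channel (fan-in-scaled, fixed seed). It is a
deterministic frozen feature map satisfying the extractor interface — any
frozen backbone (e.g. an ImageNet-pretrained CNN truncated at global average
pooling) can be plugged in through the same `FeatureExtractor` protocol,
declaring `output_dim` and optional channel constants. Patient embeddings
are the componentwise mean of slice embeddings, hence invariant to slice
order.

## Synthetic cohort generator

The generator emulates the structure of a 41-patient cohort in three
clinician-assigned severity groups (19 mild / 8 moderate / 14 severe):

* **Continuous clinical variables** are truncated normals per group with
  μ = published group median and σ = IQR/1.349, truncated at physiologic
  bounds (SpO₂ ≤ 100, distances ≥ 0, …). Draws are quantile-stratified (one
  uniform per equal-probability stratum, shuffled): the marginal law is
  exactly the truncated normal while group medians/IQRs stay pinned to their
  calibration targets at n as small as 8 — the calibration contract is that
  simulated group medians fall inside the published IQRs. Age, SpO₂, FEV₁%,
  DLCO%, 6MWT and VO₂max are calibrated to published values; DLCO/VA%, MIP
  and MEP have no published dispersion and use plausible clinical defaults,
  documented as uncalibrated. mMRC is a thresholded latent normal (ordinal
  0–4); sex and the three treatment flags are Bernoulli with group-dependent
  probabilities (treatment probabilities rising with severity).
* **Latent severity scores.** Each patient carries a clinical factor `s`
  (group center −1.0 / 0.25 / 1.0 + N(0, 0.3); moderate and severe sit close
  together, mirroring their overlapping functional profiles; the cohort SD
  of `s` is ≈1 so that `discordance_magnitude` reads in SD units) and an
  imaging factor `t`.
* **Embeddings** follow the factor model `e = W·u(t) + ε` with
  `u(t) = (t, t², 1)`, `W ∈ ℝ⁵¹²ˣ³` i.i.d. standard normal under a dedicated
  seed (fixed across cohort draws), and isotropic noise with SD 0.2. The
  noise default reflects the pipeline it emulates: slice-level noise at
  roughly the per-dimension signal scale, average-pooled over 32 slices
  (1/√32 ≈ 0.18).
* **Discordance injection.** `round(fraction·N)` patients (default 15% → 6)
  are chosen uniformly without replacement; with equal probability their
  imaging factor is offset by ±`discordance_magnitude` (default 3.0) or
  resampled from another group's range (rejection-retried until the
  decoupling invariant `|t − s| ≥ magnitude/2` holds, falling back to the
  offset). Concordant patients have `t = s` + small clipped noise, so the
  invariant characterizes the flag in both directions. The two branches
  emulate the two clinical discordance patterns: deviant imaging with
  preserved function, and disproportionate impairment with unremarkable
  imaging.

What the simulator does **not** emulate: real CT texture (embeddings are a
rank-3 factor model plus noise, so the VAE's task is easier and faster-
converging than on real ResNet features); within-group correlation between
clinical variables beyond the shared group; missingness (the emulated core
set is complete by design); longitudinal structure; DICOM metadata realism.
Passing tests therefore demonstrate that the pipeline recovers the kind of
structure it assumes, at the study's scale — not clinical performance on
real cohorts.

Ground-truth recovery under defaults (15% discordance, magnitude 3.0):
anomaly-score ranking separates injected discordant from concordant patients
with mean AUC ≈ 0.90 over seeds 0–4 (offset-branch patients are essentially
always ranked top; resampled cross-group patients — on-manifold in each
modality separately, anomalous only jointly — are recovered less reliably,
which is the expected hard case for reconstruction-based detection). With
`discordant_fraction = 0`, scoring a random pseudo-labelling gives AUC ≈ 0.5.

## Analysis conventions

Quantiles and percentile thresholds use linear interpolation between closest
order statistics; the threshold convention is `flag = score ≥ threshold`,
which for 41 distinct scores at the 85th percentile flags exactly 7 patients
(the threshold lands on the 35th order statistic). With all scores tied, the
threshold equals that value and every patient is flagged (degenerate limit
of the ≥ convention). Flags are invariant under strictly monotone transforms
of the scores.

The statistics battery is implemented from first principles so tests can pin
exact conventions: Kruskal–Wallis with tie correction (H undefined with
explicit "degenerate" status when all pooled values are identical); Dunn
pairwise z with tie-corrected variance and Holm step-down adjustment
(monotonicity enforced, capped at 1); Cliff's δ by exhaustive cross-pair
counting with conventional magnitude cutoffs 0.147/0.33/0.474; Spearman ρ on
average ranks with a two-sided t-approximation p-value and no
multiple-testing correction (the analysis is descriptive); percentile
bootstrap with 2000 seeded resamples (count and method are config-exposed;
the protocol states neither); PCA by eigendecomposition of the covariance of
standardized columns, components sign-fixed so each axis's largest-|loading|
element is positive.

## Problem sizes

Default analyses run at the study's own scale: 41 patients, d = 526,
200-epoch training (seconds on one CPU). Oracle equivalence uses 200 random
instances with group sizes ≤ 8; property tests use a few hundred generated
examples per invariant.

## Known limitations

In-sample scoring only; single Gaussian likelihood over mixed variable
types; no stability analysis across random initializations (config-exposed
seeds make one feasible); the shipped extractor is a frozen random
projection, not a pretrained CNN, so absolute embedding semantics are
synthetic; the anomaly score aggregates both modalities and does not
attribute deviation to imaging versus clinical input.
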