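# Methods

## Pipeline overview

`crossnorm` evaluates whether a subtype classifier trained on one expression
platform transfers to another. One experiment *cell* fixes a direction
(which platform trains), a DEG threshold `τ_DEG`, an NDEG threshold
`τ_NDEG`, a normalization method, and a classifier family. Per repeated run
the cell: (1) draws a stratified 75% training sample from the training
platform; (2) normalizes each platform independently, using the NDEG list
derived from the training platform; (3) restricts features to the DEG list;
(4) tunes the classifier by exhaustive grid search over stratified 10-fold
CV scored with weighted F1 (ties broken by enumeration order, so tuning is
deterministic); (5) predicts every sample of the other platform not drawn
into training, by ID match. Repeats are aggregated into per-metric means and
sample SDs and the Evalue.

Gene selection is computed once per cell on the training platform's full
labelled sample set, not on the 75% draw: the selection stage precedes
partitioning in the protocol, and the choice keeps DEG/NDEG sets constant
across repeats so that the Evalue measures partition stability, not
selection noise. No value or label of the test platform enters selection,
normalization fitting, or tuning at any point.

## ANOVA selection

For gene *g* with *k* classes and *N* samples,
`F = [Σ n_i(Ȳ_i − Ȳ)²/(k−1)] / [Σ Σ (Y_ij − Ȳ_i)²/(N−k)]`, with the p-value
from the upper tail of F(k−1, N−k). Degenerate cases follow the selection
semantics rather than erroring: a fully constant gene gets (F=0, p=1) so it
remains an NDEG candidate; zero within-class variance with distinct class
means gets (F=∞, p=0). Thresholding is strict (`p < τ_DEG`, `p > τ_NDEG`),
so boundary ties fall in neither set. Optional multiple-testing correction
uses the Benjamini–Hochberg step-up adjustment (`q` column); selection can
run on `q` instead of `p`. Default threshold grids are
`τ_DEG ∈ {0.001…0.01 step 0.001, 0.02, 0.03, 0.05, 0.07, 0.1, 1}` and
`τ_NDEG ∈ {0.85, 0.90, 0.92, 0.95, 0.98}`; `τ_DEG = 1` keeps all
non-constant genes and serves as the "no feature selection" arm.

## Normalization conventions

* **Percentiles.** Rank→quantile interpolation uses `(rank − 0.5)/n`;
  inverse-normal scores use `rank/(n+1)`. Both avoid ±∞ at the extremes.
  Ties always take average ranks; tied QN values receive the mean of their
  tied target positions, so equal inputs map to equal outputs.
* **Z.** Per-gene, population SD (ddof 0); constant rows map to zero rather
  than NaN.
* **LOG.** `log2(x + c)` with pseudo-count `c = 1` by default; negative
  input is rejected as a signal of already-logged data.
* **RQN.** The target is the per-rank cross-sample mean of the *reference*
  (NDEG) rows only; applying it maps each sample's G gene values at
  percentile `u = (rank − 0.5)/G` onto the target's empirical quantile
  function, whose node j of m sits at `(j − 0.5)/m`, with linear
  interpolation and end clamping. With reference = all genes and matching
  grids this reduces exactly to classic QN.
* **NICG.** Subtraction of the per-sample mean over reference rows, in log
  space (equivalently division on the linear scale); only the log-space form
  is exposed because the composite always applies it after LOG.
* **Fitting scope.** Normalizers are fitted per platform on that platform's
  own (training- or test-side) samples. Consequence worth stating plainly:
  `LOG_RQN` without the final Z keeps each platform on its own NDEG-derived
  scale — under a platform gain distortion the two normalized matrices
  remain globally offset, and per-gene distributional distance between
  platforms can even grow. The scale-free composites (`LOG_RQN_Z`,
  `LOG_NPN_Z`, `LOG_NICG_Z`) are where cross-platform alignment is
  measurable (the test suite checks that `LOG_RQN_Z` shrinks the mean
  per-gene Kolmogorov–Smirnov distance between platforms below both the raw
  value and plain Z). `LOG_RQN` still transfers classifiers well because the
  residual distortion after rank-mapping is a single global scale factor
  rather than a per-gene warp.

## Evaluation

Kappa uses `Po = trace/total` and `Pe = Σ row_i·col_i/total²`; the
degenerate `Pe = 1` case returns 0 with a warning. Balanced accuracy is the
unweighted mean of per-class recalls over the *fixed* class order; a class
with no true instance in a test split contributes recall 0 (with a warning)
rather than being dropped — conservative, since under heavy imbalance the
smallest class can vanish from a test draw. Specificity is one-vs-rest
TN/(TN+FP) macro-averaged; F1 is support-weighted; AUC is one-vs-rest
support-weighted on per-class probabilities, skipping (with renormalized
weights) classes absent from the truth.

The Evalue over r repeats is
`−100 · mean(κ) · mean(BA) · ln(max(sd(κ)·sd(BA), 1e−12))` with *sample*
standard deviations (ddof 1) and the natural log. The SD (not variance)
reading and the natural-log base are a calibration choice: with typical
repeat SDs of a few hundredths the formula produces scores in the hundreds,
the intended order of magnitude, whereas a variance reading would require
implausibly large spreads to do the same. The 1e−12 clamp keeps
zero-spread (e.g. fully deterministic) runs finite.

## Partitioning

Per-class training counts are `floor(0.75 · n_c)` — the one rounding rule
that reproduces training sizes of 390 and 389 from per-class counts
(98, 58, 231, 127, 8) and (96, 58, 231, 127, 8) respectively, with the
complementary cross-platform test set of 522 − 389 = 133 when all training
IDs exist on the other platform. A class too small to contribute
(`floor = 0`) is left out of training with a warning. Fold assignment deals
each class round-robin into k folds after a seeded shuffle, so per-class
fold sizes differ by at most one. Repeats derive their seeds as
`base_seed + repeat_index`; plans serialize to JSON for exact re-runs.

## Synthetic data generator

The generator emulates a two-platform tumor-subtype cohort: per-gene latent
log2 expression ~ Normal(8, 2²); planted DEGs (default 100 of 1000 genes)
add a shift of magnitude `effect_size × noise_sd` (default 2 within-class
SDs) to one carrier class; each platform observes latent plus independent
Normal(0, noise_sd²) noise (default SD 1) and exponentiates to the linear
scale; platform B additionally applies a monotone distortion — default a
power law `v ↦ v^1.3`, i.e. a 1.3× gain in log space — and carries two
platform-exclusive samples of the first class. Default class sizes
(96, 58, 231, 127, 8) give the 231:8 ≈ 29:1 imbalance typical of subtype
cohorts. Carrier classes are restricted to those with ≥ 20 samples so the
planted effects are statistically detectable at the design's sample sizes;
sign and carrier are drawn per gene. A small uniform per-entry missingness
(default 10⁻⁴) exercises the cleaning path; because cleaning drops any gene
with a missing value on either platform, even this small rate removes
roughly a fifth of genes at cohort-scale sample counts — recovery statistics
are therefore computed over genes surviving cleaning, since removed genes
are unobservable downstream.

What the generator does *not* model: count-based (negative-binomial)
RNA-seq noise, probe-level microarray effects, gene–gene correlation, and
batch structure within a platform. Passing tests therefore demonstrate that
the pipeline behaves correctly under a clean monotone platform distortion
with independent genes; they do not certify performance on real
cross-platform cohorts, where correlated genes and non-monotone artifacts
can matter.

## Problem sizes and defaults

Tests and the acceptance script run the generator at its default size
(1000 genes, 522 + 520 samples) with 3 repeats per cell and a singleton
linear-SVM grid for the benefit comparison; the full hyperparameter grids
transcribed in `harness.py` (LR C log-spaced 10⁻²…10¹, SVM linear/RBF,
RF/XGB tree grids, MLP architectures) are available for full experiments
via `ExperimentConfig`, with a `fast` profile (1–2 values per axis) for
desk-scale runs. The default generator seed is 20240225.

## Known limitations

* Gene selection once per cell (not per repeat) is a modelling choice; the
  alternative — reselecting inside each repeat on the training draw — is
  not currently exposed.
* The NDEG anchor assumes the reference genes are stable *within each
  platform*; reference sets contaminated by class signal degrade RQN and
  NICG in ways the generator only probes through its planted-null design.
* Probability outputs for SVM come from Platt scaling with an internal CV,
  so AUC values for that family carry extra stochastic variation (fixed by
  the per-repeat seed).
* `balanced_accuracy` penalizes classes absent from a test split (recall 0);
  comparisons with implementations that average only over present classes
  will differ exactly in that case.
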