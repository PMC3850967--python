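# Methods

## Overview

`episig` implements a pathway-activity inference workflow for epigenetic
regulators (EZH2, HDAC1, HDAC4, SIRT1, DNMT2) and the downstream analyses
that characterize how those activities relate to each other across tumors.
The workflow has five computational stages:

1. **Preprocessing** of probe-level expression matrices: log2 transform,
   quantile normalization, low-signal/low-variance probe filtering, RNA
   degradation QC (GAPDH 3'/5' ratio), per-batch adjustment, replicate
   averaging.
2. **Signature training** from two-class experiments (quiescent control
   cells vs cells with a pathway experimentally activated): gene
   selection, SVD metagene, Bayesian probit regression, LOOCV validation.
3. **Projection** of a trained signature onto an independent tumor
   compendium, yielding per-sample activation probabilities and
   within-dataset rescaled activity scores.
4. **Exclusivity analyses**: Spearman correlation matrices over pathway
   activities, 2x2 quadrant classification of a pathway pair, a
   co-activation deficit test against the independence expectation, and
   subtype association (one-way ANOVA plus enrichment fractions).
5. **Genomic correlates**: copy-number alterations specific to
   activity-defined extreme tumor groups, and sliding-window differential
   methylation with permutation-based false-positive calibration.

Everything is exercised end-to-end on synthetic data with known ground
truth generated by `episig.synthetic_data`.

## The signature model

Given a training matrix (probes x samples, log2 + quantile normalized)
and binary labels (0 = control, 1 = activated):

**Gene selection.** Probes are ranked by the regularized signal-to-noise
statistic `(mean1 - mean0) / (s_pooled + s0)`, where `s_pooled` is the
pooled within-class SD and the stabilizer `s0` (default: the median pooled
SD over all probes) prevents low-variance probes from dominating. The top
`n_genes` (default 200) are kept; exact ties break lexicographically by
probe id so selection is deterministic.

**Metagene.** Selected genes are standardized to mean 0 / SD 1 (ddof=1)
across training samples, and the genes x samples matrix is decomposed by
SVD. The first left singular vector `u` defines the metagene; sample `j`
scores `m_j = u^T x_j`, identically the first right singular vector entry
times the singular value. The sign is oriented so the activated class has
the higher mean score. One metagene is used throughout; the config keeps
an `n_metagenes` field reserved for the multi-component generalization.

**Bayesian probit.** `P(activated | m) = Phi(alpha + beta * m)` with a
weakly informative prior `(alpha, beta) ~ N(0, 100 I)`. The posterior is
sampled by data augmentation: truncated-normal latent variables given the
coefficients, then a conjugate bivariate-normal coefficient update.
Truncated normals are drawn by inverse CDF on the numerically safe tail
(via `ndtr`/`ndtri` of small positive arguments), so the sampler is stable
even under complete class separation. Predicted activation is the
**posterior mean of `Phi(alpha + beta m)`** over the stored draws, not
`Phi` at the posterior-mean coefficients — with a wide posterior the two
differ substantially, and the posterior mean gives smoother, better
calibrated probabilities.

Two numerical choices matter here:

* *Score standardization.* The probit operates on metagene scores divided
  by the training-score SD (stored in the model). Raw metagene scores
  scale with `sqrt(n_genes)`; on that scale a fixed prior is effectively
  rigid and the Gibbs chain's conditional step size (`~1/sqrt(X'X)`)
  becomes tiny relative to the posterior spread. Unit-scale scores make
  the prior genuinely weakly informative regardless of signature size.
* *Thinning.* Training perfectly separated classes leaves the likelihood
  flat over a half-space, so the posterior is wide and the data-augmentation
  chain strongly autocorrelated. Training chains therefore keep every
  10th draw by default (5000 draws after 1000 burn-in, i.e. ~51k
  iterations); without thinning the stored draws under-represent the
  posterior (intercept estimates varied by several units across seeds).
  LOOCV uses shorter unthinned chains (800 draws, 200 burn-in) because
  only the 0.5-probability decision is needed there, and it is insensitive
  to chain quality on separated data.

**LOOCV.** For each held-out sample the *entire* procedure — gene
selection, metagene, probit — is refit on the remainder, and the held-out
sample is scored with the refit model's training-parameter
standardization. Accuracy is reported at the probability-0.5 decision
boundary.

## Projection and rescaling

Signature genes are matched into the target dataset by shared identifiers
(error below 50% coverage, configurable); the loading vector is restricted
to matched genes and re-normalized. Target rows are standardized per gene
**within the target dataset** (default) — the only scale-robust choice
when projecting across platforms — with training-parameter
standardization available as an option. Zero-variance target genes are
dropped with a warning.

Raw probabilities are then log-transformed and linearly mapped within each
dataset so the scores span [0, 1] (`(log p - min)/(max - min)`; any log
base gives identical scores). A constant input maps to 0.5 and is flagged.
The fixed pipeline order is predict -> average replicates -> rescale.

**A property of this rescaling worth knowing:** the log transform
compresses the top of the probability range and stretches the bottom, so
the rescaled midpoint 0.5 corresponds to a raw probability near
`sqrt(p_min * p_max)` — typically a few percent — and well over half of
the samples in a dataset sit above it. The rescaled score is excellent for
ranking and cross-dataset comparison, but its midpoint is *not* a
meaningful activation cutoff.

## Activation calls and the co-activation deficit

Because of the property above, the package's default activation rule for
quadrant and enrichment analyses is the probit model's own decision
boundary: a sample is called activated when its **raw activation
probability exceeds 1/2** — the same rule LOOCV accuracy uses. (An
explicit numeric threshold on rescaled scores is supported everywhere;
analyses that follow published score cutoffs, such as the 0.5/0.2
extreme-group definitions, use those rescaled cutoffs directly.) In
simulation, thresholding rescaled scores at 0.5 calls ~90% of tumors
active for every pathway and leaves the planted exclusivity structure
undetectable, while the decision-boundary rule recovers it with marginals
near the latent activation prevalence.

For a pathway pair, samples fall into four quadrants (both / A-only /
B-only / neither). The independence expectation for co-activation is
exactly the product of the marginal activation fractions, and the deficit
is tested one-sidedly:

* `binomial` (default): `P(X <= both_active)` for
  `X ~ Bin(n, marginal_A * marginal_B)`. The marginals are estimated from
  the same data and co-vary positively with the observed count, which
  makes this plug-in test strongly conservative (measured type-I error
  ~0.4% at nominal 5%). It is kept as the headline measure because
  conservatism only strengthens a deficit claim.
* `fisher` / `fisher-midp`: the classical calibrated alternatives that
  condition on the observed margins (one-sided hypergeometric, optionally
  with the mid-p correction for discreteness; measured type-I ~3–4.5% at
  nominal 5%). Use these when the size of the test matters.

Subtype association uses one-way fixed-effects ANOVA of the rescaled
scores across subtypes (subtypes with fewer than 2 samples are dropped
with a warning) and reports the subtype composition of samples jointly
satisfying the configured high/low activation conditions.

## Genomic correlates

**Extreme groups.** Group 1 = pathway-A high & pathway-B low, group 2 the
mirror image, on rescaled scores. Under the default symmetric reading a
cutoff `c` means high > max(c, 1-c) and low < min(c, 1-c), so `c = 0.2`
selects the >0.8 / <0.2 corners and `c = 0.5` splits at the midpoint; an
asymmetric variant (high > c, low < c) is available.

**Copy number.** A gene is altered within a subgroup when its log2
tumor/normal ratio exceeds +0.5 (gain) or falls below -0.5 (loss) in at
least 20% of that subgroup's samples, evaluated within each subgroup
separately. Genes altered in both subgroups are removed — including the
conservative case of a gain in one subgroup and a loss in the other — and
the remainder are labeled subgroup-specifically; every gene gets exactly
one status.

**Methylation.** Probes are averaged over a centered window of adjacent
same-chromosome probes (default 5, truncated at chromosome ends), then
compared between the two groups by a Welch two-sample t-test on the window
means; features with p < 0.1 are kept. A literally *paired* test between
disjoint patient groups is not defined, so the window's probe-wise
aggregation carries the locality information instead — this substitution
is deliberate and visible in the API name. With window size 1 the
procedure reduces exactly to a per-probe Welch test. Error control
follows the permutation route: labels are shuffled (default 100 times)
preserving group sizes and the kept-fraction distribution is reported
(mean, spread, binomial SE); a Benjamini–Hochberg column is emitted for
convenience but is not part of the core procedure. The pooled sample
order is canonicalized so the estimate does not depend on which group is
called "1".

## Synthetic data generator

The generator produces every input with known ground truth:

* **Training sets**: per-probe baseline ~ N(7, 1) on the log2 scale
  (MAS5-like intensities after log transform), i.i.d. Gaussian noise
  (SD 1), and `+ effect_size * noise_sd` added to the signature genes of
  activated samples. The default effect size is 2 SD with n = 10 per
  class — strong, cleanly separable training data, as engineered
  overexpression experiments are designed to be. Optional additive batch
  offsets assign samples round-robin.
* **Tumor compendia**: latent activities per pathway are drawn from a
  Gaussian copula whose Pearson parameter is `2 sin(pi rho_s / 6)` of the
  target Spearman matrix (validated PSD; eigen-square-root used for
  sampling), then mapped through the normal CDF to [0, 1]. The default
  five-pathway target encodes the strong negative EZH2–HDAC4 dependence
  (-0.7), mild positive coupling among the deacetylases, and an
  embryonal-type positive EZH2–DNMT2 association. Expression adds
  `effect_size * noise_sd * activity` to each pathway's signature genes,
  so activity 1 matches a fully activated training sample. Subtypes are
  assigned by thresholding designated latent activities (basal-like =
  HDAC4 latent > 0.6; luminal-like = EZH2 latent > 0.6).
* **Quadrant counts**: an explicit multinomial generator over the four
  quadrant probabilities for exact-count tests and calibration studies.
* **Genomic matrices**: copy-number log2 ratios ~ N(0, 0.15) with planted
  gains/losses of ±0.8 in a configurable fraction of one group's samples;
  methylation values as clipped uniform-base + Gaussian noise with
  planted contiguous window shifts; coordinates on two synthetic
  chromosomes.

Every generator is a pure function of its seed and parameters.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level cross-hybridization and platform
effects, heavy-tailed intensity distributions, gene–gene correlation
beyond the planted pathway structure, overlap between signature gene
sets, copy-number/methylation effects that actually drive the expression
signal (alterations are planted independently given the groups), and
survival outcomes. Mutual exclusivity is generated through the latent
correlation structure rather than an explicit exclusion rule, so quadrant
deficits emerge from thresholding exactly as the analysis would detect
them in real data.

## Numerical and degenerate-input conventions

* Quantile normalization maps each column to the mean-of-order-statistics
  reference; ties receive the mean of the reference values they span.
  With that tie convention the transform is exactly idempotent only for
  tie-free columns (tied groups differing across columns perturb the
  second pass slightly); on continuous data idempotence is exact.
* The GAPDH degradation filter removes ratios strictly greater than 3
  (exactly 3.0 is kept); samples lacking control intensities are retained
  with a warning.
* Batch adjustment is per-gene location (optionally scale) alignment with
  global-mean restoration — a documented, pluggable approximation to
  heavier schemes such as distance-weighted discrimination, which needs a
  second-order-cone solver and per-dataset tuning.
* Probe-filter defaults (low-signal quantile 0.25, presence fraction
  0.25, variance quantile 0.25) are placeholders surfaced in config; any
  real dataset should set them from its own QC.
* Activation boundaries are strict everywhere (score exactly at a
  threshold is not active); zero-variance features are errors at training
  time and warn-and-drop at projection time; a degenerate rescale maps to
  0.5 and is flagged in metadata.
* All stochastic stages require explicit seeds; the pipeline derives each
  stage's generator deterministically from one master seed, and rerunning
  a fixed config reproduces every numeric artifact bitwise.

## Problem sizes

The shipped study and test suite run on one CPU in a few minutes total:
training sets of 10 + 10 samples with 200 signature genes among 500–2500
probes, compendia of 600 (pipeline demo) to 2000 (acceptance study)
tumors, 300–1000 genomic features, 100 permutations, and 500-replicate
calibration studies. These sizes were chosen so every statistical check
has comfortable power while the whole study remains quick to rerun; all
are configurable upward.

## Known limitations

* The probit posterior under complete separation is prior-dominated; the
  reported probabilities are then driven by the prior scale (100 by
  default) rather than the data. This is inherent to separable training
  sets, not a sampler defect.
* The binomial deficit test's conservatism (above) means its p-values are
  upper bounds; the margin-conditional variants should be quoted when
  calibration matters.
* Gene-level collapse of segment-style copy-number input uses a simple
  overlap mean; no segmentation uncertainty is propagated.
* Cross-platform projection relies on shared identifiers only; no probe
  re-mapping is attempted.
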