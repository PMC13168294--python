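# Methods

`neurosig` implements an end-to-end pipeline for building, thresholding,
interpreting, and clinically applying whole-brain multivariate signatures of
emotional experience and its regulation, exercised on synthetic multi-subject
voxel data.  This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic benchmark does and
does not establish.

## The decoding model

A *signature* is a linear decision rule over the in-mask voxels of a gray
matter mask: `decision(x) = w·x + b`, trained as a C-SVM with linear kernel
on paired condition images (+1 for the target condition, −1 for its control;
C = 1 by default, no feature scaling — contrast maps enter as-is).  The
libsvm solver (scikit-learn `SVC`) is used at tolerance 1e-6; an independent
dual-QP solve (SLSQP on the box-constrained dual) serves as the oracle in
tests.

Evaluation follows two paradigms:

- **Thresholded classification under LOSO-CV.**  Each subject is held out
  once; both of their images are scored by a model trained on everyone else.
  An image is classified +1 iff its decision value strictly exceeds the
  threshold (default 0); values exactly at the threshold count as incorrect —
  a conservative, deterministic tie rule.  n = number of held-out images
  (two per subject).
- **Two-alternative forced choice.**  Per subject, the condition whose image
  has higher *pattern expression* `w·x` is chosen; the intercept cancels, so
  the choice is invariant to any constant added to both images.  Equal
  expressions count as incorrect.  n = number of subjects.

Significance uses the exact binomial tail at chance 0.5.  The primary
statistic is the strict one-sided tail `P(X ≥ k | n, 0.5)`; the doubled tail
is reported alongside because published tables in this literature sometimes
print the doubled form (e.g. 2·0.5³³ ≈ 2.33e-10 at 33/33).  Accuracy SD and
95% CI come from a 1,000-resample bootstrap over subjects; the effect size is
Cohen's d of the within-subject expression differences against zero.
Reports of training-set forced choice are avoided in the analysis drivers:
SVM margins make within-training expression deltas nearly constant and the d
statistic degenerates; the held-out (LOSO) expressions are reported instead.

## Bootstrap thresholding and the encoding model

Decoder weights are not directly interpretable as activation: a voxel can
carry a large weight purely for noise cancellation.  Two steps address this.

1. **Subject-level bootstrap** (default 1,000 resamples; larger values are a
   config knob): the cohort is resampled with replacement, the decoder
   retrained per resample, and per-voxel z = mean/SE of the bootstrap weight
   distribution converted to two-tailed normal p (floored at 1/(n_boot+1))
   and Benjamini–Hochberg q.
2. **Haufe transform to an encoding map.**  With a single latent score
   s_t = w·x_t per trial, the general reconstruction
   A = cov(X)·W·cov(S)⁻¹ reduces to the per-voxel regression slope
   A_j = cov(x_j, s)/var(s), avoiding the voxel×voxel covariance.  Sample
   covariances use 1/(n−1) after per-subject trial-wise mean centering.  The
   transform is computed within subject on trial-level maps using the
   group-trained weights; group inference is a voxel-wise one-sample t-test
   (two-sided, BH-FDR q < 0.05).  A is equivariant under rescaling of w
   (w → cw gives A → A/c), so the map's direction does not depend on the
   arbitrary SVM weight scale.

Zero across-subject variance at a voxel leaves t = 0, p = 1 by convention
rather than NaN, so downstream thresholding needs no special-casing.

## JZS Bayes factors and voxel classification

Per voxel, evidence for/against activation is quantified by the
Jeffreys–Zellner–Siow default Bayes factor for the one-sample t statistic
(Cauchy effect-size prior, scale r = 0.707, "moderate effect"), computed by
adaptive quadrature of the prior integral after the compactifying
substitution g = u/(1−u) (relative tolerance 1e-8; the t-dependent power is
evaluated in log space).  BF10 is symmetric and strictly increasing in |t|
with a floor at t = 0 (≈ 0.14 at N = 59), so a BF10 threshold inverts
uniquely to a two-sided p threshold via Brent root-finding (BF10 = 5 at
N = 59 gives p ≈ 0.0067).

Voxels are classified by conjunction rules on the two regulation encoding
maps: *acceptance only* = positive activation with BF > 5 (and p below the
acceptance map's own FDR-derived p bound) for acceptance together with
BF < 1/5 for reappraisal; *reappraisal only* symmetrically; *common* =
supra-threshold positive evidence on both maps.  The p bounds are
data-dependent inputs recomputed from each map (the largest p among voxels
surviving q < 0.05), not constants.  "Positive activation" is
operationalized as a positive group encoding t at the voxel.

A conservativeness property worth stating explicitly: the BF < 1/5
requirement demands *positive evidence for the null* on the other map.
Under the null, only about half of t statistics are small enough to reach
BF10 < 0.2, at any sample size.  The recall of the "only" classes over the
true strategy-specific voxels is therefore capped near 50% by construction;
the classifier is precise rather than exhaustive, and the synthetic
benchmark tests precision over labeled voxels (observed ≈ 0.93) rather than
recall.

## Spatial-similarity interpretation

Region-level: each FDR-thresholded, positive encoding map is compared to
each parcellation region by cosine similarity against the region indicator,
and by occupancy (percent of region voxels surviving).  Relative
contributions renormalize occupancy across the three models within a region
(summing to 1 wherever any model overlaps).  A per-map normalized variant
(each region cosine divided by the map's maximum cosine over regions) is
the ribbon normalization.

Voxel-level: the joint distribution of the two z-scored regulation encoding
maps is partitioned into eight 45° sectors whose centers lie on the axes and
diagonals (x = reappraisal, y = acceptance): octant 1 = selective
acceptance+, 2 = shared+, 3 = selective reappraisal+, 4/8 = opposite signs,
5 = selective acceptance−, 6 = shared−, 7 = selective reappraisal−.
Boundaries at 22.5° + k·45° go to the lower-indexed adjacent octant;
exact-origin voxels are excluded.  Per octant, the voxel count and the sum
of squared distances from the origin are reported; the SSDs sum exactly to
Σ(z_r² + z_a²), a conservation law pinned in tests.

## Local versus whole-brain prediction

Sampling curves draw k voxels uniformly without replacement from a region
(fresh draw per repetition, per-repetition substreams; default 100
repetitions — a desk-scale setting, exposed in config) and evaluate LOSO
accuracy per draw.  When k equals the region size the draw is exhaustive and
every repetition equals the region-restricted LOSO accuracy exactly.  Curves
are summarized by a least-squares saturating fit acc(k) = a − b·exp(−k/c)
with a ∈ [0, 1]; the plateau a is the region's asymptotic performance.  The
saturating-exponential form was chosen for monotone saturation with the
fewest parameters; the literature's "parametric fit" is not more specific.
Searchlight decoding trains a LOSO decoder in a Euclidean sphere (voxel
units, center included, clipped to the mask) around every center; a
radius-3 sphere on the full lattice contains 123 voxels.

## Group application and the permutation test

Each subject contributes a pattern-expression delta (regulation minus
experience expression).  The group difference is tested by permutation:
pooled deltas are z-normalized, the difference of group means computed, and
subjects reassigned to groups of the original sizes per permutation (default
2,000; a desk-scale setting).  p = (1 + #{|null| ≥ |observed|})/(n_perm+1),
two-sided with add-one smoothing, hence floored at 1/(n_perm+1).  Because
the described procedure admits a second reading, a variant statistic — the
difference of the groups' forced-choice accuracies (fractions of positive
deltas) — is available by flag; neither is asserted as canonical.  Cohen's d
uses the pooled, (n−1)-weighted SD.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
brains.  Four unit-norm, mutually orthogonalized spatial components (compact
Gaussian blobs placed by greedy farthest-point sampling inside an ellipsoid
mask) represent negative experience, shared regulation, and the
acceptance-/reappraisal-specific processes.  Each condition-pair contrast is
a fixed amplitude-weighted sum of components; subjects multiply each
amplitude by a Normal(1, 0.2²) jitter (between-subject variance for LOSO and
group t-tests) and add i.i.d. Gaussian noise (contrast-level SD 1.0) plus a
spatially smooth component (SD 0.5, Gaussian kernel FWHM 2 voxels) and a
smooth per-subject background common to both images of a pair (SD 0.5; it
cancels in contrasts and forced choice, and stresses the threshold paradigm).
Trial-level maps carry a latent score (±1 plus Normal(0, 0.3) trial jitter)
driving the same effect pattern, which is what the Haufe reconstruction
consumes.  Defaults: 16×16×16 grid, ~2,200 in-mask voxels, 40 subjects, 12
trials per condition — the scale of the emulated paradigm, while keeping the
full test suite under a minute.

Amplitudes (8.0 experience; 4.0 shared + 6.0 specific for each regulation
contrast) were fixed so that the generator satisfies its stated
recoverability property with margin across seeds — group Haufe maps
correlate with the generating patterns at cosine ≈ 0.9 and held-out
forced-choice accuracy ≥ 0.95 — while within-subject effect sizes (d ≈ 1.8–3)
remain in the range strong task-fMRI contrasts exhibit.  The clinical
generator produces two cohorts sharing one ground-truth geometry (a common
structure seed) in which the second group's regulation amplitudes are
multiplied by an attenuation factor in [0, 1] while experience amplitudes
are untouched.

All randomness flows from a single seed through `numpy` SeedSequence
substreams (structure, then one stream per subject), so cohorts are
bit-reproducible and insensitive to parallel scheduling.

**What passing tests do not show.**  The generator's components are
orthogonal, compact, and stationary; real activation patterns overlap,
spread, and correlate across subjects far less cleanly, and real noise is
temporally autocorrelated and spatially heterogeneous.  Accuracy and
recovery figures on synthetic cohorts characterize the pipeline's
correctness and calibration, not expected performance on real fMRI data.

## Numerical conventions and degenerate inputs

- Vectorization scan order: first axis fastest (x, then y, then z), 0-based;
  fingerprinted, and models refuse data with a mismatched mask fingerprint.
- Out-of-mask voxels are written as 0 in all NIfTI outputs; affines are
  carried through but never used for resampling.
- Bootstrap resamples that collapse below two distinct subjects are redrawn
  and counted; bootstrap p is floored at 1/(n_boot+1).
- FDR is Benjamini–Hochberg (independence variant) via statsmodels.
- Constant maps: correlation is undefined (warned, NaN) while cosine is
  still returned; zero-norm thresholded maps give cosine 0 with a warning.
- The whole pipeline is deterministic given its seeds; no solver exposes
  hidden randomness.

## Known limitations

- Single-latent Haufe only; multi-class or multi-latent reconstructions are
  out of scope.
- No cluster-extent or TFCE inference; voxel-wise FDR only.
- The searchlight loops over centers in Python; it is sized for desk-scale
  grids, not 2-mm whole-brain volumes.
- Binomial inference treats the two images of a subject as independent in
  the LOSO threshold paradigm, as is conventional, though they share a
  training fold.
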