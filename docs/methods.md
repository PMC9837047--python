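# Methods

`bodymaps` implements an individual-differences analysis of bodily sensation
maps (BSMs): painted, signed rasters of where in the body people feel each of
ten emotions (anger, fear, sadness, happiness, disgust, surprise, pride,
shame, contempt, envy), analyzed jointly with a multi-scale personality
battery and per-emotion experience ratings. Because studies of this kind
rarely deposit raw data, the package ships a synthetic-cohort generator
whose
latent structure is planted and therefore known exactly; every analysis stage
is validated by recovering those planted effects.

## The generative model

A study consists of `n` subjects (default 228) painting one signed map per
emotion on a shared silhouette (default 120 x 44 pixels, ~1.7k inside the
body outline; positive = felt activation, negative = felt deactivation, one
signed channel per pixel). Maps are generated as

    map(s, e) = clip( sum_k score(s, e, k) * template_k
                      + lambda_s * c_raster * idiopattern_s + eps, -1, +1 )

* **Templates** (`K = 4`): unit-norm signed rasters for head/upper-chest
  activation, stomach activation, legs/feet deactivation (entirely
  non-positive) and heart activation. They are nearly orthogonal (pairwise
  |cosine| < 0.01 on the default mask).
* **Scores** combine four parts:
  `score(s,e,k) = mu(e,k) + 0.5 * prop(s,k) + lambda_s * u(s,e,k) + 0.15 * eta(s,e,k)`.
  `mu` is a fixed emotion-profile matrix (head strong in most emotions,
  stomach in disgust and the distress emotions, legs-deactivation in
  sadness/fear/shame/disgust, heart in happiness/pride/surprise). `prop` is
  the subject's component propensity, drawn from the copula below.
  `u` is the subject's idiosyncratic emotion profile, iid normal but
  **centered across emotions within subject** — it degrades how typical and
  classifiable a subject's maps are without moving the subject's
  emotion-averaged scores, so planted correlations are not attenuated by
  idiosyncrasy. `eta` is within-subject noise.
* `idiopattern_s` is a smooth subject-specific unit-norm raster
  (Gaussian-filtered white noise, sigma 4 px) with amplitude
  `c_raster = 0.25`; `eps` is iid pixel noise (SD 0.02). Both are kept small
  so that pipeline-recovered component scores correlate > 0.98 with the
  latents and attenuation of planted rank correlations stays below 0.02.

**Copula.** All subject-level latents — five personality factors (negative
affect, antisocial attitudes, positive affect, impulsivity, interoception),
four map propensities, an idiosyncrasy driver, and five rating latents —
are jointly Gaussian with correlations converted from target Spearman values
by r = 2 sin(pi rho_S / 6), which is exact for bivariate normal ranks. The
default planted Spearman targets are

| pair | rho |
| --- | --- |
| antisocial ~ stomach propensity | -0.207 |
| antisocial ~ heart propensity | -0.194 |
| impulsivity ~ head propensity | -0.172 |
| head propensity ~ mind-salience latent | +0.23 |
| heart propensity ~ body-salience latent | +0.17 |
| legs-deactivation propensity ~ body-salience latent | -0.16 |
| idiosyncrasy driver ~ antisocial | +0.484 (calibrated) |
| idiosyncrasy driver ~ impulsivity | +0.388 (calibrated) |

with all other pairs zero. The target matrix is checked for positive
semidefiniteness and sampling is via Cholesky.

**Idiosyncrasy calibration.** The subject's idiosyncrasy weight is
`lambda_s = 1.2 * Phi(z_driver)`. Representativeness (below) is a derived
statistic, so its correlation with a personality factor cannot be planted
directly; `calibrate_idiosyncrasy_link` measures, by Monte Carlo on
cohorts with the driver links removed, (a) the rank correlation between
representativeness and the driver and (b) the residual path from the factor
through its planted propensities, then solves for the driver-factor
correlation that lands the measured representativeness-factor Spearman on
its target (-0.18 for antisocial attitudes, -0.17 for impulsivity). The
defaults above are the frozen output of that calibration (40 cohorts).
Because the pipeline computes representativeness in grand-mean-centered
component space, the calibration does too — the centered and pipeline
versions agree at r = 0.996.

**Questionnaires.** Twenty scales load 0.92 (signed) on exactly one factor
each (e.g. psychopathy and social dominance positively and empathy
negatively on antisocial attitudes); uniqueness makes each scale's true
score unit variance. Items (default 8 per scale, 2 reverse-keyed, 1-5
Likert) discretize `0.9 * (true score + noise)` shifted by per-item
difficulty offsets spread over [-1.2, 1.2]; offsets make the keyed item sum
a fine staircase of the true score (without them the sum has about five
distinct values and rank correlations are badly tied). A paper-scale
battery (~536 items) is available through `n_items_per_scale`; the default
is desk-sized. One stated idealization does not survive discretization:
with zero item noise the Spearman correlation between a scale score and its
factor is slightly below 1 because round-and-clip produces ties (tested at
> 0.995, not 1).

**Ratings.** Five questions per emotion (body, mind, pleasantness, control,
frequency) discretize `0.8 * latent + offset(e, q) + noise` (SD 0.3) onto
1-5 Likert; offsets encode the expected emotion profile (pleasantness high
for happiness/pride, control low for fear, and so on).

**Non-compliance.** `inject_noncompliance` replaces `round(frac * n)`
subjects' items with iid uniform Likert draws (random responders) and zeroes
3-5 randomly chosen maps for a disjoint `round(frac * n)` subjects,
returning ground-truth flags for scoring the screens.

## Screening

* **Completeness rule:** subjects with >= 3 entirely empty maps (of 10) are
  removed. Missing emotion entries count as empty and are logged. Manual
  visual inspection of drawn symbols is not automated; the empty-map rule is
  the only reproducible criterion.
* **Random-responder screen:** a forward-search multivariate outlier
  procedure on item responses. The basic subset starts from the p + 1
  observations nearest the coordinatewise median (Mahalanobis about the
  median), grows by smallest scaled distance, and stops once it holds a
  majority and the next candidate exceeds the cutoff. Two corrections
  matter: subset covariances are Fisher-corrected by the truncation factor
  kappa(r/n, p), and the cutoff uses the out-of-sample distance law
  c(r, p) * F(p, r - p) at tail probability alpha/n (the algorithm's
  simultaneous form). The F form is essential here: with chi-square
  quantiles the clean-data flag rate at n = 228, p = 80 is ~32%; with the F
  form it calibrates to alpha across the regimes tested (p = 5 to p = 80).
  The alpha/n tail makes per-repetition false flags rare enough that the
  10% flag-rate removal threshold almost never removes a compliant subject,
  while uniform random responders are flagged in essentially every
  repetition. Because batteries can have more items than subjects, the
  screen runs on random 50% item subsets (capped at 0.8 n items for small
  cohorts) repeated `n_reps` times (default 1000); subjects flagged in more
  than 10% of repetitions are removed. The completeness and responder
  screens run independently on the full roster and the union is removed.

## Decomposition

* **Channels:** painting tasks collect activation and deactivation on
  separate silhouettes; how they are merged for analysis is a genuine design
  choice. The default combines them into one signed channel per pixel (one
  variable per pixel); `map_channels="split"` instead concatenates the
  nonnegative activation and deactivation parts (2P variables), with
  component naming running on the signed difference of the two channel
  loadings.
* **PCA:** maps use covariance PCA (pixels share units; observations are
  subject-emotion maps), personality uses correlation PCA (scales do not
  share units; observations are subjects). Eigenvalues are squared singular
  values over n - 1. A randomized truncated SVD is used when a small fixed
  rank is requested on the wide map matrix.
* **Retention:** sign-flip parallel analysis. Each of `n_perm` (default
  1000) permutations multiplies the centered (and scaled, for correlation
  PCA) matrix elementwise by iid +-1 — preserving per-cell magnitudes and
  hence robust to heterogeneous noise — and the observed eigenvalue must
  exceed the per-rank 95th-percentile envelope. Counting is contiguous from
  rank 1 and stops at the first failure, the standard parallel-analysis
  convention.
* **Quartimax:** pairwise Jacobi-style plane rotations with the closed-form
  angle maximizing the fourth-power criterion per pair, swept to a 1e-8
  criterion tolerance. (A gradient-projection solver stalls on the exact
  45-degree two-component case, which is a saddle of the criterion; the
  pairwise update does not.) After rotation each component is flipped so its
  largest-|loading| variable is positive, removing PCA's sign indeterminacy;
  scores are flipped consistently.
* **Component naming:** rotated map components are labeled by the body-region
  group (head+upper chest, stomach, heart, legs+feet, arms, torso) holding
  most of their squared loading mass, and oriented so the loading direction
  in that region matches the sign the cohort actually paints there
  (grand-mean map). A component pointing at a negatively painted region is
  a "deactivation" and higher scores mean more deactivation. Personality
  components are matched to the configured factor markers by greedy maximal
  |Tucker congruence| and sign-oriented to positive congruence.
* **Bootstrap loading z-scores:** observations are resampled with
  replacement `n_boot` times (default 1000); each bootstrap PCA + quartimax
  solution is aligned to the reference solution by greedy |Tucker
  congruence| matching with sign correction (ties break toward original
  column order); z = reference loading / bootstrap SD, with sd = 0 cells
  flagged NaN rather than dropped.

## Association

Emotion-averaged map-component scores are correlated with personality
component scores by average-rank Spearman correlation; p values use the t
approximation (exact/randomized permutation below n = 20). The
Benjamini-Hochberg step-up runs over the 5 x 4 component table; salience
(validation) correlations with the body/mind ratings are reported
uncorrected by default, with a flag to correct. Pixelwise one-sample t maps
set t = 0 with an undefined flag at zero-variance pixels. Extreme-group maps
average the ceil(pct% n) highest and lowest scorers (default 5%), ties
broken by subject id.

## Granularity

LDA (pooled-covariance Gaussian classifier, empirical priors; shrinkage
regularization only if the pooled covariance is singular, logged) predicts
the emotion label from the retained rotated component scores. Parametric
significance is a df = 1 goodness-of-fit chi-square of (correct, incorrect)
counts against the 10% chance proportion on full-data refit predictions;
cross-validated significance is the fraction of `n_splits` (default 1000)
subject-wise half/half splits whose test accuracy is at or below chance,
floored at 1/n_splits. Splitting by subject (all ten of a subject's maps on
one side) avoids leakage; an observation-wise mode exists. Per subject:

* **confidence** — mean posterior probability of the true label over the
  subject's maps (model fit on all data; a cross-validated variant exists);
* **differentiation** — mean pairwise cosine distance among the subject's
  ten emotion score-vectors (zero vectors skipped, denominator adjusted);
* **representativeness** — mean cosine similarity between the subject's
  per-emotion vector and the group-average vector for that emotion (group
  mean includes the subject; leave-one-out variant behind a flag).

Cosine metrics are invariant to the orthogonal rotation, so rotated and
unrotated retained spaces give identical values (asserted in tests). The
Sobel test (z = ab / sqrt(b^2 se_a^2 + a^2 se_b^2), two-sided normal p)
quantifies mediation of the antisocial-differentiation association by
representativeness.

## Recovery experiments and problem sizes

`experiments.run_recovery_cohorts` runs the full pipeline (screen ->
decompose -> associate -> granularity) on 100 freshly generated default
cohorts and reports the per-cohort recovered statistics; the distributional
tests compare their means to the planted values. Generator conditions are
never scaled. Iteration-heavy analysis settings are desk-sized in these
loops, as none of their outputs are scored there: personality retention uses
200 sign-flip permutations, the responder screen 10 item-subset repetitions
(flag rates are near 0/1 under the simultaneous cutoff, so few repetitions
identify responders exactly), classifier CV splits and loading bootstraps
are skipped, and the map rank is fixed at the four interpretable components
(the association stage's count) instead of a 1000-permutation test per
cohort. Component-count recovery is tested separately at the full 1000
permutations over 50 seeds. `scripts/acceptance.py` reruns these two
experiments from scratch and writes their headline numbers.

## What the synthetic data does and does not show

The generator emulates low-rank spatial structure, factor-structured
questionnaires, planted cross-domain correlations, subject idiosyncrasy and
gross non-compliance. It does not emulate: spatially correlated pixel noise
within maps beyond the smooth idiopattern, response styles other than
uniform random responding (acquiescence, straightlining), non-compliance
that mimics structure (drawn symbols), item-level multidimensionality, or
missing data. Passing recovery tests therefore demonstrates the pipeline's
correctness and calibration under the planted model, not robustness to
every artifact of real painted-map data. Statistics that depend on real-data
geometry (classification accuracy near 29%, a 55-component map space,
between-emotion template similarity of 0.77) are checked directionally, not
numerically: with idiosyncrasy present, group-average emotion vectors are
more similar to each other than individuals' are, representativeness and
differentiation are negatively correlated, and increasing idiosyncrasy
strictly decreases mean representativeness and mean confidence.

## Numerical choices and degenerate inputs

Tolerances: rotation orthogonality 1e-10; quartimax criterion tolerance
1e-8; eigenvalue/trace identities 1e-8. Constant columns in correlation
tables yield NaN with a logged reason and are excluded from the BH family.
Zero-variance pixels get t = 0 plus an undefined flag. Singular Hadi subset
covariances grow the subset or raise with advice to reduce variables;
singular pooled LDA covariances trigger auto-shrinkage. Empty maps
(surviving screening) are skipped in cosine metrics with the denominator
adjusted. All stage randomness derives from one master seed through named
substreams, so stages can be re-run independently and identical
(config, seed) pairs give byte-identical outputs.
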