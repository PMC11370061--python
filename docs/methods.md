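# Methods

This document specifies the models and numerical procedures implemented in
`motorstrat`, the default parameters with units and rationale, and the known
limitations. All defaults below are the package's *study conditions*: they
define the synthetic benchmark the test suite validates against.

## 1. Synthetic cohort generator (`synthetic.py`)

### Motor-profile tables

Each subject carries three standard-scored subscales — manual dexterity
(`md`), aiming & catching (`ac`), balance (`bl`) — plus their mean (`total`),
diagnosis, study site, assessment module, sex and age.

Scores are drawn from Gaussians with mean 10 and SD 3 (the standard-score
convention) and shifted additively:

- **Subtype structure (autism only).** A latent two-component mixture:
  fraction 0.44 belong to a *Low* motor-ability subtype whose `md`/`bl` are
  reduced by Cohen's d = 2.0 and `ac` by d = 0.45 relative to the *High*
  subtype; the High subtype sits 0.67 SD above the autism marginal mean so
  that the overall autism mean stays at the configured group level. The
  d = (2.0, 0.45, 2.0) pattern creates two well-separated clusters whose
  dominant axis is md/bl, with `ac` nearly uninformative — a realistic
  "one strong axis plus noise" geometry rather than a spherical toy problem.
- **Batch structure.** Additive offsets per study site
  (MEDEA 0, NDA1 +1, NDA2 −1; sampled with probabilities 0.5/0.3/0.2),
  assessment module (0, +0.5, −0.5 for modules 1–3, assigned from age:
  < 6.5 y → 1, < 10.5 y → 2, else 3) and sex (+0.3 for M; female fraction
  0.2). These are of the magnitude (≈ ⅙–⅓ SD) that makes correction
  worthwhile but leaves the subtype signal dominant.
- **Groups.** Defaults n = 156 autism, 149 TD, 23 DCD; ages uniform 3–16 y.
  The DCD group matches the autism marginal mean (a low-scoring clinical
  control).

Phenotype tables add IQ (mean 100, SD 15, reduced by d = 0.7 in the Low
subtype), age of independent walking (mean 13 mo, SD 3, delayed by d = 0.67
in Low), and null variables (age of first words, three ADOS calibrated
severity scores, SRS) that must *not* separate the subtypes — they exist to
expose false positives.

### Reach-to-drop trajectories

Trials are minimum-jerk point-to-point movements,
`s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`, for a reach (start → ball, 1.0 s) and a drop
(ball → castle, 0.8 s) separated by a 2-frame dwell, sampled at 60 Hz. Four
markers (elbow, ulnar wrist, radial wrist, hand dorsum) ride the wrist path
with rigid offsets; geometry is start (0, 0, 0), ball (250, 0, 50), castle
(400, 150, 150) mm. The analytic deceleration peak of a minimum-jerk reach
sits at τ = 0.5 + √(1/12) ≈ 0.7887 of movement duration (exported as
`MINJERK_DP_TAU`), which pins the segmentation oracle.

Motor noise is added as band-limited (8 Hz low-passed, unit-RMS) Gaussian
perturbation scaled per phase: group defaults
σ(feedforward, feedback) = (1, 1) mm for TD and High, (1.45, 1.15) mm for
Low. The 1.45/1.15 split encodes the target phenomenon — elevated noise
concentrated in the pre-planned phase — at whole-movement Cohen's d ≈ 0.8
and a detectable but not trivial group × phase interaction at n = 35 per
group. Per-subject amplitudes are log-normal around the group value
(CV = 0.30), and trial durations jitter by 3 % (SD), because identical
durations would make DTW degenerate toward the identity alignment. With
noise and jitter both zero the generator emits byte-identical trials and the
motor-noise score is exactly 0 — the calibration zero point.

What the generator deliberately does **not** emulate: grasp dynamics and
finger aperture, movement failures/restarts, marker dropout or occlusion,
drift or soft-tissue artifact, and any age dependence of kinematics.

## 2. Preprocessing (`preprocess.py`)

Tables are merged with keep-first deduplication on `subject_id`; subjects
outside the configured age window or missing ≥ 2 subscales are excluded,
with every exclusion and its reason logged to `exclusions.csv`.

Batch correction is ordinary-least-squares residualization: for each score,
fit `score ~ diagnosis + study_id + module + sex` with treatment coding
(reference = most frequent level) and subtract the fitted study, module and
sex contributions, keeping intercept and diagnosis. The projection is
idempotent — refitting on corrected data returns batch coefficients < 1e−8.
Aliased (perfectly confounded) factors are detected by QR with column
pivoting and reported by name (`ConfoundedDesignError`); single-level
factors are dropped with a warning; rows with missing scores are excluded
from the fit but retained (still missing) in the output.

## 3. Subtype discovery (`subtyping.py`)

Relative clustering validation over k = 2…10:

1. Split autism subjects 70/30, stratified on study × sex × module
   (strata with < 2 members are pooled).
2. On the training split, fit `StandardScaler` then UMAP
   (n_neighbors = 30, min_dist = 0.0, 2 components, Euclidean,
   random_state = 42) on md/ac/bl.
3. For each k: 100 repeats of 2-fold CV. In each repeat, k-means clusters
   each fold independently; a 5-nearest-neighbour classifier trained on one
   fold's labels predicts the other fold; labels are aligned by Hungarian
   assignment on the confusion matrix and the misclassification rate is
   normalized by the random-labeling asymptote (k − 1)/k.
4. Best k minimizes mean normalized stability (ties → smaller k). A final
   k-means is fitted on the training embedding; the validation split is
   embedded (UMAP transform), clustered independently, aligned into the
   training label space, and the agreement with the 5-NN prediction is the
   *generalization accuracy*. Cluster semantics (Low/High) are assigned by
   mean `total`.

The k-means inside the CV loop is a numba-compiled k-means++/Lloyd
implementation (10 restarts), numerically cross-checked against
scikit-learn; the final model uses scikit-learn's `KMeans`.

The Gaussian-null test computes the 2-means cluster index
(within-cluster SS / total SS about the grand mean) and compares it to
10 000 Monte-Carlo draws from a zero-mean Gaussian whose covariance
eigenvalues are floored at a robust background variance, (1.4826 · MAD)², of
the standardized data; p = (1 + #{null ≤ observed}) / (n_sim + 1).

**Known limitation.** UMAP with min_dist = 0 compresses even a single
spherical Gaussian into clumps, so the normalized-stability curve can show a
pronounced minimum at small k on unimodal data. On such inputs stability
alone over-detects structure; the Gaussian-null test is the guard and holds
its nominal level (empirically ≈ 0.5 % rejections at α = 0.05). Interpret
a stability minimum only together with a significant Gaussian-null p-value.

## 4. Kinematic motor noise (`kinematics.py`)

1. **Filtering.** 5th-order Butterworth low-pass at 8 Hz, zero-phase
   (forward–backward), on all 12 channels. Trials must exceed the filter
   pad length (18 frames).
2. **Velocity.** Tangential speed of the ulnar wrist marker via central
   differences (`np.gradient`) × sample rate.
3. **Segmentation.** The grasp is the speed minimum between the two
   principal speed peaks (≥ 250 ms apart); the deceleration peak is the
   first local maximum of deceleration after peak speed with prominence
   ≥ 5 % of the maximum deceleration. Feedforward = start → deceleration
   peak, feedback = deceleration peak → grasp, drop = grasp → end.
   Trials violating these assumptions raise `UnsegmentableTrial`; the
   subject is flagged and excluded from *phase* analysis only — the
   whole-movement score is still computed.
4. **DTW.** Multivariate (12-D Euclidean local cost), symmetric2 step
   pattern (diagonal steps weighted 2), both endpoints matched, normalized
   by N + M. The dynamic program is numba-compiled and validated against
   exhaustive enumeration of all warping paths.
5. **Score.** Motor noise = median of the 45 pairwise DTW distances among a
   subject's 10 trials; subjects with < 10 trials are excluded (flagged).

## 5. Inference (`inference.py`)

- `cohens_d`: pooled-SD standardized mean difference, sign = first minus
  second sample.
- `compare_groups`: Shapiro–Wilk (α = 0.05) on each group routes to Welch's
  t or the Wilcoxon rank-sum test.
- `anova_posthoc`: one-way ANOVA plus pairwise Welch contrasts with effect
  sizes.
- `aic_compare`: ΔAIC between two one-way OLS group codings of the same
  outcome (positive favours the second, finer coding).
- `fit_group_phase_lmm`: REML random-intercept model
  `value ~ group × phase + (1 | subject)` (statsmodels `MixedLM`). The
  interaction Wald χ² is converted to an F statistic with between–within
  denominator degrees of freedom (n_obs − n_subjects − n_fixed); singular
  fits fall back to OLS and are flagged (`singular_fallback`).

## 6. Numerical and reproducibility choices

- One global pipeline seed fans out to every stage through SHA-256-derived
  named substreams (`_seeding.substream_seed`), so stages are independently
  reproducible and adding a stage never shifts another stage's draws.
  Identical configuration ⇒ byte-identical CSV outputs (verified by
  manifest hashes).
- numba kernels are compiled per session (`cache=False`) so the repository
  contains no binary artifacts.
- Problem sizes in the test suite (20-seed subtype recovery, 100-run power
  checks, 1000-pair DTW oracle comparisons) are the package's own choice of
  statistical resolution versus runtime, sized to keep the full suite well
  inside a 25-minute single-CPU budget.
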