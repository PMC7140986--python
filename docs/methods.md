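# Methods

## Model and assumptions

The pipeline treats prognosis as a transfer problem: AD and NC subjects are
easy to separate, so a classifier trained on them defines a one-dimensional
"AD-likeness" axis per modality, and MCI subjects are placed on that axis.
The working assumptions are (i) progressive MCI resembles AD more than
stable MCI does, in every modality, and (ii) the modalities carry partly
complementary information, so concatenating their one-dimensional grades
retains the complementary signal while removing the dimensionality
imbalance between blocks (313 MRI columns vs 4 biological columns) that
makes direct feature concatenation kernel distances noise-dominated.

Grading models are trained once on the full AD/NC reference set and reused
across all cross-validation repetitions. This is not leakage: the reference
subjects are disjoint from the MCI evaluation set and no pMCI/sMCI label
ever reaches the grading stage (asserted structurally in the test suite by
wiping MCI conversion metadata and observing identical scores).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `C` | 1 | ELM regularizer; the solve is (Ω + I/C)⁻¹Y, so 1/C is a ridge penalty |
| `gamma` | 10·M | Gaussian kernel width, tied to the input dimension M of the stage (after feature selection for MRI; 10·K for the fused classifier) |
| `lasso.lambda` | 0.015 | L1 penalty on the literal objective ½‖y−Dα‖² + λ‖α‖₁ |
| `lasso.lambda_scale` | `literal` | `per_sample` multiplies λ by N for solvers that use the (1/2N)-scaled quadratic; the published value's convention is not recoverable from its source, so both are exposed |
| horizon | 36 months | conversion window defining pMCI; `strict` additionally excludes late converters and NC-reverters from sMCI |
| CV | k = 10, runs = 100 | repeated stratified k-fold; summary is mean ± sample SD (divisor n−1) over runs |

Response coding for the L1 step is AD = +1, NC = −1 with no intercept
(features are zero-mean on AD ∪ NC by construction). "Non-zero"
coefficients means |α| > 1e-8 after convergence at tolerance 1e-6 on the
maximum per-sweep coefficient change (max 10 000 sweeps).

## Numerical choices

- The ELM solve uses a Cholesky factorization, never an explicit inverse;
  Ω is PSD and I/C makes the system definite. A 1e-10 jitter retry exists
  only for pathological rounding and warns when used.
- Normalization SD is the population convention (divisor N); constant
  features on the reference rows are a hard error, not silently dropped.
- Classification ties (s₁ = s₂ exactly) go to the negative/reference
  class; the closed-form model defines no tie behavior, so this is a fixed
  convention.
- AUC is the rank (Mann–Whitney) statistic with half-credit ties, computed
  per run on the pooled out-of-fold grading scores, then averaged over
  runs. How to pool ROC information across folds is genuinely open; pooling
  within a run keeps every subject represented exactly once.
- Folds are stratified (class proportions preserved). With a roughly 1:2
  pMCI:sMCI imbalance, unstratified 10-fold splits occasionally produce
  degenerate folds; stratification prevents that and narrows run-to-run
  variance. A permutation that would still leave a single-class training
  set is redrawn with a warning.
- Fold permutations for run r come from `SeedSequence(seed, spawn_key=(r,))`
  and depend only on (labels, k, runs, seed), so the grading pipeline and
  the direct-concatenation baseline consume identical folds at equal seed,
  and score matrices are put in subject-id order before folding so results
  are independent of input row order.
- The coordinate-descent L1 solver can exhaust its sweep budget when the
  penalty is tiny relative to the design (e.g. the literal λ = 0.015 on a
  302 × 313 standardized design, which is nearly an underdetermined least
  squares problem). It then warns and returns the last iterate with
  `converged=False`; the per-sample scaling converges quickly.
- Extra covariates (e.g. neuropsychological scores) appended to the score
  matrix are z-scored with MCI-cohort statistics: the classifier only ever
  sees MCI rows, so reference-set statistics for these columns would be
  irrelevant to its input scale. This is an interpretation, flagged as
  such.

## Synthetic cohorts: what they emulate and what they do not

The generator draws class-conditional equicorrelated Gaussian blocks:
within a block each feature has unit variance and pairwise correlation ρ,
the first `n_informative` features carry a standardized AD-vs-NC mean
difference `effect_size` (±d/2), and MCI groups are attenuated copies of
the poles (pMCI mean = a·AD mean, sMCI mean = a·NC mean, a = `mci_mixing`).
APOE carrier status is Bernoulli per group. Conversion times for pMCI are
exponential (scale 22 months) truncated at the 36-month horizon, which
places roughly 40–50% of conversions inside the first year, matching the
strongly front-loaded conversion pattern of observational MCI cohorts; 15%
of the stable group converts after the horizon and 15% reverts to NC, so
strict labelling has realistic exclusions (~64 of 205).

The `adnilike` preset fixes group sizes 102/200/110/205 and block widths
313/20/3/1 with moderate effects (0.8/0.9/1.0 SD on 25/8/3 informative
features, ρ = 0.1–0.2, carrier frequencies 0.65/0.25/0.60/0.35,
a = 0.6). Each block's informative subspace is independent of the others,
i.e. the modalities are complementary by construction.

What this does *not* emulate: realistic neuroanatomical covariance
(morphometrics are far from equicorrelated), heavy-tailed or skewed assay
distributions, site/batch effects, age and education confounding, and
measurement missingness. Passing tests therefore demonstrate that the
implementation behaves correctly under the stated generative model — null
calibration, signal recovery, fusion benefit, concatenation inferiority —
not that the published clinical effect sizes are reproduced; the synthetic
preset's separations are chosen for testability, and its absolute CV
metrics (high 80s) should not be read as clinical performance.

## Problem sizes used in checks

End-to-end checks run the study-shaped preset (617 subjects) for fusion
comparisons and lean cohorts (300–400 subjects, 3 × 10–20 features) for
calibration and signal-recovery curves, with 3–5 cross-validation
repetitions per condition; the repetition count changes only the precision
of a run-mean, not its expectation. The acceptance script uses 100
repetitions for the fused and single-modality summaries and 20 for the
direct-concatenation baseline (whose per-fold kernels are the costly
step).

## Known limitations

- Binary APOE carrier status is z-scored like a continuous feature; allele
  dosage (0/1/2) is not modeled.
- λ is fixed, not tuned; elastic net, stability selection and nested
  hyperparameter search are out of scope.
- Only two-class problems; the feed-forward random-hidden-node ELM variant
  is not implemented (the kernel variant is deterministic and strictly
  better behaved for this use).
- Subjects missing any modality must be excluded upstream; there is no
  imputation.
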