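# Methods

This note documents the scientific model behind `cuefuse`, the assumptions it
makes, the defaults it ships with, and the numerical and inferential choices
in the implementation.

## 1. Scientific question

When a visual area represents depth from two cues — binocular disparity and
relative motion — two architectures are possible:

- **Independence**: separate populations encode each cue. A decoder reading
  both can combine them, but no better than stacking two independent
  channels.
- **Fusion**: single units encode a combined depth estimate. Fusion predicts
  (i) two-cue sensitivity *exceeding* the independent combination of the
  single-cue sensitivities, (ii) a *cost* when the cues conflict, and
  (iii) *transfer*: a decoder trained on one cue generalizes to the other.

The package quantifies all three predictions for multivoxel decoding data and
for behavioral discrimination data.

### Core statistics

Decoding accuracy `p` is converted to sensitivity

    d' = sqrt(2) * erfinv(2p - 1),

which equals the standard-normal quantile of `p`. Accuracies are clamped to
`[1/(2n), 1 - 1/(2n)]` (n = test-pattern count) before conversion so `d'`
stays finite at floor/ceiling.

The **integration index** compares the two-cue condition against the
quadratic-summation bound — the sensitivity an independent architecture
achieves by Pythagorean combination:

    phi = d'_{D+M} / sqrt(d'_D^2 + d'_M^2) - 1.

`phi = 0` is the independence bound; `phi > 0` indicates fusion. `phi` is
scale-invariant and exactly 0 for any Pythagorean triple.

The **transfer index** normalizes cross-cue decoding by within-cue decoding:

    T = 2 d'_T / (d'_D + d'_M),

with `T = 1` meaning full generalization across cues.

The congruency contrast is the raw accuracy difference
(congruent − incongruent); fusion predicts it positive, independence predicts
zero.

## 2. Generative model

### Units

A population of `n_units` units comes in three kinds. For a stimulus whose
disparity and motion carry depth signs `d, m ∈ {−1, 0, +1}`:

- disparity-only units respond `A·s·d`,
- motion-only units respond `A·s·m`,
- fusion units respond `A·s·(d+m)/2`,

where `A` is `tuning_amplitude` and `s ∈ {±1}` is the unit's preferred depth
sign (drawn uniformly, so the population is balanced). Every response gets
additive Gaussian noise with sd `unit_noise_sd`; fusion units' noise is scaled
by `fusion_noise_gain = 1/√2`, the variance reduction of an optimal average
of two equally reliable estimates.

Consequences built into this choice:

- Congruent stimuli drive fusion units at `A` with reduced noise, so a pure
  fusion population has congruent sensitivity `2/√2 = √2` times the quadratic
  sum of its single-cue sensitivities (`phi = √2 − 1 ≈ 0.414` at the unit
  level).
- Incongruent stimuli cancel exactly in fusion units (`(d − d)/2 = 0`), so a
  pure fusion population decodes incongruent depth at chance. Mixed
  populations fall between the extremes, which is what makes the decoding
  profile informative about the fusion fraction.

### Voxels

Each voxel is a fixed sparse nonnegative mixture of units: a random 25%
subset (`mixing_sparsity`) with `U(0,1)` weights, plus voxel-level Gaussian
noise (`voxel_noise_sd`). Weights are fixed per dataset; unit and voxel noise
are drawn per block.

### Timing

Blocks follow the reference block design: 24 16-s stimulus blocks per run
(3 per stimulus label, randomly ordered), 16-s fixation flanks, TR 2 s —
416-s runs of 208 volumes. Block responses are embedded as boxcars delayed by
a 2-volume hemodynamic shift on a zero baseline. The generator emulates the
block structure, shift, and population mixing; it does not model hemodynamic
convolution shape, drift, physiological noise, or spatial autocorrelation —
none of which the inference chain depends on.

### Defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| `n_units` | 200 | large enough for stable mixing, cheap to simulate |
| `f_fusion` | 0.35 | a mixed population as the generic default |
| `tuning_amplitude` | 1.0 | free scale; only signal/noise ratios matter |
| `fusion_noise_gain` | 1/√2 | optimal-combination variance reduction |
| `unit_noise_sd`, `voxel_noise_sd` | 6.0 | put single-cue decoding in the 65–80% band at the default design, where the quadratic-summation test is informative (off floor and ceiling) |
| `n_voxels` | 300 | a mid-sized ROI |
| `mixing_sparsity` | 0.25 | sparse but overlapping voxel sampling |
| `n_runs` | 10 | a realistic single-session scan count |

The noise calibration was validated against a closed-form oracle: with the
true voxel covariance `C = W diag(σ_u²) Wᵀ + σ_v² I` and class-mean
difference `s`, the optimal decoder's sensitivity is `d'² = 4 sᵀC⁻¹s`;
under `f_fusion = 0` the oracle integration index stays at 0 up to mixing
variability, confirming the generator itself sits on the independence bound.

### Behavior

A two-interval observer reports the depth-offset sign of a target with
internal Gaussian noise per condition (plus optional lapse and bias). The
`fusing` constructor sets congruent noise to the optimal combination
`1/σ_C² = 1/σ_D² + 1/σ_M²` and incongruent noise to the worse single cue.
Default runs present 12 offset magnitudes × 2 signs × 15 trials = 360 trials
per condition.

## 3. Analysis pipeline

Order is fixed and mirrors the decoding analysis the statistics assume:

1. **Z-score per run, per voxel.** Zero-variance voxels are zeroed, not
   dropped, to keep indexing stable.
2. **Shift + block averaging.** Each block's pattern is the mean of its 8
   volumes delayed by the 2-volume shift.
3. **Voxel selection.** Two-sample pooled-variance t of all stimulus patterns
   against fixation patterns; top 150 voxels by t. If fewer than 150 have
   t > 0, all and only the positive-t voxels are kept. The contrast is
   orthogonal to the near/far labels, so selection does not bias decoding.
4. **Per-pattern mean-centering,** removing univariate baseline differences.
5. **Linear SVM (C = 1), leave-one-run-out.** Accuracy is the
   count-weighted mean of per-fold accuracies. Decision values of exactly 0
   are scored as errors (deterministic, conservative tie policy).
6. **Transfer decoding** trains on one cue's patterns and tests on the other
   cue's patterns from the held-out run, in both directions; the transfer
   accuracy is the direction average. Optional recursive feature elimination
   (drop the 10% smallest |weight| per step, floor 50) runs inside each
   outer training fold only.

## 4. Inference

### Bootstrap (two-level)

Indices are bootstrapped by resampling cross-validation folds (runs) with
replacement, jointly across conditions, then — the second level — redrawing
each resampled fold's correct count from a binomial at that fold's accuracy.
The second level matters: per-fold accuracies from 6 test patterns are
themselves noisy, and resampling folds alone treats them as exact, which
makes intervals materially too narrow under the independence null; the
binomial level restores near-nominal coverage. Fold-only resampling
remains available via `two_level=False`. One-sided p-values are
`(1 + #{samples ≤ null}) / (B + 1)` with `B = 10,000` by default.

### Group analysis

Independent sessions are pooled by concatenating their folds
(`merge_decoding_results`); the bootstrap then resamples session-folds as
exchangeable units. Detection of fusion in a single 10-run session is
underpowered at α = 0.01 — the point estimate is fine but 60 test patterns
per condition leave the interval wide, and scanning longer pushes the
congruent condition to ceiling where `d'` saturates. The reference analyses
therefore pool ~5 sessions, which scales the standard error by ~1/√5 without
moving any condition closer to ceiling.

### Permutation baseline for transfer

The chance level of the transfer index is estimated by shuffling the
training-condition near/far labels within each run, recomputing both
cross-cue directions (pooled over sessions in the group variant), and
rebuilding `T` against the observed single-cue sensitivities; 1,000
permutations, significance = exceeding the 95th percentile.

### Multiple comparisons

`bonferroni(p_values, alpha)` rejects at `alpha / m` across a family of
tests (e.g. many ROIs).

## 5. Mixture recovery

`simulate_profile` maps a fusion fraction to a four-condition accuracy
profile (mean ± SEM over replicate simulated datasets); `build_mixture_grid`
tabulates fractions 0, 0.1, …, 1.0; `chi2_fit` minimizes

    chi²(f) = Σ_conditions (emp − sim(f))² / (SEM_emp² + SEM_sim²)

over the grid. The reference setting uses ten replicates per grid point and
five per empirical profile: the SEMs enter the weights, and with fewer
replicates (2 df at 3 replicates) the weights are unstable enough to
misplace the minimum. Ties break toward the smaller fraction and are logged.

Identifiability is not uniform in `f`. At low fusion fractions the profile
is nearly flat: congruent decoding at `f = 0` already combines both
single-cue unit types (the quadratic-sum geometry), and the incongruent
condition loses sensitivity only as `sqrt(1 − f)` because population `d'²`
is additive over the remaining single-cue units. One 0.1 grid step then
moves the profile by roughly 0.015 accuracy — a `d'`-ratio effect that no
overall noise rescaling changes — so resolving a single grid step at low `f`
requires on the order of thousands of test patterns per condition per
profile point. At desk-scale data volumes the fit is precise for `f ≳ 0.5`
(where the incongruent condition collapses steeply) and coarse below it;
recovered fractions in the flat region should be read as order-of-magnitude
estimates rather than grid-step-accurate values.

## 6. Searchlight

Sphere offsets are all integer lattice offsets whose world distance
(offset ∘ voxel size) is within the radius — 123 voxels at 3 mm radius on a
1-mm isotropic grid. Per center, in-mask sphere voxels are mean-centered and
decoded with the same cross-validation contract as the ROI analysis; centers
with fewer than `min_voxels` (default 10) get NaN. Group maps are per-voxel
one-sample t against chance, with t = 0 where all subjects sit exactly at
chance and NaN propagated from any subject.

## 7. Psychophysics

Per-level sensitivity uses the bias-corrected `d' = (z(H) − z(F))/2` from
"farther"-response rates to farther/nearer targets, with the same `1/(2n)`
clamping. Condition-level sensitivity comes from a maximum-likelihood
cumulative-Gaussian fit of P("farther") against signed offset (parameters:
bias μ, spread σ, lapse ≤ 0.1; L-BFGS-B on log σ). The j.n.d. is the
50%→84% offset of the fitted curve — exactly one σ — and sensitivity is its
reciprocal. The behavioral quadratic-summation test bootstraps trial
resampling + refitting to compare congruent sensitivity against the
quadratic sum of the single-cue sensitivities and against the incongruent
condition.

## 8. Numerical and design decisions

- All randomness flows through `numpy.random.SeedSequence` spawning; a
  single seed determines unit assignment, mixing weights, block orders, and
  noise independently, so changing one stage's draws cannot silently shift
  another's.
- Derived child seeds are reduced mod 2³¹ for portability.
- Accuracy clamping uses the test-pattern count actually behind each
  proportion.
- `phi` is undefined when both single-cue sensitivities are 0; bootstrap
  resamples where this happens are dropped, and the estimate is flagged
  unreliable if more than half are lost.
- The SVM is `sklearn.svm.SVC(kernel="linear", C=1)`; no probability
  calibration, no class weighting (classes are balanced by design).

## 9. Limitations

- The voxel model is linear with Gaussian noise and no temporal structure;
  it supports validating the inference chain, not forecasting effect sizes
  in real data.
- The strict-averaging fusion unit makes incongruent responses cancel
  exactly at `f_fusion = 1`; real populations likely show partial
  cancellation (robust fusion), which here corresponds to mixtures rather
  than the pure-fusion extreme.
- Decoding accuracy saturates near ceiling, where `d'` (and hence `phi`)
  is compressed by the clamp; analyses should be designed to keep the
  two-cue condition off ceiling, as the defaults do.
- The permutation baseline shuffles training labels only; it tests transfer
  above chance, not above a cue-specific confound model.
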