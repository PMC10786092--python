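# Methods

This note documents the models implemented in `rsamediate`, the defaults of
the synthetic-data generator, the numerical conventions, and the design
decisions taken where the underlying procedure left room for choice.

## 1. The analysis chain

**Preprocessing.** Trials whose absolute amplitude exceeds ±100 µV at any
channel/timepoint are rejected (the threshold applies per trial across the
whole epoch); epochs are decimated to 100 Hz by sample selection;
participants with fewer than 10 retained trials are excluded (strict `<`,
so exactly 10 is retained). The rejection screen runs on the analysis rate
(after any decimation). No baseline correction is applied by default and no
anti-alias filter precedes decimation — the generator's signals are smooth
Gaussian envelopes; a zero-phase Butterworth low-pass hook
(`preprocess.lowpass`) exists for data that need it.

**Neural RDMs.** At each timepoint, condition topographies are trial means
per condition. The channel covariance is estimated from condition-demeaned
single trials with the analytic Ledoit–Wolf shrinkage estimator (target:
scaled identity; intensity in [0, 1] chosen analytically). Estimation is
**per timepoint** by default — the demeaned trials at that timepoint only —
matching the per-timepoint topography framing and keeping estimates local;
a pooled per-epoch mode is available (`cov_mode="per_epoch"`). The
Mahalanobis distance between condition means uses a Cholesky solve; a
conditioning diagnostic (squared ratio of Cholesky diagonal extremes, a
lower bound on the condition number) rejects numerically singular
covariances. The Ledoit–Wolf implementation is vectorized over timepoints
for speed and is asserted in tests to agree exactly with
`sklearn.covariance.LedoitWolf(assume_centered=True)`.

**RSA regression.** The 28 unique off-diagonal pairs of the 8x8 RDM are
extracted in a fixed canonical order (conditions ordered lexicographically
as race {A, W} x pain {N, P} x gender {F, M}; row-major upper triangle) and
z-scored with the population-SD convention (divide by n). The z-scored
neural vector is regressed by OLS-with-intercept on the three z-scored
binary model vectors. The intercept is redundant for z-scored inputs but is
kept deliberately as a guard against convention drift. A per-race subset
mode (4 conditions, pain + gender models on the 6 unique pairs) mirrors the
separate-races analysis.

**Cluster inference.** One-sample t per timepoint over participants within
0–600 ms; runs of |t| above the two-tailed critical value at p<0.05 form
clusters split by sign; the statistic is the summed t (mass). The null is
built by randomly sign-flipping each participant's whole time course and
taking the **maximum |mass| across both signs** per iteration — this
pools the two tails and controls two-sided family-wise error (the
calibration test holds the empirical FWER in [0.01, 0.10] at nominal 0.05).
Cluster p-values use the +1-corrected Monte-Carlo estimator
`(1 + #{null >= observed}) / (1 + n_permutations)` and can never be zero.
Adjacency is strict temporal contiguity on the analysis grid; no gap
bridging. Zero-variance timepoints are flagged with a warning and
contribute t = 0 (so all-zero input yields an empty cluster list rather
than an error).

**Traits.** EG/RI scores are config-driven item-mean composites over 1–7
Likert ratings, *not* latent factor scores — latent estimation (EFA/CFA/
SEM) is out of scope, and the composite approximation is validated by the
sign-recovery tests. Orthogonalized scores are standardized OLS residuals
of one standardized trait on the other; by construction
corr(EG_orth, RI_raw) = 0 exactly. Note that orthogonalization is not a
projection onto a mutually orthogonal pair: corr(EG_orth, RI_orth) = -r.
Quantiles for the extreme-group contrast use linear interpolation with
boundary-inclusive membership (ties at the quartile boundary join the
group). The rank-sum test is Mann–Whitney U (exact for small untied
samples); an all-constant outcome returns p = 1 directly.

**Mediation.** Model-4 layout: a from M ~ X (+covariates), b and c' from
Y ~ X + M (+covariates), c from Y ~ X (+covariates); indirect = a·b; path
p-values from classical OLS t tests. The CI is **bias-corrected (BC), not
BCa** — percentile endpoints shifted by 2·z0 with
z0 = Phi^-1(fraction of bootstrap estimates below the point estimate), no
acceleration term — matching the convention of the macro this mirrors. The
bias-correction fraction is clipped to [1/(B+1), B/(B+1)] so z0 stays
finite when all bootstrap draws fall on one side. Degenerate resamples
(zero-variance X or M) are redrawn and counted. Missing data are handled
complete-case with the retained n reported. The no-covariate bootstrap path
uses closed-form OLS vectorized over resamples; tests pin it to statsmodels
and to the normal-equations solution at 1e-10.

**Sampling variability.** With-replacement resampling of participants at
each grid size, 1000 resamples by default; reported intervals are
**quantiles of the resampling distribution** (2.5/97.5 and 0.5/99.5
percentiles) plus the min–max range — "confidence interval" here follows
the resampling usage, not an analytic CI. Undefined correlations
(zero-variance resamples) are redrawn and logged.

**Size grid.** `log_spaced_sizes(n_min, n_max, n_intervals)` is uniform in
log2 and anchored at `n_max`: sizes are `floor(n_max * 2^(-k*h))` with the
step `h = log2(n_max/n_min)/(n_intervals-1)` snapped to the nearest quarter
of a doubling when that is within 0.01 (the default grid is then a
halve-every-four-steps ladder). This floor-of-quarter-doubling convention
is the one that reproduces the canonical 25…676 twenty-size grid exactly;
no single rounding of an unsnapped geometric grid does.

**A-priori SEM sample size.** `westland_min_n` returns the larger of
(i) an effect-detection bound `ceil(0.48 * (z_{1-alpha/2} + z_power)^2 /
tau^2)` with `tau = (2/pi) * asin(effect)` — a Kendall-concordance
detection bound with a conservative variance constant of 12/25 — and
(ii) the structural bound `ceil(50 r^2 - 450 r + 1100)` for
r = observed/latent. The published calculator this operationalizes does not
disclose its exact sub-formula; the variant above is pinned here because it
reproduces the calculator's worked values (679 at effect 0.15 / power 0.95
/ alpha 0.05; structural 138 at r = 5.5) and is monotone in every argument
(non-increasing in effect and alpha, non-decreasing in power). The bound is
a lower bound on adequacy, not a power analysis for a specific SEM
topology.

## 2. The synthetic cohort (the stated world)

Each participant's condition-mean topography is a sum over the three
stimulus dimensions d of

`amplitude_d * s_d(condition) * envelope_d(t) * v_d`,

where `s_d = ±1/2` codes the condition's category, `envelope_d` is a
Gaussian in time centered at the dimension's peak latency, and the `v_d`
are orthonormal random spatial patterns drawn once per cohort seed.
Trial noise is Gaussian with exponential spatial correlation
`Cov_ij = sigma^2 * exp(-|i-j|/lambda)` across channels and white over
time. Defaults:

| parameter | default | rationale |
|---|---|---|
| channels | 30 | scalp montage after mastoid removal |
| sampling rate | 100 Hz | analysis rate; 81 samples over -200..600 ms |
| trials/condition | 64 | 2 presentations x 8 face models x 4 blocks |
| race / pain / gender amplitude | 2 / 1 / 1 µV | race geometry stronger than pain; equal-order effects |
| race, pain peak | 140 ms | early race/pain extraction |
| gender peak | 300 ms | later gender extraction |
| envelope SD | 30 ms | keeps 120–160 ms window race/pain-specific |
| noise | sigma^2 = 16 µV², lambda = 3 channels | single-trial SNR well below 1, full-rank spatial correlation |
| gamma_EG, gamma_RI | +0.3, -0.3 | opposite trait -> race-strength paths |
| b, c'_EG, c'_RI | 0.3, +0.1, -0.1 | mediated plus small direct paths (indirect = ±0.09) |
| EG–RI correlation | 0.3 | positively related interdependence subcomponents |
| shock scale | 0.8–3.4 mA, anchors 1.5 / 2.8 | physical scale and conflict anchors |
| behavioral noise | 0.25 mA (diff), 0.1 mA (low anchor) | keeps clipping at the scale edges rare (<10%) |
| items | 5 EG + 4 RI, loading 0.8, noise SD 0.8 | 9-item two-factor questionnaire; composite-latent r ≈ 0.91 |

The latent race strength is `gamma_EG*EG + gamma_RI*RI + e`, with the
residual variance chosen so the latent is exactly unit-variance; the
per-participant race amplitude multiplier is
`max(0, 1 + 0.5 * race_strength_z)` (clipping at zero is rare, ~2%, and
logged in the hidden ground-truth columns). Punishment decisions are
`low_anchor + noise` and `low + 1.3 mA + b*race_z + c'*traits + noise`,
clipped to the shock scale. Likert items are
`clip(round(4 + 0.8*latent + noise), 1, 7)`.

**What the generator emulates:** dimension-specific representational
geometry with realistic latencies, spatially correlated channel noise,
trait-modulated race representation with opposite signs, questionnaire
measurement error, a known mediation structure on the physical shock
scale, and artifact spikes only insofar as tests inject them.

**What it does not emulate:** real ERP component morphology (P1/N170),
temporally correlated (1/f) noise, ocular/muscle artifacts, face-stimulus
low-level confounds, item-level acquiescence or reverse-keyed wording, and
floor/ceiling behavior of real shock choices. A green recovery test
therefore establishes that the *pipeline* recovers what was embedded — not
that real EEG would behave this way.

## 3. Numerical conventions and edge cases

- Population-SD (divide by n) z-scoring throughout RDM vectorization and
  trait standardization; regression intercepts always included.
- Canonical condition order is carried explicitly by `ModelRDMSet`; RDM
  pair order is the row-major upper triangle of that order.
- Constant RDMs, zero-variance traits, collinear model vectors, perfectly
  collinear traits, singular covariances and empty extreme groups raise
  typed errors (`DegenerateDataError` etc.) rather than propagating NaNs.
- All randomness flows through `numpy.random.default_rng` seeds; every
  stochastic function takes a `seed` argument, and the pipeline spawns
  per-stage seeds from a single global seed. Fixed seed => bit-identical
  outputs.
- Epoch serialization is plain text (wide CSV + label CSV + JSON header),
  chosen over binary EEG formats so artifacts remain diffable and the
  package has no I/O dependency beyond pandas.

## 4. Known limitations

- Factor composites stand in for SEM factor scores; absolute trait-path
  magnitudes are attenuated relative to latent-variable estimates (sign
  and ordering are preserved — this is what the tests assert).
- The cluster test is temporal-only (no channel adjacency, no TFCE).
- The Westland effect-bound sub-formula is a reconstruction (see §1); its
  worked-example agreement is exact, but other argument combinations may
  deviate from the published calculator by small amounts.
- Mahalanobis distances are not cross-validated (no crossnobis), so RDM
  entries carry a positive noise bias that the z-scoring largely absorbs.
- Acceptance-style Monte-Carlo tests scale the per-run problem size
  (participants per cohort, trials per condition) below the original
  study's n=676 to fit a single-CPU budget; repetition counts and all
  generator effect sizes are unchanged.
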