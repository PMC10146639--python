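# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the known limitations of the package.

## Preprocessing

A raw sample is a 32 × T matrix of sensor resistances with a baseline window
(carrier gas only) preceding an exposure window (sample gas at full
concentration).  The processing order is smooth → detrend → respond:

1. **Savitzky–Golay smoothing** per sensor.  Defaults: window 11 samples,
   polynomial order 3 — mild smoothing that suppresses replicate noise while
   preserving the exposure plateau; both are configurable.  Interior points
   use the standard local least-squares fit (delegated to
   `scipy.signal.savgol_filter`); within half a window of either boundary
   the polynomial is refit per point on the truncated window (degree reduced
   when the truncated window holds fewer than `polyorder + 1` points) and
   evaluated at that point.  This edge rule keeps the filter exactly
   polynomial-preserving over the whole trace.
2. **Baseline correction**: a straight line is fit to the smoothed baseline
   window, extrapolated over the full trace and subtracted, re-anchored so
   the corrected baseline mean equals R0.  R0 is the baseline-window *mean*
   (not the first point), matching the physical reading of "resistance under
   baseline gas flow" as a steady level and giving robustness at no cost.
3. **Response**: per sensor, `ΔR/R = (max over the exposure window − R0)/R0`
   computed on the smoothed, corrected trace.  Negative responses are kept —
   the formula is signed and polymer-composite resistance can fall.

ΔR/R is exactly invariant under multiplying a whole trace by any c > 0, and
preprocessing is strictly per sample.  Baseline-window length and the
smoothing parameters are declared defaults, not values inferred from any
instrument; both windows must span at least one smoothing window.

The manufacturer-flagged humidity-sensitive sensors (5, 6, 23, 31, 1-based)
can be disabled via a mask; masked responses are still computed and carried,
only excluded from model fitting and correlation.

## Recognition model

Training data are autoscaled (zero mean, unit SD per active sensor —
correlation-matrix PCA, the standard chemometrics choice for heterogeneous
sensor gains; a mean-centering-only switch is exposed), reduced to `n_pc`
principal components (default 4), and a two-class Fisher canonical axis is
fit in PC space:

    w ∝ S_pooled⁻¹ (m̄₁ − m̄₂),     S_pooled = within-class scatter / (n − 2)

Classification assigns the nearer centroid along w with equal priors; an
exact midpoint score goes deterministically to the first class label
(labels are kept sorted, so "asthma" before "control", and the axis is
oriented so that first label has the lower mean score — a pure serialization
convention).  The M-distance is

    M = sqrt((m̄₁ − m̄₂)ᵀ S_pooled⁻¹ (m̄₁ − m̄₂))

with the conventional M > 3 flag for strong discrimination.  When
`cond(S_pooled) > 1e10` a ridge `1e-8 · trace(S)/k` is added; constant
(zero-variance) sensors are dropped with a warning.  `n_pc` may not exceed
`min(active sensors, n − 1)`.

Two properties worth stating precisely:

* With **no truncation** (`n_pc` = number of active features) the composite
  map autoscale → PCA → CDA is a full-rank affine transform, and M is
  exactly invariant under any invertible affine transform of the training
  data.  With truncation (`n_pc` < p) invariance necessarily breaks —
  truncation is not affine-equivariant — so the invariance test runs in the
  no-truncation regime.
* With truncation, the fitted M slightly **underestimates** the population
  separation when the discriminative direction is imperfectly captured by
  the estimated principal subspace (about 7–9% at n = 100/class, p = 32,
  k = 4 in the simulation conditions below), while small n inflates it
  (training-set optimism); at n = 11 the inflation dominates.

## Cross-validation

"Double" leave-one-out: scaling, PCA and the canonical axis are refit on
every training fold; the held-out sample only ever passes through frozen
projections.  The API offers no entry point for reusing a full-data
projection, and a test counts fit invocations to keep it that way.
Leave-one-out is the natural fold structure at cohort sizes around eleven.
The CVA is formatted by *truncation* to two decimals
(`floor(10000·k/n)/100`, integer arithmetic): 7/11 → 63.63, 8/11 → 72.72,
9/10 → 90.00.  The instrument's proprietary onboard cross-validation figure
(CVV) is not reproduced; the same truncation formatting is exposed for it.

## External validation and its reporting conventions

A frozen model classifies a labelled validation cohort; asthma is the
positive class; the truth-vs-prediction table has rows = truth, columns =
prediction.  Metrics: accuracy (tp+tn)/n, sensitivity tp/(tp+fn),
specificity tn/(tn+fp), PPV tp/(tp+fp), NPV tn/(tn+fn); a metric with an
empty denominator is *undefined*, never zero.  Formatting: point estimates
floored to integer percent; 95% Wald intervals `p̂ ± 1.96·√(p̂(1−p̂)/n)` with
bounds rounded to one decimal and clipped to [0, 100]; degenerate
proportions (0/n, n/n) give the zero-width interval the Wald formula
implies.  These conventions reproduce the printed accuracy/PPV/NPV cells of
small e-nose validation studies digit-for-digit; no standard method
(Wald, Wilson, Agresti–Coull, Clopper–Pearson) reproduces the printed
sensitivity/specificity intervals of the study this pipeline models, so
those cells are reported under the same Wald convention without claiming
agreement.  No multiple-testing correction is applied.

Association tests on the 2×2: uncorrected Pearson Σ(O−E)²/E (zero marginal →
statistic 0, p = 1 by convention), Yates with the continuity correction
floored at zero, single-stratum Mantel–Haenszel = (n−1)/n × Pearson, and the
two-sided Fisher exact test (total probability of tables, at fixed margins,
no more likely than the observed one; delegated to
`scipy.stats.fisher_exact`, cross-checked in tests against exhaustive
hypergeometric enumeration).  The pooled/Welch summary-statistics t-test is
included for cohort-characteristics comparisons.

## Reproducibility

Duplicate agreement is the Pearson correlation *across sensors* within a
pair — one r per subject, the only reading consistent with per-subject
tabulation.  Significance uses `t = r√(m−2)/√(1−r²)` on m − 2 df, where m is
the number of active sensors: 32 by default, 28 under the humidity mask (the
df follow the mask).  A pair passes at r ≥ 0.8.

## Synthetic cohorts

The generator emulates a two-group pediatric breath-print study:

    x_ij = A (μ_c + b_i) + h_ij u + ε_ij

* `A`: 32 × q orthonormal-column loading matrix (q = 4 latent VOC factors),
  drawn deterministically from the seed via QR with fixed column signs — no
  shipped fixtures needed.
* `b_i ~ N(0, σ_subject² I_q)`: subject effect, shared by duplicate samples
  of a subject, independent across subjects (duplicates are minutes apart,
  so no day effect is modelled).
* `h_ij u`: additive rank-one humidity nuisance supported on sensors
  5, 6, 23, 31 (equal weights, unit norm), `h ~ N(0, σ_humidity²)`.
  Masking those four sensors removes it exactly.
* `ε_ij ~ N(0, σ_noise² I_32)`: replicate noise; σ_noise > 0 is required for
  a positive-definite covariance.

The latent class-mean difference lies along the first factor and is rescaled
so the *population* Mahalanobis distance under the full marginal within-class
covariance `Σ = σ_s² A Aᵀ + σ_h² u uᵀ + σ_n² I` equals the configured δ to
1e−9.  Ground truth (class means, Σ, realized δ) is returned alongside every
cohort.

Nuisance magnitudes are free parameters (the emulated studies report none);
the defaults were chosen once, analytically, to give Cyranose-scale ΔR/R
values (a few percent) and a duplicate-pair across-sensor correlation around
0.85, matching the published reproducibility regime: σ_subject = 0.04,
σ_noise = 0.006, σ_humidity = 0.01, drift SD 1e−5 per time step, trace white
noise 1e−4 (relative).  Cohort-size defaults mirror a small training model
(6 asthma vs 5 control).

Raw traces wrap the same response vectors (identical seed ⇒ identical x) as
`R_s(t) = R0_s (1 + x_s g(t) + d_s t + η_s(t))`, with g = 0 over the
baseline quarter of the trace, a linear ramp over the next fifth, and an
exposure plateau at exactly 1, so preprocessing recovers the generating
responses by round trip (within 1e−3 in the drift- and noise-free setting;
the residual is Savitzky–Golay overshoot at the ramp-to-plateau corner).
Defining the exposure window as the plateau keeps the max-based response
formula faithful for negative responses too.

One structural consequence: the seed fixes the *population* (loading matrix,
class means), not just the sampling noise.  Independent cohorts from the
same population — e.g. a training set and an external validation set — are
obtained by splitting one simulated cohort, not by changing the seed.

What the generator does **not** emulate: adsorption kinetics or temperature
effects of real polymer sensors, inter-device variation, day-to-day drift,
non-Gaussian VOC distributions, or comorbidity structure in controls.
Passing tests therefore demonstrate correctness of the analysis machinery
under a Gaussian latent-factor model with known separation — not clinical
performance on real breath data.

## Problem sizes and Monte-Carlo design

Distributional checks use cohorts of 100 per class, where leave-one-out
refits 200 models in a fraction of a second.  Under the equal-covariance
Gaussian model the Bayes accuracy is Φ(δ/2); mean leave-one-out CVA is
compared to 100·Φ(δ/2) at δ ∈ {1, 2, 3} over three seeds (±5 points).  The
fitted-M recovery check at δ ∈ {3.13, 5.55} averages five cohorts: a single
cohort of 200 has a Monte-Carlo SD near 13% of δ, so a one-seed comparison
against a ±15% band would be underpowered by construction; averaging tests
the same property with adequate power.  The duplicate-pair pass-fraction
check uses 200 pairs against a per-subject Fisher-z oracle that accounts for
the heterogeneity of each subject's true across-sensor correlation.

## Serialization

Models and reports are JSON with a `format_version` field, sorted keys and
Python's shortest-round-trip float encoding, so re-running a stage rewrites
byte-identical output and read-back reproduces classifications exactly.
Reports carry the configuration hash (SHA-256 of the canonical JSON) and
seed for provenance.  Breath prints travel as CSV
(`sample_id, subject_id, group, [replicate,] s01..s32`, comma-delimited,
decimal point, parsed with round-trip float precision); raw traces as long
CSV (`sample_id, subject_id, group, sensor, t, resistance`).  The sensor
mask is an analysis *setting*, not data, and is applied at read/fit time.

## Known limitations

* Two classes only; no multi-group canonical analysis, kernel or shrinkage
  discriminants, feature selection, ROC/AUC, or k-fold variants.
* The M-distance after PC truncation is not affine-invariant and carries
  the opposing small-sample biases described above.
* The Wald interval is used because it reproduces the published convention;
  it has poor coverage near 0 and 1 and degenerates at 0/n and n/n — it is a
  reporting convention here, not a recommended interval.
* The simulator's humidity term is additive and exactly removable by
  masking; real humidity effects are not.
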