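# Methods

This note documents the models and procedures implemented in
`fmriboot`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic cohorts do and do
not show about real data.

## Survey design

The unit of analysis is a *pseudo-study*: a with-replacement draw of n
participants from a full cohort whose own analysis is treated as the
gold standard.  The default grid follows common practice for this kind
of survey: study sizes {20, 40, 60, 80, 100} with 100 bootstrap
replicates per size.  Seeds form a hierarchy: a master seed spawns a
`numpy` `SeedSequence` child keyed by (size, replicate), so any single
pseudo-study is reproducible in isolation and replicates are mutually
independent.

For the prediction level, a fixed 20% holdout test set is split off
once per survey and reused by every study size and replicate, so all
models are scored on identical data.  Bootstrap studies for prediction
are drawn from the training pool only — the test set never overlaps any
training sample — and the gold-standard model is trained on the same
training pool.  Gold standards for the other three levels use the full
population.

## Synthetic cohorts

**Contrast maps.**  A true-effect field d(v) is a sum of isotropic
Gaussian blobs (peak Cohen's d and width in mm are configurable; the
four conventional effect classes use peaks 0.1 / 0.35 / 0.65 / 1.0).
Subject maps are `d(v) * noise_sd + N(0, noise_sd)` i.i.d. across
subjects and voxels, the simplest model for which the population
d = μ/σ equals the configured field exactly.  Real contrast maps have
spatially correlated noise; consequences of the i.i.d. choice are noted
under Limitations.  An optional per-subject jitter of blob centers
(default 0 mm) emulates across-participant variation in peak location.

**Parcellation.**  A full-grid mask is partitioned into contiguous
cuboid regions by recursive bisection along the longest axis (a 6×6×6
grid with 8 regions yields the eight octants); regions get network
labels round-robin over seven names, standing in for the canonical
resting-state networks.  The affine is the identity scaled by the voxel
size (default 2 mm).

**Connectome cohort.**  A latent score z ~ N(0,1) per subject shifts
the population correlation of `n_causal` randomly chosen edges by
`edge_slope * z` (sign random per edge, default slope 0.25) around a
base correlation of 0.1; the per-subject correlation matrix is
projected to the nearest valid correlation matrix when needed and time
series of length T (default 300) are drawn from it.  The trait is
`sqrt(R2) * z + sqrt(1 - R2) * noise`, so the population variance
explained by the true edge values is exactly the configured `target_r2`.
The defaults (slope 0.25, T = 300) keep finite-length estimation noise
in the edge estimates small relative to the latent signal, so the
configured R² is attainable by the downstream model; 24 smooth
random-walk columns stand in for motion parameters.

## Statistical kernels

- **Regional activation:** one-sample t per region (df = n−1,
  two-sided), Holm step-down across regions at α = 0.05.  Two-sided
  tests are used throughout, consistent with the power arithmetic
  below.  Zero-variance inputs return p = 0 when the mean is nonzero
  and p = 1 otherwise, with a warning.
- **Effect sizes:** d = mean/sd with the n−1 denominator (required for
  the Hedges factor to apply exactly).  Pseudo-studies are multiplied by
  the exact gamma-function small-sample factor
  J = Γ(df/2) / (√(df/2) Γ((df−1)/2)); the gold standard is left
  uncorrected (its n makes the correction negligible).  Note J(2) = 0 —
  at one degree of freedom the bias of d is unbounded.
- **ICC(C,1):** (MSR − MSE) / (MSR + (k−1) MSE) from the additive
  two-way ANOVA; the confidence interval is the McGraw–Wong
  F-distribution interval.  Negative estimates are reported as-is, not
  floored at zero.
- **Binary ICC:** one-way random-effects ANOVA moment estimator on the
  0/1 matrix, with a percentile bootstrap over units (100 resamples)
  for the interval.  All-identical matrices are flagged degenerate.
- **Power:** noncentral-t with noncentrality d√n.  The minimum n for
  80% power at α = 0.05 (two-sided) is 15 at d = 0.8, 34 at d = 0.5,
  and 199 at d = 0.2; the routine is verified in the tests against an
  independent chi/normal numerical integration.

## Peak localization

The group t-map is converted to z by quantile matching of the t(df) CDF
to the standard normal (tail-stable survival-function form).  TFCE uses
E = 0.5, H = 2 and a threshold step of 1/100 of the positive map range
(the method's conventional defaults); negative values receive an
enhanced value of 0 — the positive-contrast convention, matching the
removal of negative activation at thresholding.  The familywise
threshold is the (1−α) quantile of the max-TFCE distribution over
sign-flip permutations of the subject maps; when the full 2^n
enumeration is no larger than the requested permutation count it is
used exactly.  Peaks are voxels strictly greater than all in-bounds
26-neighbours, so tied plateaus produce no peaks and edge voxels are
compared only against existing neighbours.  Gold peaks come from the
raw (unthresholded) t-map, deduplicated to the tallest per region,
top-10 by height.  In validity proportions, studies with no
supra-threshold peak remain in the denominator and are tallied; in
reliability they are excluded and counted.  Peak-level permutation
testing defaults to study sizes of 40 and below (it dominates the
survey's cost); the cap is configurable.  Note that a coarse threshold
step can create exact ties in the enhanced map and displace strict
maxima; the default of 100 steps keeps this quantization below the
voxel scale in practice.

## Prediction pipeline

Cleaning runs detrend → 0.01–0.1 Hz fifth-order zero-phase Butterworth
band-pass → columnwise standardization → least-squares confound
regression, in that order; confounds are detrended and filtered
identically before the regression so filtering cannot reintroduce
removed nuisance signal.  Columns whose variance is numerically zero
after filtering are left unscaled rather than amplified.  Connectivity
is the Ledoit–Wolf-shrunk covariance converted to correlation, clipped
to ±(1 − 1e−7), Fisher-z transformed, and flattened over the strict
lower triangle in fixed row-major order.

The ridge pipeline screens features with training variance below 0.01,
robustly scales survivors (median / IQR from training only; zero-IQR
features dropped with a count), and picks the penalty from
10^linspace(−1, 4, 20) by exact leave-one-out cross-validation: with an
unpenalized intercept the LOO residual is (y_i − ŷ_i)/(1 − h_ii), where
the smoother diagonal is 1/n plus the diagonal of G(G + αI)^{-1} for
the centred Gram matrix G.  One eigendecomposition of G serves the
whole grid; the selection criterion is mean squared LOO error.  Scores
are Spearman correlation and R² = 1 − SSE/SST on the holdout, with R²
reported as max(R², 0); permutation significance shuffles the test-set
trait and uses the add-one estimator p = (1 + #{|r*| ≥ |r|})/(B + 1),
so p is never zero.

## Numerical and degenerate-input choices

- Highest-density intervals for detection proportions come from a
  Jeffreys Beta(s + ½, n − s + ½) posterior, minimizing interval width
  at 95% coverage.
- Rank correlations use average ranks for ties; zero-variance voxels
  are excluded from correlations and ICCs with a logged count.
- Target-region selection breaks ties by ascending region id; the
  rank-correlation validity is computed over the target regions by
  default, with an option for all regions.
- Constant predictions, all-identical binary matrices and
  zero-variance coefficient vectors are flagged rather than silently
  dropped, and flags survive report round-trips.

## Problem sizes used in the checks

The calibration and pattern checks in the test suite run at desk scale:
familywise-error calibration of the TFCE permutation procedure uses a
10³ grid with 8 subjects (256 exhaustive sign-flips, a 25-step TFCE
sweep) over 150 null cohorts; Holm calibration uses 400 regions over
1000 cohorts; effect-size recovery uses 5000 subjects on a 12³ grid;
prediction recovery uses 2000 training subjects with 16 regions; the
sample-size pattern checks use populations of 400–1200 with 15–40
replicates per size.  Assertion slacks are set from the Monte-Carlo
error at those sizes.

## Limitations

- Subject noise is spatially white.  Regional averaging over v voxels
  therefore shrinks noise by √v, which inflates regional effect sizes
  relative to real data where noise is spatially correlated; the
  regional analyses are exercised with correspondingly small
  voxel-level effects.  Passing tests show the machinery is calibrated
  under this model, not that real cohorts behave identically.
- No hemodynamics, task structure, drift, motion artifacts, or surface
  geometry are simulated, and geodesic (surface) peak distances are out
  of scope; distances are Euclidean in mm under an identity affine.
- The binary ICC point estimator is the ANOVA moment estimator;
  equivalence with latent-threshold Monte-Carlo estimators implemented
  elsewhere is not claimed.
- Bootstrap pseudo-studies drawn from a small population share
  participants, which biases reliability estimates upward; the package
  demonstrates this overlap effect directly (prediction ICC is higher
  when resampling a small pool than a large one under a matched
  design), so absolute reliability values should be read with the
  source-population size in mind.
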