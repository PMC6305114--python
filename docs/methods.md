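# Methods

## Overview

`lesionvario` quantifies the morphology of a 3D binary white-matter-lesion
mask with geostatistical variography and tracks its longitudinal evolution
across a cohort. The chain is:

1. directional empirical variograms of the indicator field (x, y, z axes);
2. an exponential variogram-model fit per axis, giving a range `a` (mm) and a
   sill `c` per direction;
3. reduction to two coordinates, `A = mean(ln a_x, ln a_y, ln a_z)` and
   `C = mean(ln c_x, ln c_y, ln c_z)`, one point per mask in the lesion
   discrimination plot (LDP), plus the total lesion volume (TLV, cm³);
4. per-gender 2-component Gaussian-mixture subgrouping of the baseline
   (A, C) points;
5. longitudinal statistics: box-whisker summaries, Kruskal–Wallis and
   Mann–Whitney tests, LDP evolution vectors, and a linear mixed model for
   the gender contrast in the dynamic subgroups.

## The variogram of a binary mask

For the indicator field z (lesion voxels 1, others 0) and an axis-aligned
lag h in mm,

    gamma(h) = (1 / (2 n(h))) * sum over pairs (z(x) - z(x + h))^2,

i.e. half the discordant fraction of the n(h) voxel pairs at that
separation. For a 0/1 variable gamma is bounded by 0.5, and for an i.i.d.
Bernoulli(p) field it concentrates at the indicator variance p(1 − p); for
lesion masks its plateau therefore tracks the lesion-volume fraction, while
the rate at which it rises tracks the pattern's spatial continuity (smooth,
extended lesions rise slowly; fragmented patterns rise fast).

The estimator runs over the full rectangular grid as stored (zeros outside
lesions count), the complete-grid convention of classical grid geostatistics;
no brain-mask restriction is applied. Only pure-axis lags are computed —
that is all the LDP consumes. A brute-force implementation
(`variogram_bruteforce`, explicit enumeration of every pair) is kept in the
package as a verification oracle and is tested to agree exactly with the
vectorised estimator.

## Exponential model fit

The model `gamma_model(h) = c (1 − exp(−3h/a))` reaches ~95% of its sill at
h = a. It is fitted by unweighted least squares over all reported lags (two
parameters, no nugget). Numerical choices:

* initialisation: `c0` = mean of the top quartile of gamma values, `a0` =
  smallest lag with gamma ≥ 0.95·c0 (fallback: max lag / 3);
* bounds: `a ∈ [lag_step/10, 10·max_lag]`, `c ∈ (0, 0.5]`; a fit pinned at a
  bound is reported as non-converged — it means the model family does not
  describe the data in that window;
* `r² = 1 − SS_res/SS_tot` about the mean of the gamma values used, on the
  same lags as the fit;
* a variogram that is identically zero (constant mask) raises a degenerate
  error rather than returning numbers.

### Lag window

`max_lag` defaults to 40 mm, appropriate for full-size (MNI-like, ~180 mm)
grids. Empirical variograms of a bounded pattern are only reliable while the
lag is small relative to the field: beyond that, hole effects and asymmetric
pair loss at the grid faces dominate, and no two-parameter exponential can
absorb them. The fitting driver therefore caps the fitted window at
`extent_fraction = 0.25` of the per-axis extent (16 mm on the default 64³
synthetic domain), which reproduces the same window-to-extent ratio that
40 mm gives on a full-size grid. When a fit still pins at a bound — the
variogram is still rising at the window edge, so the range is not identified
— the driver widens the window (2×, then 3×, capped at 60% of the extent)
before reporting failure. Both knobs are exposed in `VariographyConfig`.

## LDP descriptors and evolution vectors

`A` and `C` use natural logarithms ("logarithmic scaling" alone would be
ambiguous). Log scaling lets mild and severe lesion loads share one plane;
the price is that distances are semi-quantitative, so vector magnitudes
(`sqrt(dA² + dC²)`) should only be compared loosely. Increasing A and C
corresponds to lesion growth/confluence; decreasing A and C to shrinkage and
breakup of lesion aggregates. Descriptors whose per-axis fit r² falls below
0.8 are flagged (never dropped) in output.

Per-subgroup "total vectors" connect the componentwise medians of (A, C) at
the first and last timepoints. Componentwise medians are used rather than
the geometric (L1) median of the point pairs; with the small subgroups
involved the two rarely differ materially, and componentwise medians are
consistent with the box-plot medians reported alongside.

The subgroup delta table summarises A by subgroup medians and EDSS by
subgroup means (the conventional "average EDSS"), with their first-to-last
differences.

## Subgrouping

Within each gender, baseline (A, C) points are fitted with a 2-component
full-covariance Gaussian mixture (EM: tolerance 1e-6, 500 iterations max,
20 seeded restarts keeping the best log-likelihood, covariance
regularisation 1e-6). k = 2 is fixed; a BIC table over k = 1..4 is emitted
as a diagnostic only. Labels are deterministic: subgroup 1 is the component
with more assigned members (ties broken toward lower mean A), making output
independent of initialisation order. Each subject's maximum a posteriori
(MAP) membership probability is reported, with per-label averages.

## Longitudinal statistics

* Box-whisker summaries use medians, quartiles and 5/95% whiskers, with
  points outside the whiskers listed as outliers. All quantiles are linear
  interpolations of order statistics (numpy's default convention), stated
  here because spreadsheet packages differ.
* Kruskal–Wallis (tie-corrected, chi-square p) and Mann–Whitney (exact p for
  groups of ≤ 8 without ties, tie-corrected normal approximation otherwise)
  are applied test-wise at alpha = 0.05 with **no multiple-testing
  correction** — the raw-p convention of the exploratory analysis this
  package supports; the output says so.
* Marginal densities are Gaussian KDEs on an explicit grid extended three
  bandwidths beyond the data, normalised to integrate to 1 within 1e-3.
* The gender contrast in the dynamic subgroups is estimated with a linear
  mixed model: fixed effects for centred timepoint, gender and their
  interaction; random intercept and centred-timepoint slope per subject;
  REML estimation; Wald 95% CIs. With four annual MRIs the centred timepoint
  takes values {−1.5, −0.5, 0.5, 1.5}, so the gender coefficient is the
  group offset evaluated midway between the second and third MRI. Female is
  the reference level: the coefficient is negative when the male subgroup
  sits lower. Non-convergence and singular random-effects covariances are
  reported as flags, not exceptions. At the design sizes of interest
  (~13 subjects) Wald intervals are mildly anticonservative (normal rather
  than small-df t critical values); simulation places their coverage near
  93% rather than 95%, which is why the calibration test accepts
  [0.90, 0.99].
* Shapiro–Wilk, Anderson–Darling and Lilliefors normality diagnostics are
  available but never gate the nonparametric route.

## Synthetic cohort generator

The generator exists so the entire pipeline is testable end-to-end without
imaging data. It emulates a 4-timepoint longitudinal cohort with two
morphology archetypes per gender:

| subgroup | n (default) | archetype | blobs | radius (mm) | dynamics |
|----------|------------|-----------|-------|-------------|----------|
| F1 | 10 | complex | 150 | 1.3 ± 0.5 | static |
| F2 | 5  | smooth  | 5   | 4.5 ± 0.8 | shrink, breakup, shrink |
| M1 | 10 | complex | 150 | 1.3 ± 0.5 | static |
| M2 | 5  | smooth  | 5   | 3.8 ± 0.6 | shrink, breakup, shrink |

Patterns are unions of random ellipsoids on a 64³ grid at 1 mm isotropic
spacing (full-size grids are available via `domain_shape`; 64³ keeps a whole
cohort analysis under a few seconds). Blobs are stretched by (1.2, 1.3)
along y and z — lesion patterns show increased spatial correlation in those
directions because lesions track the CSF system. Radii are truncated-normal
draws; the broad size mixture matters: single-scale balls produce
spherical-model (kinked) variograms, whereas heterogeneous sizes produce the
exponential-shaped variograms the fitted model family assumes. Blob edges
keep a margin (default extent/8) from the grid faces, emulating the central
position of lesions in brain-space masks; a pattern flush against a face
loses its across-boundary pairs and biases gamma low along that axis.

Archetype scales were chosen so fitted ranges land at the magnitudes
reported for real lesion patterns (A roughly 1–3) and sit well inside the
fitted lag window. The complex archetype gives A ≈ 1.8 with small spread;
the smooth archetypes start near A ≈ 3.1 (F2) and 2.9 (M2) and decline
under their erosion/breakup schedules, M2 falling below the static M1 level
by the final timepoint — the qualitative geometry of the cohorts this
package is designed to analyse. Evolution operators are morphological:
dilation (growth), dilation+closing (confluence), erosion (shrinkage),
erosion plus random removal of 30% of 26-connected components (breakup).

EDSS is simulated as baseline + linear trend + noise, rounded to 0.5 steps
and clipped to [0, 10], with the trend sign tied to each subgroup's A trend
(rising for static subgroups, falling for shrinking ones). It is a coarse
ordinal surrogate sufficient to exercise the delta-table machinery — not a
clinical disability model.

What the generator does **not** emulate: anatomical lesion-probability
priors (periventricular clustering beyond the central margin), MRI intensity
or segmentation noise, registration error, irregular lesion shapes beyond
ellipsoid unions, and missing visits. Tests passing on this cohort therefore
validate the computational chain and its statistical calibration, not
segmentation robustness on real scans.

## Determinism

Every stochastic component (pattern, evolution, cohort, GMM restarts,
simulations) is driven by explicit seeds; cohorts regenerate bit-identically
from a master seed, and the pipeline writes a manifest (config hash, seeds,
library versions) from which a run can be reproduced exactly.

## Known limitations

* Fitted ranges for patterns whose correlation length approaches the lag
  window are extrapolations; the widening fallback mitigates but cannot
  remove this, and such fits surface through the non-converged flag or low
  r².
* The complete-grid convention means C (via the sill) depends on the domain
  size used to store the mask, not only on the lesions; cohorts must be
  analysed on a common grid (e.g. a shared brain-space template) for C to be
  comparable.
* Mann–Whitney exact p-values are only used for small tie-free samples; with
  heavy ties the normal approximation's calibration degrades below ~n = 8.
* The mixed model assumes linear subject trajectories over four timepoints;
  it is an estimate of average group offset, not a growth model.
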