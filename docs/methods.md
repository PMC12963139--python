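# Methods

## The polar star model

A Mirror Tracing Task star is modelled as a closed curve in polar
coordinates around a center (row, col). The radius at angle φ is

    r(φ) = r₀ · cos((2·asin k + πm)/2n) / cos((2·asin(k·cos n(φ+ω)) + πm)/2n)

The numerator is a constant chosen so that r = r₀ exactly at the outer
corners (where cos n(φ+ω) = 1); the denominator produces the star's sides
and corners. Parameters:

| parameter | meaning                       | default | units   |
|-----------|-------------------------------|---------|---------|
| `r0`      | radius at the outer corners   | —       | px      |
| `k`       | corner roundness (→1 sharp)   | 0.99    | —       |
| `m`       | side bending / depth          | 3.0     | —       |
| `n`       | number of vertices            | 5       | —       |
| `omega`   | rotation (clockwise)          | 0       | rad     |

With n = 5, m = 3, k → 1 the inner/outer radius ratio approaches
cos 72°/cos 36° ≈ 0.472, the regular-pentagram value; k = 0.99 keeps the
corners visually sharp while bounding the radial derivative, and k = 0
degenerates to a circle. Validity requires the denominator's cosine
argument to stay strictly inside (−π/2, π/2) for all φ; the constructor
rejects parameter sets that violate this (for k ≤ 1 this essentially
bounds |m| below n − 1). No further (k, m) ranges are imposed.

The double contour is a single shape function f(φ) (the expression above
with r₀ = 1) scaled by two radii r_ext > r_int. Corner angles are exact:
outer corners at φ = −ω + j·2π/n, inner corners midway between them. For
the canonical star the inner corners flank the drawing start at 36° and
324°, with the first outer corner after the start at 72°.

**Angle convention.** φ = 0 at the topmost point (the drawing start),
increasing clockwise. On a 0-based raster with rows growing downward this
is φ = atan2(col − c_col, c_row − row) mod 2π. Radians internally, degrees
in every file and report.

## Ideal and expected stars; rasterization

The *ideal star* is the midline (r_ext + r_int)/2 · f(φ) — the trajectory
of a perfect trace. Its pixel rendering samples the curve densely
(consecutive samples ≈ 0.02 px apart, refined adaptively) and collects the
rounded integer positions: the set of pixels the continuous line passes
through, forming one closed 8-connected loop. Every rendered pixel lies
within half a pixel diagonal of the curve *perpendicularly*; note that the
purely radial deviation |r − r_ideal(φ)| can exceed that bound near sharp
corners where |dr/dφ| is large — this is a property of steep curves, not a
rasterization error.

The *expected star* dilates the ideal pixel loop with a disk of radius
⌊(Θ−1)/2⌋, where Θ is the measured pen thickness (identity at Θ = 1). A
symmetric disk brush is the simplest pen model; odd Θ is recommended since
the discrete brush diameter is 2⌊(Θ−1)/2⌋+1.

## Per-drawing variables

- **Residual** per drawn pixel: (r − r_ideal(φ)) / ΔR(φ), where
  ΔR = (r_ext − r_int)·f(φ) is the local band width. 0 on the midline,
  ±0.5 on the outer/inner contour; positive outward. Pixels outside the
  star keep their residual (the definition is per pixel, position-free).
- **Density** per angular bin: drawn pixels in the bin (wherever they lie
  radially) divided by expected-star pixels in the bin. Bins are half-open
  [d, d+Δφ) degrees, default Δφ = 1°, giving 360 bins. A bin with zero
  expected pixels means the bin width is too narrow for the raster and is
  a configuration error (1° bins need a star of roughly ≥ 300 px
  diameter).
- **Legacy density** (retained for comparison only): pixels / (band area ×
  Θ). Its area normalization over-weights corners — on the expected star
  itself it varies by >10 % across bins while the adopted density is
  exactly 1 — which is why it was superseded.
- **Errors**: maximal 8-connected components of path pixels outside the
  permitted region (band ∪ border). Touching the border is not an error;
  each excursion beyond either contour counts once.
- **Summaries**: mean density over bins, and the sum over bins of squared
  *per-bin mean* residuals (missing bins excluded). Summing per-bin means
  rather than per-pixel values keeps the quantity independent of pixel
  count at fixed bin count — with 360 fixed bins, sum and mean differ only
  by the factor 360. Before cohort comparisons, summaries are Box-Cox
  transformed (profile-MLE λ, inputs shifted by 1e−6 − min when
  non-positive) and z-scored.
- **Pen thickness** Θ: path area divided by skeleton length, rounded,
  minimum 1 — robust to curvature without a stroke model.

## Image harmonization

Canonical images store the path in the red channel, the drawable band in
green, and the border in blue (8-bit PNG, threshold 127, anti-aliased
edges resolved per channel). The green channel encodes the *band between
the contours*, not the filled star interior. Raw scans are segmented by
hue/intensity windows — blue hue for the printed outline; saturated
non-blue or dark low-saturation strokes for the pen, so gray/black pens
are supported — and the band is reconstructed by fitting the star model to
the detected border and filling between the fitted contours. Images that
are already essentially pure R/G/B pass through unchanged.

Star fitting estimates the center from the border centroid, splits border
pixels into outer/inner contours by the per-angle mid radius, reads n from
the dominant Fourier harmonic of the binned mean radius, and refines
(center, r_ext, r_int, k, m, ω) jointly by bounded nonlinear least squares.
On synthetic borders the round trip recovers radii within 1 % and ω within
0.5°; fits with RMS above a configurable ceiling (default 10 px) raise a
diagnostic error.

## Series analysis

Profiles (density and per-bin mean residual channels) become
drawings × bins × channels arrays; missing bins are filled by circular
linear interpolation, and channels are z-scored across the whole dataset
so density and residual scales contribute comparably. Series start at
bin 0 (the drawing start) and are warped as linear, not circular,
sequences — the drawing has a defined start.

Distances: ED (pointwise L2), DTW (dynamic programming with squared local
cost, square root of the optimal total), and c-DTW (DTW inside a
Sakoe–Chiba band; default window 10 bins = 10°, a middle ground between
ED's rigidity and DTW's full freedom). Window 0 reduces exactly to ED, and
DTW ≤ c-DTW ≤ ED always. Barycenters: the pointwise mean under ED;
DBA (DTW barycenter averaging) warm-started from the current estimate
otherwise, which never increases the sum of squared distances. k-means
uses k-means++ seeding, metric assignment, barycenter updates, farthest-
point re-seeding of emptied clusters, and the best of `n_init` restarts by
inertia; it is deterministic for a fixed seed. Default k = 3.

## Cohort statistics

Twin data violate independence, so:

- **Age effects** are estimated by REML linear mixed models with a random
  intercept per twin pair (statsmodels `MixedLM`), Wald 95 % intervals and
  normal p-values; singular fits fall back to OLS with a logged warning.
- **Coefficient comparisons** resample whole pairs with replacement
  (default B = 1000), refit each metric's model per resample, and report
  the two-sided p-value as twice the smaller exceedance proportion, BY-FDR
  adjusted across comparisons. The bootstrap refits use an in-package
  profiled-REML solver (the per-pair covariance σ²(I + λJ) has closed-form
  inverse and determinant, leaving a 1-D REML optimization over λ) that
  matches `MixedLM` slopes to ~1e−4 while being fast enough for thousands
  of refits; the cross-check is part of the test suite.
- **Per-angle age maps** compute Pearson correlations with age per bin for
  the density and the *mean* residual channel (the residual statistic is
  configurable), adjust p-values with Benjamini–Yekutieli across the 360
  bins within each channel separately — the minimal family, and BY remains
  valid under the strong dependence between neighbouring bins — and flag a
  bin only when both channels pass α = 0.05.
- **Cluster demographics**: χ² on the sex × cluster table, Kruskal–Wallis
  on age across clusters; clusters smaller than 2 are annotated, not
  dropped.

## Synthetic drawings and cohorts

The generator renders drawings directly in the canonical convention. The
star image defines the border *radially* (pixels within border_px/2 of
either contour radius, default 3 px) and the band strictly between the
contours, giving sliver-free region boundaries. A drawing follows
r(φ) = r_ideal(φ) + g(φ)·ΔR(φ), where the deviation g is expressed in
units of the local band width so archetypes transfer across shapes and
sizes:

| pattern            | g(φ)                                             |
|--------------------|--------------------------------------------------|
| `ideal`            | 0                                                |
| `oscillation`      | offset + A·sin(freq·φ), default A=0.3, freq=30   |
| `wide_oscillation` | same with A > 0.5, crossing both contours        |
| `offset_out/in`    | ±|offset|                                        |
| `shortcut`         | straight chords across listed corners (±25°)     |
| `corner_error`     | high-amplitude tremor burst in one 20° window    |

Tremor is Gaussian noise at half-degree knots, circularly low-pass
filtered (hand tremor drifts rather than jumping pixel to pixel), rescaled
to marginal sd `radial_noise_sd` (default 0.04 band widths) and clipped at
3σ so that noiseless margins bound the excursion; the realized g — pattern
plus tremor — is returned for oracle checks. Paths are sampled at ≤ 0.25 px
steps and stamped with a disk brush of diameter Θ (default 5 px).

Cohorts draw one age per pair (twins share birthdays) uniformly over
16–79 years, a latent skill with within-pair correlation 0.5, and per-
drawing oscillation amplitude and radial offset that grow linearly with
age (defaults: 0.003 band widths of amplitude per year, no offset trend);
sex is Bernoulli with 0.69 female, matching a typical volunteer cohort.
Completion time is a simple linear-in-age stand-in. Defaults are chosen so
the typical drawing stays inside the band while older synthetic
participants oscillate visibly more.

**What the generator does not emulate:** drawing kinematics (speed,
direction reversals, lifting the pen), ink texture, scanning artifacts
(skew, shading), asymmetric or per-corner difficulty profiles, and
discrete error events other than the listed archetypes. Passing tests
demonstrate correctness of the measurement pipeline on controlled inputs,
not that real populations behave like the simulated one.

## Problem sizes and numerical choices

- Default synthetic raster 512 px (star ≈ 420 px wide); cohort drawings at
  384 px for throughput. Pen-thickness invariance of density (Θ = 3 vs 7
  within 0.15 per bin) and scale invariance of binned residuals (within
  0.02 across ×1/×2/×3 renders) are verified on a ≈ 1000-px-wide star with
  smooth traces, the regime of real scans; at very small rasters or for
  jittery traces, corner bins hold only a handful of expected pixels and
  these bounds degrade — the per-bin expected counts in `AngularProfile`
  make such bins identifiable.
- Simulation-based checks use 100-pair cohorts, 200 replicates for mixed-
  model bias/coverage, B = 500 bootstrap resamples for the comparison
  calibration, and 100/20 replicates for the null/localization behaviour
  of the per-angle maps.
- Ties in the DTW backtracking prefer the diagonal move; k-means breaks
  assignment ties by the lower cluster index (argmin).
- Degenerate inputs raise typed errors: empty paths yield empty traces and
  zero density but cannot be summarized; empty borders cannot be fitted;
  constant vectors cannot be Box-Cox standardized.

## Known limitations

- The error count is a pixel-topology proxy: an excursion that leaves and
  re-enters through the same border pixel run counts once, and two
  overlapping excursions merge. This matches the printed-image information
  available; stroke-order data would be needed to do better.
- `corner_error` localization (density ≥ 1.5 × median only near the target
  corner) is validated at 1024 px; at lower resolution natural corner
  spikes approach the threshold.
- DTW distances are not metrics (no triangle inequality); only ED's
  triangle inequality is asserted.
- The scan segmenter assumes a blue printed outline on a light background;
  it does not deskew photographs.
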