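# Methods

`understorey` re-implements, as a tested pipeline, a field-to-map
analysis of forest-floor habitat quality: ground surface temperature
(Thermal_ground, °C) and ground vegetation greenness (NDVI_down) are
measured at sample points, linked statistically to canopy structure
(leaf area index LAI and fractional canopy cover FCover), and upscaled
to landscape maps through satellite spectral/texture features and
Random-Forest regression.

## Canopy structure from hemispherical photographs

An upward fisheye photograph is reduced to its blue band (maximum
leaf/sky contrast), thresholded with the global Ridler–Calvard
(isodata) rule — the fixed point of T ← (mean below T + mean above T)/2
started at the global mean, stopped at |ΔT| < 0.01 intensity units
(max 100 iterations) — and classified into vegetation and sky. The
field of view is restricted to zenith angles 0–60° to avoid mixed
pixels near the horizon.

Gap fractions P̄(θ) are accumulated in 5°-wide zenith rings (default;
configurable), each split into 8 azimuth cells. Under the homogeneous
turbid-medium model, P(θ) = exp(−G·L/cos θ) with G the projection
function (0.5 for a spherical leaf-angle distribution), so each ring
supplies −ln P̄(θ)·cos θ = G·L. The effective plant area index is

    LAI_eff = k̂ / G,   k̂ = Σ_r w_r (−ln P̄_r · cos θ_r) / Σ_r w_r,

with ring pixel counts as weights w_r. This estimator is exact for the
homogeneous model at any ring scheme and uses the whole 0–60° cone; a
single-ring hinge-angle (57.5°) estimate is provided as a cross-check.
Foliage clumping is corrected per Lang–Xiang logarithmic gap averaging:
per ring Ω_r = ln(P̄_r) / mean-over-cells(ln P_cell), combined across
rings by pixel-count weights, and LAI = LAI_eff / Ω. Jensen's
inequality guarantees Ω ≤ 1, hence LAI ≥ LAI_eff; a numerically
out-of-range Ω is clipped to 1 with a warning. Fully vegetated cells
(P = 0) are floored at 1/(cell pixel count) before logarithms — the
standard saturation guard. LAI is a plant area index: woody material
is deliberately not masked, since hiding stems would also hide the
leaves behind them and bias LAI low.

FCover (%) is the vegetated pixel share over the 0–60° zone of each
image (a nadir-cone variant is available through the zone parameter);
plot-level LAI pools ring-wise sky/vegetation *counts* across a plot's
images before the logarithm (gap-fraction averaging precedes the log
transform), rather than averaging per-image LAI.

The lens projection defaults to equidistant (radius ∝ zenith angle),
with an equisolid alternative; field protocols rarely record the exact
projection law and the inversion is insensitive to it at ring
resolution.

## Ground imagery

Two-band (RED 660 nm / NIR 850 nm) camera digital numbers are
calibrated against a ground target of known reflectance by a per-band
multiplicative gain (known reflectance / observed target DN); a
two-target affine variant is provided since a single grey target cannot
identify an offset. NDVI = (NIR−RED)/(NIR+RED) per pixel; a zero band
sum yields an undefined pixel. Regions of interest are supplied
rectangles (the 50 × 50 cm ruler square is a cue for the operator, not
an algorithm); thermal snapshots — headerless CSV grids of °C — use a
fixed 150 × 150-cell extent. ROI summaries report mean, median, min,
max, sample sd (n−1) and the count of defined pixels. A sample is
excluded as non-sensibly calibrated when its ROI mean leaves [−1, 1] or
more than 5% of its pixels do; 5% is this package's quantification of
"non-sensible" and is recorded with the exclusion reason.

## Plot statistics

Sample points aggregate to plots as the mean (or min/max) of per-sample
ROI means. Treeless grassland plots receive LAI = 0, FCover = 0,
NDVI_up = −1. Habitat contrasts use pairwise two-sided Wilcoxon
rank-sum tests (exact enumeration when the combined n ≤ 12 without
ties; otherwise the normal approximation with tie and continuity
corrections) under Bonferroni adjustment.

Single-predictor relationships are fitted twice: an OLS line, and a
penalized cubic B-spline smooth (basis dimension 10) whose penalty
weight minimises GCV(α) = n·RSS/(n − edf)² over a log-spaced grid, with
near-ties resolved toward the smoother fit so that noise-free linear
data collapse to an effective df of 1. The fit with the higher
adjusted R² is selected; differences under 0.005 (indistinguishable at
two-decimal reporting) go to the simpler linear model. The smooth's
normal equations are solved by pseudo-inverse because the demeaned
spline basis is rank-deficient by construction.

Air-temperature effects use the interaction model
y ~ 1 + x + T_air + x·T_air (OLS). Its intercept and structure slope
at a chosen temperature are b0 + b_T·T and b_x + b_{xT}·T; under the
calibrated FCover block the marginal slope turns from +0.004 at 21 °C
to −0.054 °C per % cover at 29 °C — stronger canopy buffering under
hotter air.

## Satellite features and upscaling

Pixels whose QA code is not in the clear-condition set
{322, 386, 834, 898, 1346} — including the water codes
{324, 388, 836, 900, 1348} and everything else — are set undefined in
every band. Vegetation indices: NDVI, MSAVI2 = (2N+1−√((2N+1)²−8(N−R)))/2
and EVI2 = 2.5(N−R)/(N+2.4R+1). Texture layers come from per-pixel
grey-level co-occurrence matrices: each band is quantized to 64
equal-width levels over its global finite range (global, so textures
compare across the scene), vertical-neighbour pairs (the 90° shift)
inside a 3 × 3 window are accumulated symmetrically, and MEAN = Σ i·p(i,j)
and DISSIMILARITY = Σ |i−j|·p(i,j) are read off the normalised matrix.
Windows touching an edge or an undefined pixel are undefined. Focal
mean/sd of NDVI use a 9 × 9 window — the nearest odd window to the
8-pixel convention of the source workflow, since an even window has no
centre pixel; undefined cells are excluded from the window sample and
fewer than two defined cells leave the sd undefined.

Predictors are screened greedily in a stated priority order (the
retained sets of the reference canopy models first — SWIRM, NIRM, NIRD,
SWIRD, NDVIMFocal, NDVISD — then alphabetically): a candidate is kept
only if |Pearson r| ≤ 0.6 against everything already kept. The
threshold is read as a correlation coefficient, not a p-value — a
p-value cut of 0.6 would not screen anything meaningful. The canopy
model is a 2,000-tree bootstrap regression forest with ⌈p/3⌉ split
candidates and minimum leaf size 5; skill is the out-of-bag variance
explained (1 − OOB MSE / response variance) and importance is the
permutation increase in per-tree OOB MSE, reported as the raw mean with
its standard error across trees. Canopy maps are per-pixel ensemble
means, undefined wherever any predictor layer is; microclimate maps
chain the selected *linear* plot-level model onto the canopy raster
(smooth fits have no single slope and are refused), clipping NDVI
outputs to [−1, 1] and leaving temperatures unclipped.

## Synthetic data

The generators reproduce the study conditions so the whole chain is
testable without field data. All are pure functions of their seed.

* **Hemispheres** draw per-pixel sky states as independent Bernoulli
  variables with ring-wise probability exp(−G·L/cos θ); a clumped mode
  instead lays down opaque foliage discs from a Boolean model whose
  intensity reproduces the same expected gap fraction while dispersing
  foliage non-randomly (Ω < 1). Sky pixels are bright in the blue
  channel, vegetation dark, both with mild Gaussian intensity noise.
* **Ground scenes** construct band reflectances so that calibrated NDVI
  recovers the stated truth in expectation (band total 0.6), encode the
  target reflectance (0.87) through fixed sensor gains, and draw
  thermal matrices as uncorrelated Gaussians — sufficient for
  ROI-statistic testing, with no pretence of radiometric realism.
* **Plot campaigns** default to 34 plots with the thermal-campaign
  habitat mix (6 grassland, 1 bush, 11 edge, 12 forest, 4 plantation),
  T_air uniform on 21–29 °C, habitat-specific LAI ranges, and
  field-calibrated generative coefficients: the interaction blocks
  (FCover: 2.074357, 0.155010, 0.887836, −0.007211; LAI: 3.2155,
  3.0012, 0.8054, −0.1424) and the marginal relations
  Thermal = 27.4 − 1.19·LAI, Thermal = 27.6 − 0.06·FCover,
  NDVI_down = 0.57 − 0.09·LAI. Default residual noise (1.5 °C thermal,
  0.08 NDVI) puts model R² in the observed 0.2–0.7 range. Grassland
  rows carry no canopy fields until the defaults rule fills them.
* **Satellite scenes** drive RED/NIR/SWIR1 through saturating
  exponentials of a smoothed Gaussian random LAI field (range 0–6)
  plus noise, and assign QA codes to rank bands of a second smooth
  field so clouds and water form contiguous patches at exactly the
  stated proportions — iid QA scatter would leave almost no complete
  texture windows, which real scenes do not suffer from.

What passing these tests does *not* show: robustness to mixed pixels,
vignetting, non-Gaussian thermal noise, sensor PSF, georeferencing
error, or canopy architectures outside the turbid-medium/Boolean-disc
family.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale,
chosen to keep each Monte-Carlo bound comfortably powered: hemisphere
recovery uses 512-pixel images (52 hemispheres over L ∈ {0.5, 1, 2, 4};
median |error| < 10%), coefficient-recovery simulations use 200
replicates of n = 34 plots, and the raster chain trains on 150 plots of
a 100 × 100 scene. Replicate seeds are spawned from a single base seed
via `numpy.random.SeedSequence`, which is also how the acceptance
script derives all of its randomness from `--seed`. Isodata tolerance
is 0.01 intensity units; spline GCV searches α over 10^−6…10^10 in
half-decade steps; LAI inversion tolerates closed-form profiles to
1e−9.

## Known limitations

Exact numerical agreement with the CAN-EYE software is not claimed: its
leaf-angle model and ring scheme are not published in sufficient
detail, so this package states its own (spherical G, 5° rings,
Lang–Xiang clumping). Whether FCover means 0–60° cover or a nadir cone
is ambiguous in the field literature; both are available and 0–60° is
the default. Mosaicking, reprojection and atmospheric correction are
out of scope — the raster stage consumes one co-registered
surface-reflectance stack. Mixed-effects or spatially autocorrelated
error structures are not modelled.
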