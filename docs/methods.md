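# Methods

This note documents the models and numerical choices behind `camphen`, the
defaults that matter, what the synthetic generator does and does not
emulate, and the known limitations.

## Color statistics

All statistics operate on raw 8-bit JPEG digital numbers (DN) in double
precision. No gamma linearization, vignetting correction or radiometric
calibration is applied: chromatic coordinates are ratios of channel means,
so they are invariant to any common rescaling of the three channels, and
the quantities of interest are relative seasonal changes rather than
absolute reflectances.

Chromatic coordinates are computed as *coordinates of the mean DNs* over
the region (Gcc = Ḡ/(R̄+Ḡ+B̄)), not as the mean of per-pixel coordinates.
The two differ in general; the coordinates-of-means form is the one the
index definition states, and it is what the per-image statistics table
stores. An all-black region (nighttime exposure) has no defined chromatic
decomposition; it produces a NaN-valued record that downstream screening
drops, rather than an exception, because night images are a normal part of
real stacks.

The deviation from grey, Δ, is the Euclidean distance of the *whole-image*
chromatic coordinates from (⅓, ⅓, ⅓). Its ceiling over the chromatic
simplex is √(2/3) ≈ 0.816. Whole-image (not ROI) means are essential:
grey-world auto white balance (AWB) neutralizes the image-wide mean color,
while an ROI can remain colored.

## Quality screening

**AWB suspects.** A calendar day is "low-Δ" when it has at least one
defined Δ and every defined Δ that day is below the threshold (default
0.02, dimensionless). Maximal runs of consecutive low-Δ calendar days
strictly longer than 30 days are reported as suspect intervals. Days with
no observations break a run: a run is evidence of *sustained* neutrality,
and gaps make the evidence non-contiguous. The all-images-low rule is the
strict reading of a per-day statement about a per-image quantity; a single
colorful exposure is enough to clear a day.

**Haze degree.** ω = 100·(μ_B + (1 − C))/2, where μ_B is the mean over
pixels of the per-pixel maximum channel value scaled to [0, 1], and C is
the RMS contrast (standard deviation of per-pixel brightness) scaled by
its theoretical maximum of 0.5. A uniform white frame scores 100 %, a
uniform black frame 50 %, and blending any scene toward uniform bright
grey increases ω monotonically. The score depends only on per-pixel
channel statistics, so it is invariant to pixel permutation. Images above
40 % are flagged hazy but never removed — the flag is an annotation.
Note that this composite is deliberately simple and sits behind a single
function so a more discriminative estimator can be swapped in; because it
rewards low contrast as much as brightness, visually clear but low-texture
frames (including this package's flat synthetic scenes, ω ≈ 55–70 %) also
exceed the 40 % mark. Within any one scene the score still orders fog
levels correctly, which is what the tests rely on.

**Darkness screen.** Rows outside a local-time window (default
07:00–17:00) or below a whole-image brightness floor (default 30/255,
i.e. mean per-pixel maximum channel under 30 DN) are removed before
aggregation. Timestamps are site-local clock time throughout; no timezone
conversion is performed, and a "day" is the local calendar date.

**LOESS outlier flagging.** A robust locally weighted linear regression
(tricube weights, two robustifying iterations) of Gcc on date is the
reference trend; observations with |residual| > k·max(1.4826·MAD, σ_min)
are flagged, the fit is repeated once without them, and flags are
finalized against the refit. Defaults: k = 4; trend bandwidth ≈ 15 days of
data (at least 10 points); σ_min = 0.002 Gcc. The bandwidth is chosen so a
steep green-up (logistic time constant ~3 days) is trend rather than
outlier — with a much wider window the fit lags the transition and its
systematic residuals there get flagged. The floor σ_min reflects the
quantization granularity of Gcc computed from 8-bit DNs: on noiseless or
near-noiseless series the MAD collapses toward zero and, without a floor,
arbitrarily small residuals would be flagged. Flagging is invariant to
adding a constant to the series. Series with fewer than 10 points are left
unflagged with a warning.

## Summary products

Per-image Gcc/Rcc/Bcc are aggregated to the 0.90 quantile within 1-day or
3-day windows. The quantile estimator interpolates linearly between order
statistics at h = (n−1)q + 1 (the common statistical default; for a day
with values 0.1, 0.2, …, 1.0 it yields 0.91). The high quantile damps
darkening disturbances (clouds, rain, shadows) which push Gcc down far
more often than up. 3-day windows are non-overlapping, anchored at
January 1 of each year, and labeled with the middle day (day of year 2, 5,
8, …); the short final window of a year is aggregated as-is. Windows with
no retained images stay in the table with missing markers and
image_count = 0, so the downstream smoother always sees an even grid.
`midday_gcc` is the Gcc of the image nearest local noon on the center
date.

**Smoothing and uncertainty.** The smoothed curve is a LOESS fit (degree
1, tricube, no robust iterations — outliers are already flagged and
excluded) evaluated at every center date. The default span corresponds to
a bandwidth of ~12 days of data (at least 7 points): wide enough to
average weather noise, narrow enough that the local linear fit does not
bias the threshold crossings of a logistic transition with a 3–10 day time
constant (local-linear smoothing bias grows with the curvature of the
underlying curve times the squared bandwidth; at 12 days it is well under
half a day of date shift for those slopes). The 95 % band is a residual
resampling bootstrap: residuals of the fit are resampled with replacement
onto the fitted values, the fit is repeated (default 200 replicates,
seeded), and the 2.5/97.5 percentiles at each date form `ci_low`/
`ci_high`. The band captures sampling variability of the fit, not its
smoothing bias; on a noiseless series it collapses onto the curve.

## Transition dates

Local maxima of the smoothed curve with prominence ≥ 0.02 Gcc and spacing
≥ 30 days delimit seasonal cycles; each peak is bracketed by the curve
minima toward its neighboring peaks (or the series ends), giving one
rising and one falling limb per peak. Baseline and peak are the smoothed
curve's extremes *within* the cycle — not annual extremes — so each cycle
of a bimodal year (e.g. grasslands with a summer dry-down) is scaled by
its own amplitude. Limbs with amplitude ≤ 0.02 Gcc are discarded as noise.

For threshold p ∈ {10, 25, 50} % the target is baseline + (p/100)·
amplitude, and the date is the first crossing of the target in the limb's
direction, linearly interpolated between grid dates, ties broken toward
the earlier date, reported rounded to the nearest day (sub-day precision
is not meaningful on a 1- or 3-day grid). A target never crossed (plateau)
yields a missing date with a warning. The uncertainty interval is read off
the bootstrap band: the earliest and latest dates at which either band
bound crosses the same target, clamped to bracket the point estimate.
This reuses the band rather than re-extracting dates per bootstrap
replicate; the band already encodes the replicate spread, at a fraction of
the cost.

**Intercomparison.** Two transition-date sets are compared by pairing
dates of equal direction and threshold greedily by nearest date (each date
used at most once, pairs must lie within 30 days). Per threshold the
paired dates give the squared Pearson correlation, median absolute
difference, RMSD, and the fraction of pairs differing by more than 20
days. MAE/RMSD/fraction are symmetric and shift-invariant; R² is computed
on the dates themselves (as day numbers), so degenerate spreads return
NaN unless the sets are identical.

## Synthetic scenes

The generator exists to give the pipeline inputs with *known answers*.
The seasonal truth is a double logistic,

gcc(t) = baseline + A·[expit((t−m_up)/s_up) − expit((t−m_down)/s_down)],

chosen because its threshold crossings can be located to arbitrary
precision (the truth table evaluates the curve on a 0.01-day grid and
interpolates each limb's crossings, using per-limb baseline/peak exactly
as the pipeline defines them). Defaults describe a temperate deciduous
canopy: baseline 0.33, amplitude 0.10, green-up mid day-of-year 140
(s = 5 d), senescence mid 270 (s = 8 d), per-image Gcc noise 0.003.

Rendered frames are split into a blue sky band (top 40 %, excluded from
the canopy ROI and deliberately far from grey so that a non-AWB stack
never trips the Δ screen) and a flat canopy band whose chromatic
coordinates carry the seasonal signal; the red/blue remainder splits
55/45. Fog blends the frame toward uniform bright grey, snow paints the
canopy near-white, an optional date interval applies grey-world AWB
(each channel rescaled so its whole-image mean equals the grand mean),
and an optional per-image color cast emulates a misbalanced camera.
Quantization to 8 bits adds a ±0.5 DN uniform dither so region means stay
unbiased; JPEGs are written at maximum quality. The error budget for
round-tripping a known Gcc through rendering, JPEG, and extraction is
about one DN (≲ 0.003 in Gcc).

What the generator does **not** emulate: diurnal illumination cycles,
shadows and within-canopy texture, field-of-view shifts, exposure changes,
sensor vignetting, or photorealistic scene structure. Tests passing on
synthetic stacks therefore validate the *computational* chain — color
statistics, screening logic, aggregation, smoothing, date extraction —
not robustness to every real-world imaging artifact.

## Problem sizes used in the validation suite

The test suite and acceptance script run on desk-scale problems chosen to
exercise every code path: single site-years of 365 daily observations for
transition recovery (100 replicates for the stochastic check, with a
reduced bootstrap of 20–30 replicates where only point estimates are
scored), 40-day image series at 96×144 pixels for the AWB screen, and
10-to-150-day stacks at 32×48 for end-to-end CLI runs. Dataset-scale
results (thousands of site-years, archival version intercomparisons)
require the external image archive and are out of scope.

## Known limitations

* The haze composite is a stand-in with the behavior guarantees listed
  above, not the published haze estimator; its absolute scale is
  conservative (clear low-texture frames can exceed the 40 % flag).
* The bootstrap band underestimates uncertainty where smoothing bias
  dominates (very sharp transitions on coarse grids).
* Cycle segmentation assumes transitions are resolvable on the summary
  grid; phases shorter than ~30 days or shallower than 0.02 Gcc are
  suppressed by design.
* Open-ended ROI intervals use a far-future sentinel end date
  (9999-01-01); mask polarity follows the convention that excluded area
  is painted white (value 255), with an invert flag for masks drawn the
  other way.
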