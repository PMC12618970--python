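# Methods

## The weighted arithmetic water quality index

For a set of physicochemical parameters with measured values $v_i$, ideal
values $v_{io}$ and standard permissible values $s_i$, each parameter receives
a quality rating

$$q_i = 100\,\frac{v_i - v_{io}}{s_i - v_{io}}$$

and a unit weight inversely proportional to its permissible standard,

$$w_i = \frac{k}{s_i}, \qquad k = \frac{1}{\sum_i 1/s_i},$$

so that $\sum_i w_i = 1$ and stricter limits weigh more. The index is the
weighted mean

$$\mathrm{WQI} = \frac{\sum_i q_i w_i}{\sum_i w_i},$$

graded as excellent (≤ 25), good (25, 50], poor (50, 75], very poor (75, 100]
and unsuitable for drinking (> 100). The reference bands are printed as
integer intervals (0–25, 26–50, …), which leaves non-integer scores between
band edges unassigned; we use half-open intervals with inclusive upper bounds
so every real score receives exactly one grade.

Ideal values are 0 for all solutes except pH ($v_{io} = 7$, the neutral point)
and dissolved oxygen ($v_{io} = 14.6$ mg/l, the saturation value of pristine
cold water). The default standards are the IS 10500 (2012) limits: pH band
6.5–8.5, DO band 6.5–8 mg/l, conductivity 300 µS/cm, alkalinity 200 mg/l,
hardness 200 mg/l, chloride 250 mg/l, TDS 500 mg/l, BOD 5 mg/l, sulphate
200 mg/l, nitrate 45 mg/l. Two of these are published only as bands, without a
single $s_i$; we take $s_i$ as the upper bound of the band (8.5 for pH, 8 for
DO) so that $q_i = 0$ at the ideal and $q_i = 100$ at the permissible bound,
which is the contract of the rating formula. Both choices are overridable via
the standards config file.

**Signed vs absolute ratings.** The rating formula is signed: a value on the
far side of the ideal from the standard (acidic pH, supersaturated DO) rates
negative and *lowers* the aggregate index. This is the literal formula and the
default; an `absolute` mode (magnitudes of both deviations) is offered for
users who want any departure from the ideal to raise the index. Negative
aggregate scores grade as excellent and emit a warning.

**A consequence worth knowing.** With $v_{io} = 14.6$ and $s_i = 8$ for DO,
ordinary supply water at DO ≈ 7.5 mg/l rates $q_{DO} \approx 108$, and DO
carries a large unit weight ($w \approx 0.26$). Ward scores computed from the
literal formula over realistic supply-water values therefore tend to land in
the 50–70 range ("poor"), noticeably higher than the excellent/good grades
monitoring agencies typically report for the same data. Published grade
distributions evidently embed additional conventions (per-parameter rating
caps, alternative DO sub-index curves) that the printed formulas do not state;
this package implements the stated formulas exactly and makes no attempt to
reverse-engineer such conventions.

**Numerics.** The weighted mean is computed centred on the first rating with
compensated summation, so constant rating vectors reproduce exactly: all
parameters at their standards score exactly 100.0, all at their ideals exactly
0.0. Scores are kept at full precision internally; reports round half-up to
two decimals. Missing parameters are a hard error by default (`strict`); the
`renormalize` policy recomputes the unit weights over the parameters actually
present (a genuine re-derivation of $k$, not a rescaling).

Ward-level scores average each parameter arithmetically over the ward's
samples, then score the mean vector — means first, index second — matching the
practice of indexing a ward's average condition.

## Exceedance statistics

A value exceeds its limit when it is above an upper-only limit or outside a
two-sided band; values exactly at a bound pass (the sources never adjudicate
equality, and inclusive-pass is the conservative reading of a "permissible"
limit). Group summaries report n, min, max, arithmetic mean, sample SD (n−1
denominator — the monitoring convention; the sources do not state which was
used), exceedance count, and the percentage both half-up rounded to two
decimals and at full precision. Group values are sorted before summation so
results are independent of input row order to the last bit.

## IDW interpolation

The value at an unsampled point is $\sum_i \lambda_i v_i$ with
$\lambda_i = D_i^{-a} / \sum_j D_j^{-a}$ over the $m$ nearest sampled points
(ties at the $m$-th distance are all included, making the neighbourhood
deterministic and order-independent). Defaults: power $a = 2$, $m = 12$, no
cutoff, planar distances — over a study extent of roughly 0.2° the planar
approximation in degrees is adequate; a haversine metric (km) is available for
larger lon/lat extents. $a = 0$ degenerates to the arithmetic mean of the
neighbourhood; large $a$ converges to nearest-neighbour. Predictions are
convex combinations, hence bounded by the neighbour values. A target
coinciding with data points returns their value exactly (their mean if several
coincide with differing values, with a warning, since the weight formula is
undefined at $D = 0$). If a cutoff excludes every point the prediction is the
no-data sentinel (−9999), not an exception. Grids are evaluated at cell
centres with square cells sized by the x extent, and serialise as ESRI ASCII
(.asc). The source maps' power, neighbour count and cell size were never
published; the defaults here are this package's own choices, documented, not
reproductions.

## Synthetic sample generator

The generator emulates the study design: three municipal zones with 21, 21 and
25 wards, five sampling locations per ward, 335 samples total, inside the
study bounding box 85.733–85.917 °E, 20.200–20.417 °N. Only per-zone
min/max/mean/SD are available per parameter, so each parameter is drawn
independently from a normal(mean, SD) truncated to [min, max] — the simplest
family consistent with the four statistics' roles. Truncation shifts the
realised moments; all statistical checks compare against the truncated
distribution's true moments (via `scipy.stats.truncnorm`), not the untruncated
inputs. Draws use NumPy's seeded PCG64 generator, so a fixed integer seed
reproduces the table bit-for-bit across runs and platforms.

What the generator does **not** emulate: cross-parameter correlation (none is
published; an identity-correlation hook exists), spatial autocorrelation of
the parameter fields (coordinates are uniform ward centroids with ±1 % jitter,
so interpolated surfaces are exercised but not geostatistically realistic),
temporal dynamics, and the deposited raw data row-for-row. Passing tests
therefore demonstrate correctness of the computations under the published
summary structure, not agreement with the withheld raw measurements.

**Exceedance calibration.** The south-east zone's exceedance counts are
published (conductivity 90, hardness 56, DO 19, pH 8 of n = 125) and are
internally consistent with the design (the other zones' printed percentages
imply n ≈ 103–105 and are not reconstructible exactly). To reconstruct those
percentages through the real pipeline, an optional post-adjustment maps a
zone's n largest draws of a parameter order-preservingly into the interval
just above the upper limit and the remainder into the pass region (intersected
with [min, max]; for banded parameters the pass region is the band, so no
"passing" draw exceeds on the low side). This preserves rank order and bounds
but distorts the within-group distribution; it is a reconstruction device for
count-determined percentages, not a realistic sampler.

## Problem sizes used in the checks

The statistical recovery check uses the full design at 100× oversampling
(33,500 samples) and requires every zone × parameter mean to sit within 3
standard errors of the truncated-normal truth — a family of 30 comparisons,
run at a fixed seed since at 3 SE a ~8 % family-wise flag rate is expected
under resampling. The Monte-Carlo mean check uses 50,000 draws of one
profile against a 2 % relative tolerance. The IDW oracle comparison uses up to
50 random points per trial against a naive full-formula evaluation at 1e-12.

## Known limitations

* Grade distributions of real surveys are generally not reproducible from the
  literal formulas (see the DO discussion above).
* No unit conversions: inputs are assumed in the standards' units (mg/l,
  µS/cm, pH units).
* The IDW surfaces carry no cartography — no ward polygons, basemaps or
  projections; coordinates are WGS84 decimal degrees throughout.
* Kriging is deliberately out of scope; IDW is the implemented interpolator.
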