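# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `qwa`, and what the synthetic-data tests do and do not
demonstrate about real wood-anatomical data.

## Cell- and ring-level traits

Cell traits follow the standard quantitative-wood-anatomy definitions
(see README). Two conventions deserve spelling out:

- **Tangential lumen semi-axis.** Only the radial lumen diameter (CLD)
  and the lumen area (CLA) are required inputs; the tangential semi-axis
  is inferred from the ellipse-area relation b = CLA/(π a). Cells whose
  implied aspect ratio b/a falls outside a plausibility band (default
  0.1–10) are flagged and excluded from ring aggregation rather than
  aborting the run. Whether a given image-analysis tool uses measured
  tangential diameters instead is tool-internal; the closed form used
  here is stated so results are reproducible either way.
- **Mork's index** uses the radial wall thickness and radial lumen
  diameter (the common dendro convention): MI = 4·CWT_rad/CLD, with the
  boundary MI = 1 classified as latewood (inclusive).

**The average radial file.** Radial files differ in cell number, so each
file's trait sequence is mapped onto the common [0, 1] rank axis as a
step function and resampled, area-preserving, to the length L of the
longest file; per-rank means across files form the average file. The
area-preserving resample keeps every file's mean exactly, which makes
the construction identity RWA = CN × mean CWA of the average file hold
to machine precision regardless of unequal file lengths (CN is the mean
number of cells per file, a real number). Ring width, when not supplied
from a measured .rwl file, is estimated as CN × the average file's mean
radial cell extent (CLD + 2·CWT_rad).

**Radial-file assignment** from centroid coordinates clusters cells on
the tangential coordinate: sorted tangential gaps are bimodal (jitter
within files, about one cell spacing between files). If the largest gap
is below 6× the median, all cells form one file; otherwise files split
at gaps above one third of the largest gap. This recovers the true
assignment exactly when the largest within-file gap stays below a third
of the file spacing; heavily disordered tissue should instead supply
explicit `radial_file_id`s from the imaging tool.

## Chronologies

Detrending fits a cubic smoothing spline whose penalty weight λ is set
from the 50 %-frequency-cutoff wavelength n (default 100 years) by the
classical filter equivalence

    λ = (cos(2π/n) + 2) / (12 (1 − cos(2π/n))²)  ≈ (n/2π)⁴,

so a sinusoid of wavelength n is attenuated to half amplitude (verified
to within 2 % by an FFT oracle on a 500-year series). Indices are
ratios observed/fitted (not differences); non-positive fitted values are
flagged and excluded. Series need ≥ 10 years; internal gaps split the
series and each contiguous segment is detrended separately. No power
transformation is applied before detrending.

The site chronology is the per-year Tukey biweight robust mean
(c = 9 with raw-MAD scale, iterated to convergence; arithmetic-mean
fallback below three values, median when MAD = 0), with sample depth
recorded and years below a minimum depth (default 4) masked.

## Outbreak detection and severity

Candidate year t: host CWT index below (1 − δ) × mean of the previous
five years, with δ = 0.10. A non-host decline ≥ δ in the same year
vetoes the candidate (the two species share the climate; only the host
is defoliated). Candidates closer than 6 years are resolved greedily,
strongest relative decline first. The rule is scale-invariant. Known
outbreak years can instead be supplied directly, in which case the
module only scores and classifies them. Severity splits the events into
equal halves on the first-year CWT ratio (strongest ⌊n/2⌋ = high; odd
counts put the median event in low; ties break toward the earlier year
being high).

δ = 0.10 sits between the generator's low-severity ring-mean CWT pulse
(×0.85) and the climate-plus-sampling noise of a seven-tree chronology
(σ ≈ 2 %); the non-host veto absorbs the rare climate excursions that
cross it. The calibration tests quantify this: recall and precision
≥ 0.9 on the default eight-event schedule and ≤ 1 false event per 100
null years.

## Superposed-epoch analysis

Per tree × event, the reference is the mean of the five pre-event years
(fixed for all relative years); the deviation at relative year
k = 1…8 is value(start + k − 1)/reference. Deviations pool across trees
and events within site × severity. Significance at year k comes from
Welch's unequal-variance t-test of the pooled year-k deviations against
the pooled per-year pre-window deviations — both samples on the same
normalized scale, which calibrates the test's type-I error on null
simulations (the pre-window deviations' slight within-group dependence
makes the test mildly conservative, ~4 % at α = 5 %). Effect duration
counts consecutive significant years from k = 1 (a configurable switch
counts total significant years instead); maximum deviation is the
percent deviation in the year of strongest reduction. Groups with n < 2
or zero variance are reported untestable (NA), never as p = 0 or 1. No
multiple-testing correction is applied across parameters or years; the
star conventions report raw p-values — a deliberate caveat.

**Intra-ring profiles** regress a cell trait on the cell's relative
position (percent distance from the ring border, from cumulative
CLD + 2·CWT_rad extents when not stored) with a local-linear tricube
loess (default span 0.3 — enough to resolve the earlywood/latewood
contrast in ~40-cell files without overfitting), evaluated on a fixed
0–100 % grid. Pointwise standard errors are σ̂‖l‖ with l the equivalent
kernel of the local fit and σ̂² the residual variance around the
interpolated fit; with span 1 on linear data the fit equals ordinary
least squares exactly. Superposition subtracts the mean of the five
pre-event-year profiles, propagating SEs in quadrature.

**RW vs RWA.** Year-1 deviations of ring width and ring wall area form
per-tree×event pairs; the paired differences are tested against zero
with the one-sample t (the paired form of the unequal-variance
convention). Wall thinning makes RWA (which compounds cell number and
per-cell wall area) fall further than RW (cell number × radial
extents); without thinning the two coincide.

## Climate correlations

Pearson correlations of a chronology with each month's temperature and
precipitation (April–October), bootstrapped by resampling year pairs
with replacement (default 1000 replicates); r is reported as the
bootstrap mean and significance as the 95 % percentile interval
excluding zero. At least 25 overlapping years are required. Outbreak
exclusion removes each start year plus a configurable number of
following years (default 2, matching multi-year defoliation
carry-over); both inclusion modes are reported.

## The synthetic generator

The generator emulates a two-site, century-long study: 7 trees per
site/species, years 1900–2017, 3 radial files measured per ring,
~50 cells per file. It produces cell tables, Tucson .rwl files, monthly
climate and a JSON truth record, all passing the package's own input
validation.

- **Baseline profiles** (relative rank position p ∈ [0, 1]): lumen
  diameter 42 → 8 µm (logistic transition at p ≈ 0.68), radial wall
  thickness 3.5 → 8 µm (transition at p ≈ 0.75), tangential/radial wall
  ratio 0.9, lumen eccentricity 0.9. These magnitudes are plausible
  subalpine larch values; they are configuration, not constants. Wall
  thickness is floored at 3 µm (a biomechanical minimum); the earlywood
  baseline sits slightly above the floor so that moderate thinning can
  still bite there.
- **Cell geometry**: CLA = π a b; wall area from the
  rectangular-perimeter closed form CWA = 2·CWT_rad·TLD + 2·CWT_tan·CLD
  + 4·CWT_rad·CWT_tan, tying wall area to wall thickness so density
  co-varies realistically.
- **Climate**: monthly temperature = subalpine seasonal means + AR(1)
  anomalies (σ = 1.5 °C, ρ = 0.3); precipitation lognormal around its
  seasonal mean. Cell number is forced by the May–August anomaly
  (host β = 0.05/°C, non-host 0.02); latewood wall thickness by the
  August–September anomaly (β = 0.04/°C, weighted by the latewood share
  of the transition — the forcing lives in the latewood, not the ring
  mean).
- **Outbreaks** (host only): default schedule 1908, 1915, 1935, 1945,
  1954, 1963, 1972, 1981; high severity (1908, 1945, 1963, 1972)
  multiplies cell number by 0.45, ring-mean wall thickness by 0.70
  (≈ ×0.67 on wall area; redistributed toward the latewood by a mean-one
  weight 0.75 + 0.5 p), and lumen diameter by 0.93 early → 1.05 late;
  low severity uses 0.70 / 0.85 / 0.97 → 1.02. Multipliers recover
  geometrically toward 1 (rates: CN 0.65 per year — significant for
  ~5–6 years; CWT 0.45; CLD 0.30). With the floor active, the realized
  ring-mean wall-area deviation in year 1 is ≈ −26 % rather than −33 %,
  because floored earlywood cells cannot thin further. These multipliers
  exist to make ordering and recovery properties testable; they are not
  claimed as estimates of any real system.
- **Noise**: lognormal throughout — per-tree effects (CN 10 %, CWT 5 %,
  CLD 5 %), per-ring effects (8 / 4 / 3 %), per-cell measurement noise
  (8 %), per-file cell-count jitter (5 %). Ring width is the cell-number
  × mean-radial-extent product, so CN and RW chronologies correlate at
  r > 0.99 by construction.
- **Two generation paths.** The cell-level path draws every tracheid;
  the fast ring-level path integrates the identical driver fields over a
  40-point position grid and omits only per-cell noise (which averages
  out over ~150 cells per ring). The two agree within a few percent ring
  by ring (cross-checked in the tests); calibration analyses that need
  hundreds of replicate centuries use the fast path, profile analyses
  use cells.

**What the generator does not emulate:** missing rings, cross-dating
errors, compression wood, within-ring density fluctuations, pit anatomy,
non-stationary climate trends, spatially structured outbreak waves, or
mechanistic xylogenesis. Passing tests therefore demonstrate that the
pipeline recovers known signals under the stated statistical structure,
not that real defoliation data will be as clean.

## Problem sizes and determinism

The packaged tests use 100 replicate centuries for detection calibration
(plus 200 null centuries), 100 replicates for parameter recovery and
each qualitative pattern, and 200 replicates for the two type-I-error
calibrations; `scripts/acceptance.py` uses 30/50/25 replicates for its
summary quantities. All randomness flows from explicit seeds through
`numpy.random.SeedSequence`, so identical seeds give byte-identical
simulated datasets and identical results.

## Known limitations

- The elliptical-conduit conductivity is theoretical: no pit resistance,
  taper or embolism; values are upper bounds useful for relative
  comparisons.
- The Welch tests treat tree×event deviations as independent; parameters
  strongly forced by a common climate signal violate this within years,
  which is a property of the design (7 trees share one sky), not of the
  implementation — interpret significance for climate-coupled parameters
  accordingly.
- Severity classification is relative within the detected set (equal
  halves), not an absolute damage scale.
- The loess standard errors use a global residual-variance estimate;
  strongly heteroscedastic traits (e.g. Kh_c across the ring) get
  conservative envelopes in the earlywood.
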