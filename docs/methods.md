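# Methods

`bloomstage` implements a complete desk-scale pipeline for estimating
phytoplankton bloom stage in a seasonally ice-covered shelf sea: satellite
chlorophyll-a phenology extraction, calibration of a pheophytin-proportion
threshold that reads bloom stage from bottle samples, sea-ice year
classification, and the high- vs low-ice group comparison. This note records
the model, its assumptions, the tunable constants, and the design choices
made where the protocol left the design open.

## Satellite phenology

Each station-year is an irregular series of surface chlorophyll-a
observations (mg/m^3) on 1-based day-of-year (DOY). Processing steps:

1. **Ice masking.** Observations on days with sea-ice concentration strictly
   above 15% are removed (ice contaminates the ocean-colour retrieval). Days
   with missing ice data are retained: absence of evidence is not treated as
   ice.
2. **Quality control.** A station-year is staged only if it has at least 6
   observations, no gap between consecutive observations longer than 25
   days, and at least 3 observations in the mid-summer window DOY 174-219
   bracketing the July cruises. The gap rule is evaluated over the full
   retained series (after masking, so heavy spring ice can itself cause a QC
   failure); optional seasonal bounds can additionally penalise a late first
   or early last observation, but are off by default because the protocol's
   own wording covers only inter-observation gaps.
3. **Smoothing.** A tricube-weighted locally linear regression (LOWESS) is
   evaluated at the observation days. The span is max(7 points, 30% of the
   observations) — wide enough to be stable at the typical density of ~27
   observations per year, narrow enough to keep a 2-4 week bloom visible.
   Robustness iterations default to 0; the smoother already sits on
   per-station median-extracted data, and iterations would only matter for
   gross outliers. The smoothed points are joined by linear interpolation
   into a daily curve between the first and last observation; the curve
   never extrapolates.
4. **Bloom detection.** The daily curve is segmented at strict local minima
   (plateaus collapse to their first day). A segment is a bloom cycle when
   its peak rises at least 0.5 mg/m^3 above the starting minimum, giving
   start/peak/end days (t1, t2, t3) with the peak at the earliest day of a
   maximal plateau. A sub-threshold segment merges into the preceding
   qualifying bloom when the intervening minimum stays above that bloom's
   starting value — the deterministic reading of "continuation of a larger
   cycle"; otherwise it contributes no cycle. The bloom end is the next
   strict local minimum; if the series ends first, the cycle is flagged
   truncated.
5. **Stage classification** at a sampling day: Early Bloom on [t1, t2],
   Post Bloom on (t2, t3], No Bloom outside every cycle; a day outside the
   curve's coverage is an error distinct from No Bloom. When two cycles
   share a boundary day the earlier cycle wins, keeping the partition
   deterministic.

## Pheophytin threshold calibration

Pheophytin is the degradation product of chlorophyll-a produced by grazing
and microbial breakdown; the proportion p = Pheo/(Chl + Pheo) is low in a
growing bloom and rises as the bloom matures. The calibration matches each
staged station-year's satellite label (EB/PB only; No-Bloom and
failed-QC years are excluded) with the pheophytin proportion of its surface
(5 m) bottle sample, then scans every integer threshold T in 0..100:
classify EB when p < T/100 (equality goes to PB, keeping EB strictly
pre-peak), tabulate the 2x2 field-vs-satellite error matrix with the
satellite as reference, and compute overall accuracy, per-class producer and
user accuracies and their omission/commission complements. The selected T
maximizes overall accuracy; ties break toward the smaller
|omission(EB) - omission(PB)| (the bias-minimisation criterion made
lexicographic), then toward the smallest T. A class absent from the
reference makes its omission undefined and the bias infinite, so such ties
fall through to the smallest-T rule.

Only surface samples feed the calibration; depth-integrated proportions are
used in the group comparison alone.

## Sea-ice year classification

* **Breakup date**: the first day of the earliest run of 2 consecutive valid
  days with concentration strictly below 15%, searched after the last day of
  the annual maximum so early-winter open water cannot register as breakup.
  If concentration never reaches 15% at all, winter ice never formed: the
  year has no breakup date and is the low-ice extreme.
* **Breakup scheme**: per station, an at-most-one-change mean-shift model is
  fitted to the multi-year breakup sequence by exhaustive scan over split
  positions (minimum segment length 2, minimizing within-segment SSE). The
  split is accepted when the SSE reduction over the no-change model exceeds
  2 ln(n) times the two-segment residual variance — the standard
  likelihood-penalty form for a single normal mean change; the penalty scale
  is a config knob. The station's DOY threshold is the midpoint of the
  segment means (overall mean when no split is accepted). Years with breakup
  before the threshold are LOW, at/after it HIGH; no-ice years are LOW.
* **Concentration scheme**: a year is LOW when the Mar 1 - May 1 window
  (computed from the calendar, DOY 60-121 or 61-122 in leap years) contains
  a run of more than five consecutive days whose concentration rounds to 0
  at integer-percent precision (absorbing sub-0.5% retrieval noise); HIGH is
  the default. Missing days break runs under both schemes.

## Group comparison

Pheophytin proportions are compared between HIGH and LOW station-years four
ways: {surface, depth-integrated} x {breakup scheme, concentration scheme}.
Depth integration is trapezoidal over the sorted sampled depths with no
extrapolation to the surface or bottom, and the depth-integrated proportion
is the ratio of the integrals (the pigment-mass reading of "depth-integrated
proportion"), not the mean of pointwise ratios; a single-depth profile
degenerates to its pointwise proportion. Each cell reports n, mean, sample
SD (n-1), min, max per group and Welch's unequal-variance t-test (two-sided,
Welch-Satterthwaite degrees of freedom). A summary-statistic entry point
applies the same formulas to published (n, mean, SD) triples and agrees with
the raw-data path to machine precision. A bin with fewer than two
station-years makes that cell not-computable without affecting the others.

## Synthetic data

The generators provide the statistical structure of the real inputs without
any downloads; all are deterministic given a seed.

* **Chlorophyll**: daily truth = baseline (0.3 mg/m^3) + Gaussian pulses
  (default one pulse: peak DOY 150, amplitude 2 mg/m^3, sigma 12 days —
  consistent with the ~20-day peak-to-baseline decline of observed summer
  blooms). Observations exist only on cloud-free days, i.i.d. with retention
  0.19 over the optically retrievable season DOY 106-250, giving ~27
  observations per year, the observed usable-imagery density; an optional
  two-state persistence parameter produces autocorrelated cloud runs.
  Multiplicative lognormal noise with CV 0.15 reflects ocean-colour error
  structure. Truth t1/t2/t3 are computed by the bloom detector on the
  noiseless daily curve. Real blooms are asymmetric; an asymmetry factor is
  exposed but off by default so truth timing stays analytically
  controllable.
* **Sea ice**: an exact winter plateau, a logistic decline centred so the
  first two-day sub-15% run starts exactly on the prescribed breakup day,
  near-zero concentration after melt, optional zero-concentration open-water
  episodes punched into the plateau (they may not overlap the decline), and
  a no-winter-ice mode for years when ice never formed.
* **Pigments**: surface proportions drawn uniformly below the stage boundary
  (0.28 by default) for growing blooms and above it for post-peak blooms,
  drifting upward with depth at 0.004/m (pheopigment accumulates in bottom
  waters). With anchors on, one EB sample is pinned at boundary - 0.001 and
  one PB at the boundary, making the boundary's integer percentage the
  unique perfect threshold — the construction behind the threshold-recovery
  checks.
* **Full-study preset**: 13 stations x 7 years; 2018-2019 are low-ice years
  (no winter ice at two southern stations in 2018), low-ice years bloom
  later (still growing at the July cruise) while high-ice years peak around
  or before it, and a quarter of growing blooms carry residual high
  pheophytin from a recently ended prior bloom — the field/satellite
  mismatch mode the real comparison exhibited. Group separation and class
  balance are therefore cleaner than, but on the scale of, the real
  cruise data.

## What passing tests show — and don't

The synthetic world is separable by construction: pigment proportions are
drawn from disjoint stage ranges, clouds are (by default) independent days,
stations are spatially independent, and blooms are symmetric pulses. Tests
against it verify the pipeline's rules and numerics, not the field validity
of the 28% threshold, which only the real cruise/satellite data can support.

One empirical limit the simulations expose: with LOWESS evaluated at
observation days and linear interpolation between them, the detected peak
day can only fall on an observation day. At ~27 observations per year over a
~145-day season (daily retention p = 0.19) the probability that any
observation lands within +-3 days of the true peak is 1 - (1-p)^7 = 0.77, so
peak-day recovery to +-3 days cannot reach 90% at that density regardless of
noise level (measured: ~0.59 at noise CV 0.15, ~0.61 noiseless; ~0.90 needs
roughly 70+ observations per year). Recovery is exact in the
noiseless, fully observed limit.

## Numerical choices and degenerate inputs

* Units: 1 ug/L = 1 mg/m^3; the two are treated as numerically identical.
* Equality at the field threshold goes to PB; equality at 15% ice
  concentration is retained (masking and breakup both use strict
  comparisons); a breakup exactly on the DOY threshold is HIGH.
* Proportions with chl + pheo = 0 are undefined (below-detection samples are
  flagged and skipped, never coerced to 0 or 1).
* Empty series fail QC rule 1; a scan with no matched pairs, a changepoint
  with fewer than 4 usable years, and a Welch test with n < 2 or two
  zero-variance groups are explicit errors rather than NaN results.
* Sample SD uses the n-1 denominator throughout; p-values are two-sided.

## Problem sizes

Simulation-based checks use 100-1000 replicates per property (100 seeds for
threshold recovery, 200 for peak recovery, 500 for changepoint recovery,
1000 for the type-I calibration of the Welch test), sizes at which the
binomial uncertainty of an estimated rate is ~1-2 percentage points.
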