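# Methods

## The statistic

An acute-care unit is discretized into square grid cells (1 m × 1 m by
default). Each mobile workstation — a nursing cart whose tag position proxies
caregiver presence — projects a *coverage area*: the cell it occupies,
expanded by a Chebyshev dilation of `d` cells in all cardinal and diagonal
directions, i.e. a (2d+1)×(2d+1) block. The default `d = 2` (≈2 m at 1 m
cells) corresponds to the personal/social interaction distance of proxemics:
the range within which a caregiver stationed at the cart can plausibly see
and reach a patient. A Euclidean disc was considered and rejected; the
all-directions phrasing of the coverage rule is exactly the Chebyshev ball,
and square neighbourhoods compose cleanly on a square grid. For cell sizes
other than 1 m, a dilation specified in meters maps to `round(d_m / cell)`
cells.

A cell is in **spatial shadow** at minute *t* if it has been outside every
workstation's coverage area for at least `T` consecutive minutes ending at
*t* (`T = 60` by default, the conventional hourly-rounding interval). The
**percentage of spatial shadow zone** is the shadow area divided by the
total unit area, ×100, evaluated every minute.

Two semantics were open and are fixed as follows:

- *Offset rule.* The threshold defines shadow onset only; we reset a cell's
  uncovered counter to zero the minute it is covered, so a cell leaves
  shadow instantly and re-enters only after another full `T` uncovered
  minutes.
- *Warm-up.* Counters start at zero at stream start, i.e. cells are presumed
  recently visited. Under `warmup_policy="mask_first_T"` the first `T`
  minutes are excluded from analysis instead. Minutes with no workstation
  present at all still advance every counter — absence is precisely what the
  statistic measures.

The incremental tracker (one integer counter per cell) is the production
engine; an independent full-history implementation that rescans the last `T`
coverage rasters per minute serves as the oracle in tests, with bitwise
agreement required on randomized instances.

## Time base and carry-forward

Tags emit at 1 Hz while the workstation moves and once per minute while it
is parked. Analysis runs on calendar minutes: a tag's position at minute *t*
is its last emission at or before the minute's end, carried forward while
the tag's staleness is ≤ 2 minutes (one missed stationary beacon tolerated);
staler tags contribute no coverage. The half-open cell convention
`[k·s, (k+1)·s)` assigns a point on a cell's upper edge to the next cell,
and positions outside the unit polygon contribute nothing.

## Quality control

- *Noise rule.* A point is spurious iff its planar distance to **both** the
  preceding and following point of the same tag exceeds 2.5 m. Requiring
  both neighbours encodes "isolated": a single large step is a legitimate
  move, and two consecutive displaced points form a sustained excursion that
  is deliberately kept. Flags are evaluated simultaneously before removal,
  which makes the filter idempotent. First/last points of a tag are never
  flagged.
- *Noise rate.* Flagged ÷ total, with the companion "1 in N" odds
  denominator `round(total/flagged)`.
- *Missing rate.* Per tag-hour, expected emissions are accumulated gap by
  gap: one per second across motion gaps, one per 60 s across stationary
  gaps (gap duration within [45, 75] s, or displacement < 0.5 m — the
  stationary regime is thereby excluded from the 1 Hz expectation). The rate
  is `1 − observed/expected`, clipped to [0, 1], pooled with a
  normal-approximation 95% CI. No published formula exists for this metric;
  this regime-aware expectation is one defensible reading and is labelled as
  such.

## Accuracy validation

Estimates recorded while a tagged cart traverses a marked polyline route are
scored by planar distance to ground truth. Two correspondences are
supported: nearest point on the route polyline (default — no per-point truth
timestamps are assumed), and paired truth positions when they are known. The
distinction matters for calibration checks: isotropic Gaussian noise of
scale σ around known truth points gives radial errors with the Rayleigh mean
σ√(π/2), whereas projection onto a long straight segment keeps only the
perpendicular component, a half-normal with mean σ√(2/π). Each mode is
tested against its own closed form. Quantiles use linear interpolation
between order statistics (the convention matters for any percentile quoted
from the CDF table). Errors are 2D; the unit is single-storey and `z` is
ignored throughout.

## Association analysis

The unit of analysis is the minute. A minute is event-exposed iff it lies in
the window of `w` minutes ending at (and including) the event's minute;
overlapping windows merge, windows clip at the series start, and `w`
defaults to the persistence threshold `T` — an hour-scale exposure window is
the natural dual of an hour-scale shadow definition. Each minute carries the
day of week and the patient-to-nurse ratio of the shift containing it
(default roster 7:1 days / 9:1 evenings / 10:1 nights).

- *Group contrast:* Welch's unequal-variance two-sample t test (2-tailed)
  of shadow percentage between exposed and unexposed minutes, with the
  difference oriented exposed-minus-unexposed. Welch is used because the
  groups differ enormously in size and plausibly in variance.
- *Regression:* logistic models of the exposure flag on shadow percentage,
  patient-to-nurse ratio and day-of-week dummies (Monday reference), Wald
  CIs on the OR scale per percentage point, no multiple-testing correction.
  With rare outcomes a weekday can contain zero exposed minutes, which
  quasi-separates its dummy and stalls Newton–Raphson although all other
  coefficients are identified; the fit then falls back to BFGS and reports
  the affected levels as non-estimable. Genuine separation on a predictor
  still raises a hard error.
- *Sensitivity grid:* difference-in-means CIs over d ∈ {1,2,3,4} cells ×
  T ∈ {15,30,45,60,75,90} min, each cell relabelled with window = T. A
  single counter pass per dilation serves all thresholds.
- *Split-half:* the analysis repeated on the two halves of the span, split
  at the midpoint week boundary.
- *Fall rate:* 1000 × falls / (beds × days), one decimal; full occupancy is
  assumed when census data are absent.

Per-minute regression coefficients and windowed labels answer different
questions: events drawn per minute and then smeared over 60-minute exposure
windows yield a windowed OR larger than the per-minute generating OR,
because exposure minutes cluster where shadow is persistently high.
Parameter-recovery tests therefore label with a 1-minute window (the
correctly specified model); direction-of-effect and descriptive analyses use
the default 60-minute window.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions under
which the pipeline is exercised.

*Geometry and movement.* A 20 × 20 m (400 m²) unit with 40 beds in four
rows of ten and 4 workstations. Each workstation alternates bedside dwells
with straight-line transits at a speed drawn uniformly from 0.5–1.0 m/s.
Dwell durations are lognormal (median 60 min, σ = 0.6); the next stop is
the central station with probability 0.5, otherwise preferentially a bed
within 5 m (probability 0.8) — a rounding-style local walk. These movement
parameters are not observable from published material; they were fixed once
so that the emulated unit's occupancy statistics sit at the reported scale
(mean shadow ≈ 74%, SD ≈ 6–8 at d = 2, T = 60) and are not tuned per test.
Emission follows the tag duty cycle: 1 Hz in transit, one beacon per 60 s
while parked.

*Artifacts.* Points are deleted independently (default 1%) and surviving
interior points are displaced with probability 0.226% by a jump of 4–10 m in
a uniform direction — gross multipath outliers comfortably above the 2.5 m
rule, kept isolated so they match the artifact class the filter targets.
Injected indices are recorded so sensitivity and false-positive rate are
scored against exact truth.

*Events.* Falls and ICU transfers are per-minute Bernoulli draws with
log-odds linear in the true shadow percentage: slopes ln(1.02) and ln(0.99)
per percentage point, intercepts calibrated by bisection so expected counts
match 8 falls and 89 transfers per 210 days (an inflation factor supports
power studies). Faller types and transfer causes are sampled at the observed
frequencies. The inverse shadow–ICU association additionally has a
mechanistic arm: for each transfer, one workstation's emissions during the
preceding hour are replaced by stationary bedside beacons at a patient bed
(intensified bedside care), the shadow series is recomputed, and falls are
then drawn from the final series. Low shadow before transfers is thus a
marker of escalating acuity, not a protective factor — matching the
interpretation the analysis is meant to support.

*Reproducibility.* All randomness flows from one seed through three spawned
substreams (trajectories, corruption, events), so toggling one stage does
not shift the others; equal seeds give byte-identical outputs.

## What the generator does and does not emulate

It reproduces the emission duty cycle, walking speeds, unit geometry, the
artifact rates, event frequencies and the assumed exposure–outcome link. It
does not model walls or line-of-sight occlusion (coverage is purely metric),
patient-level risk factors, tag dropouts correlated with location, shift
handovers, or non-stationary behaviour across the study span. Passing tests
therefore demonstrate that the pipeline measures what it defines and
recovers known structure — not that the clinical associations generalize.

## Problem sizes and numerics

Tests run the tracker-vs-oracle comparison on 100 randomized grids up to
10 × 10 × 300 minutes; monotonicity on a 1-day simulated surface; parameter
recovery on 200 replicates of 7 days each with the baseline fall rate
inflated to ≈300 events per replicate, the regime in which the logistic
MLE's small-sample bias is negligible relative to Monte-Carlo error; and one
210-day full-scale study for effect directions. Counters are int32; rasters
are boolean; bisection for intercepts runs 200 iterations on a [−40, 10]
bracket. Degenerate inputs (empty streams, single-class outcomes, constant
predictors, degenerate polygons and routes) raise explicit errors rather
than propagating NaNs.

## Known limitations

- The missing-rate expectation model is a convention; alternative readings
  (e.g. excluding regime-transition gaps) would shift the metric.
- The exposure-window rule for event labelling is a convention; sensitivity
  to it is exposed via `window_minutes` but only the default is exercised in
  the shipped analyses.
- The movement model is a semi-Markov caricature of nursing workflow; it is
  adequate for exercising the statistic, not for simulating staffing policy.
- With outcome counts as small as 8, day-of-week adjustment is partially
  non-estimable by construction; the fallback reports rather than hides
  this.
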