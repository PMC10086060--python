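# Methods

This note documents the models behind `greenwave`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical decisions a user auditing results should know about.

## Phenology and IRG

Scaled NDVI is modelled as a difference of two logistics: a spring ramp
(inflection `xmidS`, scale `scalS` days) minus an autumn ramp (`xmidA`,
`scalA`). The Instantaneous Rate of Green-up is defined as the derivative
of the **spring component only**. The full-curve derivative would be
pulled negative by senescence and would shift the apparent peak for
pixels with early autumns; with the spring-only definition the date of
peak IRG is exactly `xmidS` and the peak value exactly `1/(4·scalS)`,
which the tests exploit as analytic oracles. IRG integrates to ~1 over
the year (it is the derivative of a unit-range logistic), so IRG values
are comparable across pixels regardless of green-up speed.

Scaling maps each pixel's series affinely onto [0, 1]. By default values
are first winsorised at the 2nd/98th percentiles so single snow/cloud
artefacts cannot dictate the range; raw min–max scaling is available (and
used in tests that need exact arithmetic). A constant series is flagged
unscalable; a monotone non-increasing series (no spring green-up) is
flagged unfittable, and raster fitting records such pixels as missing
rather than failing.

The nonlinear least-squares fit is multi-started: `xmidS` begins at the
day of the largest positive first difference, `xmidA` at the most
negative one, with `scalS ∈ {3, 8, 15}` and `scalA ∈ {8, 15}` days,
because the double logistic has local optima when only one shoulder of a
ramp is sampled. Bounds keep both scales in [0.5, 90] days. The best
converged start by residual sum of squares wins; observations are assumed
at roughly the 8-day compositing cadence of satellite NDVI products, and
a series needs at least 8 points.

The foraging penalty ("loss in IRG") for a pixel is the mean of
`IRG(peak) − IRG(peak + δ)` over `δ = ±1..±7` days, expressed as percent
of `IRG(peak)`. It is 0 in the limit of slow green-up and strictly
decreasing in `scalS`, which is the mechanism by which mismatch is
costlier where green-up is rapid and fleeting — in this system, toward
the distal (montane) end of the corridor.

## Track cleaning and migration segmentation

Fixes are removed by a greedy forward pass whenever the segment speed
from the last *kept* fix exceeds 10.8 km/h (the later fix of the pair is
dropped); the pass is idempotent and an error is raised if more than half
a track is removed. The threshold is the analysis constant for
implausible deer travel; the choice of dropping the later fix is the
common telemetry-cleaning convention.

Migration timing uses the logistic net-squared-displacement model
`NSD(t) = δ/(1 + exp((θ − t)/φ))` fitted by least squares (`δ` in km²).
A fitted asymptote below 25 km² (a 5-km displacement) is reported as a
resident animal-year. Timing is **not** read off the fitted curve's
tails: a logistic fitted to the ramp-like NSD of a steady migrant
stretches its tails far past the true departure (measured bias around
−9/+10 days), and a threshold at 2.5% of δ on the squared scale sits at
15.8% of the migration distance (bias ≈ +7 days on a 50-day migration).
Instead, departure and arrival are the first and last days the *observed*
net displacement crosses 2.5% and 97.5% of the asymptotic displacement
`√δ`, linearly interpolated between fixes. On simulated cohorts this
recovers true departure dates with a mean absolute error of ≈ 1.2 days,
which is the convention's validation. Duration is arrival minus
departure; distance is the straight line between the fixes nearest those
days; movement rate is distance over duration.

Seasonal ranges are 95% isopleths of a bivariate Gaussian kernel UD with
the movement-ecology reference bandwidth `h = √((var_x+var_y)/2)·n^(−1/6)`
per axis, on the same 150-m grid family used by the Brownian-bridge UD.
Winter-range fixes are those before departure; summer-range fixes those
after arrival. A range's mean peak date is the mean of `xmidS` over the
raster cells its isopleth covers.

## Brownian bridge movement model

Between consecutive fixes the animal is a conditioned Brownian motion: at
fractional time `a` of a bridge of duration `T`, position is bivariate
normal about the interpolated endpoints with variance
`T·a·(1−a)·σ²ₘ + (1−a)²·δ² + a²·δ²`, where `δ` is GPS location error
(default 20 m, a typical collar figure) and `σ²ₘ` the Brownian motion
variance. **Units:** time is measured in minutes, so `σ²ₘ` is m²/min and
the exclusion gate of 8,000 follows the convention of the field's BBMM
software; the gate is inclusive (exactly 8,000 passes).

`σ²ₘ` is estimated by maximising the leave-one-out likelihood of every
interior fix under the bridge joining its two neighbours, a bounded 1-D
search on [1e-4, 1e6]; a solution pinned at a bound is flagged (a
noiseless constant-velocity track legitimately pins the lower bound).
Monte-Carlo recovery on discretely observed Brownian tracks is within a
few percent at σ²ₘ = 500 m²/min.

The UD integrates each bridge's occupancy at ≥3 regular time steps
(default 15-min spacing) and deposits, per step, the kernel's **exact
cell-integrated mass** via per-axis normal-CDF differences. This matters:
with 2-h fixes and 20-m error the kernel can be much narrower than a
150-m cell, and centre-point evaluation would alias badly. Kernels are
truncated at 5 sd. Bridges across gaps longer than 8 h are excluded
(standard practice; long bridges are uninformative smears). The single
bridge UD agrees with a 10⁵-sample Monte-Carlo simulation to total
variation ≈ 0.01.

Stopovers are the 8-connected components of the 10% highest-density
isopleth — "10% UD" is read as the smallest region holding 10% of mass,
the standard stopover definition. Residence days per component are the
component's fix count divided by the fix rate; components under 3 days
are dropped, and an empty stopover set is a valid outcome. In the
pipeline the BBMM runs on the fixes inside the migration window only, so
winter/summer residency does not masquerade as stopover use.

## Surfing metrics and the wave profile

Days-From-Peak is `fix date − local peak date`; **positive means behind
the wave**, and the same sign convention is applied to start/end range
mismatches (`migration date − mean range peak date`). The source
analyses state the range-mismatch subtraction in the opposite order while
reporting magnitudes as "ahead/behind"; one convention is enforced
repo-wide and documented here. Per-fix DFP is averaged per (day, 1-km
corridor bin) before any population statistic; the along-corridor
kilometre of a fix is its projection onto the corridor axis, not
cumulative path length, and the corridor origin is its southern end.

The wave profile averages peak date per 1-km bin over all corridor cells
(not only track-visited ones). Propagation direction is the sign of the
finite difference of a 9-bin moving average, with same-direction runs
shorter than 5 km merged into their dominant neighbour — with ~2-day
pixel noise an unsmoothed sign would shatter the corridor into sub-scale
segments that have no ecological reading. Each surviving segment gets an
OLS regression of mean peak date on distance (slope, p-value); segments
under 3 bins carry no regression. Weekly wave profiles are median IRG
per (km, 7-day block); a lowess smoother is available for display only.
The penalty profile averages per-cell loss-in-IRG by corridor quarter and
reports the last/first ratio.

## Compensation classes and the ordinal model

Start dates are standardised to each year's median before pooling.
Timing classes use pooled type-7 (linear-interpolation) quantiles —
early ≤ Q1, late ≥ Q3, mid otherwise; the definition is documented
because class counts are sensitive to it. Under heavy ties a value
satisfying both boundary rules is early (first rule wins), so the
partition is total and deterministic.

Compensation classes are evaluated with precedence
**perfect → full → partial → non** over (|start|, |end|) with a 7-day
window: perfect iff both within 7; full iff |start| > 7 and |end| <
|start|; partial iff |start| > 7 and ||end| − |start|| ≤ 7; else non.
The precedence resolves the overlap in the verbal definitions (improving
from 20 to 15 days off is both "closer" and "within 7 of the start");
full-before-partial is chosen because full compensation dominates the
empirical counts and is the outcome the probability model targets.

The ordinal model is a cumulative-logit (proportional-odds) regression of
class — ordered `non < perfect < partial < full`, read as increasing
behavioural adjustment; the source analyses do not state their ordering —
on one predictor (absolute starting mismatch, or age, fitted separately).
Estimation is maximum likelihood via `statsmodels`' `OrderedModel`; the
likelihood is undefined for outcome levels with zero observations, so the
fit runs over the observed levels in the global order. Wald 95% CIs are
reported; `exp(β)` is the per-day odds ratio; a diverging slope
(|β| > 30 or exploding SE) raises a separation warning. Cohort utility
statistics are per-timing-class means with normal-theory CIs, a paired t
and Wilcoxon signed-rank test of |DFP| start vs end (defined as t = 0,
p = 1 for identical columns), one-way ANOVAs across timing classes, and
two-sided z-tests of mean start/end mismatch against zero.

## The synthetic study system

The generator emulates the statistical structure the analysis assumes,
not any particular landscape:

* **Landscape** — a 240 km × 5 km corridor of 1-km cells. Peak date is
  `base_peak_day + wave_slope·(km − no_wave_length)` beyond the first
  32 km (defaults: day 110 at the wave origin, 0.35 d/km — a wave
  travelling ≈ 2.9 km/day), and mildly *decreasing* with distance
  (−0.15 d/km) over the initial 32-km no-wave segment, with N(0, 2 d)
  per-cell noise. The spring scale shrinks linearly from 11 days at the
  origin to 4 days at the corridor end, making distal green-up more
  rapid and fleeting; autumn trails spring by 120 days.
* **Agents** — daily along-corridor displacement
  `clamp(base + gain·DFP, 0, max)` km while migrating (defaults 4, 0.15,
  12 km/day), zero on stopover days. The stopover rule pauses an agent
  more than 2 days ahead of local peak, but only en route (beyond a
  35-km departure commitment): departure itself is a decision taken at
  the animal's own date, and migrants that paused on the winter range
  would erase the very mismatch under study. Perceived mismatch is the
  true local DFP (no sensory noise by default — the mechanism of
  perception is left open). Fixes at 1-, 2- or 3-h schedules with 15-m
  GPS noise (a chosen figure; collar error is rarely published), small
  cross-corridor wander, and 12 recorded days on each seasonal range.
* **Cohort** — departures uniform over ~100 days around local peak;
  behaviour mixture 60% compensators (gain ~ N(0.15, 0.03), stopover
  rule on), 25% pace-keepers (constant speed near the wave's own pace,
  carrying their mismatch to arrival — the partial-compensator
  phenotype), 15% non-compensators (constant speed on their own
  schedule). Migration targets ~ N(190, 15) km; ages 1–13; everything
  reproducible from one seed.

What passing on this system shows: the estimators recover the quantities
they target under the assumed data-generating structure (logistic NSD
rise, Brownian bridges, double-logistic phenology), and the pipeline
reproduces the directional population findings (arrival compression,
faster late migrants, stopover-heavy early migrants, rising probability
of full compensation with starting mismatch). What it does not show:
robustness to missing fixes and collar failure, snow/cloud-contaminated
NDVI, topographically curved corridors, autumn migration, or behaviour
outside the three scripted archetypes. The simulator is a test harness,
not an inference target — no attempt is made to fit its rules to real
deer.

## Problem sizes and runtimes

The demo cohort is 60 animal-years at 2-h fixes on the 240-km corridor
(~8 s end to end on one CPU); segmentation recovery uses 200 simulated
migrants; the motion-variance benchmark 100 replicates of 200-fix
Brownian tracks; the bridge-UD benchmark one bridge against 10⁵
Monte-Carlo samples; phenology recovery 200 noisy refits at 8-day
cadence. These sizes make the full test suite and the acceptance script
each run in well under a minute of compute apiece while keeping
Monte-Carlo tolerances meaningful.

## Known limitations

* The NSD model fits a single spring migration; multi-leg or exploratory
  movements need pre-segmentation.
* The BBMM is time-homogeneous within an animal-year (no
  behaviour-switching dynamic variance).
* The motion-variance unit convention (m²/min) is asserted, not derived;
  analyses comparing against other software should check its time base.
* Mixed-effects variants of the population tests (year/animal random
  intercepts) are out of scope; annual standardisation is the treatment
  of year effects.
* Kernel and BBMM grids are axis-aligned with fixed 150-m cells;
  isopleth areas inherit that discretisation.
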