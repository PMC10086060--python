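# greenwave

Phenology tracking and en-route compensation analysis for migratory
ungulate GPS telemetry.

Many temperate ungulates time their spring migration to "surf" the green
wave — the spatial progression of peak plant green-up from low winter
ranges toward high-elevation summer ranges. Individuals often *start*
migration weeks ahead of or behind the wave, and the central question this
package addresses is whether they compensate en route: do mismatched
migrants speed up, slow down, or linger on stopovers so that they arrive
back in phase with peak forage quality?

`greenwave` provides the full measurement chain for that question, from
raw fixes and NDVI series to the population-level ordinal regression, plus
a behaviour-driven simulator so every stage can be exercised and validated
without field data. It is aimed at movement ecologists working with
Movebank-style telemetry and gridded vegetation phenology.

## What it computes

**Phenology.** Per-pixel scaled NDVI series are fit to the double logistic

    NDVI(t) = 1 / (1 + exp((xmidS − t)/scalS)) − 1 / (1 + exp((xmidA − t)/scalA))

with `t` in continuous day-of-year. The Instantaneous Rate of Green-up
(IRG) is the derivative of the spring component; it peaks at `xmidS` with
value `1/(4·scalS)`, which dates peak green-up for the pixel. The foraging
penalty of mismatch is scored as the *loss in IRG*: the mean drop in IRG
over 1–7 days either side of the peak, as a percent of the peak — steep,
fleeting green-up (small `scalS`) makes mismatch expensive.

**Tracks.** Fixes implying speeds above 10.8 km/h are removed as GPS
errors. Migration timing comes from the logistic net-squared-displacement
(NSD) model `NSD(t) = δ / (1 + exp((θ − t)/φ))`; departure and arrival are
the days net displacement crosses 2.5% and 97.5% of the asymptotic
displacement `√δ`. Seasonal ranges are 95% kernel-UD isopleths; migration
movement rate is straight-line distance over duration.

**Surfing.** Days-From-Peak (DFP) is the date of a fix minus the local
date of peak IRG — positive behind the wave, negative ahead, 0 for a
perfect surfer — averaged per day and kilometre of corridor to control
pseudoreplication. Start/end mismatches compare migration dates with the
mean peak date of the winter/summer range. The corridor-wide wave profile
(mean peak date per km, with signed propagation segments and per-segment
regressions) and the per-quarter penalty profile describe the resource
side of the system.

**Stopovers.** A Brownian bridge movement model with leave-one-out
motion-variance estimation yields a 150-m utilization distribution;
high-use stopovers are the connected components of the 10% highest-density
isopleth occupied for at least 3 days (fix count divided by fix rate).
Animal-years with motion variance above 8,000 are excluded as unreliable.

**Compensation.** Each animal-year is classed by timing (early/mid/late
pooled quartiles of year-standardised start dates) and by outcome —
perfect surfer, full, partial or non-compensator, from |DFP| at the start
versus the end of migration with a 7-day window. The probability of full
compensation as a function of starting mismatch is modelled with a
cumulative-logit (proportional-odds) regression; `exp(β)` is the per-day
odds ratio.

## Worked example

Simulate the default synthetic study system — a 240-km corridor whose
green wave does not propagate for the first 32 km, and 60 migrants
departing over a ~100-day window — and run the whole analysis:

```python
from greenwave import RunConfig, run_all

report = run_all(RunConfig(n_agents=60, outdir="demo_out", seed=1))
s = report.summary
per = s["per_class"].set_index("timing_class")
print(f"animal-years analysed : {len(report.records)}")
print(f"start-mismatch SD     : {s['sd_start']:.1f} d   "
      f"end-mismatch SD: {s['sd_end']:.1f} d")
print(f"paired t (|DFP| end vs start): t = {s['paired_t']['t']:.2f}, "
      f"p = {s['paired_t']['p']:.2g}")
for tc in ("early", "mid", "late"):
    print(f"{tc:>5}: n={per.loc[tc, 'n']:>2}  "
          f"rate={per.loc[tc, 'mean_movement_rate']:.2f} km/d  "
          f"stopover days={per.loc[tc, 'mean_stopover_days']:.1f}")
print(report.ordinal_fit.summary())
```

The run prints (seed 1):

```
animal-years analysed : 60
start-mismatch SD     : 26.7 d   end-mismatch SD: 20.9 d
paired t (|DFP| end vs start): t = -4.27, p = 7.2e-05
early: n=15  rate=2.94 km/d  stopover days=4.7
  mid: n=30  rate=3.83 km/d  stopover days=1.9
 late: n=15  rate=4.60 km/d  stopover days=0.5
Proportional-odds model of compensation class
  ordering : non < perfect < partial < full
  predictor: abs_dfp_start
  beta     : 0.0417 (SE 0.0202)
  95% CI   : [0.0021, 0.0813]
  odds ratio per unit: 1.0425
```

Read: the cohort departed far out of phase with the wave (SD 26.7 days)
but arrived noticeably compressed (SD 20.9 days); absolute mismatch
shrank significantly between start and end (paired t); late migrants
moved faster and used stopovers less than early migrants; and each extra
day of starting mismatch raised the odds of full compensation (β > 0,
odds ratio 1.04/day on this synthetic cohort). `demo_out/` receives the
records table, wave and penalty profiles, probability curves, figures and
a JSON report.

The same stages are scriptable from the shell:

```sh
greenwave simulate --seed 1 --outdir demo_out        # tracks + landscape
greenwave segment demo_out/tracks/deer000-2016.csv   # one migration window
greenwave run-all --seed 1 --outdir demo_out         # everything
```

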