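# hogwatch

Movement-ecology analysis pipeline for urban European hedgehogs
(*Erinaceus europaeus*) tracked with combined GPS / tri-axial
accelerometer (ACC) loggers and daily nest surveys. It quantifies how a
transient disturbance (an open-air music festival) and permanent habitat
fragmentation change spatial behaviour, activity rhythms and nesting —
the kind of before/after, control/impact comparison wildlife researchers
run on telemetry from a handful of intensively tracked animals.

Because raw field telemetry of this kind is rarely shareable, the package
ships a first-class synthetic-data generator that emulates the sampling
protocol (GPS bursts of five 1-s fixes every 10 min from 19:00 to 07:00
local; one 2.5 s / 2.64 s ACC burst at 100 Hz per minute around the
clock; daily nest records) with known ground truth, so every stage of the
analysis is testable end to end.

## What it computes

**Space use, per individual-night.** After cleaning (drop fixes > 1000 m
from the site centre, average each 5-fix burst, remove records implying
speeds > 2 m/s), each night yields

- the 95% minimum convex polygon area: keep the ⌈0.95 n⌉ positions
  nearest the arithmetic centroid and take the convex hull (MCP95, ha);
- the 50% kernel isopleth core area with the ad hoc bandwidth
  h_ref = σ · n^(−1/6), σ² the pooled coordinate variance (KDE50, ha);
- path length (m), mean step speed (m/s), and search intensity
  path / (MCP95 area), in m/(m²·d);
- the nightly centroid, and its per-axis absolute deviation from the
  individual's pre-disturbance mean centroid (the avoidance signal).

**Movement character.** Absolute turning angles θ ∈ [0, π] between
successive headings, compared between treatments by a repeated
subsampled two-sample Kolmogorov–Smirnov test (1000 draws of 200 angles
per group; report the significant fraction and median p).

**Behaviour from ACC.** Each validated burst (complete sample count
only) is summarised by 25 features (per-axis mean/SD/min/max/skewness,
mean ODBA, axis correlations, per-axis dominant frequency and spectral
entropy) and classified into resting / balling (rolled up) / walking by
one-vs-rest SVMs with calibrated probabilities; a maximum class
probability below 0.7 yields "other". Daily behaviour budgets are class
proportions over complete days (≥ 1430 of 1440 minute records).

**Circadian coupling (DFC).** Per-minute activity intensity (summed
per-axis SD of each burst) over sliding 3-day windows is autocorrelated,
Fourier-decomposed at periods T/m (T = 3 d, periods 3 d … 2 min), and the
Degree of Functional Coupling is the share of significant rhythmic power
at periods that divide 24 h evenly (m a multiple of 3). DFC = 1 means
activity locked to the environmental day; 0 means no coupling.

**Nesting.** Daily nest fixes within 2 m of a known nest are the same
nest; runs of consecutive days in one nest become occupation intervals,
right-censored at study boundaries and tracking gaps; survivorship is
estimated by Kaplan–Meier and compared between groups with the log-rank
(Mantel) test, alongside next-day reuse probabilities.

**Group comparisons.** Night-level responses are modelled as

  y = treatment × sex (fixed) + individual (random intercept) + ε

by REML, with Type II Wald χ² tests and the study's contrast family
(pre ♀ vs ♂, pre vs festival within sex, pre vs fragmented within sex,
fragmented ♀ vs ♂) under a single-step max-|z| family-wise adjustment.
Square-root (centroid deviations) and arcsine (DFC) transforms and an
optional power-of-the-mean variance weighting are built in.

## Worked example

```python
from datetime import date
from hogwatch import preprocess, space_use, synthetic, telemetry_io

cfg = synthetic.SimConfig(
    n_individuals_per_sex_per_treatment=2,
    treatment_calendar=[
        ("pre", (date(2016, 8, 10), date(2016, 8, 19))),
        ("festival", (date(2016, 8, 29), date(2016, 9, 7))),
    ],
    seed=42)

fixes = synthetic.simulate_tracks(cfg)
fixes = telemetry_io.add_planar_coordinates(fixes, cfg.site_centre)
records, report = preprocess.preprocess(fixes, cfg.site_centre)
print(f"{report.n_input_fixes} fixes -> {report.n_records} positions")

nights, _ = space_use.nightly_summaries(records)
print(nights.groupby(["sex", "treatment"])[["mcp95_ha", "kde50_ha"]].mean().round(2))

dev = space_use.centroid_deviation(nights)
print(dev[dev["treatment"] == "festival"]
      .groupby("sex")[["abs_dev_east_m", "abs_dev_north_m"]].mean().round(1))
```

prints

```
29200 fixes -> 5840 positions
                  mcp95_ha  kde50_ha
sex    treatment
female festival       1.41      0.75
       pre            2.85      1.70
male   festival       2.39      1.39
       pre            4.62      2.81
        abs_dev_east_m  abs_dev_north_m
sex
female            34.9             31.3
male              67.1            105.5
```

Two animals per sex were tracked for ten nights before and ten nights
during a simulated festival. Control females used ~2.9 ha per night and
males ~4.6 ha (the generator's calibration targets are 2.55 and
4.71 ha); both sexes contracted their ranges during the festival, and
the nightly centroids moved away from the pre-phase mean by ~(35, 31) m
in females and ~(67, 106) m in males — the pipeline recovering the
generator's configured (35, 30) and (65, 105) m displacement almost
exactly.

A command-line interface mirrors the stages
(`hogwatch simulate | preprocess | spaceuse | angles | behave | dfc |
nests | infer | run-all`); `hogwatch run-all --seed 7 --out out/` runs
the whole chain and writes a provenance manifest.

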