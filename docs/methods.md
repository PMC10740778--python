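# Methods

## Model

The package implements a deterministic, daily-timestep stock-and-flow
model of herd forage demand.  For animal *i* on day *d* (0-based, one
index per day of the grazing period), daily dry-matter intake is

    DMI_{i,d} = BW_{i,d} · pct_bw / 100   [kg DM d⁻¹]

and the herd ledger is the discrete accumulation

    cumDMI(d) = cumDMI(d−1) + Σ_i DMI_{i,d},      cumDMI(−1) = 0,
    cumHa(d)  = cumDMI(d) / (F · HE),

where `F` is standing forage (kg DM ha⁻¹) and `HE` the harvest
efficiency.  The conservation identity `cumHa · F · HE = cumDMI` holds
exactly at every day, and the model is exactly linear in `pct_bw`, in
head count, and in BW; the test suite asserts all three.

Assumptions worth stating plainly:

- **Static forage supply.** `F` is a single number for the whole
  period (initial dormant-season or peak standing crop).  No regrowth,
  senescence, or nutrient dynamics — appropriate for dormant winter
  range, increasingly wrong for a growing sward.
- **Intake is a fixed fraction of BW.** No energy-balance (NRC-style)
  intake equation, no forage-quality feedback, no supplement
  accounting.  `pct_bw` is the single behavioural parameter.
- **Monthly aggregation** samples the cumulative series every 30 days
  (`days_per_month`) plus the period end; the final block may be
  partial.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `au_base_bw` | 454 | kg | definition of the animal unit |
| `au_pct_bw` | 2.6 | %BW d⁻¹ | reference-cow intake; gives 354.12 kg per AUM |
| `days_per_month` | 30 | d | stocking-month convention |
| `pct_bw` | 2.5 | %BW d⁻¹ | nominal for growing cattle on rangeland |
| `harvest_efficiency` | 0.25 | — | take half, leave half: 50% left standing, half the taken 50% lost to trampling/fouling |
| `residual_cutoff` | 3.0 | robust SDs | flag records beyond 3 MAD-based scales from the robust trend |
| `smoothing_window` | 3 | d | damp rumen-fill (gut content) swings without distorting growth |
| `%BW range` | 1.8–2.7 | %BW d⁻¹ | spans low- to high-quality forage intake rates |

Internal arithmetic is full precision; rounding (ha and AU to 2
decimals, kg to integers) happens only at reporting edges (CLI
summaries, examples).

## Cleaning the scale stream

In-pasture scales produce repeated, irregular, noisy observations.
The pipeline is per animal:

1. **Robust outlier filter.** A linear BW-vs-day trend is fitted with
   a Huber M-estimator (statsmodels RLM, iteratively reweighted).
   Residual scale is 1.4826 × MAD with a tiny floor so an exact fit
   does not divide by zero.  Records beyond `residual_cutoff` × scale
   are flagged; the line is refitted once on the kept records and
   flags recomputed (two-pass).  Fewer than 8 records: pass through
   with a warning.  All records on one day: median/MAD fallback.  The
   filter sees only the (day, weight) set, so it is order-invariant.
   The loss, cutoff and per-animal (rather than pooled) fitting are
   this package's choices; "robust regression" admits many variants
   and we chose the most conventional bounded-influence one.
2. **Daily alignment.** Same-day kept records are averaged; interior
   gaps are linearly interpolated; leading/trailing gaps carry the
   nearest observation.  Gaps longer than `max_gap_days` raise a
   `DataQualityWarning` naming the days so an analyst can instead drop
   those days herd-wide (the practice used in the original trials,
   which shortened the heifer period from 175 to 167 d).
3. **Smoothing.** A centered rolling mean (default 3 d, configurable,
   odd) with truncated edge windows.  Note the truncated edges mean a
   perfectly linear series is reproduced exactly only in the interior;
   the first and last days are pulled half a daily gain inward.  We
   accept this bias (≤ 0.4 kg at default ADG) in exchange for
   output length equal to input length with no extrapolation.

## Scenarios and extrapolation

Scenario 1 holds every animal at the herd-average initial BW; Scenario
2 at a static mid-season BW; Scenario 3 feeds the cleaned per-animal
panel through unchanged.  A precision scenario whose matrix is constant
at the initial BW reproduces Scenario 1 exactly (tested).  Mid-season
BW offers three conventions: `endpoint_mean` (mean of initial and
final herd BW — the steer convention), `target_fraction` (initial +
fraction of the distance to a management target such as a breeding
weight), and `passthrough` (a published literal; the heifer case's
301.53 kg is not recoverable from the stated target arithmetic over
167 d, so it is carried as given).

Regional extrapolation multiplies a per-herd area difference by the
ratio of regional to local head count and **truncates toward zero**
(floor for positive values): the published state totals (458,812 from
458,812.5; 1,659,687 from 1,659,687.5) force truncation rather than
round-half-up.

## Sensitivity

Because the ledger is linear in `pct_bw`, the exact envelope of any
total under a %BW range is `total · lower/nominal` to
`total · upper/nominal`; the max/min ratio is always `upper/lower`
(1.5 for 2.7/1.8).  The Monte Carlo (default 10,000 runs) draws %BW
from a truncated normal on [1.8, 2.7].  Only the range is pinned by
the published results; mean 2.25 (midpoint) and sd 0.15 (≈ range/6)
are this package's defaults and are configurable.  One draw per run is
applied herd-wide, matching a single-parameter sensitivity; a
`per_animal` mode draws independently per animal, which narrows the
envelope by herd averaging.  In herd-wide mode each run is the nominal
ledger rescaled — an optimization the tests verify is *exactly* equal
to a full rerun, not an approximation.  Percentile bands default to
50/75/95/100% coverage (percentiles 25/75, 12.5/87.5, 2.5/97.5,
0/100, plus the median).

## Synthetic data

The generator emulates the structure the pipeline assumes: per-animal
linear growth `BW_{i,d} = BW_{i,0} + ADG_i · d` with normal initial BW
and ADG, observed through Bernoulli daily visitation, a 3-day-period
rumen-fill sinusoid with per-animal phase, Gaussian measurement error,
and Bernoulli ± shocks tagged in a hidden truth table.  Heifer preset:
n=60, 167 d, initial 237.6 ± 15.5 kg, ADG 0.70 ± 0.08 kg d⁻¹
(back-derived from the cohort's initial and mid-season averages).
Steer preset: n=127, 60 d, initial 293 ± 49.6 kg, ADG 0.74 ± 0.12.
Observation defaults — visit probability 0.8, noise sd 5 kg, rumen
amplitude 4 kg, 5% spurious records at ±60 kg — are chosen to be
realistic for walk-over scale streams, not measured from any deposited
dataset.

What the generator does **not** emulate: growth curvature and
compensatory gain, weather- or behaviour-driven visitation (multi-day
water-point absences are possible but uncorrelated), scale drift, and
correlated errors from mis-identification.  Passing the end-to-end
recovery test (cleaned budget within 2% of the noise-free budget)
therefore shows the pipeline handles the *assumed* error structure; it
does not certify performance on pathologies outside it.

## Numerical choices and degenerate inputs

- Day grid is 0-based integer; calendar dates are converted to offsets
  at ingestion and never touched again.
- Weights are full BW in kg throughout; no unit conversion.
- Zero kept records for an animal is a hard error naming the animal;
  an empty herd is an error; period/matrix dimension mismatches are
  errors rather than silent broadcasts.
- `pct_bw` must be strictly positive (the zero-intake limit is
  available through linearity, not through a degenerate parameter).
- Robust-scale floor: `max(1.4826·MAD, 1e-8·max(1, median |BW|))`.

## Known limitations

- Scenario-3 published totals (334.07 ha in one table, 338.96 ha in
  another) cannot be recomputed because the underlying per-animal
  weight streams were never deposited; both literals are shipped
  frozen in `foragebudget.reference` and checked only for internal
  consistency.  Likewise the published per-pasture steer totals
  require per-pasture head counts that were never published; the
  `reproduce` path takes them as user input.
- The 30-day month convention makes one published introductory example
  (0.42 ha/AUM for a 381 kg heifer) come out at 0.41 here; a 31-day
  month reproduces it, but the defaults follow the parameter table.
- Test and acceptance problem sizes follow the case-study dimensions
  (60 × 167 and smaller); the Monte Carlo uses the published 10,000
  runs, which the linear-scaling implementation makes essentially free.
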