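# foragebudget

Forage budgets and stocking rates for grazing beef cattle, driven by
precision body-weight data.

## The problem

Rangeland stocking rates are set with animal unit months (AUM): one
animal unit (AU) is a 454 kg cow eating 2.6% of her body weight (BW)
per day on a dry-matter basis, so one AUM is about 354 kg of forage.
Daily dry-matter intake (DMI) is modelled as a fraction of BW,

    DMI_{i,d} = BW_{i,d} · pct_bw / 100        [kg DM d⁻¹],

herd demand is accumulated day by day, and dividing by the *consumable*
forage density — standing forage (kg DM ha⁻¹) × harvest efficiency,
0.25 under the NRCS "take half, leave half" rule — gives the hectares
the herd needs:

    cumHa(d) = Σ_{d'≤d} Σ_i DMI_{i,d'} / (F · HE).

Traditionally BW is a single herd-average *initial* weight held fixed
for the whole season, which understates demand for growing cattle.
In-pasture walk-over scales now yield daily per-animal weights, and
this package quantifies what that precision buys: it cleans the raw
scale stream (robust outlier filtering, daily alignment, rumen-fill
smoothing), runs the daily intake/area ledger on per-animal weights,
compares it against initial-BW and mid-season-BW baselines, and
propagates uncertainty in the %BW intake parameter (range 1.8–2.7)
through a Monte Carlo percentile envelope.  A synthetic-data module
generates scale streams with known ground truth for end-to-end
validation, and frozen reference tables from the two South Dakota
case studies the model was developed against (60 replacement heifers
over 167 d; 254 yearling steers over 60 d) support reproduction checks.

Intended users: rangeland and animal scientists working with precision
weighing systems, and modellers building grazing decision-support tools.

## Worked example

```python
import foragebudget as fb

params = fb.IntakeParameters(pct_bw=2.5, head_count=60, period_days=167)
supply = fb.ForageSupply(forage_kg_per_ha=917.78, harvest_efficiency=0.25)
period = fb.GrazingPeriod(167, label="heifer winter")

s1 = fb.run_scenario(fb.ScenarioSpec(kind="initial_bw", static_bw_kg=243.45),
                     params, supply, period)
s2 = fb.run_scenario(fb.ScenarioSpec(kind="midseason_bw", static_bw_kg=301.53),
                     params, supply, period)
print(round(s1.total_ha, 2), round(s2.total_ha, 2))
```

prints `265.79 329.2`: budgeting 60 heifers at their initial 243.45 kg
for 167 days requires 265.79 ha of this dormant range, while the static
mid-season weight of 301.53 kg raises that to 329.20 ha — a 63 ha gap
from ignoring growth.  `examples/heifer_scenarios.py` extends this with
a precision scenario on a synthetic growing herd and scales the gap to
a 375,000-head state herd with `extrapolate_overgrazing`;
`examples/sensitivity_envelope.py` shows that the %BW range 1.8–2.7
alone swings a 338.96 ha budget between 244 and 366 ha; and
`examples/synthetic_cleaning_pipeline.py` demonstrates sub-percent
recovery of a noise-free forage budget from a noisy simulated scale
stream (100% of injected spurious readings caught, 0.35% false flags).

A thin CLI mirrors the library: `forage-budget simulate|clean|run|
compare|sensitivity|extrapolate|reproduce` (see `--help`).

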