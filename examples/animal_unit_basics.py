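"""Animal-unit arithmetic: what one AUM is and what an animal needs.

Run: python examples/animal_unit_basics.py
"""

import foragebudget as fb

# One animal unit (AU) is a 454 kg cow eating 2.6% of her BW per day.
aum_kg = fb.monthly_aum_forage()
print(f"forage per AUM: {aum_kg:.2f} kg DM  (reported as {round(aum_kg)} kg)")

# A light 227 kg heifer at 2.5 %BW on range offering 700 kg/ha of
# consumable forage (2800 kg/ha standing, harvest efficiency 0.25):
ha = fb.ha_per_aum(bw_kg=227, pct_bw=2.5, days_per_month=30, consumable_kg_per_ha=700)
print(f"227 kg heifer: {ha:.2f} ha per animal-month of grazing")

# AU equivalents express any animal as a fraction of the reference cow.
for bw in (243.45, 352.91, 454.0):
    print(f"  {bw:6.2f} kg -> {fb.animal_unit_equivalent(bw):.2f} AU")

# The numbers mean: a growing heifer is roughly half an animal unit, so
# traditional AUM tables overstate her intake if she is counted as 1 AU,
# and understate it as she gains weight over the season.
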