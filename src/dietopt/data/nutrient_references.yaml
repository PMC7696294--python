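# Default daily nutrient reference values (EFSA-style, adult population).
#
# These are configuration defaults shipped with dietopt, NOT values taken from
# any single study: recommended values (rv) follow EFSA DRV ranges for adults,
# maximum values (mv) follow the usual <10 % of energy guidance for saturated
# fat and free sugars (at the 2228 kcal/day target) and the WHO/EFSA safe
# sodium level. Override with your own file for a different population.
version: 1
energy_target_kcal: 2228.0
rv:
  protein: 55.0        # g/day
  fiber: 25.0          # g/day
  calcium: 950.0       # mg/day
  iron: 11.0           # mg/day
  magnesium: 350.0     # mg/day
  potassium: 3500.0    # mg/day
  vitamin_a: 750.0     # µg RE/day
  vitamin_c: 95.0      # mg/day
  vitamin_e: 13.0      # mg/day
mv:
  saturated_fat: 24.8  # g/day  (~10 % of 2228 kcal at 9 kcal/g)
  added_sugar: 55.7    # g/day  (~10 % of 2228 kcal at 4 kcal/g)
  sodium: 2000.0       # mg/day
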