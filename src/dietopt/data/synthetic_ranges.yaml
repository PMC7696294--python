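# Sampling ranges for the synthetic food-product generator (version 1).
#
# Each category carries a [low, high] uniform range per field. Nutrient
# densities are per gram of food as consumed (legumes on a dry basis):
#   energy_kcal_per_g  kcal/g
#   protein, fiber, saturated_fat, added_sugar  g/g
#   calcium, iron, magnesium, potassium, sodium, vitamin_c, vitamin_e  mg/g
#   vitamin_a  µg RE/g
#   price_eur_per_kg  €/kg      ghg_kgco2e_per_kg  kg CO2eq/kg
#
# Ranges are set from general food-composition, retail-price and food-LCA
# knowledge for a Southern-European market basket. Animal-source categories
# are deliberately GHG-intensive relative to plant categories; dairy and the
# fortified plant drinks are Ca-rich; legumes and vegetables are fiber/K-rich;
# oils are energy-dense and vitamin-E-rich.
version: 1
categories:
  red_meat:
    energy_kcal_per_g: [2.0, 3.0]
    protein: [0.18, 0.26]
    fiber: [0.0, 0.0]
    calcium: [0.05, 0.2]
    iron: [0.015, 0.035]
    magnesium: [0.15, 0.25]
    potassium: [2.5, 4.0]
    vitamin_a: [0.0, 0.1]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.002, 0.006]
    saturated_fat: [0.03, 0.08]
    added_sugar: [0.0, 0.0]
    sodium: [0.5, 0.9]
    price_eur_per_kg: [7.0, 15.0]
    ghg_kgco2e_per_kg: [14.0, 30.0]
  white_meat:
    energy_kcal_per_g: [1.1, 2.0]
    protein: [0.18, 0.25]
    fiber: [0.0, 0.0]
    calcium: [0.05, 0.15]
    iron: [0.005, 0.015]
    magnesium: [0.2, 0.3]
    potassium: [2.0, 3.5]
    vitamin_a: [0.0, 0.2]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.002, 0.005]
    saturated_fat: [0.01, 0.03]
    added_sugar: [0.0, 0.0]
    sodium: [0.5, 1.0]
    price_eur_per_kg: [4.0, 9.0]
    ghg_kgco2e_per_kg: [4.0, 8.0]
  processed_meat:
    energy_kcal_per_g: [2.5, 4.0]
    protein: [0.12, 0.2]
    fiber: [0.0, 0.0]
    calcium: [0.1, 0.3]
    iron: [0.008, 0.02]
    magnesium: [0.12, 0.2]
    potassium: [1.5, 3.0]
    vitamin_a: [0.0, 0.1]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.002, 0.005]
    saturated_fat: [0.08, 0.15]
    added_sugar: [0.0, 0.01]
    sodium: [8.0, 12.0]
    price_eur_per_kg: [8.0, 15.0]
    ghg_kgco2e_per_kg: [7.0, 14.0]
  fish:
    energy_kcal_per_g: [0.8, 2.0]
    protein: [0.16, 0.24]
    fiber: [0.0, 0.0]
    calcium: [0.1, 0.4]
    iron: [0.003, 0.015]
    magnesium: [0.25, 0.35]
    potassium: [2.5, 4.5]
    vitamin_a: [0.1, 0.5]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.005, 0.02]
    saturated_fat: [0.005, 0.03]
    added_sugar: [0.0, 0.0]
    sodium: [0.8, 1.2]
    price_eur_per_kg: [6.0, 18.0]
    ghg_kgco2e_per_kg: [3.0, 8.0]
  eggs:
    energy_kcal_per_g: [1.4, 1.5]
    protein: [0.12, 0.13]
    fiber: [0.0, 0.0]
    calcium: [0.5, 0.56]
    iron: [0.018, 0.022]
    magnesium: [0.11, 0.13]
    potassium: [1.3, 1.4]
    vitamin_a: [1.4, 1.6]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.01, 0.013]
    saturated_fat: [0.03, 0.035]
    added_sugar: [0.0, 0.0]
    sodium: [1.3, 1.4]
    price_eur_per_kg: [2.0, 4.0]
    ghg_kgco2e_per_kg: [3.0, 5.0]
  dairy:
    energy_kcal_per_g: [0.45, 0.9]
    protein: [0.03, 0.06]
    fiber: [0.0, 0.0]
    calcium: [1.1, 1.8]
    iron: [0.0, 0.001]
    magnesium: [0.1, 0.15]
    potassium: [1.3, 1.9]
    vitamin_a: [0.1, 0.6]
    vitamin_c: [0.0, 0.02]
    vitamin_e: [0.0, 0.001]
    saturated_fat: [0.006, 0.025]
    added_sugar: [0.0, 0.04]
    sodium: [0.4, 0.55]
    price_eur_per_kg: [0.8, 3.0]
    ghg_kgco2e_per_kg: [1.2, 3.0]
  vegetables:
    energy_kcal_per_g: [0.2, 0.6]
    protein: [0.01, 0.03]
    fiber: [0.02, 0.04]
    calcium: [0.3, 1.2]
    iron: [0.005, 0.025]
    magnesium: [0.1, 0.3]
    potassium: [2.0, 5.0]
    vitamin_a: [0.2, 4.0]
    vitamin_c: [0.1, 0.8]
    vitamin_e: [0.002, 0.02]
    saturated_fat: [0.0, 0.001]
    added_sugar: [0.0, 0.0]
    sodium: [0.05, 0.5]
    price_eur_per_kg: [1.0, 3.0]
    ghg_kgco2e_per_kg: [0.3, 1.5]
  fruits:
    energy_kcal_per_g: [0.4, 0.9]
    protein: [0.005, 0.015]
    fiber: [0.015, 0.04]
    calcium: [0.05, 0.3]
    iron: [0.002, 0.006]
    magnesium: [0.05, 0.15]
    potassium: [1.0, 3.5]
    vitamin_a: [0.05, 1.0]
    vitamin_c: [0.05, 0.6]
    vitamin_e: [0.001, 0.01]
    saturated_fat: [0.0, 0.001]
    added_sugar: [0.0, 0.0]
    sodium: [0.0, 0.05]
    price_eur_per_kg: [1.2, 3.0]
    ghg_kgco2e_per_kg: [0.3, 1.2]
  legumes:
    energy_kcal_per_g: [3.0, 3.5]
    protein: [0.2, 0.25]
    fiber: [0.15, 0.25]
    calcium: [0.6, 2.5]
    iron: [0.05, 0.08]
    magnesium: [1.0, 1.9]
    potassium: [10.0, 14.0]
    vitamin_a: [0.0, 0.1]
    vitamin_c: [0.0, 0.05]
    vitamin_e: [0.005, 0.02]
    saturated_fat: [0.001, 0.003]
    added_sugar: [0.0, 0.0]
    sodium: [0.0, 0.1]
    price_eur_per_kg: [2.0, 4.0]
    ghg_kgco2e_per_kg: [0.8, 2.0]
  grains:
    energy_kcal_per_g: [2.5, 3.6]
    protein: [0.08, 0.13]
    fiber: [0.03, 0.1]
    calcium: [0.1, 0.4]
    iron: [0.01, 0.04]
    magnesium: [0.25, 1.2]
    potassium: [1.0, 3.5]
    vitamin_a: [0.0, 0.0]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.002, 0.01]
    saturated_fat: [0.002, 0.01]
    added_sugar: [0.0, 0.02]
    sodium: [0.0, 5.0]
    price_eur_per_kg: [1.0, 3.0]
    ghg_kgco2e_per_kg: [0.8, 2.0]
  tubers:
    energy_kcal_per_g: [0.7, 0.9]
    protein: [0.015, 0.025]
    fiber: [0.015, 0.025]
    calcium: [0.05, 0.15]
    iron: [0.003, 0.008]
    magnesium: [0.2, 0.25]
    potassium: [3.5, 4.5]
    vitamin_a: [0.0, 0.1]
    vitamin_c: [0.1, 0.2]
    vitamin_e: [0.0, 0.001]
    saturated_fat: [0.0, 0.001]
    added_sugar: [0.0, 0.0]
    sodium: [0.0, 0.1]
    price_eur_per_kg: [0.8, 1.5]
    ghg_kgco2e_per_kg: [0.2, 0.6]
  nuts:
    energy_kcal_per_g: [5.5, 6.5]
    protein: [0.15, 0.25]
    fiber: [0.07, 0.12]
    calcium: [0.6, 2.6]
    iron: [0.025, 0.05]
    magnesium: [1.5, 3.0]
    potassium: [4.0, 7.0]
    vitamin_a: [0.0, 0.0]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.05, 0.26]
    saturated_fat: [0.04, 0.1]
    added_sugar: [0.0, 0.0]
    sodium: [0.0, 0.05]
    price_eur_per_kg: [8.0, 20.0]
    ghg_kgco2e_per_kg: [1.5, 4.0]
  oils:
    energy_kcal_per_g: [8.8, 9.0]
    protein: [0.0, 0.0]
    fiber: [0.0, 0.0]
    calcium: [0.0, 0.0]
    iron: [0.0, 0.0]
    magnesium: [0.0, 0.0]
    potassium: [0.0, 0.0]
    vitamin_a: [0.0, 0.0]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.14, 0.5]
    saturated_fat: [0.1, 0.15]
    added_sugar: [0.0, 0.0]
    sodium: [0.0, 0.0]
    price_eur_per_kg: [3.0, 8.0]
    ghg_kgco2e_per_kg: [2.0, 6.0]
  sweets:
    energy_kcal_per_g: [4.0, 5.5]
    protein: [0.04, 0.08]
    fiber: [0.01, 0.03]
    calcium: [0.2, 1.0]
    iron: [0.01, 0.03]
    magnesium: [0.3, 1.0]
    potassium: [1.0, 4.0]
    vitamin_a: [0.0, 0.5]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.01, 0.05]
    saturated_fat: [0.05, 0.18]
    added_sugar: [0.3, 0.6]
    sodium: [0.5, 3.0]
    price_eur_per_kg: [4.0, 10.0]
    ghg_kgco2e_per_kg: [2.0, 5.0]
  beverages:
    energy_kcal_per_g: [0.2, 0.5]
    protein: [0.0, 0.005]
    fiber: [0.0, 0.002]
    calcium: [0.05, 0.15]
    iron: [0.0, 0.002]
    magnesium: [0.02, 0.1]
    potassium: [0.5, 1.5]
    vitamin_a: [0.0, 0.1]
    vitamin_c: [0.0, 0.3]
    vitamin_e: [0.0, 0.002]
    saturated_fat: [0.0, 0.001]
    added_sugar: [0.05, 0.11]
    sodium: [0.0, 0.2]
    price_eur_per_kg: [0.7, 2.0]
    ghg_kgco2e_per_kg: [0.3, 0.8]
  plant_drinks:
    energy_kcal_per_g: [0.35, 0.6]
    protein: [0.01, 0.035]
    fiber: [0.002, 0.008]
    calcium: [1.0, 1.6]
    iron: [0.002, 0.006]
    magnesium: [0.1, 0.2]
    potassium: [0.8, 1.5]
    vitamin_a: [0.0, 0.1]
    vitamin_c: [0.0, 0.0]
    vitamin_e: [0.001, 0.005]
    saturated_fat: [0.001, 0.004]
    added_sugar: [0.0, 0.03]
    sodium: [0.3, 0.5]
    price_eur_per_kg: [1.0, 2.5]
    ghg_kgco2e_per_kg: [0.3, 0.9]
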