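"""Published index values for six Spanish dietary patterns.

These are the reported daily indicators of six pre-defined eating patterns
for the Spanish context — current consumption (CC), national dietary
guidelines (NDG), Mediterranean (MED), ovo-lacto-vegetarian (OLV), vegan
(VEG) and the EAT-Lancet planetary-health (PLH) pattern — all isocaloric at
2228 kcal/day. They serve as the package's worked comparison set: the
distance and corrected-GHG machinery can be exercised on them without access
to the underlying proprietary food-composition, price and LCA tables.

``PREDEFINED_INDICES`` carries each pattern's NRD9.3 score, daily cost TC
(€/day), daily emissions GHG (kg CO2eq/day) and the normalized scores
(X_NUTR, X_ENV, X_EC) as printed. ``COMPARISON_FACTORS`` carries the
affordability/nutrition-corrected emission factors (price, NRD9.3, GHG, RIS,
NS, c-GHG) for the six patterns and their six optimized counterparts.
"""

from __future__ import annotations

import pandas as pd

#: Daily consumption income (€/day) consistent with the published RIS values
#: (back-derived: RIS = 1 − cost/income reproduces all twelve printed RIS
#: values to their printed precision; the feasible income interval is about
#: 29.1–29.5 €/day). [DERIVED]
CONSUMPTION_INCOME = 29.3

#: Reference NRD9.3 for the nutritional score NS (planetary-health pattern).
REFERENCE_NRD93 = 680.0

#: Common daily energy of the isocaloric patterns (kcal/day).
REFERENCE_ENERGY = 2228.0

_PREDEFINED = {
    #       nrd93   cost   ghg   x_nutr  x_env  x_ec
    "CC":  (498.0, 4.32, 4.52, 0.611, 1.000, 0.947),
    "NDG": (679.0, 3.77, 3.93, 0.754, 0.869, 0.827),
    "MED": (662.0, 4.51, 4.07, 0.736, 0.903, 1.000),
    "OLV": (637.0, 2.83, 2.91, 0.708, 0.644, 0.621),
    "VEG": (632.0, 2.36, 1.41, 0.702, 0.312, 0.518),
    "PLH": (680.0, 3.56, 2.95, 0.756, 0.653, 0.781),
}

PREDEFINED_INDICES: pd.DataFrame = pd.DataFrame(
    _PREDEFINED, index=["nrd93", "cost", "ghg", "x_nutr", "x_env", "x_ec"]
).T

_COMPARISON = [
    # group, diet, price €/day, nrd93, ghg, ris, ns, c_ghg
    ("optimized", "VEG-Opt", 4.28, 748.0, 1.81, 0.85, 1.10, 1.92),
    ("optimized", "PLH-Opt", 2.57, 717.0, 2.12, 0.91, 1.06, 2.21),
    ("optimized", "OLV-Opt", 2.88, 690.0, 2.18, 0.90, 1.01, 2.38),
    ("optimized", "NDG-Opt", 2.92, 728.0, 2.61, 0.90, 1.07, 2.71),
    ("optimized", "MED-Opt", 3.17, 684.0, 2.71, 0.89, 1.01, 3.02),
    ("optimized", "CC-Opt", 3.33, 620.0, 3.15, 0.89, 0.91, 3.90),
    ("predefined", "VEG", 2.36, 632.0, 1.41, 0.92, 0.93, 1.65),
    ("predefined", "PLH", 3.56, 680.0, 2.95, 0.88, 1.00, 3.36),
    ("predefined", "OLV", 2.83, 637.0, 2.91, 0.90, 0.94, 3.44),
    ("predefined", "NDG", 3.77, 679.0, 3.93, 0.87, 1.00, 4.51),
    ("predefined", "MED", 4.51, 663.0, 4.07, 0.85, 0.97, 4.94),
    ("predefined", "CC", 4.32, 498.0, 4.52, 0.85, 0.73, 7.28),
]

COMPARISON_FACTORS: pd.DataFrame = pd.DataFrame(
    _COMPARISON,
    columns=["group", "diet", "price", "nrd93", "ghg", "ris", "ns", "c_ghg"],
).set_index("diet")

#: Published per-diet distances (equally weighted / maximal / minimal Dn and
#: the over-weighted aspect at each extremum) for cross-checking the distance
#: module against the same six patterns.
REFERENCE_DISTANCES: pd.DataFrame = pd.DataFrame(
    {
        "CC":  (0.826, 0.968, "ENV", 0.508, "NUTR"),
        "NDG": (0.707, 0.840, "ENV", 0.385, "NUTR"),
        "MED": (0.793, 0.962, "EC", 0.426, "NUTR"),
        "OLV": (0.543, 0.625, "ENV", 0.357, "NUTR"),
        "VEG": (0.389, 0.495, "EC", 0.318, "NUTR"),
        "PLH": (0.604, 0.749, "EC", 0.348, "NUTR"),
    },
    index=["equally_weighted", "maximal_dn", "max_overweighted", "minimal_dn", "min_overweighted"],
).T
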