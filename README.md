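# dietopt

Multi-objective design and comparison of sustainable diets by
**distance-to-target (compromise-programming) optimization**.

`dietopt` is for nutrition and food-systems modellers who want to score
eating patterns simultaneously on nutritional quality, greenhouse-gas
emissions and cost, and to search for acceptable re-arrangements of a
baseline diet that move it toward an ideal on all three axes at once.

## The model

A diet is a vector of daily intakes $Q_i$ (g/day) over a food database of
products with per-gram energy and nutrient densities, prices $C_i$ (€/kg)
and GHG intensities $E_i$ (kg CO₂eq/kg). Three indicators are computed:

* **Nutrition — NRD9.3.** With nine qualifying nutrients (protein, fiber,
  Ca, Fe, Mg, K, vitamins A, C, E; recommended values $RV_i$) and three
  limiting nutrients (saturated fat, added sugar, Na; maxima $MV_i$):

  $$\mathrm{NRD9.3} = \sum_{i=1}^{9} \frac{\min(NRI_i, RV_i)}{RV_i}\cdot 100
    \;-\; \sum_{i=1}^{3} \frac{LNI_i}{MV_i}\cdot 100,$$

  capped so surpluses of qualifying nutrients earn no credit; the
  theoretical maximum is 900. A weighted variant NRD9.3w carries
  per-nutrient weights on floor-constrained simplices
  ($\sum kr_i = 9$, $kr_i \ge 0.5$; $\sum km_i = 3$, $km_i \ge 0.2$).
* **Environment and economy.** $\mathrm{GHG} = \sum Q_i E_i$ and
  $TC = \sum Q_i C_i$ (with the g→kg conversion).

The indicators are normalized — $X_{NUTR} = \mathrm{NRD9.3}/900$,
$X_{ENV} = \mathrm{GHG}/\mathrm{GHG}_{max}$, $X_{EC} = TC/TC_{max}$, maxima
taken over the baseline diet set — and collapsed into the normalized
weighted distance to the ideal target $G = (1, 0, 0)$:

$$D_n = \sqrt{\tfrac{1}{n}\sum_i k_i \left(F_i - G_i\right)^2},
  \qquad \sum k_i = n,\; k_i \ge V_L = 0.2,$$

which lies in $[0, 1]$. The optimizer minimizes $D_n$ over $Q$ subject to
an energy equality (2228 kcal/day by default), nutrient adequacy
($NRI_i \ge RV_i$), limits ($LNI_i \le MV_i$) and acceptability bounds
around the baseline (a ±TV % band, or a $[0.1\,Q^{base}_i,\ N_V Q^{base}_i]$
band for far-from-target baselines). Supporting machinery includes the
minimal-margin (TV/NV) bisection, ε-constraint Pareto fronts, Monte-Carlo
sensitivity of NRD9.3w to the nutrient weights, and the corrected-emission
metric $c\text{-}\mathrm{GHG} = \mathrm{GHG}/(RIS\cdot\alpha\cdot NS)$ that
charges emissions against affordability ($RIS$), energy ($\alpha$) and
nutritional quality ($NS$).

The real Spanish food-composition/price/LCA tables behind the published
six-pattern comparison are proprietary; the package ships a synthetic
63-product generator emulating that basket (see `docs/methods.md`) plus the
published six-pattern index table (`dietopt.reference_diets`) as a worked
comparison set.

## Worked example

```bash
dietopt synth --n-products 63 --seed 1 --out-dir demo
dietopt evaluate --database demo/food_database.csv --diets demo/diets.csv --out-dir demo
```

prints the indicator table of the two generated baselines:

```
        omnivorous    vegan
NRD9.3     631.197  769.103
TC           5.343    4.000
GHG          4.489    1.442
XNUTR        0.701    0.855
XENV         1.000    0.321
XEC          1.000    0.749
```

The omnivorous pattern carries 3.1× the vegan pattern's emissions and a
weaker nutrient profile (capped coverage minus a near-maximal saturated-fat
penalty), so its equally weighted distance is much larger: `demo/distances.csv`
reports $D_n$ = 0.834 vs 0.478, with the environmental axis the worst aspect
of the omnivorous diet (maximal $D_n$ 0.969 when ENV is over-weighted) and
nutrition the best aspect of both. The minimal acceptability margins

```bash
dietopt optimize --database demo/food_database.csv --diets demo/diets.csv --find-margin --out-dir demo
```

come out as TV = 22 % (omnivorous) and TV = 17 % (vegan), calcium being the
margin-limiting nutrient for both — below those bands no re-arrangement of
the baseline can reach calcium adequacy while holding energy fixed.
`dietopt optimize --tv 60 ...` then returns optimized diets whose $D_n$
drops to 0.553 (omnivorous) and 0.413 (vegan), and `dietopt compare` emits
the corrected-GHG table.

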