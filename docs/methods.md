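# Methods notes

## Model and conventions

Quantities $Q_i$ are grams of food as consumed per day; energy and nutrient
densities are per gram; prices and GHG intensities are per kilogram with the
explicit ×10⁻³ conversion inside the cost/emission sums. The edible/gross
intake distinction is not modelled: the same quantities feed the nutrition
and the footprint calculations. Legume quantities in the synthetic basket
are on a dry basis.

The nutrition index caps only the qualifying-nutrient ratios. Limiting
ratios are deliberately left uncapped: a diet can be penalized by more than
100 points for a single limiting nutrient, which is what makes poor
patterns separate cleanly on the nutrition axis. Inside the constrained
optimizer this choice is inert — the limit constraints force every limiting
ratio ≤ 1 at feasibility — but it matters when scoring non-optimized diets.

Relative intakes are computed on whole-diet totals (not per item or per
100 kcal), and normalization of cost/GHG is always over whole diets from the
baseline set, never over single products (a single product cannot feed a
person, so a per-product maximum is meaningless). The normalization context
is frozen from the baseline set before optimization; otherwise the
objective's denominators would move with the decision variables. Diets
outside the baseline set may legitimately score $X > 1$.

## Distance and extremal weighting

$D_n = \sqrt{\sum_i k_i (F_i-G_i)^2 / n}$ with targets $(1,0,0)$. With
$F, G \in [0,1]$ and $\sum k_i = n$, $D_n \le 1$ because
$\sum_i (k_i/n)\,d_i^2 \le \max d_i^2 \le 1$. Reading the radical over the
whole weighted mean (rather than inside the sum) is fixed by numerical
consistency: it reproduces all eighteen published per-diet distances of the
six-pattern comparison set from their printed normalized scores, which the
test-suite asserts.

$D_n^2$ is linear in the weights, so its extrema over the floor-constrained
simplex $\{\sum k_i = 3,\ k_i \ge V_L\}$ sit at the three vertices where one
objective takes $3 - 2V_L$ (2.6 at the default $V_L = 0.2$) and the others
take the floor. `extremal_distances` enumerates the vertices exhaustively;
ties break on the fixed objective order NUTR < ENV < EC. The same argument,
applied blockwise, gives the NRD9.3w extrema: one qualifying nutrient at 5
(rest 0.5), one limiting nutrient at 2.6 (rest 0.2), with the two blocks
optimized independently.

## Optimizer

All constraints (energy equality, adequacy, limits, acceptability boxes)
are linear in $Q$; only the objective is nonlinear. Consequences used
throughout:

* **Feasibility is an LP.** Existence of an acceptable diet, the violated-
  constraint report, and the minimal TV/NV margin search are answered with
  `scipy.optimize.linprog` (HiGHS), exactly. The TV search bisects at
  integer-percent resolution (feasible regions are nested in TV, so
  bisection is valid — asserted over the recorded trace); if TV = 100 % is
  still infeasible the search switches to the NV mode on a 0.5 grid. The
  margin-limiting nutrients are read off as the constraints whose best
  attainable relative slack is ~0 at the (continuously refined) threshold;
  slacks are evaluated at a slightly relaxed margin because at the exact
  threshold the feasible set degenerates to a point and the slack LPs are
  numerically fragile.
* **The $D_n$ minimization is a smooth multistart SLSQP** (default 5 starts:
  an LP-feasible vertex, the clipped baseline, the box midpoint and seeded
  uniform points; energy equality as a ±10⁻⁶ relative band). The capping
  min() in the objective is evaluated exactly; under the adequacy
  constraints every qualifying ratio is ≥ 1 at feasible points, so the kink
  can only sit on the constraint boundary, and in practice SLSQP converges
  from all starts with best-objective spread < 10⁻⁴ on the test fixtures.
  Returned points are re-checked by an independent linear constraint
  evaluator before being reported feasible.
* **The ε-constraint Pareto steps are exact LPs.** Maximizing the capped
  NRD9.3 (concave piecewise-linear) under cost/GHG caps is reformulated
  with auxiliary capped-ratio variables $t_i \le NRI_i/RV_i$, $t_i \le 1$ —
  no smoothing involved. Returned points pass a mutual-dominance filter;
  infeasible levels are skipped with a log entry.

Products absent from the baseline stay absent under both acceptability
modes (TV % of zero is zero; the NV band is likewise degenerate at zero):
the bounds are taken literally, and introducing new products would defeat
the purpose of limiting deviation from the baseline.

## Default reference values

The comparison framework never fixes numeric $RV_i/MV_i$; the package ships
EFSA-style adult defaults as labelled configuration
(`data/nutrient_references.yaml`): protein 55 g, fiber 25 g, Ca 950 mg,
Fe 11 mg, Mg 350 mg, K 3500 mg, vitamin A 750 µg RE, vitamin C 95 mg,
vitamin E 13 mg; saturated fat 24.8 g and added sugar 55.7 g (≈10 % of the
2228 kcal/day energy target each), Na 2000 mg. Different populations should
supply their own file; nothing downstream hard-codes these numbers.

The consumption income behind the residual-income score defaults to
29.3 €/day. The published comparison set prints RIS but not the income; the
interval of incomes consistent with all twelve printed (cost, RIS) pairs is
≈ [29.1, 29.5] €/day and 29.3 reproduces every printed RIS at its printed
precision. This is a back-derived convenience default, clearly overridable.
The energy score α uses the ratio branch below the reference energy and 1
at or above it; all shipped comparisons are isocaloric, so α = 1.

## Synthetic data: what it emulates and what it does not

`generate_synthetic_database` draws products from 16 food categories
(meats, processed meat, fish, eggs, dairy, vegetables, fruits, legumes,
grains, tubers, nuts, oils, sweets, beverages, fortified plant drinks) with
per-category uniform ranges for energy, the 12 nutrient densities, price
and GHG intensity (`data/synthetic_ranges.yaml`, versioned). Ranges follow
general food-composition, retail-price and food-LCA knowledge for a
Southern-European basket: animal categories are GHG-intensive (red meat
14–30 kg CO₂eq/kg vs ≤ 2 for most plant categories), dairy and fortified
plant drinks are Ca-rich, legumes/vegetables fiber- and K-rich, oils
energy-dense and vitamin-E-rich. The fortified plant-drinks category
reflects actual vegan practice (calcium-fortified soy/oat drinks,
calcium-set tofu) and is what makes a calcium-adequate vegan pattern
reachable at moderate acceptability margins rather than only through an
NV-style relaxation.

`generate_baseline_diets` builds an omnivorous-like and a vegan-like
pattern from fixed category-gram templates (seeded Dirichlet splits within
categories), each rescaled exactly to the 2228 kcal/day target. With the
default ranges and references the patterns land close to published
whole-diet magnitudes (omnivorous ≈ 4.5 kg CO₂eq/day and a strong
saturated-fat penalty; vegan ≈ 1.4 kg CO₂eq/day with mild Ca deficit),
which is the behavior regime the optimizer tests exercise.

What the synthetic basket does *not* capture: intra-category correlation
structure (draws are independent within ranges), seasonal/regional price
variation, processed composite foods, food-away-from-home, bioavailability
differences (e.g. non-heme iron), and any real product identity. Passing
tests therefore demonstrate the *properties* of the method — feasibility
logic, monotonicity in the acceptability margin, improvement of $D_n$ over
baselines, Pareto monotonicity — not the published optimized Spanish diets
themselves, which depend on the proprietary tables.

## Monte-Carlo weight sensitivity

Weight sets are drawn uniformly on the floor-shifted simplices:
$kr = 0.5 + 4.5\,\mathrm{Dir}(\mathbf{1}_9)$,
$km = 0.2 + 2.4\,\mathrm{Dir}(\mathbf{1}_3)$ (renormalized so sums and
floors hold to 10⁻¹²). The underlying comparison framework specifies only
"random" weights; the flat Dirichlet is the maximum-entropy choice on the
constrained simplex and is an assumption of this package. The same draw
list is applied to every diet (paired design), so per-draw scatter and win
fractions are meaningful; draw distributions are bounded by the LP extrema
and carry no attached hypothesis tests. Default 1000 draws.

## Numerical choices and problem sizes

Energy equality: ±10⁻⁶ relative band. SLSQP: ftol 10⁻¹², maxiter 400,
independent re-check tolerance 10⁻⁵ relative. LP solver: HiGHS defaults.
Unrestricted mode caps each product at 2000 g/day. Degenerate inputs raise
typed errors (empty databases, all-zero energy, unaffordable diets,
correction scores at the 10⁻⁶ guard floor) rather than returning
non-finite values.

The shipped tests and the acceptance script run the full pipeline at the
63-product scale with two baselines and a four-level TV sweep — the same
problem shape as the published study — which keeps the whole suite around a
minute on one CPU while exercising every code path; the method itself has
no scale-dependent approximations (LPs and a 63-variable NLP).

## Known limitations

* The SLSQP multistart is a local method; the improvement and monotonicity
  guarantees asserted in tests hold for the returned local optima (warm
  starts across TV levels enforce nesting in practice), not as global
  optimality proofs.
* The corrected-GHG metric inherits the instability of its ratio form: RIS,
  α or NS near zero inflate it without bound, hence the guard-floor error.
* Added sugar is an ordinary database column; no disaggregation from total
  sugars is attempted, so composition sources that only report total sugar
  need preprocessing.
* Acceptability is purely quantitative (per-product bounds); palatability,
  serving sizes and cultural substitution patterns are out of scope.
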