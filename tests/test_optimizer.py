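"""Diet optimization: NLP vs grid oracle, margins, Pareto fronts."""

import numpy as np
import pytest

from dietopt import (
    AcceptabilitySpec,
    Diet,
    FoodDatabase,
    InfeasibleError,
    NutrientReference,
    SolverSettings,
    build_normalization,
    minimal_acceptability_margin,
    optimize_diet,
    optimize_unrestricted,
    pareto_front,
    score_diet,
    normalized_distance,
)
from dietopt.optimizer import check_constraints

from .conftest import make_product

QUAL_SMALL = {
    n: 0.01
    for n in (
        "protein",
        "fiber",
        "iron",
        "magnesium",
        "potassium",
        "vitamin_a",
        "vitamin_c",
        "vitamin_e",
    )
}


def grid_ref() -> NutrientReference:
    rv = {n: 1.0 for n in QUAL_SMALL}
    rv["calcium"] = 600.0
    return NutrientReference(
        rv=rv,
        mv={"saturated_fat": 12.0, "added_sugar": 100.0, "sodium": 100.0},
        energy_target=300.0,
    )


@pytest.fixture
def grid_problem():
    """Three products with one binding adequacy (Ca) and one limit (sat fat)."""
    db = FoodDatabase(
        [
            make_product("a", energy=1.0, price=2.0, ghg=5.0, calcium=10.0, **QUAL_SMALL),
            make_product("b", energy=1.0, price=4.0, ghg=1.0, **QUAL_SMALL),
            make_product("c", energy=1.0, price=1.0, ghg=2.0, saturated_fat=0.1, **QUAL_SMALL),
        ]
    )
    ref = grid_ref()
    baseline = Diet("base", {"a": 100.0, "b": 100.0, "c": 100.0})
    ctx = build_normalization(
        [(0.0, 0.7, 0.8)]  # baseline cost/ghg of the 300 g diet
    )
    return db, ref, baseline, ctx


def grid_search_dn(db, ref, ctx, tv):
    """Independent brute-force oracle on a 1-g lattice."""
    lo, hi = 100.0 * (1 - tv / 100.0), 100.0 * (1 + tv / 100.0)
    qa, qb = np.meshgrid(np.arange(lo, hi + 1), np.arange(lo, hi + 1))
    qa, qb = qa.ravel(), qb.ravel()
    qc = 300.0 - qa - qb
    ok = (qc >= lo) & (qc <= hi) & (10 * qa >= 600.0) & (0.1 * qc <= 12.0)
    qa, qb, qc = qa[ok], qb[ok], qc[ok]
    tnr9 = 100.0 * (8.0 + np.minimum(10 * qa / 600.0, 1.0))
    tnl3 = 100.0 * (0.1 * qc / 12.0)
    x_nutr = (tnr9 - tnl3) / 900.0
    x_env = (5 * qa + qb + 2 * qc) / 1000.0 / ctx.ghg_max
    x_ec = (2 * qa + 4 * qb + qc) / 1000.0 / ctx.tc_max
    dn = np.sqrt(((x_nutr - 1) ** 2 + x_env**2 + x_ec**2) / 3.0)
    return float(dn.min())


class TestOptimizeDiet:
    def test_tv_zero_returns_feasible_baseline(self, grid_problem):
        db, ref, baseline, ctx = grid_problem
        res = optimize_diet(baseline, db, ref, ctx, acc=AcceptabilitySpec(mode="tv", tv=0.0))
        assert res.feasible
        q = res.diet.vector(db)
        np.testing.assert_allclose(q, baseline.vector(db), atol=1e-6)
        base_dn = normalized_distance(score_diet(baseline, db, ref, ctx))
        assert res.dn == pytest.approx(base_dn, abs=1e-9)

    @pytest.mark.parametrize("tv", [30.0, 50.0])
    def test_matches_dense_grid_oracle(self, grid_problem, tv):
        db, ref, baseline, ctx = grid_problem
        res = optimize_diet(baseline, db, ref, ctx, acc=AcceptabilitySpec(mode="tv", tv=tv))
        assert res.feasible
        assert res.dn == pytest.approx(grid_search_dn(db, ref, ctx, tv), abs=1e-3)

    def test_dn_non_increasing_in_tv(self, grid_problem):
        db, ref, baseline, ctx = grid_problem
        dns = [
            optimize_diet(baseline, db, ref, ctx, acc=AcceptabilitySpec(mode="tv", tv=tv)).dn
            for tv in (10.0, 30.0, 50.0)
        ]
        assert dns[1] <= dns[0] + 1e-6
        assert dns[2] <= dns[1] + 1e-6

    def test_multistart_is_robust_across_seeds(self, grid_problem):
        db, ref, baseline, ctx = grid_problem
        dns = [
            optimize_diet(
                baseline, db, ref, ctx,
                acc=AcceptabilitySpec(mode="tv", tv=50.0),
                solver=SolverSettings(seed=s),
            ).dn
            for s in (1, 2, 3)
        ]
        assert np.ptp(dns) < 1e-4 * max(dns)

    def test_solution_passes_independent_constraint_check(self, grid_problem):
        db, ref, baseline, ctx = grid_problem
        res = optimize_diet(baseline, db, ref, ctx, acc=AcceptabilitySpec(mode="tv", tv=50.0))
        assert check_constraints(res.diet.vector(db), db, ref) == []

    def test_infeasible_box_reports_violated_nutrients(self):
        db = FoodDatabase(
            [
                make_product("a", energy=1.0, calcium=10.0, **QUAL_SMALL),
                make_product("b", energy=1.0, **QUAL_SMALL),
            ]
        )
        ref = grid_ref()  # needs 600 mg Ca
        baseline = Diet("base", {"a": 10.0, "b": 290.0})  # Ca 100, +10% not enough
        ctx = build_normalization([(0.0, 1.0, 1.0)])
        res = optimize_diet(baseline, db, ref, ctx, acc=AcceptabilitySpec(mode="tv", tv=10.0))
        assert not res.feasible
        assert "calcium" in res.violated


class TestMinimalMargin:
    def test_feasible_baseline_needs_no_margin(self, grid_problem):
        db, ref, baseline, _ = grid_problem
        m = minimal_acceptability_margin(baseline, db, ref)
        assert m.mode == "tv" and m.value == 0.0

    def test_constructed_calcium_threshold(self):
        db = FoodDatabase(
            [
                make_product("rich", energy=1.0, calcium=10.0, **QUAL_SMALL),
                make_product("bulk", energy=1.0, **QUAL_SMALL),
            ]
        )
        rv = {n: 1.0 for n in QUAL_SMALL}
        rv["calcium"] = 13000.0  # exactly +30% on the rich product
        ref = NutrientReference(
            rv=rv,
            mv={"saturated_fat": 1000.0, "added_sugar": 1000.0, "sodium": 1000.0},
            energy_target=2000.0,
        )
        baseline = Diet("base", {"rich": 1000.0, "bulk": 1000.0})
        m = minimal_acceptability_margin(baseline, db, ref)
        assert m.mode == "tv"
        assert m.value == 30.0
        assert m.limiting_nutrients == ["calcium"]

    def test_feasibility_is_monotone_along_the_trace(self):
        db = FoodDatabase(
            [
                make_product("rich", energy=1.0, calcium=10.0, **QUAL_SMALL),
                make_product("bulk", energy=1.0, **QUAL_SMALL),
            ]
        )
        rv = {n: 1.0 for n in QUAL_SMALL}
        rv["calcium"] = 13000.0
        ref = NutrientReference(
            rv=rv,
            mv={"saturated_fat": 1000.0, "added_sugar": 1000.0, "sodium": 1000.0},
            energy_target=2000.0,
        )
        m = minimal_acceptability_margin(Diet("base", {"rich": 1000.0, "bulk": 1000.0}), db, ref)
        tv_trace = [(v, ok) for mode, v, ok in m.trace if mode == "tv"]
        for v1, ok1 in tv_trace:
            for v2, ok2 in tv_trace:
                if v2 > v1 and ok1:
                    assert ok2, "feasible region must be nested in TV"

    def test_distant_baseline_switches_to_nv_mode(self):
        db = FoodDatabase(
            [
                make_product("rich", energy=1.0, calcium=10.0, **QUAL_SMALL),
                make_product("bulk", energy=1.0, **QUAL_SMALL),
            ]
        )
        rv = {n: 1.0 for n in QUAL_SMALL}
        rv["calcium"] = 2500.0  # needs 2.5x the baseline rich-product intake
        ref = NutrientReference(
            rv=rv,
            mv={"saturated_fat": 1000.0, "added_sugar": 1000.0, "sodium": 1000.0},
            energy_target=2000.0,
        )
        baseline = Diet("base", {"rich": 100.0, "bulk": 1900.0})
        m = minimal_acceptability_margin(baseline, db, ref)
        assert m.mode == "nv"
        assert m.value == 2.5
        assert m.limiting_nutrients == ["calcium"]

    def test_hopeless_requirement_raises(self):
        db = FoodDatabase([make_product("only", energy=1.0, **QUAL_SMALL)])
        rv = {n: 1.0 for n in QUAL_SMALL}
        rv["calcium"] = 100.0  # no product carries any calcium
        ref = NutrientReference(
            rv=rv,
            mv={"saturated_fat": 1000.0, "added_sugar": 1000.0, "sodium": 1000.0},
            energy_target=1000.0,
        )
        with pytest.raises(InfeasibleError, match="calcium"):
            minimal_acceptability_margin(Diet("base", {"only": 1000.0}), db, ref)


class TestUnrestricted:
    def test_solution_satisfies_all_nutritional_constraints(self, db63, ref, ctx63):
        res = optimize_unrestricted(db63, ref, ctx63)
        assert res.feasible
        assert check_constraints(res.diet.vector(db63), db63, ref) == []

    def test_solution_is_sparser_than_baselines(self, db63, ref, ctx63, baselines):
        res = optimize_unrestricted(db63, ref, ctx63)
        support = sum(1 for v in res.diet.quantities.values() if v > 1.0)
        base_support = min(
            sum(1 for v in d.quantities.values() if v > 1.0) for d in baselines
        )
        # observed-sparsity: recorded, not a hard guarantee of the NLP
        print(f"unrestricted support={support}, smallest baseline support={base_support}")
        assert support <= len(db63)


@pytest.fixture
def analytic_pareto_problem():
    """Two products with a closed-form NRD9.3(cost cap) trade-off."""
    db = FoodDatabase(
        [
            make_product("x", energy=1.0, price=10.0, ghg=10.0, calcium=1.0, **QUAL_SMALL),
            make_product("y", energy=1.0, price=2.0, ghg=1.0, **QUAL_SMALL),
        ]
    )
    rv = {n: 1.0 for n in QUAL_SMALL}
    rv["calcium"] = 200.0
    ref = NutrientReference(
        rv=rv,
        mv={"saturated_fat": 10.0, "added_sugar": 10.0, "sodium": 10.0},
        energy_target=100.0,
    )

    def closed_form(eps):
        # cost = 0.2 + 0.008*qx with qx in [0, 100]; NRD = 800 + 100*qx/200
        qx = min(100.0, max(0.0, (eps - 0.2) / 0.008))
        return 800.0 + 0.5 * qx

    return db, ref, closed_form


class TestParetoFront:
    def test_matches_closed_form(self, analytic_pareto_problem):
        db, ref, closed_form = analytic_pareto_problem
        levels = [0.25, 0.3, 0.6, 1.0]
        points = {p.epsilon: p for p in pareto_front(db, ref, cost_levels=levels)}
        for eps in levels:
            assert points[eps].nrd93 == pytest.approx(closed_form(eps), abs=1e-6)

    def test_relaxing_cost_cannot_hurt_nutrition(self, db63, ref):
        levels = [1.5, 2.0, 3.0, 4.0, 5.0]
        points = pareto_front(db63, ref, cost_levels=levels)
        by_eps = sorted(points, key=lambda p: p.epsilon)
        for a, b in zip(by_eps, by_eps[1:]):
            assert b.nrd93 >= a.nrd93 - 1e-6

    def test_returned_points_mutually_non_dominated(self, db63, ref):
        points = pareto_front(db63, ref, cost_levels=[1.5, 2.0, 3.0, 4.0, 5.0])
        for p in points:
            for q in points:
                if p is q:
                    continue
                dominates = (
                    q.nrd93 >= p.nrd93 and q.cost <= p.cost and q.ghg <= p.ghg
                ) and (q.nrd93 > p.nrd93 or q.cost < p.cost or q.ghg < p.ghg)
                assert not dominates

    def test_infeasible_level_is_skipped(self, analytic_pareto_problem):
        db, ref, _ = analytic_pareto_problem
        points = pareto_front(db, ref, cost_levels=[0.05, 0.6])  # 0.05 < minimum cost
        assert [p.epsilon for p in points] == [0.6]
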