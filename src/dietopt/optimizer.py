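"""Constrained optimization of food quantities.

The decision vector is the diet itself — grams/day of every product. The
objective is the normalized weighted distance Dn of the candidate's score
vector (nutrition, environment, economy) to the ideal target (1, 0, 0),
evaluated against a *frozen* normalization context. Constraints:

* energy equality  Σ Q_i·EN_i = energy target (implemented as a ±1e-6
  relative band for solver friendliness),
* adequacy         NRI_i ≥ RV_i for the nine qualifying nutrients,
* limits           LNI_i ≤ MV_i for the three limiting nutrients,
* acceptability    per-product bounds around the baseline: a symmetric ±TV %
  band, or for far-from-target baselines a [10 % of baseline, NV× baseline]
  band. Products absent from the baseline stay absent under either mode.

All constraints are linear in Q, so pure feasibility questions (and the
minimal-acceptability-margin search) are answered exactly with LPs; the Dn
minimization itself is a smooth NLP solved by multistart SLSQP. The capping
min(NRI_i, RV_i) inside the objective is evaluated exactly: under the
adequacy constraints every qualifying ratio is ≥ 1 at feasible points, so
the kink sits on the constraint boundary at worst.

The ε-constraint Pareto machinery maximizes the capped NRD9.3 (a concave
piecewise-linear function) under cost/GHG caps via an exact LP
reformulation with auxiliary capped-ratio variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog, minimize

from .distance import ObjectiveWeights, TargetVector, normalized_distance
from .exceptions import InfeasibleError, SolverError, ValidationError
from .foodmodel import (
    LIMITING_NUTRIENTS,
    QUALIFYING_NUTRIENTS,
    Diet,
    FoodDatabase,
    NutrientReference,
)
from .nutrition import MAX_SCORE
from .sustainability import NormalizationContext, ScoreVector, normalize

logger = logging.getLogger(__name__)

_ENERGY_REL_TOL = 1e-6
_G_PER_KG = 1000.0


@dataclass(frozen=True)
class AcceptabilitySpec:
    """Bounds on optimized quantities relative to the baseline diet."""

    mode: str = "none"  # none | tv | nv
    tv: float = 60.0  # percent band half-width
    nv: float = 7.0  # upper-bound multiplier

    def __post_init__(self):
        if self.mode not in ("none", "tv", "nv"):
            raise ValidationError(f"unknown acceptability mode {self.mode!r}")
        if self.mode == "tv" and self.tv < 0:
            raise ValidationError(f"TV must be >= 0, got {self.tv}")
        if self.mode == "nv" and self.nv < 1:
            raise ValidationError(f"NV must be >= 1, got {self.nv}")

    def bounds(self, q_base: np.ndarray, q_max: float) -> tuple[np.ndarray, np.ndarray]:
        if self.mode == "tv":
            lb = np.clip(q_base * (100.0 - self.tv) / 100.0, 0.0, None)
            ub = q_base * (100.0 + self.tv) / 100.0
        elif self.mode == "nv":
            lb = q_base * 0.1
            ub = q_base * self.nv
        else:
            lb = np.zeros_like(q_base)
            ub = np.full_like(q_base, q_max)
        return lb, ub


@dataclass(frozen=True)
class SolverSettings:
    n_starts: int = 5
    seed: int = 1
    maxiter: int = 400
    ftol: float = 1e-12
    constraint_tol: float = 1e-5  # re-check tolerance (relative)
    q_max: float = 2000.0  # g/day cap per product in unrestricted mode


@dataclass
class OptimizationResult:
    diet: Diet
    scores: ScoreVector | None
    dn: float
    solver_status: str
    n_starts: int
    feasible: bool
    violated: list[str] = field(default_factory=list)


def _matrices(db: FoodDatabase, ref: NutrientReference):
    """(energy row, adequacy matrix 9×n, limits matrix 3×n, RV, MV)."""
    nq = len(QUALIFYING_NUTRIENTS)
    return (
        db.energy,
        db.nutrients[:nq, :],
        db.nutrients[nq:, :],
        ref.rv_vector,
        ref.mv_vector,
    )


def check_constraints(
    q: np.ndarray, db: FoodDatabase, ref: NutrientReference, rel_tol: float = 1e-5
) -> list[str]:
    """Independent evaluator: names of violated energy/adequacy/limit constraints."""
    en, nmat, lmat, rv, mv = _matrices(db, ref)
    violated = []
    energy = float(en @ q)
    if abs(energy / ref.energy_target - 1.0) > _ENERGY_REL_TOL + rel_tol:
        violated.append(f"energy={energy:.3f} != {ref.energy_target:.3f}")
    nri = nmat @ q
    for name, got, need in zip(QUALIFYING_NUTRIENTS, nri, rv):
        if got < need * (1.0 - rel_tol):
            violated.append(f"adequacy:{name} ({got:.3f} < {need:.3f})")
    lni = lmat @ q
    for name, got, cap in zip(LIMITING_NUTRIENTS, lni, mv):
        if got > cap * (1.0 + rel_tol):
            violated.append(f"limit:{name} ({got:.3f} > {cap:.3f})")
    return violated


def _feasible_point(
    db: FoodDatabase,
    ref: NutrientReference,
    lb: np.ndarray,
    ub: np.ndarray,
) -> np.ndarray | None:
    """LP feasibility of Eqs energy/adequacy/limits inside the box, or None."""
    en, nmat, lmat, rv, mv = _matrices(db, ref)
    a_ub = np.vstack([-nmat, lmat])
    b_ub = np.concatenate([-rv, mv])
    res = linprog(
        c=np.zeros(len(db)),
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=en[None, :],
        b_eq=[ref.energy_target],
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.x if res.status == 0 else None


def _max_slacks(
    db: FoodDatabase, ref: NutrientReference, lb: np.ndarray, ub: np.ndarray
) -> dict[str, float]:
    """Best attainable relative slack of each nutrient constraint inside the box.

    Adequacy slack = (max NRI_i − RV_i)/RV_i; limit slack = (MV_i − min
    LNI_i)/MV_i; both computed subject to all other constraints. Negative
    slack means the constraint is unsatisfiable in this box.
    """
    en, nmat, lmat, rv, mv = _matrices(db, ref)
    a_ub = np.vstack([-nmat, lmat])
    b_ub = np.concatenate([-rv, mv])
    bounds = list(zip(lb, ub))
    slacks: dict[str, float] = {}

    def solve(c, drop_row):
        keep = [r for r in range(a_ub.shape[0]) if r != drop_row]
        res = linprog(
            c=c,
            A_ub=a_ub[keep],
            b_ub=b_ub[keep],
            A_eq=en[None, :],
            b_eq=[ref.energy_target],
            bounds=bounds,
            method="highs",
        )
        return res

    for i, name in enumerate(QUALIFYING_NUTRIENTS):
        res = solve(-nmat[i], drop_row=i)
        slacks[name] = (
            (float(-res.fun) - rv[i]) / rv[i] if res.status == 0 else -np.inf
        )
    nq = len(QUALIFYING_NUTRIENTS)
    for j, name in enumerate(LIMITING_NUTRIENTS):
        res = solve(lmat[j], drop_row=nq + j)
        slacks[name] = (
            (mv[j] - float(res.fun)) / mv[j] if res.status == 0 else -np.inf
        )
    return slacks


def _dn_objective(
    db: FoodDatabase,
    ref: NutrientReference,
    ctx: NormalizationContext,
    w: ObjectiveWeights,
    g: TargetVector,
):
    en, nmat, lmat, rv, mv = _matrices(db, ref)
    kv = w.vector
    gv = g.vector
    n_obj = len(kv)

    def dn(q: np.ndarray) -> float:
        tnr9 = np.minimum((nmat @ q) / rv, 1.0).sum() * 100.0
        tnl3 = ((lmat @ q) / mv).sum() * 100.0
        x = np.array(
            [
                (tnr9 - tnl3) / MAX_SCORE,
                (q / _G_PER_KG) @ db.ghg / ctx.ghg_max,
                (q / _G_PER_KG) @ db.price / ctx.tc_max,
            ]
        )
        return float(np.sqrt((kv * (x - gv) ** 2).sum() / n_obj))

    return dn


def _score_vector(q: np.ndarray, db: FoodDatabase, ref: NutrientReference,
                  ctx: NormalizationContext) -> ScoreVector:
    en, nmat, lmat, rv, mv = _matrices(db, ref)
    tnr9 = np.minimum((nmat @ q) / rv, 1.0).sum() * 100.0
    tnl3 = ((lmat @ q) / mv).sum() * 100.0
    return normalize(
        tnr9 - tnl3,
        float((q / _G_PER_KG) @ db.price),
        float((q / _G_PER_KG) @ db.ghg),
        ctx,
    )


def _nlp_constraints(db: FoodDatabase, ref: NutrientReference):
    en, nmat, lmat, rv, mv = _matrices(db, ref)
    target = ref.energy_target
    return [
        # energy equality as a ±1e-6 relative band
        {"type": "ineq", "fun": lambda q: (en @ q) / target - 1.0 + _ENERGY_REL_TOL},
        {"type": "ineq", "fun": lambda q: 1.0 + _ENERGY_REL_TOL - (en @ q) / target},
        {"type": "ineq", "fun": lambda q: (nmat @ q) / rv - 1.0},
        {"type": "ineq", "fun": lambda q: 1.0 - (lmat @ q) / mv},
    ]


def _multistart_minimize(
    db: FoodDatabase,
    ref: NutrientReference,
    ctx: NormalizationContext,
    w: ObjectiveWeights,
    g: TargetVector,
    lb: np.ndarray,
    ub: np.ndarray,
    starts: Sequence[np.ndarray],
    settings: SolverSettings,
) -> tuple[np.ndarray | None, float, str]:
    objective = _dn_objective(db, ref, ctx, w, g)
    constraints = _nlp_constraints(db, ref)
    bounds = list(zip(lb, ub))
    best_q, best_dn, status = None, np.inf, "no_start_converged"
    for q0 in starts:
        res = minimize(
            objective,
            np.clip(q0, lb, ub),
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": settings.maxiter, "ftol": settings.ftol},
        )
        q = np.clip(res.x, lb, ub)
        if check_constraints(q, db, ref, settings.constraint_tol):
            continue
        dn = objective(q)
        if dn < best_dn:
            best_q, best_dn, status = q, dn, "converged"
    return best_q, best_dn, status


def _starts(
    lb: np.ndarray,
    ub: np.ndarray,
    anchors: Sequence[np.ndarray],
    settings: SolverSettings,
) -> list[np.ndarray]:
    rng = np.random.default_rng(settings.seed)
    starts = [np.clip(a, lb, ub) for a in anchors]
    while len(starts) < settings.n_starts:
        starts.append(lb + rng.random(len(lb)) * (ub - lb))
    return starts[: max(settings.n_starts, len(anchors))]


def optimize_diet(
    baseline: Diet,
    db: FoodDatabase,
    ref: NutrientReference,
    ctx: NormalizationContext,
    w: ObjectiveWeights | None = None,
    acc: AcceptabilitySpec | None = None,
    solver: SolverSettings | None = None,
    g: TargetVector | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> OptimizationResult:
    """Minimize Dn over quantities inside the acceptability box around ``baseline``."""
    w = w or ObjectiveWeights.uniform()
    acc = acc or AcceptabilitySpec()
    solver = solver or SolverSettings()
    g = g or TargetVector()
    q_base = baseline.vector(db)
    lb, ub = acc.bounds(q_base, solver.q_max)

    lp_point = _feasible_point(db, ref, lb, ub)
    if lp_point is None:
        slacks = _max_slacks(db, ref, lb, ub)
        violated = sorted(n for n, s in slacks.items() if s < 0)
        return OptimizationResult(
            diet=baseline,
            scores=None,
            dn=np.inf,
            solver_status="infeasible",
            n_starts=0,
            feasible=False,
            violated=violated or ["energy"],
        )

    anchors = [lp_point, q_base, 0.5 * (lb + ub), *extra_starts]
    starts = _starts(lb, ub, anchors, solver)
    best_q, best_dn, status = _multistart_minimize(
        db, ref, ctx, w, g, lb, ub, starts, solver
    )
    if best_q is None:
        raise SolverError("SLSQP failed to return a feasible point from every start")
    return OptimizationResult(
        diet=Diet.from_vector(f"{baseline.name}-opt", best_q, db),
        scores=_score_vector(best_q, db, ref, ctx),
        dn=best_dn,
        solver_status=status,
        n_starts=len(starts),
        feasible=True,
    )


def optimize_unrestricted(
    db: FoodDatabase,
    ref: NutrientReference,
    ctx: NormalizationContext,
    w: ObjectiveWeights | None = None,
    solver: SolverSettings | None = None,
    g: TargetVector | None = None,
) -> OptimizationResult:
    """Minimize Dn with only Q_i ≥ 0 and the nutritional constraints.

    Solutions are typically sparse (few products); the support size is logged.
    """
    solver = solver or SolverSettings()
    empty = Diet("unrestricted", {})
    result = optimize_diet(
        empty,
        db,
        ref,
        ctx,
        w=w,
        acc=AcceptabilitySpec(mode="none"),
        solver=solver,
        g=g,
    )
    if result.feasible:
        support = sum(1 for v in result.diet.quantities.values() if v > 1.0)
        logger.info("unrestricted optimum uses %d products (> 1 g/day)", support)
    return result


# ---------------------------------------------------------------------------
# Minimal acceptability margin (Tv / Nv search)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginResult:
    mode: str  # "tv" or "nv"
    value: float  # smallest feasible TV (integer %) or NV (0.5 resolution)
    limiting_nutrients: list[str]
    trace: list[tuple[str, float, bool]]  # (mode, tested value, feasible)


def minimal_acceptability_margin(
    baseline: Diet,
    db: FoodDatabase,
    ref: NutrientReference,
    tv_max: float = 100.0,
    nv_max: float = 20.0,
) -> MarginResult:
    """Smallest acceptability margin making the nutritional constraints feasible.

    Bisects the symmetric TV band at integer-percent resolution; if even
    ``tv_max`` fails, switches to the NV mode (lower bound 10 % of baseline)
    at 0.5 resolution. Also reports which adequacy/limit constraints are
    active at the continuous threshold (the margin-limiting nutrients).
    """
    q_base = baseline.vector(db)
    trace: list[tuple[str, float, bool]] = []

    def feasible(mode: str, value: float) -> bool:
        spec = AcceptabilitySpec(mode=mode, tv=value) if mode == "tv" else AcceptabilitySpec(
            mode=mode, nv=value
        )
        lb, ub = spec.bounds(q_base, q_max=np.inf)
        ok = _feasible_point(db, ref, lb, ub) is not None
        trace.append((mode, value, ok))
        return ok

    def limiting(mode: str, lo: float, hi: float) -> list[str]:
        # Refine the continuous threshold, then read off the constraints with
        # (near-)zero best attainable slack. Slacks are evaluated at a
        # slightly relaxed margin so the LPs are solidly feasible: at the
        # exact threshold the feasible set degenerates to a point and the
        # slack subproblems become numerically fragile.
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if feasible(mode, mid):
                hi = mid
            else:
                lo = mid
        relaxed = hi + 1e-2 if mode == "tv" else hi + 1e-3
        spec = AcceptabilitySpec(mode=mode, tv=relaxed) if mode == "tv" else AcceptabilitySpec(
            mode=mode, nv=relaxed
        )
        lb, ub = spec.bounds(q_base, q_max=np.inf)
        slacks = _max_slacks(db, ref, lb, ub)
        return sorted(n for n, s in slacks.items() if s < 1e-3)

    if feasible("tv", 0.0):
        # baseline itself is feasible; report its active nutrient constraints
        en, nmat, lmat, rv, mv = _matrices(db, ref)
        rel_slack = dict(zip(QUALIFYING_NUTRIENTS, (nmat @ q_base - rv) / rv))
        rel_slack.update(zip(LIMITING_NUTRIENTS, (mv - lmat @ q_base) / mv))
        active = sorted(n for n, s in rel_slack.items() if s < 1e-6)
        return MarginResult(mode="tv", value=0.0, limiting_nutrients=active, trace=trace)

    if feasible("tv", tv_max):
        lo, hi = 0, int(np.ceil(tv_max))  # lo infeasible, hi feasible
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if feasible("tv", float(mid)):
                hi = mid
            else:
                lo = mid
        return MarginResult(
            mode="tv",
            value=float(hi),
            limiting_nutrients=limiting("tv", float(lo), float(hi)),
            trace=trace,
        )

    # NV mode on a 0.5 grid
    if not feasible("nv", nv_max):
        slacks_at_max = _max_slacks(
            db, ref, *AcceptabilitySpec(mode="nv", nv=nv_max).bounds(q_base, np.inf)
        )
        unsat = sorted(n for n, s in slacks_at_max.items() if s < 0)
        raise InfeasibleError(
            f"no acceptability margin up to NV={nv_max} satisfies the nutritional "
            f"constraints (unsatisfiable: {unsat})",
            report={"unsatisfiable": unsat},
        )
    grid = np.arange(1.0, nv_max + 0.25, 0.5)
    lo_i, hi_i = 0, len(grid) - 1  # grid[hi_i] known feasible
    if feasible("nv", grid[0]):
        hi_i = 0
    else:
        while hi_i - lo_i > 1:
            mid = (lo_i + hi_i) // 2
            if feasible("nv", float(grid[mid])):
                hi_i = mid
            else:
                lo_i = mid
    nv_value = float(grid[hi_i])
    lo_cont = float(grid[lo_i]) if hi_i > 0 else 1.0
    return MarginResult(
        mode="nv",
        value=nv_value,
        limiting_nutrients=limiting("nv", lo_cont, nv_value),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# ε-constraint Pareto front (exact LP with capped-ratio auxiliaries)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParetoPoint:
    diet: Diet
    nrd93: float
    cost: float  # €/day
    ghg: float  # kg CO2eq/day
    epsilon: float  # the bound that generated this point


def _max_nrd_lp(
    db: FoodDatabase,
    ref: NutrientReference,
    cost_cap: float | None,
    ghg_cap: float | None,
    q_max: float,
):
    """Maximize capped NRD9.3 s.t. energy equality and optional cost/GHG caps."""
    en, nmat, lmat, rv, mv = _matrices(db, ref)
    n = len(db)
    nq = len(rv)
    w_l = 100.0 * (1.0 / mv) @ lmat  # TNL3 = w_l @ q
    c = np.concatenate([w_l, -100.0 * np.ones(nq)])  # minimize TNL3 − TNR9
    # t_i − (N_i/RV_i)@q ≤ 0
    a_rows = [np.concatenate([-nmat[i] / rv[i], np.eye(nq)[i]]) for i in range(nq)]
    b_rows = [0.0] * nq
    if cost_cap is not None:
        a_rows.append(np.concatenate([db.price / _G_PER_KG, np.zeros(nq)]))
        b_rows.append(cost_cap)
    if ghg_cap is not None:
        a_rows.append(np.concatenate([db.ghg / _G_PER_KG, np.zeros(nq)]))
        b_rows.append(ghg_cap)
    res = linprog(
        c=c,
        A_ub=np.array(a_rows),
        b_ub=np.array(b_rows),
        A_eq=np.concatenate([en, np.zeros(nq)])[None, :],
        b_eq=[ref.energy_target],
        bounds=[(0.0, q_max)] * n + [(0.0, 1.0)] * nq,
        method="highs",
    )
    if res.status != 0:
        return None
    q = res.x[:n]
    return q, float(-res.fun)


def _dominates(a: ParetoPoint, b: ParetoPoint) -> bool:
    ge = a.nrd93 >= b.nrd93 and a.cost <= b.cost and a.ghg <= b.ghg
    strict = a.nrd93 > b.nrd93 or a.cost < b.cost or a.ghg < b.ghg
    return ge and strict


def pareto_front(
    db: FoodDatabase,
    ref: NutrientReference,
    cost_levels: Sequence[float] = (),
    ghg_levels: Sequence[float] = (),
    q_max: float = 2000.0,
) -> list[ParetoPoint]:
    """ε-constraint front: maximize NRD9.3 under each cost (and/or GHG) cap.

    Infeasible levels are skipped with a log entry; the returned set is
    filtered to mutually non-dominated points.
    """
    if not len(cost_levels) and not len(ghg_levels):
        raise ValidationError("pareto_front needs at least one ε-level")
    points: list[ParetoPoint] = []
    for eps in cost_levels:
        sol = _max_nrd_lp(db, ref, cost_cap=eps, ghg_cap=None, q_max=q_max)
        if sol is None:
            logger.info("cost level %.3f €/day infeasible; skipped", eps)
            continue
        q, nrd = sol
        points.append(
            ParetoPoint(
                diet=Diet.from_vector(f"pareto_cost_{eps:g}", q, db),
                nrd93=nrd,
                cost=float((q / _G_PER_KG) @ db.price),
                ghg=float((q / _G_PER_KG) @ db.ghg),
                epsilon=float(eps),
            )
        )
    for eps in ghg_levels:
        sol = _max_nrd_lp(db, ref, cost_cap=None, ghg_cap=eps, q_max=q_max)
        if sol is None:
            logger.info("GHG level %.3f kg/day infeasible; skipped", eps)
            continue
        q, nrd = sol
        points.append(
            ParetoPoint(
                diet=Diet.from_vector(f"pareto_ghg_{eps:g}", q, db),
                nrd93=nrd,
                cost=float((q / _G_PER_KG) @ db.price),
                ghg=float((q / _G_PER_KG) @ db.ghg),
                epsilon=float(eps),
            )
        )
    return [p for p in points if not any(_dominates(o, p) for o in points if o is not p)]
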