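"""Corrected GHG emissions: a nutrition- and affordability-aware functional unit.

Raw per-day emissions are a poor basis for comparing diets that differ in
nutritional quality and cost. The corrected metric divides a diet's GHG by
three scores:

* RIS — residual income score, 1 − cost/consumption-income (affordability),
* α (ES) — energy score, DE_diet/DE_ref capped at 1 (1 for isocaloric diets),
* NS — nutritional score, NRD9.3_diet / NRD9.3_ref.

    c-GHG = GHG / (RIS · α · NS)

so an expensive, nutritionally poor diet is charged more per "functional"
unit than its raw footprint suggests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import UnaffordableDietError, ValidationError
from .reference_diets import CONSUMPTION_INCOME, REFERENCE_ENERGY, REFERENCE_NRD93

_SCORE_FLOOR = 1e-6


@dataclass(frozen=True)
class ComparisonContext:
    """Reference quantities for the correction scores."""

    consumption_income: float = CONSUMPTION_INCOME  # €/day
    reference_nrd93: float = REFERENCE_NRD93  # percentage points
    reference_energy: float = REFERENCE_ENERGY  # kcal/day

    def __post_init__(self):
        for label, v in (
            ("consumption_income", self.consumption_income),
            ("reference_nrd93", self.reference_nrd93),
            ("reference_energy", self.reference_energy),
        ):
            if v <= 0:
                raise ValidationError(f"{label} must be > 0, got {v}")


@dataclass(frozen=True)
class CorrectedScore:
    ris: float
    alpha: float
    ns: float
    c_ghg: float  # c-kg CO2eq/day


def residual_income_score(cost: float, ctx: ComparisonContext) -> float:
    """RIS = 1 − cost/consumption-income (RI_max normalized to one)."""
    if cost >= ctx.consumption_income:
        raise UnaffordableDietError(
            f"diet cost {cost:.2f} €/day meets or exceeds the consumption income "
            f"{ctx.consumption_income:.2f} €/day"
        )
    return 1.0 - cost / ctx.consumption_income


def energy_score(de_diet: float, ctx: ComparisonContext) -> float:
    """α = DE_diet/DE_ref below the reference energy, 1 at or above it."""
    if de_diet <= 0:
        raise ValidationError(f"diet energy must be > 0, got {de_diet}")
    if de_diet < ctx.reference_energy:
        return de_diet / ctx.reference_energy
    return 1.0


def nutritional_score(nrd93_diet: float, ctx: ComparisonContext) -> float:
    """NS = NRD9.3_diet / NRD9.3_ref (may exceed 1)."""
    return nrd93_diet / ctx.reference_nrd93


def corrected_ghg(ghg: float, ris: float, alpha: float, ns: float) -> float:
    """c-GHG = GHG/(RIS·α·NS); raises rather than returning near-infinities."""
    for label, score in (("ris", ris), ("alpha", alpha), ("ns", ns)):
        if score <= _SCORE_FLOOR:
            raise ValidationError(
                f"correction score {label}={score} is at or below the {_SCORE_FLOOR} guard floor"
            )
    return ghg / (ris * alpha * ns)


def corrected_score(
    ghg: float,
    cost: float,
    nrd93: float,
    ctx: ComparisonContext | None = None,
    de_diet: float | None = None,
) -> CorrectedScore:
    """All correction factors plus c-GHG for one diet."""
    ctx = ctx or ComparisonContext()
    ris = residual_income_score(cost, ctx)
    alpha = energy_score(de_diet if de_diet is not None else ctx.reference_energy, ctx)
    ns = nutritional_score(nrd93, ctx)
    return CorrectedScore(ris=ris, alpha=alpha, ns=ns, c_ghg=corrected_ghg(ghg, ris, alpha, ns))


def comparison_table(
    rows: dict[str, tuple[float, float, float]], ctx: ComparisonContext | None = None
) -> pd.DataFrame:
    """Per-diet comparison table from {name: (cost, nrd93, ghg)} (isocaloric)."""
    ctx = ctx or ComparisonContext()
    records = []
    for name, (cost, nrd93, ghg) in rows.items():
        cs = corrected_score(ghg=ghg, cost=cost, nrd93=nrd93, ctx=ctx)
        records.append(
            {
                "diet": name,
                "price": cost,
                "nrd93": nrd93,
                "ghg": ghg,
                "ris": cs.ris,
                "ns": cs.ns,
                "c_ghg": cs.c_ghg,
            }
        )
    return pd.DataFrame(records).set_index("diet")
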