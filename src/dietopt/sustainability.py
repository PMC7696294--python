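"""Environmental and economic indicators and their normalization.

Daily GHG emissions and total cost are linear aggregations of the diet's
gram quantities against per-kilogram intensities (with the explicit g→kg
conversion). The three indicators are mapped onto a dimensionless score
vector: X_NUTR = NRD9.3/900 (fixed theoretical maximum), while X_ENV and
X_EC divide by the maxima observed over a *set of whole diets* — never over
single products, and frozen from the baseline set before any optimization so
the objective's denominators do not move with the decision variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import NormalizationError
from .foodmodel import Diet, FoodDatabase, NutrientReference, compute_intake
from .nutrition import MAX_SCORE, compute_nrd93

_G_PER_KG = 1000.0


@dataclass(frozen=True)
class ScoreVector:
    """Raw indicators plus their normalized [0, 1] counterparts for one diet."""

    nrd93: float  # percentage points
    cost: float  # €/day (TC)
    ghg: float  # kg CO2eq/day
    x_nutr: float
    x_env: float
    x_ec: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x_nutr, self.x_env, self.x_ec])


@dataclass(frozen=True)
class NormalizationContext:
    """Per-objective maxima taken over the baseline diet set."""

    ghg_max: float  # kg CO2eq/day
    tc_max: float  # €/day

    def __post_init__(self):
        if self.ghg_max <= 0 or self.tc_max <= 0:
            raise NormalizationError(
                f"normalization maxima must be > 0 (ghg_max={self.ghg_max}, tc_max={self.tc_max})"
            )


def total_ghg(diet: Diet, db: FoodDatabase) -> float:
    """Daily diet emissions, kg CO2eq/day (quantities g/day × intensities kg CO2eq/kg)."""
    return float((diet.vector(db) / _G_PER_KG) @ db.ghg)


def total_cost(diet: Diet, db: FoodDatabase) -> float:
    """Daily diet cost, €/day (quantities g/day × prices €/kg)."""
    return float((diet.vector(db) / _G_PER_KG) @ db.price)


def build_normalization(
    diet_scores: Iterable[tuple[float, float, float]]
) -> NormalizationContext:
    """Context from (nrd93, cost, ghg) triples of the baseline diets."""
    scores = list(diet_scores)
    if not scores:
        raise NormalizationError("cannot build a normalization context from an empty set")
    ghg_max = max(s[2] for s in scores)
    tc_max = max(s[1] for s in scores)
    return NormalizationContext(ghg_max=ghg_max, tc_max=tc_max)


def normalize(
    nrd93: float, cost: float, ghg: float, ctx: NormalizationContext
) -> ScoreVector:
    """Dimensionless score vector; values may exceed 1 outside the baseline set."""
    return ScoreVector(
        nrd93=nrd93,
        cost=cost,
        ghg=ghg,
        x_nutr=nrd93 / MAX_SCORE,
        x_env=ghg / ctx.ghg_max,
        x_ec=cost / ctx.tc_max,
    )


def score_diet(
    diet: Diet, db: FoodDatabase, ref: NutrientReference, ctx: NormalizationContext
) -> ScoreVector:
    """Full (raw + normalized) score vector of one diet."""
    nut = compute_nrd93(compute_intake(diet, db), ref)
    return normalize(nut.nrd93, total_cost(diet, db), total_ghg(diet, db), ctx)


def baseline_context(
    diets: Sequence[Diet], db: FoodDatabase, ref: NutrientReference
) -> NormalizationContext:
    """Build the frozen context from a set of baseline diets."""
    triples = []
    for d in diets:
        nut = compute_nrd93(compute_intake(d, db), ref)
        triples.append((nut.nrd93, total_cost(d, db), total_ghg(d, db)))
    return build_normalization(triples)


def score_table(
    diets: Sequence[Diet], db: FoodDatabase, ref: NutrientReference,
    ctx: NormalizationContext | None = None,
) -> pd.DataFrame:
    """Indicator table: one column per diet, rows NRD9.3/TC/GHG/XNUTR/XENV/XEC."""
    if ctx is None:
        ctx = baseline_context(diets, db, ref)
    columns = {}
    for d in diets:
        s = score_diet(d, db, ref, ctx)
        columns[d.name] = [s.nrd93, s.cost, s.ghg, s.x_nutr, s.x_env, s.x_ec]
    return pd.DataFrame(
        columns, index=["NRD9.3", "TC", "GHG", "XNUTR", "XENV", "XEC"]
    )
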