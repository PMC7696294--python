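"""Nutrient-density scoring: NRD9.3 and its weighted variant NRD9.3w.

NRD9.3 = TNR9 − TNL3, where TNR9 sums the percent coverage of the nine
qualifying-nutrient recommended values (each capped at 100 so overconsumption
earns no credit) and TNL3 sums the percent of the three limiting-nutrient
maxima (uncapped — a diet can be penalized beyond 100 per nutrient). The
theoretical maximum is 900: full coverage of every qualifying nutrient with
zero limiting intake.

The weighted variant multiplies each per-nutrient term by a weight; weights
live on floor-constrained simplices (Σ kr_i = 9, kr_i ≥ 0.5 for qualifying;
Σ km_i = 3, km_i ≥ 0.2 for limiting). Because the score is linear in the
weights, its extrema over that polytope are attained at vertices where a
single nutrient carries all slack mass — the basis of the extremal analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .foodmodel import (
    LIMITING_NUTRIENTS,
    QUALIFYING_NUTRIENTS,
    NutrientIntake,
    NutrientReference,
)

KR_SUM = 9.0
KR_FLOOR = 0.5
KM_SUM = 3.0
KM_FLOOR = 0.2
MAX_SCORE = 900.0

_TOL = 1e-9


@dataclass(frozen=True)
class NutrientWeights:
    """Per-nutrient weights (kr_i qualifying, km_i limiting)."""

    kr: Mapping[str, float]
    km: Mapping[str, float]

    def __post_init__(self):
        kr = self.kr_vector
        km = self.km_vector
        if abs(float(kr.sum()) - KR_SUM) > _TOL:
            raise ValidationError(
                f"qualifying weights must sum to {KR_SUM:g}, got {kr.sum():.12g}"
            )
        if float(kr.min()) < KR_FLOOR - _TOL:
            raise ValidationError(
                f"each qualifying weight must be >= {KR_FLOOR}, min is {kr.min():.12g}"
            )
        if abs(float(km.sum()) - KM_SUM) > _TOL:
            raise ValidationError(
                f"limiting weights must sum to {KM_SUM:g}, got {km.sum():.12g}"
            )
        if float(km.min()) < KM_FLOOR - _TOL:
            raise ValidationError(
                f"each limiting weight must be >= {KM_FLOOR}, min is {km.min():.12g}"
            )

    @property
    def kr_vector(self) -> np.ndarray:
        try:
            return np.array([float(self.kr[n]) for n in QUALIFYING_NUTRIENTS])
        except KeyError as exc:
            raise ValidationError(f"kr is missing nutrient {exc.args[0]!r}") from None

    @property
    def km_vector(self) -> np.ndarray:
        try:
            return np.array([float(self.km[n]) for n in LIMITING_NUTRIENTS])
        except KeyError as exc:
            raise ValidationError(f"km is missing nutrient {exc.args[0]!r}") from None

    @classmethod
    def uniform(cls) -> "NutrientWeights":
        return cls(
            kr={n: 1.0 for n in QUALIFYING_NUTRIENTS},
            km={n: 1.0 for n in LIMITING_NUTRIENTS},
        )

    @classmethod
    def from_vectors(cls, kr: np.ndarray, km: np.ndarray) -> "NutrientWeights":
        return cls(
            kr=dict(zip(QUALIFYING_NUTRIENTS, map(float, kr))),
            km=dict(zip(LIMITING_NUTRIENTS, map(float, km))),
        )


@dataclass(frozen=True)
class NutritionScore:
    """Capped sub-scores and the NRD9.3 total (percentage points)."""

    tnr9: float
    tnl3: float
    nrd93: float
    relative_intakes: Mapping[str, float]  # NRI_i/RV_i (uncapped) or LNI_i/MV_i


def _ratios(intake: NutrientIntake, ref: NutrientReference) -> tuple[np.ndarray, np.ndarray]:
    """(qualifying NRI_i/RV_i uncapped, limiting LNI_i/MV_i)."""
    return intake.qualifying / ref.rv_vector, intake.limiting / ref.mv_vector


def compute_nrd93(intake: NutrientIntake, ref: NutrientReference) -> NutritionScore:
    """Unweighted NRD9.3 with qualifying intakes capped at their RV."""
    qr, lr = _ratios(intake, ref)
    tnr9 = float(np.minimum(qr, 1.0).sum() * 100.0)
    tnl3 = float(lr.sum() * 100.0)
    relative = dict(zip(QUALIFYING_NUTRIENTS, map(float, qr)))
    relative.update(zip(LIMITING_NUTRIENTS, map(float, lr)))
    return NutritionScore(tnr9=tnr9, tnl3=tnl3, nrd93=tnr9 - tnl3, relative_intakes=relative)


def compute_nrd93_weighted(
    intake: NutrientIntake, ref: NutrientReference, w: NutrientWeights
) -> float:
    """Weighted NRD9.3w; reduces to NRD9.3 when all weights are 1."""
    qr, lr = _ratios(intake, ref)
    return float(
        (w.kr_vector * np.minimum(qr, 1.0)).sum() * 100.0
        - (w.km_vector * lr).sum() * 100.0
    )


@dataclass(frozen=True)
class ExtremalScores:
    min_score: float
    max_score: float
    min_weights: NutrientWeights
    max_weights: NutrientWeights


def _vertex(n: int, total: float, floor: float, hot: int) -> np.ndarray:
    v = np.full(n, floor)
    v[hot] = total - floor * (n - 1)
    return v


def extremal_weighted_scores(
    intake: NutrientIntake, ref: NutrientReference
) -> ExtremalScores:
    """Extrema of NRD9.3w over the feasible weight polytope.

    The score is linear in (kr, km) and the two weight blocks are independent,
    so the extrema are found by enumerating the 9 qualifying and 3 limiting
    single-nutrient-overweight vertices. Ties break on nutrient order.
    """
    qr, lr = _ratios(intake, ref)
    a = np.minimum(qr, 1.0) * 100.0  # qualifying contribution per unit weight
    b = lr * 100.0  # limiting penalty per unit weight

    def block_extrema(coef: np.ndarray, total: float, floor: float):
        values = [
            float(coef @ _vertex(len(coef), total, floor, hot))
            for hot in range(len(coef))
        ]
        lo = int(np.argmin(values))
        hi = int(np.argmax(values))
        return (values[lo], lo), (values[hi], hi)

    (a_min, a_min_hot), (a_max, a_max_hot) = block_extrema(a, KR_SUM, KR_FLOOR)
    (b_min, b_min_hot), (b_max, b_max_hot) = block_extrema(b, KM_SUM, KM_FLOOR)

    # max score: most favorable qualifying vertex, least penalizing limiting vertex
    max_w = NutrientWeights.from_vectors(
        _vertex(9, KR_SUM, KR_FLOOR, a_max_hot), _vertex(3, KM_SUM, KM_FLOOR, b_min_hot)
    )
    min_w = NutrientWeights.from_vectors(
        _vertex(9, KR_SUM, KR_FLOOR, a_min_hot), _vertex(3, KM_SUM, KM_FLOOR, b_max_hot)
    )
    return ExtremalScores(
        min_score=a_min - b_max,
        max_score=a_max - b_min,
        min_weights=min_w,
        max_weights=max_w,
    )
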