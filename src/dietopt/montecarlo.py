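"""Monte-Carlo sensitivity of NRD9.3w to the nutrient weights.

Weight sets are drawn uniformly (flat Dirichlet) on the floor-shifted
simplices — kr = 0.5 + 4.5·Dir(1⁹), km = 0.2 + 2.4·Dir(1³) — the
maximum-entropy law consistent with the weight constraints. The same draws
are applied to every diet (paired design), so per-draw scatter comparisons
between two diets are meaningful. Draw distributions are bounded by the
linear-programming extrema of the weighted score and carry no further
statistical inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .foodmodel import NutrientIntake, NutrientReference
from .nutrition import (
    KM_FLOOR,
    KM_SUM,
    KR_FLOOR,
    KR_SUM,
    NutrientWeights,
    compute_nrd93_weighted,
)

DEFAULT_DRAWS = 1000


@dataclass(frozen=True)
class WeightSample:
    weights: NutrientWeights
    draw_index: int


def sample_weights(n_draws: int = DEFAULT_DRAWS, seed: int = 0) -> list[WeightSample]:
    """Draw ``n_draws`` weight sets satisfying the sum/floor constraints exactly."""
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    kr_mass = KR_SUM - 9 * KR_FLOOR  # slack mass above the floors
    km_mass = KM_SUM - 3 * KM_FLOOR
    kr_draws = rng.dirichlet(np.ones(9), size=n_draws)
    km_draws = rng.dirichlet(np.ones(3), size=n_draws)
    samples = []
    for i in range(n_draws):
        kr = KR_FLOOR + kr_mass * kr_draws[i] / kr_draws[i].sum()
        km = KM_FLOOR + km_mass * km_draws[i] / km_draws[i].sum()
        samples.append(
            WeightSample(weights=NutrientWeights.from_vectors(kr, km), draw_index=i)
        )
    return samples


def score_distribution(
    intake: NutrientIntake, ref: NutrientReference, samples: Sequence[WeightSample]
) -> np.ndarray:
    """NRD9.3w of one intake under every sampled weight set."""
    return np.array(
        [compute_nrd93_weighted(intake, ref, s.weights) for s in samples]
    )


@dataclass(frozen=True)
class PairedComparison:
    scores_a: np.ndarray
    scores_b: np.ndarray
    win_fraction: float  # fraction of draws with score_a > score_b (ties excluded)


def pairwise_comparison(
    intake_a: NutrientIntake,
    intake_b: NutrientIntake,
    ref: NutrientReference,
    samples: Sequence[WeightSample],
) -> PairedComparison:
    """Apply the same weight draws to both diets and count strict wins of A."""
    a = score_distribution(intake_a, ref, samples)
    b = score_distribution(intake_b, ref, samples)
    return PairedComparison(
        scores_a=a, scores_b=b, win_fraction=float(np.mean(a > b))
    )
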