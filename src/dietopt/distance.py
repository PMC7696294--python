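"""Distance-to-target objective: Euclidean and normalized weighted distances.

The compromise-programming indicator is

    Dn = sqrt( Σ_i k_i (F_i − G_i)² / n )

over the n = 3 normalized objectives (nutrition, environment, economy) with
targets G = (1, 0, 0): full nutritional coverage at zero cost and zero
emissions. Weights live on the floor-constrained simplex Σ k_i = n,
k_i ≥ V_L (default 0.2); with F, G in [0, 1] this bounds Dn in [0, 1].
Dn² is linear in k, so its extrema over the simplex sit at vertices where one
objective carries all slack weight (n − (n−1)·V_L) — over-weighting the least
(most) favorable aspect yields the maximal (minimal) distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .sustainability import ScoreVector

OBJECTIVES: tuple[str, ...] = ("NUTR", "ENV", "EC")
DEFAULT_FLOOR = 0.2

_TOL = 1e-9


@dataclass(frozen=True)
class ObjectiveWeights:
    """Objective weights k_i on the floor-constrained simplex."""

    k: Mapping[str, float]
    floor: float = DEFAULT_FLOOR

    def __post_init__(self):
        kv = self.vector
        n = len(OBJECTIVES)
        if abs(float(kv.sum()) - n) > _TOL:
            raise ValidationError(f"objective weights must sum to {n}, got {kv.sum():.12g}")
        if float(kv.min()) < self.floor - _TOL:
            raise ValidationError(
                f"each objective weight must be >= {self.floor}, min is {kv.min():.12g}"
            )

    @property
    def vector(self) -> np.ndarray:
        try:
            return np.array([float(self.k[o]) for o in OBJECTIVES])
        except KeyError as exc:
            raise ValidationError(f"weights missing objective {exc.args[0]!r}") from None

    @classmethod
    def uniform(cls, floor: float = DEFAULT_FLOOR) -> "ObjectiveWeights":
        return cls(k={o: 1.0 for o in OBJECTIVES}, floor=floor)

    @classmethod
    def vertex(cls, overweighted: str, floor: float = DEFAULT_FLOOR) -> "ObjectiveWeights":
        """Vertex weights: ``overweighted`` gets n − (n−1)·floor, the rest the floor."""
        if overweighted not in OBJECTIVES:
            raise ValidationError(f"unknown objective {overweighted!r}")
        n = len(OBJECTIVES)
        k = {o: floor for o in OBJECTIVES}
        k[overweighted] = n - (n - 1) * floor
        return cls(k=k, floor=floor)


@dataclass(frozen=True)
class TargetVector:
    """Normalized targets G_i; defaults to the ideal diet (1, 0, 0)."""

    g: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.g is None:
            object.__setattr__(self, "g", {"NUTR": 1.0, "ENV": 0.0, "EC": 0.0})
        missing = set(OBJECTIVES) - set(self.g)
        if missing:
            raise ValidationError(f"target vector missing objective(s) {sorted(missing)}")

    @property
    def vector(self) -> np.ndarray:
        return np.array([float(self.g[o]) for o in OBJECTIVES])


def _scores_array(x: "ScoreVector | Sequence[float] | np.ndarray") -> np.ndarray:
    if isinstance(x, ScoreVector):
        return x.as_array()
    arr = np.asarray(x, dtype=float)
    return arr


def euclidean_distance(f: Sequence[float], g: "TargetVector | Sequence[float]") -> float:
    """Plain Euclidean distance between a score vector and a target vector."""
    fv = np.asarray(f, dtype=float)
    gv = g.vector if isinstance(g, TargetVector) else np.asarray(g, dtype=float)
    if fv.shape != gv.shape:
        raise ValueError(f"dimension mismatch: {fv.shape} vs {gv.shape}")
    return float(np.sqrt(((fv - gv) ** 2).sum()))


def normalized_distance(
    x: "ScoreVector | Sequence[float]",
    g: TargetVector | None = None,
    w: ObjectiveWeights | None = None,
) -> float:
    """Normalized weighted distance Dn in [0, 1] for normalized scores."""
    g = g or TargetVector()
    w = w or ObjectiveWeights.uniform()
    fv = _scores_array(x)
    dev2 = (fv - g.vector) ** 2
    return float(np.sqrt((w.vector * dev2).sum() / len(OBJECTIVES)))


@dataclass(frozen=True)
class ExtremalDistances:
    min_dn: float
    max_dn: float
    min_weights: ObjectiveWeights
    max_weights: ObjectiveWeights
    min_overweighted: str  # most favorable aspect (smallest squared deviation)
    max_overweighted: str  # least favorable aspect (largest squared deviation)


def extremal_distances(
    x: "ScoreVector | Sequence[float]",
    g: TargetVector | None = None,
    floor: float = DEFAULT_FLOOR,
) -> ExtremalDistances:
    """Extrema of Dn over the weight simplex, by exhaustive vertex enumeration.

    Ties between vertices break on objective order NUTR < ENV < EC.
    """
    if not 0.0 < floor <= 1.0:
        raise ValidationError(f"weight floor must lie in (0, 1], got {floor}")
    g = g or TargetVector()
    candidates = [
        (normalized_distance(x, g, ObjectiveWeights.vertex(o, floor)), o)
        for o in OBJECTIVES
    ]
    values = np.array([c[0] for c in candidates])
    lo = int(np.argmin(values))
    hi = int(np.argmax(values))
    return ExtremalDistances(
        min_dn=candidates[lo][0],
        max_dn=candidates[hi][0],
        min_weights=ObjectiveWeights.vertex(OBJECTIVES[lo], floor),
        max_weights=ObjectiveWeights.vertex(OBJECTIVES[hi], floor),
        min_overweighted=OBJECTIVES[lo],
        max_overweighted=OBJECTIVES[hi],
    )


def distance_table(scores: Mapping[str, "ScoreVector | Sequence[float]"],
                   floor: float = DEFAULT_FLOOR):
    """Per-diet distance summary (equally weighted, maximal, minimal + aspects)."""
    import pandas as pd

    rows: dict[str, list] = {
        "equally_weighted": [],
        "maximal_dn": [],
        "max_overweighted": [],
        "minimal_dn": [],
        "min_overweighted": [],
    }
    for name, x in scores.items():
        ext = extremal_distances(x, floor=floor)
        rows["equally_weighted"].append(normalized_distance(x))
        rows["maximal_dn"].append(ext.max_dn)
        rows["max_overweighted"].append(ext.max_overweighted)
        rows["minimal_dn"].append(ext.min_dn)
        rows["min_overweighted"].append(ext.min_overweighted)
    return pd.DataFrame(rows, index=list(scores)).T
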