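"""Domain model for food products, diets and nutrient intakes.

The model follows the NRD9.3 nutrient-profiling convention: nine *qualifying*
(encouraging) nutrients whose intake is rewarded — protein, fiber, Ca, Fe,
Mg, K and vitamins A, C and E — and three *limiting* nutrients whose intake
is penalized — saturated fat, added sugar and sodium.

Unit conventions (used consistently across the package):

* diet quantities ``Q_i`` are grams of food per day,
* energy and nutrient densities are per gram of food,
* price (``C_i``, €/kg) and GHG intensity (``E_i``, kg CO2eq/kg) are per
  kilogram, with the gram→kilogram conversion applied inside the cost and
  emission aggregations.

The module also ships a synthetic food-database / baseline-diet generator
emulating a ~63-product Southern-European market basket, used throughout the
test-suite in place of proprietary food-composition, price and LCA tables.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    InfeasibleError,
    SchemaError,
    UnknownProductError,
    ValidationError,
)


class NutrientClass(str, Enum):
    QUALIFYING = "qualifying"
    LIMITING = "limiting"


@dataclass(frozen=True)
class Nutrient:
    """One of the 12 nutrients of the NRD9.3 index."""

    code: str
    cls: NutrientClass
    unit: str  # daily-amount unit


QUALIFYING_NUTRIENTS: tuple[str, ...] = (
    "protein",
    "fiber",
    "calcium",
    "iron",
    "magnesium",
    "potassium",
    "vitamin_a",
    "vitamin_c",
    "vitamin_e",
)
LIMITING_NUTRIENTS: tuple[str, ...] = ("saturated_fat", "added_sugar", "sodium")
NUTRIENT_ORDER: tuple[str, ...] = QUALIFYING_NUTRIENTS + LIMITING_NUTRIENTS

_UNITS = {
    "protein": "g",
    "fiber": "g",
    "calcium": "mg",
    "iron": "mg",
    "magnesium": "mg",
    "potassium": "mg",
    "vitamin_a": "ug_RE",
    "vitamin_c": "mg",
    "vitamin_e": "mg",
    "saturated_fat": "g",
    "added_sugar": "g",
    "sodium": "mg",
}

NUTRIENTS: dict[str, Nutrient] = {
    code: Nutrient(
        code,
        NutrientClass.QUALIFYING if code in QUALIFYING_NUTRIENTS else NutrientClass.LIMITING,
        _UNITS[code],
    )
    for code in NUTRIENT_ORDER
}

#: Categories treated as animal-source when building plant-based patterns.
ANIMAL_CATEGORIES: frozenset[str] = frozenset(
    {"red_meat", "white_meat", "processed_meat", "fish", "eggs", "dairy"}
)

_DB_COLUMNS = (
    ["id", "name", "category", "energy_kcal_per_g"]
    + list(NUTRIENT_ORDER)
    + ["price_eur_per_kg", "ghg_kgco2e_per_kg"]
)


@dataclass(frozen=True)
class FoodProduct:
    """Per-gram/per-kg descriptors of one food item."""

    id: str
    name: str
    category: str
    energy_density: float  # kcal/g
    nutrient_density: Mapping[str, float]  # per g, keys = NUTRIENT_ORDER
    price: float  # €/kg (C_i)
    ghg_intensity: float  # kg CO2eq/kg (E_i)

    def __post_init__(self):
        missing = set(NUTRIENT_ORDER) - set(self.nutrient_density)
        if missing:
            raise SchemaError(
                f"product {self.id!r}: missing nutrient densities {sorted(missing)}"
            )
        for label, value in (
            ("energy_density", self.energy_density),
            ("price", self.price),
            ("ghg_intensity", self.ghg_intensity),
            *((n, self.nutrient_density[n]) for n in NUTRIENT_ORDER),
        ):
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"product {self.id!r}: {label} must be finite and >= 0, got {value}"
                )


class FoodDatabase:
    """Ordered collection of :class:`FoodProduct` with cached numeric views."""

    def __init__(self, products: Sequence[FoodProduct]):
        products = list(products)
        if not products:
            raise ValidationError("food database must contain at least one product")
        ids = [p.id for p in products]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate product ids: {dup}")
        self.products: list[FoodProduct] = products
        self._index = {p.id: k for k, p in enumerate(products)}
        self.energy = np.array([p.energy_density for p in products])
        # rows follow NUTRIENT_ORDER, columns follow product order
        self.nutrients = np.array(
            [[p.nutrient_density[n] for p in products] for n in NUTRIENT_ORDER]
        )
        self.price = np.array([p.price for p in products])
        self.ghg = np.array([p.ghg_intensity for p in products])

    def __len__(self) -> int:
        return len(self.products)

    def __iter__(self):
        return iter(self.products)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.products]

    @property
    def categories(self) -> set[str]:
        return {p.category for p in self.products}

    def index(self, product_id: str) -> int:
        try:
            return self._index[product_id]
        except KeyError:
            raise UnknownProductError(f"unknown product id {product_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": p.id,
                "name": p.name,
                "category": p.category,
                "energy_kcal_per_g": p.energy_density,
                **{n: p.nutrient_density[n] for n in NUTRIENT_ORDER},
                "price_eur_per_kg": p.price,
                "ghg_kgco2e_per_kg": p.ghg_intensity,
            }
            for p in self.products
        ]
        return pd.DataFrame(rows, columns=_DB_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FoodDatabase":
        missing = [c for c in _DB_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"food database table is missing column(s) {missing}")
        products = []
        for _, row in frame.iterrows():
            products.append(
                FoodProduct(
                    id=str(row["id"]),
                    name=str(row["name"]),
                    category=str(row["category"]),
                    energy_density=float(row["energy_kcal_per_g"]),
                    nutrient_density={n: float(row[n]) for n in NUTRIENT_ORDER},
                    price=float(row["price_eur_per_kg"]),
                    ghg_intensity=float(row["ghg_kgco2e_per_kg"]),
                )
            )
        return cls(products)


def read_food_database(path: str | Path, format: str | None = None) -> FoodDatabase:
    """Read a food database from CSV or JSON (UTF-8, '.' decimal)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.read_csv(path)
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            frame = pd.DataFrame(json.load(fh)["products"])
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return FoodDatabase.from_frame(frame)


def write_food_database(db: FoodDatabase, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        db.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        payload = {"products": db.to_frame().to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


@dataclass(frozen=True)
class NutrientReference:
    """Daily recommended values (RV, qualifying) and maxima (MV, limiting)."""

    rv: Mapping[str, float]
    mv: Mapping[str, float]
    energy_target: float = 2228.0  # kcal/day

    def __post_init__(self):
        missing = set(QUALIFYING_NUTRIENTS) - set(self.rv)
        if missing:
            raise SchemaError(f"rv: missing nutrient(s) {sorted(missing)}")
        missing = set(LIMITING_NUTRIENTS) - set(self.mv)
        if missing:
            raise SchemaError(f"mv: missing nutrient(s) {sorted(missing)}")
        for code, value in (*self.rv.items(), *self.mv.items()):
            if value <= 0:
                raise ValidationError(f"reference for {code!r} must be > 0, got {value}")
        if self.energy_target <= 0:
            raise ValidationError("energy_target must be > 0")

    @property
    def rv_vector(self) -> np.ndarray:
        return np.array([self.rv[n] for n in QUALIFYING_NUTRIENTS])

    @property
    def mv_vector(self) -> np.ndarray:
        return np.array([self.mv[n] for n in LIMITING_NUTRIENTS])

    @classmethod
    def from_mapping(cls, data: Mapping) -> "NutrientReference":
        for key in ("rv", "mv", "energy_target_kcal"):
            if key not in data:
                raise SchemaError(f"nutrient reference config: missing key {key!r}")
        return cls(
            rv=dict(data["rv"]),
            mv=dict(data["mv"]),
            energy_target=float(data["energy_target_kcal"]),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "NutrientReference":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
        return cls.from_mapping(data)


def default_reference() -> NutrientReference:
    """Packaged EFSA-style adult reference values (see data/nutrient_references.yaml)."""
    text = (
        importlib.resources.files("dietopt.data")
        .joinpath("nutrient_references.yaml")
        .read_text(encoding="utf-8")
    )
    return NutrientReference.from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class Diet:
    """Named vector of daily intake quantities (g/day) over a food database."""

    name: str
    quantities: Mapping[str, float]

    def __post_init__(self):
        for pid, q in self.quantities.items():
            if not np.isfinite(q) or q < 0:
                raise ValidationError(f"diet {self.name!r}: quantity of {pid!r} is {q}")

    def vector(self, db: FoodDatabase) -> np.ndarray:
        """Quantities as an array aligned with ``db`` product order."""
        q = np.zeros(len(db))
        for pid, grams in self.quantities.items():
            q[db.index(pid)] = grams
        return q

    @classmethod
    def from_vector(cls, name: str, q: np.ndarray, db: FoodDatabase) -> "Diet":
        return cls(name, {pid: float(v) for pid, v in zip(db.ids, q)})

    def scaled(self, factor: float, name: str | None = None) -> "Diet":
        return Diet(name or self.name, {k: v * factor for k, v in self.quantities.items()})


@dataclass(frozen=True)
class NutrientIntake:
    """Daily nutrient amounts (NRI_i qualifying, LNI_i limiting) and energy EN."""

    intake: Mapping[str, float]
    energy: float  # kcal/day

    @property
    def qualifying(self) -> np.ndarray:
        return np.array([self.intake[n] for n in QUALIFYING_NUTRIENTS])

    @property
    def limiting(self) -> np.ndarray:
        return np.array([self.intake[n] for n in LIMITING_NUTRIENTS])


def compute_intake(diet: Diet, db: FoodDatabase) -> NutrientIntake:
    """Aggregate a diet's daily energy and nutrient amounts (linear in Q_i)."""
    q = diet.vector(db)
    amounts = db.nutrients @ q
    return NutrientIntake(
        intake={n: float(a) for n, a in zip(NUTRIENT_ORDER, amounts)},
        energy=float(db.energy @ q),
    )


# ---------------------------------------------------------------------------
# Synthetic data generation
# ---------------------------------------------------------------------------

def load_synthetic_ranges() -> dict:
    """Packaged category-conditioned sampling ranges (versioned YAML)."""
    text = (
        importlib.resources.files("dietopt.data")
        .joinpath("synthetic_ranges.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


_RANGE_FIELDS = (
    ["energy_kcal_per_g"] + list(NUTRIENT_ORDER) + ["price_eur_per_kg", "ghg_kgco2e_per_kg"]
)


def generate_synthetic_database(
    n_products: int, seed: int, ranges: dict | None = None
) -> FoodDatabase:
    """Sample a deterministic synthetic food database.

    Products cycle through the configured categories so that any reasonably
    sized database spans the full basket; each field is drawn uniformly from
    its category range.
    """
    if n_products < 3:
        raise ValueError(f"n_products must be >= 3, got {n_products}")
    config = ranges if ranges is not None else load_synthetic_ranges()
    categories = list(config["categories"])
    rng = np.random.default_rng(seed)
    products = []
    counters: dict[str, int] = {}
    for j in range(n_products):
        cat = categories[j % len(categories)]
        counters[cat] = counters.get(cat, 0) + 1
        spec = config["categories"][cat]
        draw = {}
        for fld in _RANGE_FIELDS:
            lo, hi = spec[fld]
            draw[fld] = float(rng.uniform(lo, hi))
        products.append(
            FoodProduct(
                id=f"{cat}_{counters[cat]}",
                name=f"{cat.replace('_', ' ')} {counters[cat]}",
                category=cat,
                energy_density=draw["energy_kcal_per_g"],
                nutrient_density={n: draw[n] for n in NUTRIENT_ORDER},
                price=draw["price_eur_per_kg"],
                ghg_intensity=draw["ghg_kgco2e_per_kg"],
            )
        )
    return FoodDatabase(products)


#: Daily gram templates per category for the two emulated eating patterns.
BASELINE_TEMPLATES: dict[str, dict[str, float]] = {
    "omnivorous": {
        "red_meat": 100.0,
        "white_meat": 60.0,
        "processed_meat": 40.0,
        "fish": 70.0,
        "eggs": 30.0,
        "dairy": 350.0,
        "vegetables": 220.0,
        "fruits": 300.0,
        "legumes": 15.0,
        "grains": 200.0,
        "tubers": 80.0,
        "nuts": 5.0,
        "oils": 35.0,
        "sweets": 40.0,
        "beverages": 250.0,
    },
    "vegan": {
        "vegetables": 300.0,
        "fruits": 350.0,
        "legumes": 80.0,
        "grains": 280.0,
        "tubers": 120.0,
        "nuts": 40.0,
        "oils": 35.0,
        "plant_drinks": 300.0,
        "beverages": 100.0,
    },
}


def generate_baseline_diets(
    db: FoodDatabase, energy_target: float = 2228.0, seed: int = 0
) -> list[Diet]:
    """Build the emulated baseline eating patterns over ``db``.

    Category grams follow :data:`BASELINE_TEMPLATES` (an omnivorous-like and
    a vegan-like pattern), split across the category's products with a mild
    seeded Dirichlet jitter, then the whole diet is rescaled so its energy
    equals ``energy_target`` exactly.
    """
    if float(np.max(db.energy)) <= 0.0:
        raise InfeasibleError("database has no energy-yielding product")
    rng = np.random.default_rng(seed)
    by_category: dict[str, list[int]] = {}
    for k, p in enumerate(db.products):
        by_category.setdefault(p.category, []).append(k)

    diets = []
    for name, template in BASELINE_TEMPLATES.items():
        q = np.zeros(len(db))
        for cat, grams in template.items():
            members = by_category.get(cat, [])
            if not members:
                continue
            shares = rng.dirichlet(np.full(len(members), 5.0))
            for idx, share in zip(members, shares):
                q[idx] = grams * share
        energy = float(db.energy @ q)
        if energy <= 0.0:
            raise InfeasibleError(f"pattern {name!r} has zero energy on this database")
        q *= energy_target / energy
        diets.append(Diet.from_vector(name, q, db))
    return diets


# ---------------------------------------------------------------------------
# Diet table I/O (CSV: diet, product_id, grams_per_day; JSON mirror)
# ---------------------------------------------------------------------------

def read_diets(path: str | Path, format: str | None = None) -> list[Diet]:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.read_csv(path)
        missing = [c for c in ("diet", "product_id", "grams_per_day") if c not in frame.columns]
        if missing:
            raise SchemaError(f"diet table is missing column(s) {missing}")
        if frame.empty:
            raise ValidationError(f"diet table {path} contains no rows")
        diets = []
        for name, group in frame.groupby("diet", sort=False):
            diets.append(
                Diet(str(name), dict(zip(group["product_id"].astype(str), group["grams_per_day"])))
            )
        return diets
    if fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if "diets" not in data:
            raise SchemaError("diet JSON is missing key 'diets'")
        return [Diet(d["name"], dict(d["quantities"])) for d in data["diets"]]
    raise ValueError(f"unsupported format {fmt!r}")


def write_diets(diets: Iterable[Diet], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    diets = list(diets)
    if fmt == "csv":
        rows = [
            {"diet": d.name, "product_id": pid, "grams_per_day": grams}
            for d in diets
            for pid, grams in d.quantities.items()
        ]
        pd.DataFrame(rows, columns=["diet", "product_id", "grams_per_day"]).to_csv(
            path, index=False
        )
    elif fmt == "json":
        payload = {
            "diets": [{"name": d.name, "quantities": dict(d.quantities)} for d in diets]
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unsupported format {fmt!r}")
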