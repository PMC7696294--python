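import numpy as np
import pytest

from dietopt import (
    Diet,
    FoodDatabase,
    FoodProduct,
    NutrientReference,
    NUTRIENT_ORDER,
    baseline_context,
    default_reference,
    generate_baseline_diets,
    generate_synthetic_database,
)


def make_product(pid: str, category: str = "misc", energy: float = 1.0,
                 price: float = 1.0, ghg: float = 1.0, **densities) -> FoodProduct:
    """Product with zero densities except the ones given (per-gram units)."""
    nd = {n: 0.0 for n in NUTRIENT_ORDER}
    nd.update(densities)
    return FoodProduct(
        id=pid, name=pid, category=category,
        energy_density=energy, nutrient_density=nd, price=price, ghg_intensity=ghg,
    )


@pytest.fixture(scope="session")
def ref() -> NutrientReference:
    return default_reference()


@pytest.fixture(scope="session")
def db63() -> FoodDatabase:
    return generate_synthetic_database(63, seed=1)


@pytest.fixture(scope="session")
def baselines(db63, ref):
    return generate_baseline_diets(db63, ref.energy_target, seed=1)


@pytest.fixture(scope="session")
def ctx63(baselines, db63, ref):
    return baseline_context(baselines, db63, ref)


@pytest.fixture
def toy_db() -> FoodDatabase:
    """Three hand-built products used by the summation oracles."""
    return FoodDatabase(
        [
            make_product("a", energy=2.0, price=4.0, ghg=2.0,
                         protein=0.2, calcium=1.2, saturated_fat=0.05),
            make_product("b", energy=0.5, price=1.5, ghg=0.5,
                         fiber=0.03, potassium=3.0, sodium=0.1),
            make_product("c", energy=9.0, price=6.0, ghg=4.0,
                         vitamin_e=0.4, saturated_fat=0.12),
        ]
    )


@pytest.fixture
def toy_diet() -> Diet:
    return Diet("toy", {"a": 150.0, "b": 400.0, "c": 30.0})


def intake_from_ratios(ref: NutrientReference, qualifying, limiting):
    """NutrientIntake whose relative intakes equal the given ratios."""
    from dietopt import NutrientIntake, QUALIFYING_NUTRIENTS, LIMITING_NUTRIENTS

    qualifying = np.broadcast_to(np.asarray(qualifying, dtype=float), (9,))
    limiting = np.broadcast_to(np.asarray(limiting, dtype=float), (3,))
    intake = {n: r * ref.rv[n] for n, r in zip(QUALIFYING_NUTRIENTS, qualifying)}
    intake.update({n: r * ref.mv[n] for n, r in zip(LIMITING_NUTRIENTS, limiting)})
    return NutrientIntake(intake=intake, energy=ref.energy_target)
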