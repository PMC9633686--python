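import numpy as np
import pandas as pd
import pytest

from foplabel.foods import FoodItem, FrequencyMapping
from foplabel.nutriscore import PointTable
from foplabel.simulate import CohortSimulator, GeneratorConfig
from foplabel.warning import LabelThresholds


@pytest.fixture(scope="session")
def mapping():
    return FrequencyMapping.default()


@pytest.fixture(scope="session")
def thresholds():
    return LabelThresholds.default()


@pytest.fixture(scope="session")
def point_table():
    return PointTable.default()


def make_food(**kw):
    base = dict(
        item_id="x1", name="test food", group="misc", state="solid",
        packaged_eligible=True, portion_g=50.0, energy_kcal=100.0,
        total_sugars_g=5.0, sat_fat_g=1.0, protein_g=5.0, fibre_g=1.0,
        sodium_mg=100.0, fvnl_pct=0.0,
    )
    base.update(kw)
    return FoodItem(**base)


@pytest.fixture
def food_factory():
    return make_food


@pytest.fixture(scope="session")
def small_bundle():
    """Small simulated cohort shared by pipeline tests (n=3000)."""
    return CohortSimulator(GeneratorConfig(n=3000, seed=42)).run()


@pytest.fixture(scope="session")
def big_bundle():
    """Full-size cohort for distribution-level checks (n=20000)."""
    return CohortSimulator(GeneratorConfig(n=20_000, seed=2024)).run()


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same draws regardless of
    # which tests ran before it
    return np.random.default_rng(12345)
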