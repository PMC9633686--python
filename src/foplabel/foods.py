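"""Food-composition data model and FFQ intake computation.

A food-frequency questionnaire (FFQ) asks participants how often, on a fixed
category scale, they consume each of a list of food items.  Each item is
backed by a per-100 g/ml nutrient profile from a food-composition table.
Daily intake of an item is ``servings/day x portion grams``, and daily
nutrient totals are the intake-weighted sums of the per-100 g/ml values.

Liquids are carried in grams throughout, with density fixed at exactly
1 g/ml, so a single intake unit serves both physical states.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, JoinError, SchemaError, StateError, ValidationError

logger = logging.getLogger(__name__)

STATES = ("solid", "liquid")

#: per-100 g/ml nutrient columns carried on every food item
NUTRIENT_FIELDS = (
    "energy_kcal",
    "energy_kj",
    "total_sugars_g",
    "added_sugars_g",
    "sat_fat_g",
    "protein_g",
    "fibre_g",
    "sodium_mg",
    "alcohol_g",
)

KCAL_TO_KJ = 4.184


@dataclass
class FoodItem:
    """One FFQ item with its per-100 g/ml nutrient profile.

    ``packaged_eligible`` marks pre-packaged processed/ultra-processed
    products and added fats — the only items that can carry "High in"
    warning labels.  ``is_dairy`` switches the sugar-label comparison to
    added sugars (lactose is not counted against dairy products).
    """

    item_id: str
    name: str
    group: str
    state: str
    packaged_eligible: bool
    portion_g: float
    energy_kcal: float
    total_sugars_g: float
    sat_fat_g: float
    protein_g: float
    fibre_g: float
    sodium_mg: float
    fvnl_pct: float = 0.0
    added_sugars_g: float | None = None
    is_dairy: bool = False
    density_g_per_ml: float = 1.0
    energy_kj: float | None = None
    alcohol_g: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_kj is None:
            self.energy_kj = self.energy_kcal * KCAL_TO_KJ
        if self.added_sugars_g is None:
            if self.is_dairy:
                raise ValidationError(
                    f"item {self.item_id!r}: added_sugars_g is required for dairy items"
                )
            # for non-dairy items all sugars are treated as added by default
            self.added_sugars_g = self.total_sugars_g
        self.validate()

    def validate(self) -> None:
        if self.state not in STATES:
            raise ValidationError(f"item {self.item_id!r}: unknown state {self.state!r}")
        for f in NUTRIENT_FIELDS:
            v = getattr(self, f)
            if v < 0:
                raise ValidationError(f"item {self.item_id!r}: {f} = {v} is negative")
        if self.added_sugars_g > self.total_sugars_g + 1e-9:
            raise ValidationError(
                f"item {self.item_id!r}: added_sugars_g ({self.added_sugars_g}) "
                f"exceeds total_sugars_g ({self.total_sugars_g})"
            )
        if not 0 <= self.fvnl_pct <= 100:
            raise ValidationError(f"item {self.item_id!r}: fvnl_pct outside [0, 100]")
        if self.portion_g <= 0:
            raise ValidationError(f"item {self.item_id!r}: portion_g must be positive")
        if self.state == "liquid" and self.density_g_per_ml != 1.0:
            raise ValidationError(
                f"item {self.item_id!r}: liquid items carry density 1 g/ml exactly, "
                f"got {self.density_g_per_ml}"
            )


@dataclass(frozen=True)
class FrequencyMapping:
    """Ordered FFQ frequency categories with servings-per-day multipliers."""

    categories: tuple[str, ...]
    servings_per_day: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != 9 or len(self.servings_per_day) != 9:
            raise ConfigError("frequency mapping must define exactly 9 categories")
        mult = np.asarray(self.servings_per_day)
        if mult[0] != 0.0:
            raise ConfigError("first frequency category must map to 0 servings/day")
        if not np.all(np.diff(mult) > 0):
            raise ConfigError("servings-per-day multipliers must be strictly increasing")

    @classmethod
    def default(cls) -> "FrequencyMapping":
        cfg = load_default_config("frequency_mapping")
        return cls(tuple(cfg["categories"]), tuple(cfg["servings_per_day"]))

    def as_series(self) -> pd.Series:
        return pd.Series(self.servings_per_day, index=list(self.categories))


@dataclass
class IntakeRecord:
    """Per-participant daily intakes (g/day) and daily nutrient totals."""

    participant_id: str
    intakes_g: pd.Series  # indexed by item_id
    totals: dict[str, float] = field(default_factory=dict)


def load_default_config(name: str) -> dict:
    """Load one of the packaged JSON configs (``configs/<name>.json``)."""
    ref = resources.files("foplabel") / "configs" / f"{name}.json"
    return json.loads(ref.read_text())


def frequency_to_daily(category: str, mapping: FrequencyMapping) -> float:
    """Servings/day for one frequency category label."""
    try:
        idx = mapping.categories.index(category)
    except ValueError:
        raise KeyError(
            f"unknown frequency category {category!r}; known: {mapping.categories}"
        ) from None
    return mapping.servings_per_day[idx]


# ---------------------------------------------------------------------------
# composition-table I/O


DEFAULT_SCHEMA: dict[str, str] = {f.name: f.name for f in fields(FoodItem)}

_BOOL_FIELDS = ("packaged_eligible", "is_dairy")
_REQUIRED = (
    "item_id", "name", "group", "state", "packaged_eligible", "portion_g",
    "energy_kcal", "total_sugars_g", "sat_fat_g", "protein_g", "fibre_g",
    "sodium_mg",
)


def read_composition_table(
    path, schema_config: Mapping[str, str] | None = None
) -> list[FoodItem]:
    """Read a food-composition CSV into validated :class:`FoodItem` records.

    ``schema_config`` maps FoodItem field names to CSV column names; fields
    absent from the map (or from the file, for optional fields) fall back to
    FoodItem defaults.  Invariant violations are rejected with the offending
    row index and field.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema_config:
        colmap.update(schema_config)
    df = pd.read_csv(path)
    missing = [colmap[f] for f in _REQUIRED if colmap[f] not in df.columns]
    if missing:
        raise SchemaError(f"composition table missing required columns: {missing}")
    foods: list[FoodItem] = []
    for i, row in df.iterrows():
        kwargs = {}
        for f in fields(FoodItem):
            col = colmap.get(f.name, f.name)
            if col in df.columns and not pd.isna(row[col]):
                v = row[col]
                if f.name in _BOOL_FIELDS:
                    v = _as_bool(v)
                kwargs[f.name] = v
        try:
            foods.append(FoodItem(**kwargs))
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
    logger.info("read %d food items from %s", len(foods), path)
    return foods


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "y")
    return bool(v)


def read_ffq_responses(path, layout: str = "wide") -> pd.DataFrame:
    """Read FFQ responses as a wide table (participants x items).

    ``layout="wide"`` expects one column per item with the participant id
    in the first column; ``"long"`` expects columns participant_id,
    item_id, category and pivots them.
    """
    if layout == "wide":
        return pd.read_csv(path, index_col=0, dtype=str)
    if layout == "long":
        df = pd.read_csv(path, dtype=str)
        needed = {"participant_id", "item_id", "category"}
        if not needed <= set(df.columns):
            raise SchemaError(f"long FFQ layout needs columns {sorted(needed)}")
        return df.pivot(index="participant_id", columns="item_id",
                        values="category")
    raise SchemaError(f"unknown FFQ layout {layout!r}")


def foods_to_frame(foods: Iterable[FoodItem]) -> pd.DataFrame:
    """Composition table as a DataFrame indexed by ``item_id``."""
    df = pd.DataFrame([vars(f) for f in foods]).set_index("item_id")
    return df


def write_composition_table(foods: Iterable[FoodItem], path) -> None:
    foods_to_frame(foods).reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# aggregation and intake computation


def aggregate_constituents(members: Sequence[FoodItem]) -> FoodItem:
    """Collapse constituent foods into one FFQ item by unweighted nutrient means.

    Mirrors how composite FFQ items (e.g. "sausages" standing for several
    cold cuts) are profiled: each nutrient of the result is the arithmetic
    mean of the members' values; eligibility is inherited if any member is
    eligible.  Members must share a physical state.
    """
    if not members:
        raise ValidationError("aggregate_constituents requires at least one member")
    states = {m.state for m in members}
    if len(states) > 1:
        raise StateError(f"cannot aggregate mixed solid/liquid members: {sorted(states)}")
    first = members[0]
    if len(members) == 1:
        return replace(first)
    num_fields = NUTRIENT_FIELDS + ("portion_g", "fvnl_pct")
    means = {f: float(np.mean([getattr(m, f) for m in members])) for f in num_fields}
    return FoodItem(
        item_id=first.item_id,
        name=" / ".join(m.name for m in members),
        group=first.group,
        state=first.state,
        packaged_eligible=any(m.packaged_eligible for m in members),
        is_dairy=any(m.is_dairy for m in members),
        **means,
    )


def responses_to_servings(
    responses: pd.DataFrame, mapping: FrequencyMapping
) -> pd.DataFrame:
    """Map a wide FFQ response table (category labels) to servings/day."""
    cats = pd.Categorical(responses.to_numpy().ravel(),
                          categories=list(mapping.categories))
    codes = cats.codes
    if (codes < 0).any():
        bad = sorted(set(np.asarray(responses.to_numpy().ravel())[codes < 0]))[:5]
        raise KeyError(f"unknown frequency categories {bad}")
    mult = np.asarray(mapping.servings_per_day)[codes].reshape(responses.shape)
    return pd.DataFrame(mult, index=responses.index, columns=responses.columns)


def compute_intake_frame(
    responses: pd.DataFrame,
    foods: Sequence[FoodItem] | pd.DataFrame,
    mapping: FrequencyMapping | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised intake computation for a whole cohort.

    Parameters
    ----------
    responses
        Wide table indexed by participant_id with one column per item_id
        holding frequency-category labels.
    foods
        The composition table (FoodItem list or frame from
        :func:`foods_to_frame`).
    mapping
        Frequency mapping; package default when omitted.

    Returns
    -------
    (intake_df, totals_df)
        ``intake_df`` — grams/day per participant x item;
        ``totals_df`` — daily nutrient totals (one column per nutrient
        field, plus ``servings_<group>`` per food group).
    """
    if mapping is None:
        mapping = FrequencyMapping.default()
    fdf = foods if isinstance(foods, pd.DataFrame) else foods_to_frame(foods)
    orphans = [c for c in responses.columns if c not in fdf.index]
    if orphans:
        raise JoinError(f"FFQ items missing from composition table: {orphans}")
    fdf = fdf.loc[list(responses.columns)]
    servings = responses_to_servings(responses, mapping)
    intake = servings * fdf["portion_g"].to_numpy()[None, :]

    per100 = fdf[list(NUTRIENT_FIELDS)].to_numpy()
    totals = pd.DataFrame(
        intake.to_numpy() @ (per100 / 100.0),
        index=responses.index,
        columns=list(NUTRIENT_FIELDS),
    )
    for grp, cols in fdf.groupby("group").groups.items():
        totals[f"servings_{grp}"] = servings[list(cols)].sum(axis=1)
        totals[f"grams_{grp}"] = intake[list(cols)].sum(axis=1)
    return intake, totals


def compute_intakes(
    responses: pd.DataFrame,
    foods: Sequence[FoodItem] | pd.DataFrame,
    mapping: FrequencyMapping | None = None,
) -> list[IntakeRecord]:
    """Record-oriented wrapper around :func:`compute_intake_frame`."""
    intake, totals = compute_intake_frame(responses, foods, mapping)
    nutrient_totals = totals[list(NUTRIENT_FIELDS)]
    return [
        IntakeRecord(str(pid), intake.loc[pid], nutrient_totals.loc[pid].to_dict())
        for pid in responses.index
    ]
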