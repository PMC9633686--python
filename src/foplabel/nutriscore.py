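"""FSAm-NPS (Nutri-Score) food and individual scoring, plus the 0-9
Mediterranean-diet score used as a covariate.

The FSAm-NPS allocates 0-10 "negative" points per 100 g/ml for each of
energy (kJ), sugars (g), saturated fat (g) and sodium (mg), and 0-5
"positive" points for fibre (g), protein (g) and the percentage of fruit,
vegetables, legumes, nuts and rapeseed/walnut/olive oils (FVNL).  The
food-level score is negative minus positive points, ranging from -15
(healthiest) to +40 (least healthy).  The individual-level score is the
energy-weighted mean of the food-level scores over everything consumed.

The official algorithm withholds protein points when the negative subtotal
reaches 11 unless the FVNL component is at its maximum; this exception rule
is carried as a flag (default off: plain subtraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FopLabelError
from .foods import KCAL_TO_KJ, FoodItem, foods_to_frame, load_default_config

NEGATIVE_COMPONENTS = ("energy_kj", "sugars_g", "sat_fat_g", "sodium_mg")
POSITIVE_COMPONENTS = ("fibre_g", "protein_g", "fvnl_pct")

_FOOD_FIELD = {
    "energy_kj": "energy_kj",
    "sugars_g": "total_sugars_g",
    "sat_fat_g": "sat_fat_g",
    "sodium_mg": "sodium_mg",
    "fibre_g": "fibre_g",
    "protein_g": "protein_g",
    "fvnl_pct": "fvnl_pct",
}

#: negative subtotal at which the protein exception rule kicks in
EXCEPTION_CAP = 11


@dataclass(frozen=True)
class PointTable:
    """Cutoff lists for each scoring component.

    Each negative component maps to an ascending cutoff list awarding
    up to 10 points; each positive component to ``{"cutoffs": [...],
    "points": [...]}`` awarding up to 5 (``points`` optional; defaults to
    1, 2, 3, ... per cutoff crossed, as for the uniform lists).
    """

    negative: Mapping[str, Sequence[float]]
    positive: Mapping[str, Mapping]
    exception_rule: bool = False
    version: str = "custom"

    def __post_init__(self) -> None:
        for comp in NEGATIVE_COMPONENTS:
            _check_cutoffs(comp, self.negative.get(comp))
        for comp in POSITIVE_COMPONENTS:
            spec = self.positive.get(comp)
            if spec is None:
                raise ConfigError(f"point table missing positive component {comp!r}")
            _check_cutoffs(comp, spec.get("cutoffs"))
            pts = spec.get("points")
            if pts is not None and len(pts) != len(spec["cutoffs"]):
                raise ConfigError(f"{comp}: points list length mismatch")

    @classmethod
    def default(cls, exception_rule: bool = False) -> "PointTable":
        cfg = load_default_config("fsam_points")
        return cls(
            negative=cfg["negative"],
            positive=cfg["positive"],
            exception_rule=cfg.get("exception_rule", exception_rule) or exception_rule,
            version=cfg.get("version", "custom"),
        )

    def max_negative(self) -> int:
        return sum(len(self.negative[c]) for c in NEGATIVE_COMPONENTS)

    def max_positive(self) -> int:
        total = 0
        for c in POSITIVE_COMPONENTS:
            spec = self.positive[c]
            pts = spec.get("points")
            total += max(pts) if pts else len(spec["cutoffs"])
        return total


def _check_cutoffs(comp: str, cutoffs) -> None:
    if cutoffs is None:
        raise ConfigError(f"point table missing component {comp!r}")
    arr = np.asarray(cutoffs, dtype=float)
    if arr.ndim != 1 or len(arr) == 0 or not np.all(np.diff(arr) > 0):
        raise ConfigError(f"{comp}: cutoff list must be non-empty and strictly increasing")


@dataclass
class FsamScore:
    """Food-level FSAm-NPS decomposition: total = N - P."""

    item_id: str
    negative_points: int
    positive_points: int
    total: int


def component_points(
    value: float, cutoffs: Sequence[float], points: Sequence[int] | None = None
) -> int:
    """Points for one component: count of cutoffs strictly exceeded.

    With a ``points`` map, the award for crossing the k-th cutoff is
    ``points[k-1]`` (used for the non-uniform FVNL scale 1/2/5).
    """
    _check_cutoffs("component", cutoffs)
    crossed = int(np.searchsorted(np.asarray(cutoffs, dtype=float), value, side="left"))
    # value exactly at a cutoff does not cross it ("more than" convention)
    if crossed == 0:
        return 0
    if points is not None:
        return int(points[crossed - 1])
    return crossed


def food_fsam_score(food: FoodItem, table: PointTable | None = None) -> FsamScore:
    """Score one food: N = sum of negative points, P = sum of positive
    points (protein withheld under the exception rule), total = N - P."""
    if table is None:
        table = PointTable.default()
    n = 0
    for comp in NEGATIVE_COMPONENTS:
        n += component_points(getattr(food, _FOOD_FIELD[comp]), table.negative[comp])
    parts = {}
    for comp in POSITIVE_COMPONENTS:
        spec = table.positive[comp]
        parts[comp] = component_points(
            getattr(food, _FOOD_FIELD[comp]), spec["cutoffs"], spec.get("points")
        )
    p = sum(parts.values())
    if table.exception_rule and n >= EXCEPTION_CAP:
        fvnl_max = max(
            table.positive["fvnl_pct"].get(
                "points", range(1, len(table.positive["fvnl_pct"]["cutoffs"]) + 1)
            )
        )
        if parts["fvnl_pct"] < fvnl_max:
            p -= parts["protein_g"]
    return FsamScore(food.item_id, n, p, n - p)


def food_scores_frame(
    foods: Sequence[FoodItem] | pd.DataFrame, table: PointTable | None = None
) -> pd.DataFrame:
    """Per-item FSAm-NPS scores (columns negative, positive, total)."""
    if isinstance(foods, pd.DataFrame):
        from .foods import FoodItem as _FI

        foods = [
            _FI(item_id=str(i), **{k: v for k, v in row.items() if k in _FI.__dataclass_fields__})
            for i, row in foods.iterrows()
        ]
    rows = [food_fsam_score(f, table) for f in foods]
    return pd.DataFrame(
        {
            "negative": [r.negative_points for r in rows],
            "positive": [r.positive_points for r in rows],
            "total": [r.total for r in rows],
        },
        index=pd.Index([r.item_id for r in rows], name="item_id"),
    )


def individual_fsam_score(
    intakes: pd.DataFrame | pd.Series,
    scores: pd.DataFrame | pd.Series,
    foods: Sequence[FoodItem] | pd.DataFrame,
) -> pd.Series | float:
    """Energy-weighted individual FSAm-NPS score.

    score = sum_i s_i * E_i / sum_i E_i with E_i = I_i * kcal_i / 100.
    """
    fdf = foods if isinstance(foods, pd.DataFrame) else foods_to_frame(foods)
    s = scores["total"] if isinstance(scores, pd.DataFrame) else scores
    single = isinstance(intakes, pd.Series)
    frame = intakes.to_frame().T if single else intakes
    kcal = fdf.loc[list(frame.columns), "energy_kcal"].to_numpy() / 100.0
    energy = frame.to_numpy() * kcal[None, :]
    tot = energy.sum(axis=1)
    if np.any(tot <= 0):
        raise FopLabelError("individual FSAm-NPS score undefined at zero total energy")
    vals = (energy @ s.loc[list(frame.columns)].to_numpy()) / tot
    if single:
        return float(vals[0])
    return pd.Series(vals, index=frame.index, name="fsam_score")


# ---------------------------------------------------------------------------
# Mediterranean-diet score (0-9)

#: component -> +1 when at/above (beneficial) or below (detrimental) the
#: sex-specific median; alcohol scores +1 inside a moderate window (g/day)
MEDDIET_BENEFICIAL = ("vegetables", "fruits_nuts", "legumes", "cereals", "fish", "fat_ratio")
MEDDIET_DETRIMENTAL = ("meat", "dairy")
DEFAULT_ALCOHOL_WINDOW = {"male": (10.0, 50.0), "female": (5.0, 25.0)}


def meddiet_score(
    components: pd.DataFrame,
    sex: pd.Series | None = None,
    sex_specific_medians: Mapping[str, Mapping[str, float]] | None = None,
    alcohol_window: Mapping[str, tuple] | None = None,
) -> pd.Series:
    """0-9 Mediterranean-diet adherence score.

    ``components`` needs one column per component in
    :data:`MEDDIET_BENEFICIAL` + :data:`MEDDIET_DETRIMENTAL` plus
    ``alcohol_g``.  Medians are computed within sex unless supplied.
    """
    needed = (*MEDDIET_BENEFICIAL, *MEDDIET_DETRIMENTAL, "alcohol_g")
    missing = [c for c in needed if c not in components.columns]
    if missing:
        raise FopLabelError(f"MedDiet components missing: {missing}")
    if alcohol_window is None:
        alcohol_window = DEFAULT_ALCOHOL_WINDOW
    if sex is None:
        sex = pd.Series("all", index=components.index)
        if sex_specific_medians is None:
            med = components.median()
            sex_specific_medians = {"all": med.to_dict()}
        if "all" not in alcohol_window:
            alcohol_window = {"all": (5.0, 25.0)}
    elif sex_specific_medians is None:
        sex_specific_medians = {
            g: sub.median().to_dict() for g, sub in components.groupby(sex)
        }
    score = pd.Series(0, index=components.index, dtype=int)
    for g, sub in components.groupby(sex):
        med = sex_specific_medians[g]
        s = pd.Series(0, index=sub.index, dtype=int)
        for comp in MEDDIET_BENEFICIAL:
            s += (sub[comp] >= med[comp]).astype(int)
        for comp in MEDDIET_DETRIMENTAL:
            s += (sub[comp] < med[comp]).astype(int)
        lo, hi = alcohol_window[g] if g in alcohol_window else (5.0, 25.0)
        s += ((sub["alcohol_g"] >= lo) & (sub["alcohol_g"] <= hi)).astype(int)
        score.loc[sub.index] = s
    return score.rename("meddiet")
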