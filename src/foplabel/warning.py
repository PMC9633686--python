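"""Chilean "High in" warning labels and the daily warning-label score.

A pre-packaged product receives one black-octagon warning label for every
critical component — energy, sugars, saturated fat, sodium — whose content
per 100 g (solids) or 100 ml (liquids) reaches the regulatory cutoff, so a
product can carry 0–4 labels.  For dairy products only added sugars count
against the sugar cutoff (lactose is exempt).  Non-eligible foods (fresh,
unpackaged) never carry labels.

The individual-level daily score is

    score = sum_i  WS_i * I_i / 100

where ``WS_i`` is the label count of item *i* and ``I_i`` the participant's
daily intake of that item in grams (liquids at density 1 g/ml).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, JoinError
from .foods import FoodItem, foods_to_frame, load_default_config

LABELS = ("energy", "sugar", "sat_fat", "sodium")

# FoodItem column backing each label comparison (sugar handled separately)
_LABEL_NUTRIENT = {"energy": "energy_kcal", "sat_fat": "sat_fat_g", "sodium": "sodium_mg"}
_CUTOFF_KEY = {
    "energy": "energy_kcal",
    "sugar": "sugars_g",
    "sat_fat": "sat_fat_g",
    "sodium": "sodium_mg",
}


@dataclass(frozen=True)
class LabelThresholds:
    """Per-state regulatory cutoffs and the comparison rule.

    ``rule="inclusive"`` labels content at or above the cutoff;
    ``"strict"`` requires strictly greater.
    """

    solid: Mapping[str, float]
    liquid: Mapping[str, float]
    rule: str = "inclusive"
    version: str = "custom"

    def __post_init__(self) -> None:
        if self.rule not in ("inclusive", "strict"):
            raise ConfigError(f"unknown comparison rule {self.rule!r}")
        for state_name, cuts in (("solid", self.solid), ("liquid", self.liquid)):
            for key in _CUTOFF_KEY.values():
                if key not in cuts:
                    raise ConfigError(f"{state_name} thresholds missing {key!r}")
                if cuts[key] <= 0:
                    raise ConfigError(f"{state_name} cutoff {key} must be positive")

    @classmethod
    def default(cls) -> "LabelThresholds":
        cfg = load_default_config("warning_thresholds")
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "LabelThresholds":
        return cls(
            solid=dict(cfg["solid"]),
            liquid=dict(cfg["liquid"]),
            rule=cfg.get("rule", "inclusive"),
            version=cfg.get("version", "custom"),
        )

    def cutoff(self, state: str, label: str) -> float:
        table = self.solid if state == "solid" else self.liquid
        return float(table[_CUTOFF_KEY[label]])


@dataclass
class WarningAssignment:
    """Label set and count for one item; WS = |labels|, 0 for ineligible items."""

    item_id: str
    labels: frozenset
    ws: int

    def __post_init__(self) -> None:
        if self.ws != len(self.labels) or not 0 <= self.ws <= 4:
            raise ValueError(f"item {self.item_id!r}: inconsistent label count")


def _exceeds(value: float, cutoff: float, rule: str) -> bool:
    return value >= cutoff if rule == "inclusive" else value > cutoff


def assign_warning_labels(
    food: FoodItem,
    thresholds: LabelThresholds | None = None,
    exclude: str | None = None,
) -> WarningAssignment:
    """Assign "High in" labels to one food.

    ``exclude`` drops one label type from counting (leave-one-label-out
    sensitivity analyses).
    """
    if thresholds is None:
        thresholds = LabelThresholds.default()
    if not food.packaged_eligible:
        return WarningAssignment(food.item_id, frozenset(), 0)
    labels = set()
    for label in LABELS:
        if label == exclude:
            continue
        if label == "sugar":
            value = food.added_sugars_g if food.is_dairy else food.total_sugars_g
        else:
            value = getattr(food, _LABEL_NUTRIENT[label])
        if _exceeds(value, thresholds.cutoff(food.state, label), thresholds.rule):
            labels.add(label)
    return WarningAssignment(food.item_id, frozenset(labels), len(labels))


def assign_labels_frame(
    foods: Sequence[FoodItem] | pd.DataFrame,
    thresholds: LabelThresholds | None = None,
    exclude: str | None = None,
) -> pd.DataFrame:
    """Vectorised label assignment: one row per item with boolean label
    columns and the count ``ws``."""
    if thresholds is None:
        thresholds = LabelThresholds.default()
    fdf = foods if isinstance(foods, pd.DataFrame) else foods_to_frame(foods)
    eligible = fdf["packaged_eligible"].to_numpy(dtype=bool)
    liquid = (fdf["state"] == "liquid").to_numpy()
    sugar_value = np.where(
        fdf["is_dairy"].to_numpy(dtype=bool),
        fdf["added_sugars_g"].to_numpy(dtype=float),
        fdf["total_sugars_g"].to_numpy(dtype=float),
    )
    out = pd.DataFrame(index=fdf.index)
    for label in LABELS:
        if label == "sugar":
            value = sugar_value
        else:
            value = fdf[_LABEL_NUTRIENT[label]].to_numpy(dtype=float)
        cut = np.where(
            liquid, thresholds.cutoff("liquid", label), thresholds.cutoff("solid", label)
        )
        hit = value >= cut if thresholds.rule == "inclusive" else value > cut
        out[label] = hit & eligible & (label != exclude)
    out["ws"] = out[list(LABELS)].sum(axis=1).astype(int)
    return out


def participant_warning_score(
    intakes: pd.DataFrame | pd.Series,
    assignments: pd.DataFrame | Iterable[WarningAssignment],
) -> pd.Series | float:
    """Daily warning-label score, sum_i WS_i * I_i / 100.

    ``intakes`` is grams/day, either one participant (Series indexed by
    item_id) or a cohort (DataFrame, participants x items).
    """
    if isinstance(assignments, pd.DataFrame):
        ws = assignments["ws"]
    else:
        ws = pd.Series({a.item_id: a.ws for a in assignments})
    single = isinstance(intakes, pd.Series)
    frame = intakes.to_frame().T if single else intakes
    missing = [c for c in frame.columns if c not in ws.index]
    if missing:
        raise JoinError(f"no warning assignment for items: {missing}")
    score = frame.to_numpy() @ (ws.loc[list(frame.columns)].to_numpy() / 100.0)
    if single:
        return float(score[0])
    return pd.Series(score, index=frame.index, name="warning_score")


def export_assignments(assignments: pd.DataFrame, path) -> None:
    """Write item_id, labels, WS as CSV."""
    out = pd.DataFrame(index=assignments.index)
    out["labels"] = [
        "|".join(l for l in LABELS if assignments.loc[i, l]) for i in assignments.index
    ]
    out["ws"] = assignments["ws"]
    out.reset_index().to_csv(path, index=False)
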