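"""Synthetic FFQ cohort generator.

Emulates the structure of a large prospective cohort of university
graduates followed for mortality: a 136-item food-frequency questionnaire
backed by a synthetic food-composition table, baseline covariates, a
repeat FFQ after 10 years with a configurable score autocorrelation,
missing-at-random smoking pack-years, and cause-specific survival outcomes
generated from a piecewise-constant baseline hazard on the age scale with
injectable quartile log-hazards.

Every quantity the downstream pipeline consumes is produced here from a
single seeded generator, so the full analysis is testable end-to-end with
known truths and no external data.

Calibration is deterministic: eligible-item consumption rates are scaled
so a neutral participant's daily warning-label score equals the configured
median target, remaining rates are scaled toward the target mean energy,
the baseline-hazard scale is found by bisection against the target event
rate, and the latent-trait autocorrelation behind the 10-year FFQ is
solved from an internal replicate so the induced score correlation hits
its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FopLabelError
from .foods import FoodItem, FrequencyMapping, foods_to_frame
from .warning import LabelThresholds, assign_labels_frame, participant_warning_score

LN = np.log


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Quartile log-hazards are per cause (three values: Q2, Q3, Q4 vs Q1);
    the defaults inject the cause-specific multivariable effect profile the
    package's analyses are designed to recover, with null effects for
    other/unknown causes.
    """

    n: int = 20_000
    seed: int = 0
    n_items: int = 136
    eligible_fraction: float = 0.47
    #: per-cause (Q2, Q3, Q4) log hazard ratios vs Q1
    quartile_log_hr: Mapping[str, tuple] = field(default_factory=lambda: {
        "cancer": (LN(1.14), LN(1.50), LN(1.91)),
        "cvd": (LN(0.87), LN(0.77), LN(1.20)),
        "other": (0.0, 0.0, 0.0),
        "unknown": (0.0, 0.0, 0.0),
    })
    #: baseline share of deaths by cause
    cause_shares: Mapping[str, float] = field(default_factory=lambda: {
        "cancer": 0.518, "cvd": 0.193, "other": 0.261, "unknown": 0.028,
    })
    target_event_rate: float = 0.023
    loss_rate: float = 0.07
    rho_10y: float = 0.37
    packyears_missing_rate: float = 0.079
    target_median_score: float = 7.1
    target_mean_energy: float = 2500.0
    #: hazard log-linear covariate effects
    covariate_log_hr: Mapping[str, float] = field(default_factory=lambda: {
        "male": 0.45, "smoke_current": 0.80, "smoke_former": 0.25,
        "bmi_per_unit": 0.03,
    })
    gompertz_slope: float = 0.085      # log-hazard slope per year of age
    recruit_start: float = 1999.9
    recruit_end: float = 2017.2
    admin_end: float = 2019.9
    age_mean: float = 38.0
    age_sd: float = 12.4
    male_fraction: float = 0.39
    appetite_sd: float = 0.25          # SD of log appetite
    trait_loading: float = 0.35        # log-consumption loading of the
                                       # unhealthy-diet trait on flagged groups
    healthy_loading: float = -0.15
    item_noise_sd: float = 0.50        # item-level log noise

    def __post_init__(self) -> None:
        if self.n < 100:
            raise FopLabelError("generator needs n >= 100")
        for r in (self.eligible_fraction, self.target_event_rate, self.loss_rate,
                  self.packyears_missing_rate):
            if not 0 <= r <= 1:
                raise FopLabelError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# food-group blueprint
#
# count, state, eligible, dairy, fvnl%, portion g, base servings/day/item,
# trait loading class (+ unhealthy / - healthy / 0), per-100 g nutrient
# means: kcal, total sugars, added-sugar fraction, sat fat, protein, fibre,
# sodium mg, alcohol g

GROUPS: tuple[dict, ...] = (
    dict(name="vegetables", n=12, state="solid", elig=False, dairy=False, fvnl=95,
         portion=150, base=0.30, load="-", kcal=30, sug=4, addf=0.0, sat=0.1,
         pro=2.0, fib=3.0, na=20, alc=0),
    dict(name="fruits", n=12, state="solid", elig=False, dairy=False, fvnl=100,
         portion=150, base=0.20, load="-", kcal=55, sug=10, addf=0.0, sat=0.05,
         pro=0.7, fib=2.5, na=3, alc=0),
    dict(name="legumes", n=4, state="solid", elig=False, dairy=False, fvnl=100,
         portion=60, base=0.08, load="-", kcal=330, sug=3, addf=0.0, sat=0.3,
         pro=21, fib=15, na=15, alc=0),
    dict(name="nuts", n=3, state="solid", elig=False, dairy=False, fvnl=100,
         portion=30, base=0.10, load="-", kcal=600, sug=5, addf=0.0, sat=6,
         pro=20, fib=8, na=5, alc=0),
    dict(name="fresh_meat", n=8, state="solid", elig=False, dairy=False, fvnl=0,
         portion=125, base=0.18, load="0", kcal=180, sug=0.5, addf=0.0, sat=4,
         pro=21, fib=0, na=80, alc=0),
    dict(name="processed_meat", n=8, state="solid", elig=True, dairy=False, fvnl=0,
         portion=50, base=0.22, load="+", kcal=320, sug=1.5, addf=0.5, sat=11,
         pro=15, fib=0, na=1100, alc=0),
    dict(name="fish", n=8, state="solid", elig=False, dairy=False, fvnl=0,
         portion=125, base=0.12, load="0", kcal=120, sug=0.3, addf=0.0, sat=1.2,
         pro=20, fib=0, na=90, alc=0),
    dict(name="canned_fish", n=3, state="solid", elig=True, dairy=False, fvnl=0,
         portion=55, base=0.08, load="0", kcal=200, sug=0.5, addf=0.0, sat=2.5,
         pro=24, fib=0, na=600, alc=0),
    dict(name="eggs", n=2, state="solid", elig=False, dairy=False, fvnl=0,
         portion=60, base=0.35, load="0", kcal=150, sug=0.6, addf=0.0, sat=3.2,
         pro=12.5, fib=0, na=140, alc=0),
    dict(name="milk", n=4, state="liquid", elig=False, dairy=True, fvnl=0,
         portion=200, base=0.45, load="0", kcal=55, sug=4.8, addf=0.0, sat=1.9,
         pro=3.2, fib=0, na=45, alc=0),
    dict(name="sweet_dairy", n=4, state="solid", elig=True, dairy=True, fvnl=0,
         portion=125, base=0.25, load="+", kcal=105, sug=13, addf=0.7, sat=2.5,
         pro=3.8, fib=0, na=60, alc=0),
    dict(name="milkshake", n=2, state="liquid", elig=True, dairy=True, fvnl=0,
         portion=250, base=0.05, load="+", kcal=80, sug=11, addf=0.65, sat=2.2,
         pro=3.2, fib=0, na=55, alc=0),
    dict(name="cheese", n=4, state="solid", elig=True, dairy=True, fvnl=0,
         portion=40, base=0.30, load="0", kcal=350, sug=2, addf=0.0, sat=18,
         pro=24, fib=0, na=700, alc=0),
    dict(name="white_bread", n=2, state="solid", elig=True, dairy=False, fvnl=0,
         portion=40, base=0.80, load="+", kcal=260, sug=2, addf=0.3, sat=0.4,
         pro=8, fib=3, na=500, alc=0),
    dict(name="whole_bread", n=2, state="solid", elig=True, dairy=False, fvnl=0,
         portion=40, base=0.18, load="-", kcal=230, sug=2, addf=0.3, sat=0.5,
         pro=9, fib=7, na=420, alc=0),
    dict(name="breakfast_cereal", n=2, state="solid", elig=True, dairy=False,
         fvnl=0, portion=30, base=0.15, load="+", kcal=380, sug=22, addf=0.9,
         sat=1.5, pro=8, fib=5, na=350, alc=0),
    dict(name="rice_pasta", n=4, state="solid", elig=False, dairy=False, fvnl=0,
         portion=70, base=0.25, load="0", kcal=360, sug=1, addf=0.0, sat=0.3,
         pro=11, fib=3, na=5, alc=0),
    dict(name="olive_oil", n=2, state="solid", elig=False, dairy=False, fvnl=100,
         portion=10, base=1.20, load="-", kcal=884, sug=0, addf=0.0, sat=14,
         pro=0, fib=0, na=0, alc=0),
    dict(name="animal_fat", n=3, state="solid", elig=True, dairy=False, fvnl=0,
         portion=12, base=0.25, load="+", kcal=740, sug=0.6, addf=0.0, sat=50,
         pro=0.7, fib=0, na=550, alc=0),
    dict(name="margarine", n=1, state="solid", elig=True, dairy=False, fvnl=0,
         portion=12, base=0.15, load="+", kcal=720, sug=0.5, addf=0.0, sat=16,
         pro=0.2, fib=0, na=700, alc=0),
    dict(name="pastries", n=8, state="solid", elig=True, dairy=False, fvnl=0,
         portion=50, base=0.28, load="+", kcal=420, sug=25, addf=0.9, sat=8,
         pro=6, fib=2, na=300, alc=0),
    dict(name="salty_snacks", n=3, state="solid", elig=True, dairy=False, fvnl=0,
         portion=30, base=0.08, load="+", kcal=500, sug=3, addf=0.6, sat=6,
         pro=6, fib=3, na=800, alc=0),
    dict(name="candy", n=3, state="solid", elig=True, dairy=False, fvnl=0,
         portion=25, base=0.12, load="+", kcal=380, sug=60, addf=1.0, sat=2,
         pro=2, fib=0, na=50, alc=0),
    dict(name="ice_cream", n=1, state="solid", elig=True, dairy=True, fvnl=0,
         portion=60, base=0.08, load="+", kcal=210, sug=22, addf=0.9, sat=7,
         pro=3.5, fib=0, na=70, alc=0),
    dict(name="ready_meals", n=5, state="solid", elig=True, dairy=False, fvnl=0,
         portion=200, base=0.10, load="+", kcal=190, sug=3, addf=0.5, sat=3.5,
         pro=8, fib=1.5, na=550, alc=0),
    dict(name="ssb", n=4, state="liquid", elig=True, dairy=False, fvnl=0,
         portion=250, base=0.12, load="+", kcal=42, sug=10.5, addf=1.0, sat=0,
         pro=0, fib=0, na=10, alc=0),
    dict(name="bottled_juice", n=3, state="liquid", elig=True, dairy=False,
         fvnl=45, portion=200, base=0.10, load="+", kcal=45, sug=10, addf=0.8,
         sat=0, pro=0.3, fib=0.2, na=5, alc=0),
    dict(name="diet_soda", n=2, state="liquid", elig=True, dairy=False, fvnl=0,
         portion=250, base=0.08, load="+", kcal=1, sug=0, addf=0.0, sat=0,
         pro=0, fib=0, na=15, alc=0),
    dict(name="beer", n=2, state="liquid", elig=False, dairy=False, fvnl=0,
         portion=200, base=0.15, load="+", kcal=43, sug=0.2, addf=0.0, sat=0,
         pro=0.4, fib=0, na=5, alc=4),
    dict(name="wine", n=2, state="liquid", elig=False, dairy=False, fvnl=0,
         portion=100, base=0.25, load="0", kcal=70, sug=0.6, addf=0.0, sat=0,
         pro=0.1, fib=0, na=4, alc=10),
    dict(name="spirits", n=1, state="liquid", elig=False, dairy=False, fvnl=0,
         portion=40, base=0.05, load="+", kcal=230, sug=0.1, addf=0.0, sat=0,
         pro=0, fib=0, na=1, alc=33),
    dict(name="coffee_tea", n=2, state="liquid", elig=False, dairy=False, fvnl=0,
         portion=150, base=1.00, load="0", kcal=2, sug=0.1, addf=0.0, sat=0,
         pro=0.1, fib=0, na=2, alc=0),
    dict(name="sauces", n=4, state="solid", elig=True, dairy=False, fvnl=0,
         portion=20, base=0.30, load="+", kcal=180, sug=6, addf=0.8, sat=2,
         pro=1.5, fib=0.5, na=900, alc=0),
    dict(name="misc_plain", n=6, state="solid", elig=False, dairy=False, fvnl=10,
         portion=150, base=0.25, load="0", kcal=80, sug=1.5, addf=0.0, sat=0.3,
         pro=2, fib=1.5, na=20, alc=0),
)

#: ultra-processed groups (servings/day of these feed the provided UPF column)
UPF_GROUPS = frozenset({
    "processed_meat", "milkshake", "breakfast_cereal", "pastries",
    "salty_snacks", "candy", "ice_cream", "ready_meals", "ssb",
    "bottled_juice", "diet_soda",
})

#: items whose eligibility may be toggled to hit the configured fraction
_SWING_OFF = ("whole_bread", "canned_fish", "sauces", "bottled_juice", "diet_soda")
_SWING_ON = ("nuts", "rice_pasta", "misc_plain", "coffee_tea")

_NUTRIENT_SD_LOG = 0.18


class CohortSimulator:
    """Seeded end-to-end generator; see module docstring.

    Operations can be called individually (composition table -> cohort ->
    follow-up FFQ -> outcomes -> missingness) or through :meth:`run`.
    """

    def __init__(self, config: GeneratorConfig | None = None, seed: int | None = None):
        self.config = config or GeneratorConfig()
        if seed is not None:
            self.config = replace(self.config, seed=seed)
        self.rng = np.random.default_rng(self.config.seed)
        self.mapping = FrequencyMapping.default()
        self.thresholds = LabelThresholds.default()
        self._latent: dict | None = None
        self._foods_df: pd.DataFrame | None = None

    # -- composition table -------------------------------------------------

    def generate_composition_table(self) -> list[FoodItem]:
        cfg = self.config
        rng = self.rng
        rows = []
        scale = cfg.n_items / sum(g["n"] for g in GROUPS)
        counts = {g["name"]: max(1, round(g["n"] * scale)) for g in GROUPS}
        # trim/pad the largest groups so counts sum exactly to n_items
        names = sorted(counts, key=counts.get, reverse=True)
        i = 0
        while sum(counts.values()) != cfg.n_items:
            counts[names[i % len(names)]] += 1 if sum(counts.values()) < cfg.n_items else -1
            i += 1
        k = 0
        for g in GROUPS:
            for j in range(counts[g["name"]]):
                noise = rng.normal(0.0, _NUTRIENT_SD_LOG, size=6)
                kcal = g["kcal"] * np.exp(noise[0]) if g["kcal"] else 0.0
                sug = g["sug"] * np.exp(noise[1]) if g["sug"] else 0.0
                sat = g["sat"] * np.exp(noise[2]) if g["sat"] else 0.0
                pro = g["pro"] * np.exp(noise[3]) if g["pro"] else 0.0
                fib = g["fib"] * np.exp(noise[4]) if g["fib"] else 0.0
                na = g["na"] * np.exp(noise[5]) if g["na"] else 0.0
                rows.append(dict(
                    item_id=f"i{k:03d}", name=f"{g['name']}_{j}", group=g["name"],
                    state=g["state"], packaged_eligible=bool(g["elig"]),
                    is_dairy=bool(g["dairy"]),
                    fvnl_pct=float(np.clip(g["fvnl"] + rng.normal(0, 2), 0, 100)),
                    portion_g=float(g["portion"]), energy_kcal=float(kcal),
                    total_sugars_g=float(sug),
                    added_sugars_g=float(min(sug, g["addf"] * sug)),
                    sat_fat_g=float(sat), protein_g=float(pro),
                    fibre_g=float(fib), sodium_mg=float(na),
                    alcohol_g=float(g["alc"]),
                ))
                k += 1
        df = pd.DataFrame(rows)
        self._adjust_eligibility(df)
        foods = [FoodItem(**r) for r in df.to_dict("records")]
        self._foods_df = foods_to_frame(foods)
        self._base_rates = self._calibrated_base_rates(df)
        return foods

    def _adjust_eligibility(self, df: pd.DataFrame) -> None:
        target = round(self.config.eligible_fraction * len(df))
        current = int(df["packaged_eligible"].sum())
        if current > target:
            pool = df.index[df["group"].isin(_SWING_OFF) & df["packaged_eligible"]]
            df.loc[pool[: current - target], "packaged_eligible"] = False
        elif current < target:
            pool = df.index[df["group"].isin(_SWING_ON) & ~df["packaged_eligible"]]
            df.loc[pool[: target - current], "packaged_eligible"] = True

    def _calibrated_base_rates(self, df: pd.DataFrame) -> pd.Series:
        """Deterministic two-stage calibration of per-item base servings/day."""
        cfg = self.config
        gmap = {g["name"]: g for g in GROUPS}
        base = df["group"].map(lambda n: gmap[n]["base"]).astype(float)
        base.index = df["item_id"]
        labels = assign_labels_frame(self._foods_df, self.thresholds)
        ws = labels["ws"].to_numpy(dtype=float)
        portion = self._foods_df["portion_g"].to_numpy(dtype=float)
        kcal = self._foods_df["energy_kcal"].to_numpy(dtype=float)
        elig = self._foods_df["packaged_eligible"].to_numpy(dtype=bool)
        score0 = float((base.to_numpy() * portion * ws)[elig].sum() / 100.0)
        # item-level log noise averages out across items, so the realised
        # per-participant score carries the log-normal mean factor
        f_item = float(np.exp(cfg.item_noise_sd ** 2 / 2.0))
        scale_e = cfg.target_median_score / (score0 * f_item)
        base[elig] *= scale_e
        e_elig = float((base.to_numpy() * portion * kcal)[elig].sum() / 100.0)
        e_inelig = float((base.to_numpy() * portion * kcal)[~elig].sum() / 100.0)
        # cohort mean additionally carries the appetite and (approximate)
        # trait log-normal factors
        f_mean = f_item * float(np.exp(cfg.appetite_sd ** 2 / 2.0)) * 1.04
        scale_i = max(0.1, (cfg.target_mean_energy / f_mean - e_elig) / e_inelig)
        base[~elig] *= scale_i
        return base

    # -- cohort ------------------------------------------------------------

    def _draw_responses(self, u: np.ndarray, log_a: np.ndarray) -> pd.DataFrame:
        """FFQ category draw given latent traits (u) and log appetite."""
        cfg = self.config
        fdf = self._foods_df
        gmap = {g["name"]: g for g in GROUPS}
        loading = fdf["group"].map(
            lambda n: {"+": cfg.trait_loading, "-": cfg.healthy_loading,
                       "0": 0.0}[gmap[n]["load"]]).to_numpy()
        base = self._base_rates.loc[fdf.index].to_numpy()
        eps = self.rng.normal(0.0, cfg.item_noise_sd, size=(len(u), len(base)))
        log_s = (np.log(base)[None, :] + log_a[:, None]
                 + u[:, None] * loading[None, :] + eps)
        mult = np.asarray(self.mapping.servings_per_day)
        inner = np.sqrt(mult[1:-1] * mult[2:])          # geometric midpoints
        edges = np.concatenate([[np.log(mult[1] / 2.0)], np.log(inner)])
        idx = np.searchsorted(edges, log_s, side="right")
        cats = np.asarray(self.mapping.categories)[idx]
        pids = [f"p{i:06d}" for i in range(len(u))]
        return pd.DataFrame(cats, index=pd.Index(pids, name="participant_id"),
                            columns=list(fdf.index))

    def generate_cohort(self, foods=None) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Baseline FFQ responses and covariate table."""
        if foods is None and self._foods_df is None:
            self.generate_composition_table()
        cfg = self.config
        rng = self.rng
        n = cfg.n
        u = rng.normal(0.0, 1.0, n)                 # unhealthy-diet trait
        log_a = rng.normal(0.0, cfg.appetite_sd, n)  # appetite
        responses = self._draw_responses(u, log_a)
        pids = responses.index

        def logistic(x):
            return 1.0 / (1.0 + np.exp(-x))

        male = rng.random(n) < logistic(np.log(cfg.male_fraction /
                                               (1 - cfg.male_fraction)) + 0.30 * u)
        age = np.clip(cfg.age_mean + cfg.age_sd * (-0.25 * u +
                      np.sqrt(1 - 0.0625) * rng.normal(size=n)), 20.0, 75.0)
        r = rng.random(n)
        p_never = 0.48 + 0.02 * u / 3.0
        p_current = 0.215 + 0.015 * u / 3.0
        smoking = np.where(r < p_never, "never",
                           np.where(r < p_never + p_current, "current", "former"))
        bmi = np.clip(rng.normal(23.5, 3.5, n) - 0.05 * u, 15.0, 45.0)
        mets = np.clip(rng.gamma(2.0, 11.0, n), 0.0, 150.0)
        married = rng.random(n) < logistic(0.10 + 0.012 * (age - 38) - 0.20 * u)
        education = np.clip(rng.normal(5.0, 1.5, n), 1.0, 10.0)
        snacking = rng.random(n) < logistic(-0.70 + 0.40 * u)
        special_diet = rng.random(n) < logistic(-2.40 - 0.45 * u)
        prev = {}
        for namep, b0, b_age, b_u in (
            ("prev_diabetes", -4.6, 0.05, -0.25), ("prev_cancer", -4.1, 0.05, -0.20),
            ("prev_htn", -2.8, 0.06, -0.15), ("prev_cvd", -4.5, 0.05, -0.20),
            ("prev_depression", -2.1, 0.00, -0.05),
            ("hypercholesterolemia", -2.0, 0.04, -0.15),
        ):
            prev[namep] = rng.random(n) < logistic(b0 + b_age * (age - 38) + b_u * u)
        famhx_cvd = rng.random(n) < 0.14
        famhx_cancer = rng.random(n) < 0.15
        intensity = np.exp(rng.normal(-0.6, 0.4, n))
        ever = smoking != "never"
        pack_years = np.where(
            ever, np.clip((age - 18.0), 0, None) * intensity *
            np.where(smoking == "former", 0.7, 1.0), 0.0)
        entry_year = cfg.recruit_start + (cfg.recruit_end - cfg.recruit_start) * \
            rng.beta(1.2, 1.6, n)

        cov = pd.DataFrame({
            "male": male.astype(int), "age": age, "entry_age": age,
            "smoking": smoking, "pack_years": pack_years,
            "bmi": bmi, "mets": mets, "married": married.astype(int),
            "education_years": education, "snacking": snacking.astype(int),
            "special_diet": special_diet.astype(int),
            "famhx_cvd": famhx_cvd.astype(int),
            "famhx_cancer": famhx_cancer.astype(int),
            "entry_year": entry_year,
            "_trait": u, "_log_appetite": log_a,
        }, index=pids)
        for k, v in prev.items():
            cov[k] = v.astype(int)
        self._latent = {"u": u, "log_a": log_a}
        return responses, cov

    # -- follow-up FFQ -----------------------------------------------------

    def generate_followup_ffq(
        self, baseline: pd.DataFrame, rho: float | None = None
    ) -> pd.DataFrame:
        """10-year repeat FFQ whose warning-score correlation with baseline
        targets ``rho`` (self-calibrated against an internal replicate)."""
        cfg = self.config
        rho = cfg.rho_10y if rho is None else rho
        if not 0.0 <= rho <= 1.0:
            raise FopLabelError(f"rho must lie in [0, 1], got {rho}")
        if rho == 1.0:
            return baseline.copy()
        if self._latent is None:
            raise FopLabelError("generate the baseline cohort first")
        u, log_a = self._latent["u"], self._latent["log_a"]
        assignments = assign_labels_frame(self._foods_df, self.thresholds)
        portion = self._foods_df["portion_g"]

        def score_of(resp):
            from .foods import responses_to_servings
            intake = responses_to_servings(resp, self.mapping) * portion.to_numpy()[None, :]
            return participant_warning_score(intake, assignments)

        s_base = score_of(baseline)
        # replicate with identical latents isolates the item-noise ceiling
        s_rep = score_of(self._draw_responses(u, log_a))
        r_max = float(np.corrcoef(s_base, s_rep)[0, 1])

        def draw_at(a: float) -> pd.DataFrame:
            z_u = self.rng.normal(size=len(u))
            z_a = self.rng.normal(size=len(u))
            u_f = a * u + np.sqrt(1 - a * a) * z_u
            log_a_f = a * log_a + np.sqrt(1 - a * a) * cfg.appetite_sd * z_a
            return self._draw_responses(u_f, log_a_f)

        # two-step solve: linear first guess, then one multiplicative
        # correction against the realised correlation
        a1 = float(np.clip(rho / max(r_max, 1e-6), 0.0, 1.0))
        cand = draw_at(a1)
        r1 = float(np.corrcoef(s_base, score_of(cand))[0, 1])
        if abs(r1 - rho) <= 0.02 or r1 <= 0:
            return cand
        a2 = float(np.clip(a1 * rho / r1, 0.0, 1.0))
        return draw_at(a2)

    # -- outcomes ----------------------------------------------------------

    _AGE_BANDS = np.arange(20.0, 105.0, 5.0)

    def _band_rates(self) -> np.ndarray:
        mids = (self._AGE_BANDS[:-1] + self._AGE_BANDS[1:]) / 2.0
        return np.exp(self.config.gompertz_slope * (mids - 45.0))

    def _cum_rate(self, ages: np.ndarray) -> np.ndarray:
        """Integral of the unscaled piecewise-constant age rate from the
        first band edge to each age."""
        edges = self._AGE_BANDS
        rates = self._band_rates()
        cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
        idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0,
                      len(rates) - 1)
        return cum[idx] + rates[idx] * (ages - edges[idx])

    def _inv_cum_rate(self, target: np.ndarray) -> np.ndarray:
        edges = self._AGE_BANDS
        rates = self._band_rates()
        cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
        idx = np.clip(np.searchsorted(cum, target, side="right") - 1, 0,
                      len(rates) - 1)
        return edges[idx] + (target - cum[idx]) / rates[idx]

    def generate_outcomes(
        self, covariates: pd.DataFrame, quartile: pd.Series,
        config: GeneratorConfig | None = None,
    ) -> pd.DataFrame:
        """Cause-specific survival outcomes with injected quartile effects.

        Event times follow a piecewise-constant baseline hazard on the age
        scale multiplied by exp(cause-specific quartile log-HR + covariate
        effects); the hazard scale is calibrated by bisection to the target
        event rate under the realised censoring pattern.
        """
        cfg = config or self.config
        rng = self.rng
        n = len(covariates)
        q = quartile.reindex(covariates.index).to_numpy()
        causes = list(cfg.cause_shares)
        shares = np.array([cfg.cause_shares[c] for c in causes])
        shares = shares / shares.sum()

        ch = cfg.covariate_log_hr
        cov_lp = (ch["male"] * covariates["male"].to_numpy()
                  + ch["smoke_current"] * (covariates["smoking"] == "current").to_numpy()
                  + ch["smoke_former"] * (covariates["smoking"] == "former").to_numpy()
                  + ch["bmi_per_unit"] * (covariates["bmi"].to_numpy() - 23.5))
        lp = np.zeros((n, len(causes)))
        for j, c in enumerate(causes):
            betas = np.concatenate([[0.0], np.asarray(cfg.quartile_log_hr[c])])
            lp[:, j] = betas[q - 1] + cov_lp
        mix = (shares[None, :] * np.exp(lp)).sum(axis=1)  # per-participant factor

        a0 = covariates["entry_age"].to_numpy(dtype=float)
        fup_admin = cfg.admin_end - covariates["entry_year"].to_numpy(dtype=float)
        lost = rng.random(n) < cfg.loss_rate
        censor = np.where(lost, rng.random(n) * fup_admin, fup_admin)
        censor = np.maximum(censor, 0.05)
        integral = self._cum_rate(a0 + censor) - self._cum_rate(a0)

        def expected_rate(lam):
            return float(np.mean(1.0 - np.exp(-lam * mix * integral)))

        lo, hi = 1e-8, 1.0
        while expected_rate(hi) < cfg.target_event_rate:
            hi *= 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if expected_rate(mid) < cfg.target_event_rate:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)

        e = rng.exponential(size=n)
        total = lam * mix * integral
        died = e < total
        t_event = np.full(n, np.nan)
        t_event[died] = self._inv_cum_rate(
            self._cum_rate(a0[died]) + e[died] / (lam * mix[died])) - a0[died]
        exit_age = a0 + np.where(died, t_event, censor)
        probs = shares[None, :] * np.exp(lp)
        probs = probs / probs.sum(axis=1, keepdims=True)
        cu = probs.cumsum(axis=1)
        draw = rng.random(n)[:, None]
        cause_idx = (draw > cu).sum(axis=1)
        event = np.where(died, np.asarray(causes)[cause_idx], "none")

        out = pd.DataFrame({
            "entry_age": a0, "exit_age": exit_age, "event": event,
            "entry_year": covariates["entry_year"],
        }, index=covariates.index)
        return out

    # -- missingness -------------------------------------------------------

    def inject_missingness(self, records: pd.DataFrame,
                           col: str = "pack_years") -> pd.DataFrame:
        """MAR missingness in pack-years, likelier for former smokers."""
        cfg = self.config
        rate = cfg.packyears_missing_rate
        if rate == 0:
            return records.copy()
        w = np.where(records["smoking"] == "former", 2.0,
                     np.where(records["smoking"] == "current", 1.0, 0.7))
        p = rate * w / w.mean()
        mask = self.rng.random(len(records)) < np.clip(p, 0, 1)
        out = records.copy()
        out.loc[mask, col] = np.nan
        return out

    def _meddiet(self, totals: pd.DataFrame, cov: pd.DataFrame) -> pd.Series:
        """0-9 Mediterranean-diet adherence from group-level intakes."""
        from .nutriscore import meddiet_score

        g = totals
        comp = pd.DataFrame({
            "vegetables": g["grams_vegetables"],
            "fruits_nuts": g["grams_fruits"] + g["grams_nuts"],
            "legumes": g["grams_legumes"],
            "cereals": (g["grams_rice_pasta"] + g["grams_white_bread"]
                        + g["grams_whole_bread"] + g["grams_breakfast_cereal"]),
            "fish": g["grams_fish"] + g["grams_canned_fish"],
            "fat_ratio": g["grams_olive_oil"] / (g["grams_animal_fat"] + 1.0),
            "meat": g["grams_fresh_meat"] + g["grams_processed_meat"],
            "dairy": g["grams_milk"] + g["grams_cheese"] + g["grams_sweet_dairy"],
            "alcohol_g": g["alcohol_g"],
        })
        sex = cov["male"].map({1: "male", 0: "female"})
        return meddiet_score(comp, sex=sex)

    # -- end-to-end --------------------------------------------------------

    def run(self, with_followup: bool = True) -> dict:
        """Full bundle: foods, FFQs, covariates, scores, quartiles, outcomes.

        The returned ``records`` frame merges covariates, survival columns,
        energy/alcohol totals and the baseline warning score; ``exposures``
        holds baseline/follow-up scores for cumulative-average updating.
        """
        from .foods import compute_intake_frame
        from .nutriscore import PointTable, food_scores_frame, individual_fsam_score

        foods = self.generate_composition_table()
        responses, cov = self.generate_cohort(foods)
        intake, totals = compute_intake_frame(responses, self._foods_df, self.mapping)
        assignments = assign_labels_frame(self._foods_df, self.thresholds)
        ws = participant_warning_score(intake, assignments)
        fsam_items = food_scores_frame(foods, PointTable.default())
        fsam = individual_fsam_score(intake, fsam_items, self._foods_df)

        from .cohort import classify_quartiles
        quartile, cutpoints = classify_quartiles(ws)
        outcomes = self.generate_outcomes(cov, quartile)

        upf_cols = [f"servings_{g}" for g in UPF_GROUPS
                    if f"servings_{g}" in totals.columns]
        records = cov.drop(columns=["_trait", "_log_appetite"]).join(
            outcomes.drop(columns=["entry_year", "entry_age"]))
        records["energy_kcal"] = totals["energy_kcal"]
        records["alcohol_g"] = totals["alcohol_g"]
        records["fibre_g"] = totals["fibre_g"]
        records["upf_servings"] = totals[upf_cols].sum(axis=1)
        records["warning_score"] = ws
        records["fsam_score"] = fsam
        records["died"] = (records["event"] != "none").astype(int)
        records["meddiet"] = self._meddiet(totals, cov)
        records = self.inject_missingness(records)

        bundle = {
            "foods": foods, "foods_df": self._foods_df,
            "responses": responses, "covariates": cov,
            "intake": intake, "totals": totals,
            "warning_score": ws, "fsam_score": fsam,
            "quartile": quartile, "cutpoints": cutpoints,
            "records": records, "config": self.config,
        }
        if with_followup:
            responses_10y = self.generate_followup_ffq(responses)
            intake_10y, totals_10y = compute_intake_frame(
                responses_10y, self._foods_df, self.mapping)
            ws_10y = participant_warning_score(intake_10y, assignments)
            bundle["responses_10y"] = responses_10y
            bundle["warning_score_10y"] = ws_10y
            bundle["exposures"] = pd.DataFrame(
                {"baseline": ws, "followup": ws_10y})
            former = (self.rng.random(len(records)) < 0.30) & \
                (records["smoking"] == "current").to_numpy()
            upd_smoking = records["smoking"].where(~former, "former")
            bundle["updated"] = pd.DataFrame({
                "smoke_current": (upd_smoking == "current").astype(int),
                "smoke_former": (upd_smoking == "former").astype(int),
                "energy_kcal": totals_10y["energy_kcal"],
                "alcohol_g": totals_10y["alcohol_g"],
            }, index=records.index)
        return bundle
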