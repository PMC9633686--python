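"""Cohort survival pipeline: exclusions, imputation, quartile exposure
classification, and stratified proportional-hazards modelling on the age
timescale.

The central objects are :class:`MortalityCoxModel` — a proportional-hazards
model with attained age as the analysis time (birth as origin, delayed
entry at the age the baseline questionnaire was returned) and strata for
age decile x recruitment period — and :class:`MortalityCoxResults`, which
carries hazard ratios, Wald confidence intervals, the log partial
likelihood and AIC/BIC.  Repeated dietary measurements enter through
(start, stop] age intervals with cumulative-average exposure updating.

Partial-likelihood maximisation is delegated to lifelines
(:class:`~lifelines.CoxTimeVaryingFitter`, Efron ties); everything around
it — design construction, stratification, trend and interaction tests,
restricted cubic splines, sensitivity suites and information criteria —
lives here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .exceptions import FitError, FopLabelError, ValidationError
from .warning import LABELS, assign_labels_frame, participant_warning_score

logger = logging.getLogger(__name__)

EVENT_CAUSES = ("none", "cvd", "cancer", "other", "unknown")

#: covariates of the fully adjusted ("multivariable") model
DEFAULT_COVARIATES = (
    "male", "married", "mets", "alcohol_g", "smoke_current", "smoke_former",
    "pack_years", "snacking", "special_diet", "bmi_c", "bmi_sq",
    "energy_q2", "energy_q3", "energy_q4", "education_years",
    "famhx_cvd", "famhx_cancer", "prev_cvd", "prev_htn", "prev_diabetes",
    "prev_cancer", "prev_depression", "hypercholesterolemia",
)

#: covariates of the minimally adjusted model (age enters via the timescale
#: and strata)
BASIC_COVARIATES = ("male",)


# ---------------------------------------------------------------------------
# exclusions / flow chart


class CohortFlow:
    """Sequential exclusion log (flow-chart bookkeeping).

    Each :meth:`exclude` call drops rows and records the stage name and
    count, so the familiar arithmetic `initial - dropped... = analysed`
    is reproducible from the log.
    """

    def __init__(self, df: pd.DataFrame, label: str = "eligible"):
        self.df = df
        self.stages: list[tuple[str, int, int]] = [(label, 0, len(df))]

    def exclude(self, name: str, mask) -> "CohortFlow":
        """Drop rows where ``mask`` is True (callable or boolean array)."""
        if callable(mask):
            mask = mask(self.df)
        mask = np.asarray(mask, dtype=bool)
        dropped = int(mask.sum())
        self.df = self.df.loc[~mask]
        self.stages.append((name, dropped, len(self.df)))
        logger.info("flow: %s dropped %d, %d remain", name, dropped, len(self.df))
        return self

    @property
    def n(self) -> int:
        return len(self.df)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "dropped", "remaining"])


ENERGY_RULES = ("percentile_1_99", "willett", "percentile_5_95")
WILLETT_LIMITS = {"male": (800.0, 4000.0), "female": (500.0, 3500.0)}


def apply_energy_exclusions(
    records: pd.DataFrame,
    rule: str = "percentile_1_99",
    energy_col: str = "energy_kcal",
    male_col: str = "male",
) -> tuple[pd.DataFrame, dict]:
    """Drop implausible total-energy reporters.

    Percentile rules drop values strictly outside the sample percentiles
    (1st/99th or 5th/95th); the Willett rule drops men outside
    [800, 4000] kcal/day and women outside [500, 3500].
    """
    if len(records) == 0:
        raise FopLabelError("energy exclusions on an empty cohort")
    if rule not in ENERGY_RULES:
        raise FopLabelError(f"unknown energy rule {rule!r}; choose from {ENERGY_RULES}")
    energy = records[energy_col]
    if rule == "willett":
        male = records[male_col].astype(bool)
        lo = np.where(male, WILLETT_LIMITS["male"][0], WILLETT_LIMITS["female"][0])
        hi = np.where(male, WILLETT_LIMITS["male"][1], WILLETT_LIMITS["female"][1])
        drop = (energy < lo) | (energy > hi)
    else:
        q = (1, 99) if rule == "percentile_1_99" else (5, 95)
        lo, hi = np.percentile(energy, q)
        drop = (energy < lo) | (energy > hi)
    kept = records.loc[~drop]
    log = {"rule": rule, "n_input": len(records), "n_dropped": int(drop.sum()),
           "n_kept": len(kept)}
    logger.info("energy exclusions (%s): dropped %d of %d", rule, log["n_dropped"],
                log["n_input"])
    return kept, log


# ---------------------------------------------------------------------------
# imputation

PACK_YEARS_PREDICTORS = (
    "age", "male", "mets", "education_years", "bmi", "alcohol_g", "meddiet", "died",
)


def impute_pack_years(
    records: pd.DataFrame,
    col: str = "pack_years",
    predictors: Sequence[str] = PACK_YEARS_PREDICTORS,
) -> pd.DataFrame:
    """Single deterministic least-squares imputation of missing pack-years.

    A linear model in the listed predictors is fitted on complete cases;
    missing values are replaced by its prediction, floored at zero.
    Observed values are untouched.
    """
    missing = [p for p in predictors if p not in records.columns]
    if missing:
        raise FopLabelError(f"imputation predictors missing from records: {missing}")
    mask = records[col].isna()
    if not mask.any():
        return records.copy()
    if mask.mean() > 0.5:
        raise FopLabelError(
            f"{col}: {mask.mean():.0%} missing exceeds the 50% imputation limit"
        )
    import statsmodels.api as sm

    X = sm.add_constant(records[list(predictors)].astype(float), has_constant="add")
    fit = sm.OLS(records.loc[~mask, col].astype(float), X.loc[~mask]).fit()
    pred = fit.predict(X.loc[mask]).clip(lower=0.0)
    out = records.copy()
    out.loc[mask, col] = pred
    logger.info("imputed %d missing %s values (R2=%.3f)", mask.sum(), col, fit.rsquared)
    return out


# ---------------------------------------------------------------------------
# quartile classification


def classify_quartiles(scores: pd.Series | np.ndarray) -> tuple[pd.Series, tuple]:
    """Quartile labels 1-4 with left-open/right-closed intervals above Q1.

    value <= c1 -> 1; c1 < value <= c2 -> 2; c2 < value <= c3 -> 3;
    value > c3 -> 4, with (c1, c2, c3) the sample quartiles.
    """
    s = pd.Series(scores)
    if s.nunique() < 4:
        raise ValidationError("quartile classification needs at least 4 distinct values")
    c1, c2, c3 = np.quantile(s.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    labels = (1 + (s > c1).astype(int) + (s > c2).astype(int) + (s > c3).astype(int))
    return labels.rename("quartile"), (float(c1), float(c2), float(c3))


def quartile_medians(scores: pd.Series, labels: pd.Series) -> pd.Series:
    """Median exposure within each quartile (trend-test regressor values)."""
    return scores.groupby(labels).median()


# ---------------------------------------------------------------------------
# repeated measures / time-varying dataset

UPDATED_AT_FOLLOWUP = ("smoke_current", "smoke_former", "energy_kcal", "alcohol_g",
                       "energy_q2", "energy_q3", "energy_q4")


def build_timevarying_dataset(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    split_years: float = 10.0,
    updated: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Split follow-up at the repeat-questionnaire year with
    cumulative-average exposure updating.

    ``records`` has one row per participant (``entry_age``, ``exit_age``,
    ``event`` plus covariates); ``exposures`` has columns ``baseline`` and
    optional ``followup`` indexed like ``records``.  Participants followed
    beyond ``split_years`` contribute two (start, stop] age intervals: the
    first at the baseline exposure, the second at the mean of baseline and
    follow-up values (cumulative average), with any columns present in
    ``updated`` overwritten on the second interval.  Total person-time is
    conserved exactly.
    """
    if ((records["exit_age"] - records["entry_age"]) <= 0).any():
        raise ValidationError("follow-up must be positive for every participant")
    base = exposures["baseline"]
    fup = exposures["followup"] if "followup" in exposures.columns else pd.Series(
        np.nan, index=exposures.index)
    followup_years = records["exit_age"] - records["entry_age"]
    has_second = followup_years > split_years
    orphan_fup = fup.notna() & ~has_second.reindex(fup.index, fill_value=False)
    if orphan_fup.any():
        warnings.warn(
            f"{int(orphan_fup.sum())} follow-up exposures ignored "
            f"(follow-up shorter than {split_years} years)"
        )

    first = records.copy()
    first["start"] = records["entry_age"]
    first["stop"] = np.minimum(records["exit_age"],
                               records["entry_age"] + split_years)
    first["exposure"] = base.reindex(records.index)
    # events occurring after the split belong to the second interval
    first.loc[has_second, "event"] = "none"

    second = records.loc[has_second].copy()
    second["start"] = second["entry_age"] + split_years
    second["stop"] = second["exit_age"]
    cumavg = np.where(
        fup.reindex(second.index).notna(),
        (base.reindex(second.index) + fup.reindex(second.index)) / 2.0,
        base.reindex(second.index),
    )
    second["exposure"] = cumavg
    if updated is not None:
        cols = [c for c in updated.columns if c in second.columns]
        upd = updated.reindex(second.index)
        for c in cols:
            second[c] = upd[c].where(upd[c].notna(), second[c])
    out = pd.concat([first, second])
    out.index.name = records.index.name or "participant_id"
    out = out.reset_index().rename(columns={out.index.name or "index": "participant_id"})
    return out


# ---------------------------------------------------------------------------
# design preparation


def prepare_design(records: pd.DataFrame, n_periods: int = 5) -> pd.DataFrame:
    """Derive modelling columns from raw covariates.

    Adds smoking dummies, centred BMI and its square, total-energy quartile
    dummies, age-decile and recruitment-period strata.  Idempotent: already
    present columns are left alone.
    """
    df = records.copy()
    if "smoke_current" not in df.columns and "smoking" in df.columns:
        df["smoke_current"] = (df["smoking"] == "current").astype(int)
        df["smoke_former"] = (df["smoking"] == "former").astype(int)
    if "bmi_c" not in df.columns and "bmi" in df.columns:
        df["bmi_c"] = df["bmi"] - 25.0
        df["bmi_sq"] = df["bmi_c"] ** 2
    if "energy_q2" not in df.columns and "energy_kcal" in df.columns:
        eq, _ = classify_quartiles(df["energy_kcal"])
        for k in (2, 3, 4):
            df[f"energy_q{k}"] = (eq == k).astype(int)
    if "age_decile" not in df.columns and "entry_age" in df.columns:
        df["age_decile"] = pd.qcut(df["entry_age"], 10, labels=False, duplicates="drop")
    if "recruitment_period" not in df.columns and "entry_year" in df.columns:
        df["recruitment_period"] = pd.qcut(
            df["entry_year"], n_periods, labels=False, duplicates="drop")
    return df


# ---------------------------------------------------------------------------
# the model / results pair


@dataclass
class MortalityCoxResults:
    """Estimates and fit statistics of one proportional-hazards fit.

    ``hazard_ratios``/``conf_int``/``pvalues`` are indexed by parameter
    name; exposure levels appear as ``q2``, ``q3``, ``q4`` (reference Q1).
    AIC = -2 logL + 2k; BIC = -2 logL + k ln(n) with n the number of
    participants.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns lower, upper (log-HR scale)
    log_likelihood: float
    k: int
    n_participants: int
    n_events: int
    person_years: float
    outcome: str
    exposure_params: tuple[str, ...]
    covariance: pd.DataFrame | None = None
    trend_p: float | None = None
    tag: str = ""

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    @property
    def hr_conf_int(self) -> pd.DataFrame:
        return np.exp(self.conf_int)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.k * np.log(self.n_participants)

    def hr_table(self) -> pd.DataFrame:
        ci = self.hr_conf_int
        return pd.DataFrame({
            "HR": self.hazard_ratios,
            "lower95": ci["lower"],
            "upper95": ci["upper"],
            "p": self.pvalues,
        })

    def summary(self) -> str:
        lines = [
            "Proportional-hazards fit (age timescale, delayed entry)",
            f"  outcome: {self.outcome}   tag: {self.tag or '-'}",
            f"  participants: {self.n_participants}   events: {self.n_events}"
            f"   person-years: {self.person_years:.0f}",
            f"  log partial likelihood: {self.log_likelihood:.2f}   k: {self.k}",
            f"  AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
        ]
        if self.trend_p is not None:
            lines.append(f"  p-trend: {self.trend_p:.4g}")
        lines.append("")
        lines.append(f"  {'parameter':<22}{'HR':>8}{'95% CI':>20}{'p':>10}")
        ci = self.hr_conf_int
        for name in self.params.index:
            hr = float(np.exp(self.params[name]))
            lines.append(
                f"  {name:<22}{hr:>8.3f}"
                f"{'(' + format(ci.loc[name, 'lower'], '.3f') + '-' + format(ci.loc[name, 'upper'], '.3f') + ')':>20}"
                f"{self.pvalues[name]:>10.3g}"
            )
        return "\n".join(lines)


class MortalityCoxModel:
    """Stratified Cox model on the age timescale for cohort mortality.

    Parameters
    ----------
    data
        Analysis table.  Either one row per participant with ``entry_age``/
        ``exit_age`` or a (start, stop] interval table with ``start``/
        ``stop`` and ``participant_id``.  Must contain ``event`` (one of
        ``none, cvd, cancer, other, unknown``), the exposure column and all
        covariate/strata columns (see :func:`prepare_design`).
    exposure
        Column holding the exposure.  With ``exposure_type="quartile"`` it
        holds labels 1-4 and enters as indicator terms ``q2, q3, q4``
        (reference Q1); ``"continuous"`` enters the column as-is.
    outcome
        ``"all_cause"`` or a specific cause; cause-specific fits drop
        participants who died of other causes.
    covariates, strata
        Adjustment columns and strata columns (cross-classified).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure: str = "quartile",
        outcome: str = "all_cause",
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        strata: Sequence[str] = ("age_decile", "recruitment_period"),
        exposure_type: str = "quartile",
        score_col: str | None = None,
        tag: str = "",
    ):
        self.exposure = exposure
        self.outcome = outcome
        self.exposure_type = exposure_type
        self.covariates = [c for c in covariates if c in data.columns]
        lost = set(covariates) - set(self.covariates)
        if lost:
            logger.debug("covariates absent from data, skipped: %s", sorted(lost))
        self.strata = [s for s in strata if s in data.columns]
        self.score_col = score_col
        self.tag = tag
        self.data = self._as_intervals(data)
        if outcome not in ("all_cause",) + EVENT_CAUSES[1:]:
            raise FopLabelError(f"unknown outcome {outcome!r}")
        if outcome != "all_cause":
            other = ~self.data["event"].isin(["none", outcome])
            drop_ids = self.data.loc[other, "participant_id"].unique()
            self.data = self.data[~self.data["participant_id"].isin(drop_ids)]
            logger.info("%s: excluded %d other-cause deaths", outcome, len(drop_ids))

    @staticmethod
    def _as_intervals(data: pd.DataFrame) -> pd.DataFrame:
        df = data.copy()
        if "start" not in df.columns:
            df["start"] = df["entry_age"]
            df["stop"] = df["exit_age"]
        if "participant_id" not in df.columns:
            df = df.reset_index().rename(
                columns={df.index.name or "index": "participant_id"})
        if (df["stop"] <= df["start"]).any():
            raise ValidationError("intervals must satisfy stop > start")
        return df

    # -- design -----------------------------------------------------------

    def _design(
        self,
        exposure_cols: Mapping[str, np.ndarray] | None = None,
        covariates: Sequence[str] | None = None,
    ) -> tuple[pd.DataFrame, list[str]]:
        df = self.data
        cov = list(self.covariates if covariates is None else covariates)
        X = pd.DataFrame(index=df.index)
        X["participant_id"] = df["participant_id"].to_numpy()
        X["start"] = df["start"].to_numpy(dtype=float)
        X["stop"] = df["stop"].to_numpy(dtype=float)
        if self.outcome == "all_cause":
            X["_event"] = (df["event"] != "none").to_numpy()
        else:
            X["_event"] = (df["event"] == self.outcome).to_numpy()
        if exposure_cols is None:
            exposure_cols = self._exposure_columns()
        for name, vals in exposure_cols.items():
            X[name] = np.asarray(vals, dtype=float)
        for c in cov:
            X[c] = df[c].to_numpy(dtype=float)
        if self.strata:
            key = df[self.strata[0]].astype(str)
            for s in self.strata[1:]:
                key = key + "|" + df[s].astype(str)
            X["_stratum"] = key.to_numpy()
        bad = [c for c in X.columns if X[c].isna().any()]
        if bad:
            raise FitError(f"NaNs in model columns {bad}; impute or drop first")
        return X, list(exposure_cols.keys())

    def _exposure_columns(self) -> dict[str, np.ndarray]:
        vals = self.data[self.exposure]
        if self.exposure_type == "quartile":
            return {f"q{k}": (vals == k).to_numpy(dtype=float) for k in (2, 3, 4)}
        return {self.exposure: vals.to_numpy(dtype=float)}

    # -- fitting ----------------------------------------------------------

    def _fit_design(self, X: pd.DataFrame, exposure_params: list[str],
                    tag: str = "") -> MortalityCoxResults:
        if not X["_event"].any():
            raise FitError(f"no {self.outcome} events in the analysis sample")
        ctv = CoxTimeVaryingFitter(penalizer=0.0)
        strata = ["_stratum"] if "_stratum" in X.columns else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ctv.fit(
                    X,
                    id_col="participant_id",
                    event_col="_event",
                    start_col="start",
                    stop_col="stop",
                    strata=strata,
                )
        except (ConvergenceError, np.linalg.LinAlgError) as e:
            raise FitError(f"Cox fit did not converge: {e}") from e
        ci = ctv.confidence_intervals_.copy()
        ci.columns = ["lower", "upper"]
        return MortalityCoxResults(
            params=ctv.params_.copy(),
            bse=ctv.standard_errors_.copy(),
            pvalues=ctv.summary["p"].copy(),
            conf_int=ci,
            log_likelihood=float(ctv.log_likelihood_),
            k=len(ctv.params_),
            n_participants=int(X["participant_id"].nunique()),
            n_events=int(X["_event"].sum()),
            person_years=float((X["stop"] - X["start"]).sum()),
            outcome=self.outcome,
            exposure_params=tuple(exposure_params),
            covariance=pd.DataFrame(
                np.asarray(ctv.variance_matrix_), index=ctv.params_.index,
                columns=ctv.params_.index),
            tag=tag or self.tag,
        )

    def fit(self, with_trend: bool = False) -> MortalityCoxResults:
        X, expo = self._design()
        res = self._fit_design(X, expo)
        if with_trend and self.exposure_type == "quartile":
            res.trend_p = self.trend_test()
        return res

    def trend_test(self) -> float:
        """Linear trend across quartiles: each participant-interval gets the
        median exposure of its quartile and the Wald p of that single
        continuous regressor is returned."""
        if self.exposure_type != "quartile":
            raise FopLabelError("trend test requires quartile exposure")
        if self.score_col is None or self.score_col not in self.data.columns:
            raise FopLabelError("trend test needs score_col with the raw score")
        med = self.data.groupby(self.exposure)[self.score_col].median()
        trend = self.data[self.exposure].map(med).to_numpy(dtype=float)
        X, _ = self._design(exposure_cols={"trend": trend})
        res = self._fit_design(X, ["trend"], tag="trend")
        return float(res.pvalues["trend"])


def fit_cox(
    dataset: pd.DataFrame,
    exposure: str = "quartile",
    outcome: str = "all_cause",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    strata: Sequence[str] = ("age_decile", "recruitment_period"),
    exposure_type: str = "quartile",
    score_col: str | None = None,
    with_trend: bool = False,
    tag: str = "",
) -> MortalityCoxResults:
    """Functional wrapper: build a :class:`MortalityCoxModel` and fit it."""
    model = MortalityCoxModel(
        dataset, exposure=exposure, outcome=outcome, covariates=covariates,
        strata=strata, exposure_type=exposure_type, score_col=score_col, tag=tag,
    )
    return model.fit(with_trend=with_trend)


def likelihood_ratio_test(ll_full: float, ll_reduced: float, df: int) -> float:
    """p-value of the LRT with ``df`` degrees of freedom."""
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(lr, df))


def analyze_cohort(
    records: pd.DataFrame,
    outcome: str = "all_cause",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    score_col: str = "warning_score",
    energy_rule: str = "percentile_1_99",
    with_trend: bool = False,
    strata: Sequence[str] = ("age_decile", "recruitment_period"),
) -> tuple[MortalityCoxResults, pd.DataFrame]:
    """Standard analysis chain on a one-row-per-participant cohort table:
    energy exclusions -> pack-years imputation -> design preparation ->
    score quartiles -> stratified fit.  Returns the results and the
    prepared analysis table (with ``quartile`` attached)."""
    df, _ = apply_energy_exclusions(records, energy_rule)
    if "pack_years" in df.columns and df["pack_years"].isna().any():
        df = impute_pack_years(df)
    df = prepare_design(df)
    labels, _ = classify_quartiles(df[score_col])
    df = df.copy()
    df["quartile"] = labels
    res = fit_cox(df, exposure="quartile", outcome=outcome,
                  covariates=covariates, strata=strata, score_col=score_col,
                  with_trend=with_trend, tag=f"multivariable-{outcome}")
    return res, df


# ---------------------------------------------------------------------------
# subgroup & sensitivity suites


DEFAULT_SUBGROUPS = (
    {"name": "sex", "column": "male", "split": 0.5,
     "labels": ("women", "men")},
    {"name": "age_at_recruitment", "column": "entry_age", "split": 45.0,
     "labels": ("<45", ">=45")},
    {"name": "bmi", "column": "bmi", "split": 25.0, "labels": ("<25", ">=25")},
    {"name": "smoking", "column": "ever_smoker", "split": 0.5,
     "labels": ("never", "ever")},
)

DEFAULT_SENSITIVITY = (
    "energy_willett", "energy_p5_95", "exclude_prevalent",
    "exclude_premature", "no_snacking_adjustment", "adjust_fibre",
)


def _refit_on(records: pd.DataFrame, score_col: str, **model_kw) -> MortalityCoxResults:
    """Re-classify quartiles on a (sub)sample and fit."""
    labels, _ = classify_quartiles(records[score_col])
    df = records.copy()
    df["quartile"] = labels
    return fit_cox(df, exposure="quartile", score_col=score_col, **model_kw)


def subgroup_and_sensitivity_suite(
    records: pd.DataFrame,
    score_col: str = "warning_score",
    subgroups: Sequence[Mapping] = DEFAULT_SUBGROUPS,
    sensitivity: Sequence[str] = DEFAULT_SENSITIVITY,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    **model_kw,
) -> dict[str, MortalityCoxResults | float]:
    """Stratified subgroup fits with interaction LRTs, plus the sensitivity
    scenarios (alternative energy limits, prevalent-condition and
    premature-death exclusions, snacking/fibre adjustment changes).

    Returns a mapping ``tag -> results`` (interaction p-values under
    ``"interaction_p:<name>"``).  Scenarios without events are skipped
    with a warning.
    """
    out: dict[str, MortalityCoxResults | float] = {}
    records = records.copy()
    if "ever_smoker" not in records.columns and "smoking" in records.columns:
        records["ever_smoker"] = (records["smoking"] != "never").astype(int)

    for sg in subgroups:
        col, cut = sg["column"], sg["split"]
        below = records[records[col] < cut]
        above = records[records[col] >= cut]
        for part, label in zip((below, above), sg["labels"]):
            tag = f"{sg['name']}:{label}"
            try:
                if len(part) < 50:
                    raise FitError("subgroup too small")
                out[tag] = _refit_on(part, score_col, covariates=covariates,
                                     tag=tag, **model_kw)
            except (FitError, ValidationError) as e:
                warnings.warn(f"subgroup {tag} skipped: {e}")
        out[f"interaction_p:{sg['name']}"] = interaction_test(
            records, score_col, (records[col] >= cut).astype(int),
            covariates=covariates, **model_kw,
        )

    for scen in sensitivity:
        try:
            out[scen] = _sensitivity_fit(records, scen, score_col,
                                         covariates=covariates, **model_kw)
        except (FitError, ValidationError, FopLabelError) as e:
            warnings.warn(f"sensitivity scenario {scen} skipped: {e}")
    return out


def _sensitivity_fit(records, scenario, score_col, covariates, **model_kw):
    cov = list(covariates)
    df = records
    if scenario == "energy_willett":
        df, _ = apply_energy_exclusions(df, "willett")
    elif scenario == "energy_p5_95":
        df, _ = apply_energy_exclusions(df, "percentile_5_95")
    elif scenario == "exclude_prevalent":
        flags = [c for c in ("prev_cvd", "prev_cancer", "prev_diabetes")
                 if c in df.columns]
        df = df[~df[flags].astype(bool).any(axis=1)]
    elif scenario == "exclude_premature":
        premature = (df["event"] != "none") & (
            df["exit_age"] - df["entry_age"] < 2.0)
        df = df[~premature]
    elif scenario == "no_snacking_adjustment":
        cov = [c for c in cov if c != "snacking"]
    elif scenario == "adjust_fibre":
        cov = cov + ["fibre_g"]
    else:
        raise FopLabelError(f"unknown sensitivity scenario {scenario!r}")
    return _refit_on(df, score_col, covariates=cov, tag=scenario, **model_kw)


def interaction_test(
    records: pd.DataFrame,
    score_col: str,
    group: pd.Series,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    **model_kw,
) -> float:
    """LRT p of the exposure-quartile x group product terms (df = 3)."""
    df = records.copy()
    df["_group"] = np.asarray(group, dtype=float)
    labels, _ = classify_quartiles(df[score_col])
    df["quartile"] = labels
    cov = [c for c in covariates if c in df.columns and c != "_group"]
    # the group main effect joins the adjustment set unless it is already
    # spanned by existing covariates (e.g. an ever-smoking split alongside
    # smoking-status indicators)
    for with_main in (True, False):
        model = MortalityCoxModel(
            df, exposure="quartile",
            covariates=cov + (["_group"] if with_main else []),
            score_col=score_col, **model_kw)
        try:
            base_X, expo = model._design()
            base = model._fit_design(base_X, expo, tag="interaction-base")
            inter_cols = model._exposure_columns()
            g = model.data["_group"].to_numpy(dtype=float)
            for k in (2, 3, 4):
                inter_cols[f"q{k}_x_group"] = inter_cols[f"q{k}"] * g
            full_X, names = model._design(exposure_cols=inter_cols)
            full = model._fit_design(full_X, names, tag="interaction-full")
        except FitError:
            if with_main:
                continue
            raise
        return likelihood_ratio_test(full.log_likelihood, base.log_likelihood,
                                     df=3)


# ---------------------------------------------------------------------------
# leave-one-label-out


def leave_one_label_out(
    intake_df: pd.DataFrame,
    foods,
    records: pd.DataFrame,
    thresholds=None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    **model_kw,
) -> dict[str, MortalityCoxResults]:
    """Recompute the warning score with one label type removed at a time,
    re-classify quartiles, and refit the mortality model for each."""
    out = {}
    for label in LABELS:
        assignments = assign_labels_frame(foods, thresholds, exclude=label)
        scores = participant_warning_score(intake_df, assignments)
        df = records.copy()
        df["_loo_score"] = scores.reindex(df.index)
        out[label] = _refit_on(df, "_loo_score", covariates=covariates,
                               tag=f"excl_{label}", **model_kw)
    return out


# ---------------------------------------------------------------------------
# restricted cubic spline dose-response


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Non-linear term of the 3-knot restricted cubic spline (Harrell form):
    linear beyond the boundary knots, scaled by (t3 - t1)^2."""
    t1, t2, t3 = knots
    def pp(v):  # (v)+^3
        return np.clip(v, 0.0, None) ** 3
    z = (pp(x - t1)
         - pp(x - t2) * (t3 - t1) / (t3 - t2)
         + pp(x - t3) * (t2 - t1) / (t3 - t2))
    return z / (t3 - t1) ** 2


@dataclass
class SplineCurve:
    """Dose-response curve HR(x) relative to the reference exposure."""

    grid: np.ndarray
    hr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    knots: tuple[float, float, float]
    reference: float
    nonlinearity_p: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.grid, "hr": self.hr,
            "lower95": self.lower, "upper95": self.upper,
        })

    def plot(self, ax=None):
        """Spline dose-response plot with 95% bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.hr, color="C0")
        ax.plot(self.grid, self.lower, "--", color="C0", lw=0.8)
        ax.plot(self.grid, self.upper, "--", color="C0", lw=0.8)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("daily warning-label score")
        ax.set_ylabel(f"hazard ratio (ref {self.reference:g})")
        ax.set_yscale("log")
        return ax


def fit_spline(
    records: pd.DataFrame,
    score_col: str = "warning_score",
    knots: Sequence[float] | None = None,
    grid: np.ndarray | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    reference: float = 0.0,
    **model_kw,
) -> SplineCurve:
    """Restricted-cubic-spline dose-response for a continuous exposure.

    Knots default to the 10th/50th/90th percentiles.  The curve is
    normalised to HR(reference) = 1 (reference 0 unless the exposure has no
    support near zero, in which case it is shifted to the observed minimum
    with a warning).  Non-linearity is the LRT of the non-linear term.
    """
    x = records[score_col].to_numpy(dtype=float)
    if knots is None:
        knots = tuple(np.percentile(x, [10, 50, 90]))
    if reference < x.min() - 1e-9 and x.min() > 0.5:
        warnings.warn(
            f"no exposure support near {reference:g}; reference moved to "
            f"{x.min():.2f}")
        reference = float(x.min())
    df = records.copy()
    df["_x"] = x
    df["_z"] = rcs_basis(x, knots)
    model = MortalityCoxModel(df, exposure="_x", exposure_type="continuous",
                              covariates=covariates, **model_kw)
    X_full, _ = model._design(exposure_cols={
        "_x": model.data["_x"].to_numpy(dtype=float),
        "_z": model.data["_z"].to_numpy(dtype=float)})
    full = model._fit_design(X_full, ["_x", "_z"], tag="spline")
    X_lin, _ = model._design(exposure_cols={
        "_x": model.data["_x"].to_numpy(dtype=float)})
    lin = model._fit_design(X_lin, ["_x"], tag="spline-linear")
    p_nl = likelihood_ratio_test(full.log_likelihood, lin.log_likelihood, df=1)

    if grid is None:
        grid = np.linspace(max(0.0, reference), np.percentile(x, 99), 60)
    zg = rcs_basis(np.asarray(grid, dtype=float), knots)
    z0 = rcs_basis(np.array([reference]), knots)[0]
    G = np.column_stack([np.asarray(grid) - reference, zg - z0])
    beta = full.params[["_x", "_z"]].to_numpy()
    V = full.covariance.loc[["_x", "_z"], ["_x", "_z"]].to_numpy()
    lp = G @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", G, V, G))
    return SplineCurve(
        grid=np.asarray(grid, dtype=float),
        hr=np.exp(lp),
        lower=np.exp(lp - 1.959964 * se),
        upper=np.exp(lp + 1.959964 * se),
        knots=tuple(float(k) for k in knots),
        reference=float(reference),
        nonlinearity_p=p_nl,
    )


# ---------------------------------------------------------------------------
# combined exposures


def combined_exposure_analysis(
    records: pd.DataFrame,
    exposure_a: str,
    exposure_b: str,
    cut_a: float | str = "median",
    cut_b: float | str = "median",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    **model_kw,
) -> dict:
    """Cross-classify two exposures at their cut-points (>= cut is "high";
    a value exactly at the median lands in the high cell) and fit HRs for
    the three non-reference cells plus an interaction LRT (df = 1)."""
    df = records.copy()
    ca = float(df[exposure_a].median()) if cut_a == "median" else float(cut_a)
    cb = float(df[exposure_b].median()) if cut_b == "median" else float(cut_b)
    a_high = (df[exposure_a] >= ca).astype(int)
    b_high = (df[exposure_b] >= cb).astype(int)
    cells = {"low_low": (0, 0), "high_low": (1, 0), "low_high": (0, 1),
             "high_high": (1, 1)}
    counts = {}
    for name, (a, b) in cells.items():
        counts[name] = int(((a_high == a) & (b_high == b)).sum())
        if counts[name] == 0:
            raise FopLabelError(f"combined-exposure cell {name!r} is empty")
    df["_a"] = a_high
    df["_b"] = b_high
    model = MortalityCoxModel(df, exposure="_a", exposure_type="continuous",
                              covariates=covariates, **model_kw)
    a = model.data["_a"].to_numpy(dtype=float)
    b = model.data["_b"].to_numpy(dtype=float)
    cell_cols = {
        "high_low": a * (1 - b), "low_high": (1 - a) * b, "high_high": a * b,
    }
    X_cells, names = model._design(exposure_cols=cell_cols)
    res = model._fit_design(X_cells, names, tag=f"{exposure_a}x{exposure_b}")
    X_main, _ = model._design(exposure_cols={"_a": a, "_b": b})
    main = model._fit_design(X_main, ["_a", "_b"], tag="main-effects")
    p_int = likelihood_ratio_test(res.log_likelihood, main.log_likelihood, df=1)
    return {"results": res, "interaction_p": p_int,
            "cuts": {exposure_a: ca, exposure_b: cb}, "cell_counts": counts}


# ---------------------------------------------------------------------------
# information criteria


def compare_aic_bic(fit_a: MortalityCoxResults, fit_b: MortalityCoxResults) -> pd.DataFrame:
    """AIC/BIC comparison of two fits on the same participants and outcome."""
    if fit_a.outcome != fit_b.outcome:
        raise FopLabelError("AIC/BIC comparison requires the same outcome")
    if fit_a.n_participants != fit_b.n_participants:
        raise FopLabelError("AIC/BIC comparison requires the same analysis sample")
    rows = pd.DataFrame({
        "logL": [fit_a.log_likelihood, fit_b.log_likelihood],
        "k": [fit_a.k, fit_b.k],
        "n": [fit_a.n_participants] * 2,
        "AIC": [fit_a.aic, fit_b.aic],
        "BIC": [fit_a.bic, fit_b.bic],
    }, index=[fit_a.tag or "model_a", fit_b.tag or "model_b"])
    rows["dAIC"] = rows["AIC"] - rows["AIC"].min()
    rows["dBIC"] = rows["BIC"] - rows["BIC"].min()
    return rows


def aic(log_likelihood: float, k: int) -> float:
    return -2.0 * log_likelihood + 2.0 * k


def bic(log_likelihood: float, k: int, n: int) -> float:
    return -2.0 * log_likelihood + k * np.log(n)


# ---------------------------------------------------------------------------
# report tables


def cause_share_table(cause_counts: Mapping[str, int]) -> pd.DataFrame:
    """Deaths by cause with percentage shares (closing to 100%)."""
    total = sum(cause_counts.values())
    df = pd.DataFrame({
        "deaths": pd.Series(cause_counts),
    })
    df["percent"] = 100.0 * df["deaths"] / total
    df.loc["total"] = [total, 100.0]
    return df


def baseline_table(
    records: pd.DataFrame, quartile: pd.Series,
    continuous: Sequence[str] = (), binary: Sequence[str] = (),
) -> pd.DataFrame:
    """Baseline-characteristics table by exposure quartile: mean (SD) for
    continuous variables, % for binary ones."""
    if not continuous and not binary:
        numeric = records.select_dtypes(include=[np.number])
        binary = [c for c in numeric.columns
                  if set(numeric[c].dropna().unique()) <= {0, 1}]
        continuous = [c for c in numeric.columns if c not in binary]
    rows = {}
    grouped = records.groupby(quartile)
    rows["N"] = grouped.size().astype(float)
    for c in continuous:
        g = grouped[c]
        rows[c] = g.mean().round(2).astype(str) + " (" + g.std().round(2).astype(str) + ")"
    for c in binary:
        rows[f"{c} (%)"] = (100.0 * grouped[c].mean()).round(1)
    tab = pd.DataFrame(rows).T
    tab.columns = [f"Q{int(q)}" for q in tab.columns]
    return tab


def mortality_table(
    records: pd.DataFrame,
    quartile: pd.Series,
    results: Mapping[str, MortalityCoxResults],
    outcome: str = "all_cause",
) -> pd.DataFrame:
    """Participants, person-years and deaths per quartile with HR rows;
    the trailing column carries the row totals (closure check)."""
    df = records.copy()
    df["_q"] = quartile.reindex(df.index)
    if outcome != "all_cause":
        df = df[df["event"].isin(["none", outcome])]
        event = df["event"] == outcome
    else:
        event = df["event"] != "none"
    py = df["exit_age"] - df["entry_age"]
    g = df.groupby("_q")
    out = pd.DataFrame({
        "participants": g.size(),
        "person_years": py.groupby(df["_q"]).sum(),
        "deaths": event.groupby(df["_q"]).sum(),
    }).T
    out.columns = [f"Q{int(q)}" for q in out.columns]
    out["total"] = out.sum(axis=1)
    for tag, res in results.items():
        row = {"Q1": "1.00 (ref)"}
        ci = res.hr_conf_int
        for k in (2, 3, 4):
            name = f"q{k}"
            if name in res.params.index:
                row[f"Q{k}"] = (f"{np.exp(res.params[name]):.2f} "
                                f"({ci.loc[name, 'lower']:.2f}-"
                                f"{ci.loc[name, 'upper']:.2f})")
        row["total"] = "" if res.trend_p is None else f"p-trend={res.trend_p:.3f}"
        out.loc[tag] = pd.Series(row)
    return out
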