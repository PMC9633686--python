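"""Survival pipeline: exclusions, imputation, quartiles, time-varying
datasets, stratified Cox fits and downstream analyses."""

import numpy as np
import pandas as pd
import pytest

from foplabel.cohort import (
    CohortFlow,
    MortalityCoxModel,
    aic,
    apply_energy_exclusions,
    analyze_cohort,
    bic,
    build_timevarying_dataset,
    cause_share_table,
    classify_quartiles,
    combined_exposure_analysis,
    compare_aic_bic,
    fit_cox,
    fit_spline,
    impute_pack_years,
    leave_one_label_out,
    mortality_table,
    prepare_design,
    rcs_basis,
    subgroup_and_sensitivity_suite,
)
from foplabel.exceptions import FitError, FopLabelError, ValidationError
from foplabel.warning import assign_labels_frame, participant_warning_score


# ---------------------------------------------------------------------------
# exclusions


class TestEnergyExclusions:
    def test_percentile_rule_matches_sort_and_cut(self, rng):
        energy = pd.DataFrame({"energy_kcal": rng.normal(2500, 600, 100),
                               "male": rng.integers(0, 2, 100)})
        kept, log = apply_energy_exclusions(energy, "percentile_1_99")
        lo, hi = np.percentile(energy["energy_kcal"], [1, 99])
        expected = energy[(energy.energy_kcal >= lo) & (energy.energy_kcal <= hi)]
        assert len(kept) == len(expected) == log["n_kept"]
        assert log["n_dropped"] == 100 - len(expected)

    def test_identical_energies_drop_nothing(self):
        df = pd.DataFrame({"energy_kcal": [2000.0] * 50, "male": 0})
        kept, log = apply_energy_exclusions(df, "percentile_1_99")
        assert log["n_dropped"] == 0

    def test_willett_sex_specific_limits(self):
        df = pd.DataFrame({
            "energy_kcal": [700, 900, 3600, 4200, 450, 600, 3400, 3600],
            "male": [1, 1, 1, 1, 0, 0, 0, 0],
        })
        kept, _ = apply_energy_exclusions(df, "willett")
        assert kept["energy_kcal"].tolist() == [900, 3600, 600, 3400]

    def test_empty_input_rejected(self):
        with pytest.raises(FopLabelError):
            apply_energy_exclusions(pd.DataFrame({"energy_kcal": []}), "willett")


def test_cohort_flow_bookkeeping(rng):
    df = pd.DataFrame({"x": rng.normal(size=500)})
    flow = CohortFlow(df)
    flow.exclude("extreme", df.index < 10)
    flow.exclude("lost", flow.df["x"] > 2)
    tab = flow.summary()
    assert tab["remaining"].iloc[-1] == flow.n == len(df) - tab["dropped"].sum()


# ---------------------------------------------------------------------------
# imputation


def packyears_frame(n, rng, missing=0.0, noise_sd=2.0):
    age = rng.uniform(25, 65, n)
    male = rng.integers(0, 2, n)
    truth = 0.8 * (age - 25) + 5 * male
    df = pd.DataFrame({
        "age": age, "male": male, "mets": rng.uniform(0, 40, n),
        "education_years": rng.uniform(3, 8, n), "bmi": rng.normal(24, 3, n),
        "alcohol_g": rng.uniform(0, 30, n), "meddiet": rng.integers(0, 10, n),
        "died": rng.integers(0, 2, n),
        "pack_years": truth + rng.normal(0, noise_sd, n),
    })
    df["_truth"] = truth
    if missing:
        mask = rng.random(n) < missing
        df.loc[mask, "pack_years"] = np.nan
    return df


class TestImputePackYears:
    def test_no_missing_is_identity(self, rng):
        df = packyears_frame(100, rng)
        out = impute_pack_years(df)
        pd.testing.assert_series_equal(out["pack_years"], df["pack_years"])

    def test_constant_predictors_give_mean(self, rng):
        df = packyears_frame(100, rng, missing=0.2)
        for c in ("age", "male", "mets", "education_years", "bmi",
                  "alcohol_g", "meddiet", "died"):
            df[c] = 1.0
        out = impute_pack_years(df)
        obs_mean = df["pack_years"].mean()
        imputed = out.loc[df["pack_years"].isna(), "pack_years"]
        assert np.allclose(imputed, obs_mean)

    def test_recovers_linear_generating_model(self, rng):
        df = packyears_frame(3000, rng, missing=0.079, noise_sd=2.0)
        out = impute_pack_years(df)
        mask = df["pack_years"].isna()
        rmse = float(np.sqrt(np.mean(
            (out.loc[mask, "pack_years"] - df.loc[mask, "_truth"]) ** 2)))
        assert rmse < 2.0  # below the residual SD of the generating model

    def test_imputed_values_floored_at_zero(self, rng):
        df = packyears_frame(200, rng, missing=0.3)
        df["pack_years"] = df["pack_years"] - 40  # push predictions negative
        out = impute_pack_years(df)
        assert (out.loc[df["pack_years"].isna(), "pack_years"] >= 0).all()

    def test_missing_predictor_rejected(self, rng):
        df = packyears_frame(50, rng).drop(columns=["bmi"])
        with pytest.raises(FopLabelError, match="bmi"):
            impute_pack_years(df)

    def test_over_half_missing_rejected(self, rng):
        df = packyears_frame(100, rng, missing=0.7)
        with pytest.raises(FopLabelError, match="50%"):
            impute_pack_years(df)


# ---------------------------------------------------------------------------
# quartiles


class TestClassifyQuartiles:
    def test_printed_boundary_convention(self):
        # sample built so the quartiles are exactly (5.0, 7.1, 9.8)
        s = pd.Series([1, 2, 3, 5.0, 6, 6.5, 7.1, 8, 9, 9.8, 10, 11, 12])
        labels, cuts = classify_quartiles(s)
        assert cuts == pytest.approx((5.0, 7.1, 9.8))
        assert labels[s[s == 5.0].index[0]] == 1    # at cut -> lower interval
        assert labels[s[s == 7.1].index[0]] == 2
        assert labels[s[s == 9.8].index[0]] == 3
        assert labels[s[s == 10].index[0]] == 4     # just above third cut

    def test_balanced_partition(self):
        labels, _ = classify_quartiles(pd.Series(range(1, 9), dtype=float))
        assert labels.value_counts().tolist() == [2, 2, 2, 2]

    def test_large_sample_near_equal_counts(self, rng):
        labels, _ = classify_quartiles(pd.Series(rng.normal(size=10_000)))
        counts = labels.value_counts()
        assert counts.max() - counts.min() <= 2

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        s = pd.Series(rng.normal(size=500))
        labels, (c1, c2, c3) = classify_quartiles(s)
        assert set(labels.unique()) == {1, 2, 3, 4}
        assert ((s <= c1) == (labels == 1)).all()
        assert (((s > c1) & (s <= c2)) == (labels == 2)).all()
        assert ((s > c3) == (labels == 4)).all()

    def test_too_few_distinct_values(self):
        with pytest.raises(ValidationError):
            classify_quartiles(pd.Series([1.0, 1.0, 2.0, 2.0]))


# ---------------------------------------------------------------------------
# time-varying dataset


def survival_frame(rows):
    return pd.DataFrame(rows, index=pd.Index(
        [f"p{i}" for i in range(len(rows))], name="participant_id"))


class TestBuildTimevarying:
    def test_cumulative_average_split(self):
        rec = survival_frame([{"entry_age": 40.0, "exit_age": 54.0,
                               "event": "cancer"}])
        expo = pd.DataFrame({"baseline": [6.0], "followup": [8.0]},
                            index=rec.index)
        out = build_timevarying_dataset(rec, expo)
        assert len(out) == 2
        first, second = out.iloc[0], out.iloc[1]
        assert (first["start"], first["stop"]) == (40.0, 50.0)
        assert first["exposure"] == 6.0 and first["event"] == "none"
        assert (second["start"], second["stop"]) == (50.0, 54.0)
        assert second["exposure"] == pytest.approx(7.0)
        assert second["event"] == "cancer"

    def test_short_followup_single_interval(self):
        rec = survival_frame([{"entry_age": 40.0, "exit_age": 48.0,
                               "event": "none"}])
        expo = pd.DataFrame({"baseline": [6.0]}, index=rec.index)
        out = build_timevarying_dataset(rec, expo)
        assert len(out) == 1 and out.iloc[0]["exposure"] == 6.0

    def test_orphan_followup_warns_and_is_ignored(self):
        rec = survival_frame([{"entry_age": 40.0, "exit_age": 45.0,
                               "event": "none"}])
        expo = pd.DataFrame({"baseline": [6.0], "followup": [9.0]},
                            index=rec.index)
        with pytest.warns(UserWarning, match="ignored"):
            out = build_timevarying_dataset(rec, expo)
        assert len(out) == 1

    def test_person_time_conserved(self, rng):
        n = 300
        entry = rng.uniform(25, 60, n)
        fup = rng.uniform(0.5, 20, n)
        rec = pd.DataFrame({
            "entry_age": entry, "exit_age": entry + fup,
            "event": rng.choice(["none", "cancer"], n),
        }, index=pd.Index([f"p{i}" for i in range(n)], name="participant_id"))
        expo = pd.DataFrame({
            "baseline": rng.uniform(0, 15, n),
            "followup": np.where(fup > 10, rng.uniform(0, 15, n), np.nan),
        }, index=rec.index)
        out = build_timevarying_dataset(rec, expo)
        assert (out["stop"] - out["start"]).sum() == pytest.approx(fup.sum())

    def test_updated_covariates_applied_to_second_interval(self):
        rec = survival_frame([{"entry_age": 40.0, "exit_age": 54.0,
                               "event": "none", "alcohol_g": 5.0}])
        expo = pd.DataFrame({"baseline": [6.0], "followup": [8.0]},
                            index=rec.index)
        upd = pd.DataFrame({"alcohol_g": [12.0]}, index=rec.index)
        out = build_timevarying_dataset(rec, expo, updated=upd)
        assert out.iloc[0]["alcohol_g"] == 5.0
        assert out.iloc[1]["alcohol_g"] == 12.0


# ---------------------------------------------------------------------------
# Cox fits


def exponential_two_group(n, rng, hr=2.0, rate0=0.1, censor=8.0):
    g = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (rate0 * np.where(g == 1, hr, 1.0)))
    df = pd.DataFrame({
        "entry_age": 0.001,
        "exit_age": np.minimum(t, censor) + 0.001,
        "event": np.where(t < censor, "cancer", "none"),
        "g": g,
    })
    return df


class TestFitCox:
    def test_matches_exponential_rate_ratio_mle(self, rng):
        df = exponential_two_group(2000, rng)
        res = fit_cox(df, exposure="g", exposure_type="continuous",
                      covariates=(), strata=())
        py = df["exit_age"] - df["entry_age"]
        ev = df["event"] != "none"
        mle = ((ev[df.g == 1].sum() / py[df.g == 1].sum())
               / (ev[df.g == 0].sum() / py[df.g == 0].sum()))
        assert np.exp(res.params["g"]) == pytest.approx(mle, rel=0.02)

    def test_null_simulation_q4_near_one(self, rng):
        n = 5000
        score = rng.normal(size=n)
        q, _ = classify_quartiles(pd.Series(score))
        t = rng.exponential(10.0, n)
        df = pd.DataFrame({
            "entry_age": 0.001, "exit_age": np.minimum(t, 3.0) + 0.001,
            "event": np.where(t < 3.0, "cancer", "none"),
            "quartile": q.to_numpy(),
        })
        res = fit_cox(df, covariates=(), strata=())
        hr = float(np.exp(res.params["q4"]))
        ci = res.hr_conf_int.loc["q4"]
        assert 0.85 <= hr <= 1.18
        assert ci["lower"] <= 1.0 <= ci["upper"]

    def test_quartile_parameter_recovery(self, rng):
        n = 20_000
        q = rng.integers(1, 5, n)
        beta = np.log(1.5)
        rate = 0.004 * np.exp(beta * (q == 4))
        t = rng.exponential(1.0 / rate)
        df = pd.DataFrame({
            "entry_age": 0.001, "exit_age": np.minimum(t, 12.0) + 0.001,
            "event": np.where(t < 12.0, "cancer", "none"),
            "quartile": q,
        })
        res = fit_cox(df, covariates=(), strata=())
        assert np.exp(res.params["q4"]) == pytest.approx(1.5, rel=0.10)

    def test_no_events_raises(self):
        df = pd.DataFrame({
            "entry_age": [0.0] * 8, "exit_age": [1.0] * 8,
            "event": ["none"] * 8, "quartile": [1, 2, 3, 4] * 2,
        })
        with pytest.raises(FitError, match="events"):
            fit_cox(df, covariates=(), strata=())

    def test_cause_specific_drops_other_causes(self, small_bundle):
        rec = small_bundle["records"].copy()
        rec["quartile"] = small_bundle["quartile"]
        model = MortalityCoxModel(rec, outcome="cancer", covariates=(),
                                  strata=())
        other = rec["event"].isin(["cvd", "other", "unknown"]).sum()
        assert model.data["participant_id"].nunique() == len(rec) - other

    def test_aic_bic_identities(self, rng):
        df = exponential_two_group(500, rng)
        res = fit_cox(df, exposure="g", exposure_type="continuous",
                      covariates=(), strata=())
        assert res.aic == pytest.approx(aic(res.log_likelihood, res.k))
        assert res.bic == pytest.approx(
            bic(res.log_likelihood, res.k, res.n_participants))
        assert res.summary()  # renders without error


class TestTrend:
    def test_strong_monotone_effect_detected(self, rng):
        n = 4000
        score = rng.uniform(0, 10, n)
        q, _ = classify_quartiles(pd.Series(score))
        rate = 0.02 * np.exp(0.25 * (q.to_numpy() - 1))
        t = rng.exponential(1.0 / rate)
        df = pd.DataFrame({
            "entry_age": 0.001, "exit_age": np.minimum(t, 10.0) + 0.001,
            "event": np.where(t < 10.0, "cancer", "none"),
            "quartile": q.to_numpy(), "score": score,
        })
        model = MortalityCoxModel(df, exposure="quartile", covariates=(),
                                  strata=(), score_col="score")
        assert model.trend_test() < 0.01

    def test_tied_quartile_medians_allowed(self, rng):
        n = 400
        score = np.concatenate([np.full(n // 2, 1.0), np.full(n // 4, 2.0),
                                rng.uniform(3, 4, n - 3 * n // 4)])
        t = rng.exponential(5.0, n)
        df = pd.DataFrame({
            "entry_age": 0.001, "exit_age": np.minimum(t, 4.0) + 0.001,
            "event": np.where(t < 4.0, "cancer", "none"),
            "score": score,
        })
        df["quartile"], _ = classify_quartiles(df["score"])
        model = MortalityCoxModel(df, exposure="quartile", covariates=(),
                                  strata=(), score_col="score")
        assert 0.0 <= model.trend_test() <= 1.0


class TestCompareAicBic:
    def test_formula_evaluations(self):
        assert aic(-2130.0, 2) == pytest.approx(4264.0)
        assert bic(-2100.0, 27, 20_666) == pytest.approx(4468.3, abs=0.05)

    def test_identical_fits_have_zero_deltas(self, rng):
        df = exponential_two_group(400, rng)
        res = fit_cox(df, exposure="g", exposure_type="continuous",
                      covariates=(), strata=())
        tab = compare_aic_bic(res, res)
        assert tab["dAIC"].tolist() == [0.0, 0.0]
        assert tab["dBIC"].tolist() == [0.0, 0.0]

    def test_different_outcomes_not_comparable(self, rng):
        df = exponential_two_group(400, rng)
        a = fit_cox(df, exposure="g", exposure_type="continuous",
                    covariates=(), strata=())
        b = fit_cox(df, exposure="g", exposure_type="continuous",
                    covariates=(), strata=(), outcome="cancer")
        b.outcome = "cvd"
        with pytest.raises(FopLabelError):
            compare_aic_bic(a, b)


# ---------------------------------------------------------------------------
# splines


class TestSpline:
    def test_basis_linear_beyond_boundary_knots(self):
        knots = (2.0, 5.0, 9.0)
        x = np.linspace(10, 30, 50)
        z = rcs_basis(x, knots)
        second_diff = np.diff(z, 2)
        assert np.allclose(second_diff, 0.0, atol=1e-9)

    def test_reference_hr_is_one_and_bands_contain_estimate(self, rng):
        n = 3000
        score = rng.gamma(3.0, 2.5, n)
        rate = 0.02 * np.exp(0.05 * score)
        t = rng.exponential(1.0 / rate)
        df = pd.DataFrame({
            "entry_age": 0.001, "exit_age": np.minimum(t, 8.0) + 0.001,
            "event": np.where(t < 8.0, "cancer", "none"),
            "warning_score": score,
        })
        curve = fit_spline(df, covariates=(), strata=(),
                           grid=np.linspace(0, 15, 31))
        assert curve.hr[0] == pytest.approx(1.0)
        assert (curve.lower <= curve.hr + 1e-12).all()
        assert (curve.upper >= curve.hr - 1e-12).all()
        # positive log-linear truth: the curve rises over the upper range
        assert curve.hr[-1] > curve.hr[len(curve.hr) // 2]
        # log-linear truth: no evidence of non-linearity expected
        assert curve.nonlinearity_p > 0.01

    def test_reference_shift_warning_without_support_near_zero(self, rng):
        n = 800
        score = rng.uniform(5, 15, n)
        t = rng.exponential(8.0, n)
        df = pd.DataFrame({
            "entry_age": 0.001, "exit_age": np.minimum(t, 5.0) + 0.001,
            "event": np.where(t < 5.0, "cancer", "none"),
            "warning_score": score,
        })
        with pytest.warns(UserWarning, match="reference"):
            curve = fit_spline(df, covariates=(), strata=())
        assert curve.reference >= 5.0


# ---------------------------------------------------------------------------
# combined exposures


class TestCombinedExposure:
    def make_df(self, rng, n=4000, effect=0.0):
        a = rng.uniform(0, 10, n)
        b = rng.uniform(0, 10, n)
        rate = 0.02 * np.exp(effect * ((a >= np.median(a)) & (b >= np.median(b))))
        t = rng.exponential(1.0 / rate)
        return pd.DataFrame({
            "entry_age": 0.001, "exit_age": np.minimum(t, 8.0) + 0.001,
            "event": np.where(t < 8.0, "cancer", "none"),
            "score_a": a, "score_b": b,
        })

    def test_null_exposures_cover_one(self, rng):
        df = self.make_df(rng)
        out = combined_exposure_analysis(df, "score_a", "score_b",
                                         covariates=(), strata=())
        ci = out["results"].hr_conf_int
        for cell in ("high_low", "low_high", "high_high"):
            assert ci.loc[cell, "lower"] <= 1.0 <= ci.loc[cell, "upper"]
        assert 0.0 <= out["interaction_p"] <= 1.0

    def test_cell_counts_partition_cohort(self, rng):
        df = self.make_df(rng, n=1000)
        out = combined_exposure_analysis(df, "score_a", "score_b",
                                         covariates=(), strata=())
        assert sum(out["cell_counts"].values()) == 1000

    def test_value_at_median_lands_in_high_cell(self, rng):
        df = self.make_df(rng, n=501)
        med = float(df["score_a"].median())
        df.loc[df.index[0], "score_a"] = med
        out = combined_exposure_analysis(df, "score_a", "score_b",
                                         covariates=(), strata=())
        assert (df["score_a"] >= out["cuts"]["score_a"]).iloc[0]

    def test_empty_cell_rejected(self, rng):
        df = self.make_df(rng, n=200)
        df["score_b"] = df["score_a"]  # perfectly dependent -> empty cells
        with pytest.raises(FopLabelError, match="cell"):
            combined_exposure_analysis(df, "score_a", "score_b",
                                       covariates=(), strata=())


# ---------------------------------------------------------------------------
# suites on a simulated cohort


REDUCED_COVARIATES = ("male", "smoke_current", "smoke_former", "bmi_c", "bmi_sq")


@pytest.fixture(scope="module")
def prepared_small(small_bundle):
    rec = prepare_design(small_bundle["records"])
    rec = impute_pack_years(rec)
    labels, _ = classify_quartiles(rec["warning_score"])
    rec["quartile"] = labels
    return rec


class TestSuites:
    def test_subgroup_and_sensitivity_suite(self, prepared_small):
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            out = subgroup_and_sensitivity_suite(
                prepared_small, covariates=REDUCED_COVARIATES,
                strata=("age_decile",))
        assert "interaction_p:sex" in out
        assert 0.0 <= out["interaction_p:sex"] <= 1.0
        assert out["exclude_premature"].tag == "exclude_premature"
        # premature-death exclusion removes early events from the risk set
        early = ((prepared_small["event"] != "none") &
                 (prepared_small["exit_age"] - prepared_small["entry_age"] < 2))
        full_events = (prepared_small["event"] != "none").sum()
        assert out["exclude_premature"].n_events <= full_events - early.sum() + 1
        assert out["adjust_fibre"].k == len(REDUCED_COVARIATES) + 4

    def test_analyze_cohort_end_to_end(self, small_bundle):
        res, df = analyze_cohort(small_bundle["records"],
                                 covariates=REDUCED_COVARIATES,
                                 with_trend=True)
        assert res.n_participants == len(df)
        assert res.trend_p is not None
        assert set(res.exposure_params) == {"q2", "q3", "q4"}

    def test_leave_one_label_out_scores_monotone(self, small_bundle):
        foods_df = small_bundle["foods_df"]
        intake = small_bundle["intake"]
        full_scores = small_bundle["warning_score"]
        for label in ("energy", "sugar", "sat_fat", "sodium"):
            excl = assign_labels_frame(foods_df, exclude=label)
            s = participant_warning_score(intake, excl)
            assert (s <= full_scores + 1e-9).all()

    def test_leave_one_label_out_noop_exclusion(self, rng):
        # foods carry only sugar and sodium labels; removing sat_fat is a no-op
        from .conftest import make_food
        foods = [make_food(item_id=f"i{k}", total_sugars_g=20.0,
                           sodium_mg=800.0, sat_fat_g=0.0, energy_kcal=100.0)
                 for k in range(8)]
        n = 600
        intake = pd.DataFrame(rng.uniform(0, 300, size=(n, 8)),
                              columns=[f.item_id for f in foods],
                              index=pd.Index([f"p{i}" for i in range(n)],
                                             name="participant_id"))
        full = participant_warning_score(intake, assign_labels_frame(foods))
        sat_excl = participant_warning_score(
            intake, assign_labels_frame(foods, exclude="sat_fat"))
        pd.testing.assert_series_equal(full, sat_excl)
        t = rng.exponential(8.0, n)
        rec = pd.DataFrame({
            "entry_age": 0.001, "exit_age": np.minimum(t, 5.0) + 0.001,
            "event": np.where(t < 5.0, "cancer", "none"),
        }, index=intake.index)
        fits = leave_one_label_out(intake, foods, rec, covariates=(),
                                   strata=())
        full_fit = fits["sat_fat"]  # sat_fat removal leaves scores unchanged
        again = fits["energy"]
        assert full_fit.n_events == again.n_events
        assert np.isfinite(full_fit.params).all()

    def test_repeated_measures_fit_runs(self, small_bundle):
        rec = prepare_design(small_bundle["records"])
        rec = impute_pack_years(rec)
        tv = build_timevarying_dataset(rec, small_bundle["exposures"],
                                       updated=small_bundle["updated"])
        tv["quartile"], _ = classify_quartiles(tv["exposure"])
        res = fit_cox(tv, covariates=REDUCED_COVARIATES, strata=("age_decile",),
                      score_col="exposure")
        assert res.person_years == pytest.approx(
            (rec["exit_age"] - rec["entry_age"]).sum())


# ---------------------------------------------------------------------------
# report tables


class TestReports:
    def test_cause_shares_close_to_100(self):
        tab = cause_share_table({"cvd": 90, "cancer": 242, "other": 137,
                                 "unknown": 13})
        assert tab.loc["total", "deaths"] == 482  # 90+242+137+13
        assert tab["percent"].drop("total").sum() == pytest.approx(100.0)

    def test_mortality_table_closure(self, prepared_small):
        res = fit_cox(prepared_small, covariates=REDUCED_COVARIATES,
                      strata=("age_decile",), score_col="warning_score")
        tab = mortality_table(prepared_small, prepared_small["quartile"],
                              {"multivariable": res})
        py_cols = [c for c in tab.columns if c.startswith("Q")]
        assert tab.loc["person_years", "total"] == pytest.approx(
            tab.loc["person_years", py_cols].sum())
        assert tab.loc["deaths", "total"] == \
            (prepared_small["event"] != "none").sum()
        assert tab.loc["participants", "total"] == len(prepared_small)
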