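"""Coding schemes, forward selection, exposure augmentation, and the
robustness analyses, exercised against the reduced-form generators."""

import numpy as np
import pandas as pd
import pytest

from gazecog import assoc, synth


@pytest.fixture
def truth():
    return synth.SynthTruth(household_offsets={}, seed=0)


@pytest.fixture
def shift_cells(truth):
    d = synth.generate_shift_cells(150, truth, seed=20)
    coded, _ = assoc.code_predictors(d)
    return coded


class TestCoding:
    def test_two_level_factors_difference_coded(self, shift_cells):
        assert set(shift_cells["Year"].unique()) == {-0.5, 0.5}
        assert set(shift_cells["Age"].unique()) == {-0.5, 0.5}

    def test_ses_centered(self, shift_cells):
        assert shift_cells["SES"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_load_contrast_rows_sum_to_zero(self, shift_cells):
        levels = shift_cells.drop_duplicates("load_level")[["Load1", "Load2"]]
        assert levels.to_numpy().sum(axis=0) == pytest.approx([0.0, 0.0])

    def test_unknown_level_rejected(self):
        bad = pd.DataFrame({"year": [1, 3]})
        with pytest.raises(ValueError, match="year"):
            assoc.code_predictors(bad)


class TestBuildBaseline:
    def test_no_candidates_returns_main_effects(self, shift_cells):
        spec, fit, log = assoc.build_baseline("shift_rate", [], shift_cells)
        assert spec.fixed_terms == ["Year", "Load", "SES", "Age"]
        assert log == []
        assert fit.reml and fit.n_groups == 150

    def test_true_interaction_retained(self, truth):
        d = synth.generate_cp_cells(200, truth, seed=21, beta_year_ses=0.3)
        coded, _ = assoc.code_predictors(d)
        spec, fit, log = assoc.build_baseline("cp_no_change", ["Year:SES"], coded)
        assert "Year:SES" in spec.fixed_terms

    def test_marginality_blocks_higher_order_without_constituents(self, truth):
        d = synth.generate_cp_cells(80, truth, seed=22)
        coded, _ = assoc.code_predictors(d)
        spec, fit, log = assoc.build_baseline(
            "cp_no_change", ["Year:SES:LookingWindow1"], coded)
        rec = log[0]
        assert rec["tested"] is False and "marginality" in rec["reason"]

    def test_candidates_ordered_by_interaction_order(self, truth):
        d = synth.generate_cp_cells(80, truth, seed=23)
        coded, _ = assoc.code_predictors(d)
        # three-way listed first must still be tested after its two-ways
        spec, fit, log = assoc.build_baseline(
            "cp_no_change",
            ["Year:SES:LookingWindow1", "Year:SES", "SES:LookingWindow1",
             "Year:LookingWindow1"],
            coded)
        tested = [r["candidate"] for r in log]
        assert tested.index("Year:SES") < tested.index("Year:SES:LookingWindow1")


class TestAddAirQuality:
    def test_negative_aqi_effect_detected_on_shift_rate(self, truth):
        d = synth.generate_shift_cells(250, truth, seed=24, offset_sd=45.0)
        coded, _ = assoc.code_predictors(d)
        spec, _, _ = assoc.build_baseline("shift_rate", [], coded)
        fit, comp = assoc.add_air_quality(
            spec, pd.DataFrame(columns=["household_id", "exposure_score"]), coded)
        assert fit.coef.loc["AQI", "Estimate"] < 0
        assert "baseline_vs_augmented" in comp

    def test_year_specific_cp_effect_keeps_interaction(self, truth):
        """A year-1-only exposure effect should retain Year x AQI in most
        replicates."""
        kept = 0
        for r in range(15):
            t = synth.SynthTruth(household_offsets={}, beta_aqi_cp_y1=-1.6e-3,
                                 beta_aqi_cp_y2=0.0)
            d = synth.generate_cp_cells(220, t, seed=300 + r, offset_sd=40.0)
            coded, _ = assoc.code_predictors(d)
            spec = assoc.ModelSpec("cp_no_change",
                                   ["Year", "Load", "SES", "LookingWindow1", "Age"],
                                   True)
            _, comp = assoc.add_air_quality(
                spec, pd.DataFrame(columns=["household_id", "exposure_score"]),
                coded)
            kept += comp["year_aqi_interaction"]["kept"]
        assert kept / 15 > 0.5

    def test_all_zero_exposure_flagged_degenerate(self, truth):
        d = synth.generate_shift_cells(60, truth, seed=25)
        d["exposure"] = 0.0
        coded, _ = assoc.code_predictors(d)
        spec, _, _ = assoc.build_baseline("shift_rate", [], coded)
        fit, comp = assoc.add_air_quality(
            spec, pd.DataFrame(columns=["household_id", "exposure_score"]), coded)
        assert fit.coef.loc["AQI", "Estimate"] == 0.0
        assert np.isnan(fit.coef.loc["AQI", "Std. Error"])
        assert any("degenerate" in f for f in fit.flags)

    def test_missing_exposure_households_dropped_with_warning(self, truth, caplog):
        d = synth.generate_shift_cells(30, truth, seed=26)
        coded, _ = assoc.code_predictors(d)
        coded = coded.drop(columns=["AQI"])
        expo = pd.DataFrame({
            "household_id": [f"p{i:04d}" for i in range(20)],
            "exposure_score": np.random.default_rng(0).normal(0, 30, 20),
        })
        spec, _, _ = assoc.build_baseline("shift_rate", [], coded)
        with caplog.at_level("WARNING"):
            fit, _ = assoc.add_air_quality(spec, expo, coded)
        assert fit.n_groups == 20
        assert any("without exposure" in r.message for r in caplog.records)


class TestRobustness:
    def _merged(self, truth, seed=27, n=150):
        cp = synth.generate_cp_cells(n, truth, seed=seed)
        sr = synth.generate_shift_cells(n, truth, seed=seed + 1)
        m = cp.merge(
            sr[["participant_id", "year", "load_level", "shift_rate"]],
            on=["participant_id", "year", "load_level"])
        coded, _ = assoc.code_predictors(m)
        return coded

    def test_orthogonal_covariate_leaves_aqi_estimate(self, truth):
        data = self._merged(truth)
        cp_spec = assoc.ModelSpec(
            "cp_no_change", ["Year", "Load", "SES", "LookingWindow1", "Age", "AQI"],
            True)
        sr_spec = assoc.ModelSpec(
            "shift_rate", ["Year", "Load", "SES", "Age", "AQI"], True)
        base = assoc.fit_model(data, "cp", cp_spec)
        cp_fit, sr_fit = assoc.robustness_cross_covariate(data, cp_spec, sr_spec)
        # shift rate and cp are generated independently here: adding the
        # cross covariate barely moves the AQI coefficient
        a0 = base.coef.loc["AQI", "Estimate"]
        a1 = cp_fit.coef.loc["AQI", "Estimate"]
        assert a1 == pytest.approx(a0, abs=3 * base.coef.loc["AQI", "Std. Error"])
        assert "ShiftRate" in cp_fit.coef.index
        assert "ChangePreference" in sr_fit.coef.index

    def test_duplicated_covariate_flagged_collinear(self, truth):
        data = self._merged(truth, seed=28)
        data["shift_rate"] = data["cp"]  # covariate duplicates the outcome
        cp_spec = assoc.ModelSpec("cp_no_change", ["Year", "Load", "SES"], True)
        sr_spec = assoc.ModelSpec("shift_rate", ["Year", "Load", "SES"], True)
        cp_fit, sr_fit = assoc.robustness_cross_covariate(data, cp_spec, sr_spec)
        assert any("collinear" in f for f in cp_fit.flags)


class TestLoadMatched:
    def test_subset_is_year1_medium_and_year2_low(self, truth):
        d = synth.generate_cp_cells(80, truth, seed=29)
        coded, _ = assoc.code_predictors(d)
        coded["AQI"] = coded["exposure"]
        fit = assoc.load_matched_analysis(coded)
        expected = (((coded["year"] == 1) & (coded["load_level"] == "medium"))
                    | ((coded["year"] == 2) & (coded["load_level"] == "low"))).sum()
        assert fit.n_obs == expected
        assert "load_matched_interaction_F" in fit.comparison

    def test_empty_subset_fails_informatively(self, truth):
        d = synth.generate_cp_cells(20, truth, seed=30)
        d = d[(d["year"] == 1) & (d["load_level"] != "medium")]
        coded, _ = assoc.code_predictors(d)
        coded["AQI"] = coded["exposure"]
        with pytest.raises(ValueError, match="load-2"):
            assoc.load_matched_analysis(coded)


class TestAssessmentModels:
    def _table(self, n, seed, beta_ses=0.8, noise_sd=10.0):
        hh = synth.generate_households(n, seed=seed)
        cfg = synth.GenConfig(n_households=n)
        truth = synth.make_truth(hh, cfg, seed=seed,
                                 beta_ses_assessment=beta_ses)
        df = synth.generate_assessments(hh, truth, seed=seed, noise_sd=noise_sd)
        meta = pd.DataFrame([vars(h) for h in hh])
        df = df.merge(meta[["household_id", "ses_score", "cohort"]],
                      left_on="participant_id", right_on="household_id")
        df["exposure"] = [truth.household_offsets[p] for p in df["participant_id"]]
        coded, _ = assoc.code_predictors(df)
        return coded, truth

    def test_zero_noise_zero_effect_slopes_exactly_zero(self):
        coded, _ = self._table(40, seed=31, beta_ses=0.0, noise_sd=0.0)
        # remove the built-in age effect by subsetting one cohort
        coded = coded[coded["cohort"] == "6mo"]
        fits = assoc.fit_assessment_models(coded)
        f = fits["mullen_composite"]["augmented"]
        assert f.coef.loc["SES", "Estimate"] == pytest.approx(0.0, abs=1e-9)
        assert f.coef.loc["AQI", "Estimate"] == pytest.approx(0.0, abs=1e-9)

    def test_positive_ses_effect_recovered_within_2se(self):
        coded, truth = self._table(400, seed=32)
        fits = assoc.fit_assessment_models(coded)
        f = fits["asq_problem_solving"]["baseline"]
        est = f.coef.loc["SES", "Estimate"]
        se = f.coef.loc["SES", "Std. Error"]
        assert abs(est - truth.beta_ses_assessment) < 2 * se
        assert est > 0

    def test_null_aqi_rarely_significant(self):
        hits = 0
        reps = 30
        for r in range(reps):
            coded, _ = self._table(150, seed=600 + r)
            fits = assoc.fit_assessment_models(coded)
            p = fits["mullen_composite"]["augmented"].coef.loc["AQI", "Pr(>|t|)"]
            hits += p < 0.05
        assert hits / reps <= 0.10


def test_modelfit_serializes_to_json(truth, tmp_path):
    import json
    d = synth.generate_shift_cells(40, truth, seed=33)
    coded, _ = assoc.code_predictors(d)
    spec, fit, _ = assoc.build_baseline("shift_rate", [], coded)
    blob = json.dumps(fit.to_dict())
    back = json.loads(blob)
    assert back["outcome"] == "shift_rate"
    assert {"term", "Estimate", "Std. Error", "DF", "t value", "Pr(>|t|)"} <= \
        set(back["coefficients"][0])
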