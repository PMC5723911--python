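import numpy as np
import pandas as pd
import pytest

import bymgamma as bg
from bymgamma.standardize import band_bounds, EXPOSURE_FLAGS

from conftest import make_records


class TestAgeRestrict:
    def test_stroke_keeps_fifty_plus(self):
        recs = make_records(
            [{"region_id": "R", "year": 2008, "sex": "M", "age_group": a}
             for a in ("19-29", "30-39", "50-59", "60+")]
        )
        kept = bg.age_restrict(recs, "stroke")
        assert set(kept["age_group"]) == {"50-59", "60+"}

    def test_hypertension_identity_when_all_thirty_plus(self):
        recs = make_records(
            [{"region_id": "R", "year": 2008, "sex": "F", "age_group": a}
             for a in ("30-34", "45-49", "80+")]
        )
        assert len(bg.age_restrict(recs, "hypertension")) == len(recs)

    def test_straddling_band_rejected(self):
        recs = make_records(
            [{"region_id": "R", "year": 2008, "sex": "M", "age_group": "35-44"}]
        )
        with pytest.raises(ValueError, match="straddles"):
            bg.age_restrict(recs, "myocardial_infarction")

    def test_unknown_outcome_rejected(self):
        with pytest.raises(KeyError):
            bg.age_restrict(make_records([]), "gout")


def test_band_bounds_parsing():
    assert band_bounds("30-34") == (30, 34)
    assert band_bounds("80+") == (80, np.inf)
    with pytest.raises(ValueError):
        band_bounds("adult")


def stratified_records(strata):
    """strata: list of (sex, band, n, n_positive) for the hypertension flag."""
    rows = []
    for sex, band, n, pos in strata:
        for i in range(n):
            rows.append({
                "region_id": "R", "year": 2008, "sex": sex, "age_group": band,
                "hypertension": 1.0 if i < pos else 0.0,
            })
    return make_records(rows)


class TestDirectStandardize:
    def test_equal_weights_average_rates(self):
        recs = stratified_records([("M", "30-39", 10, 1), ("F", "30-39", 10, 3)])
        std = bg.StandardPopulation({("M", "30-39"): 0.5, ("F", "30-39"): 0.5})
        assert bg.direct_standardize(recs, "hypertension", std) == pytest.approx(20.0)

    def test_hand_computed_weighted_sum(self):
        # rates 10%, 20%, 40% with weights .2/.3/.5 -> 28.0%
        recs = stratified_records(
            [("M", "30-39", 10, 1), ("M", "40-49", 10, 2), ("F", "30-39", 10, 4)]
        )
        std = bg.StandardPopulation({
            ("M", "30-39"): 0.2, ("M", "40-49"): 0.3, ("F", "30-39"): 0.5,
        })
        assert bg.direct_standardize(recs, "hypertension", std) == pytest.approx(28.0)

    def test_constant_rate_invariant_to_weights(self):
        recs = stratified_records([("M", "30-39", 10, 2), ("F", "60+", 5, 1)])
        for w in ({("M", "30-39"): 0.9, ("F", "60+"): 0.1},
                  {("M", "30-39"): 0.1, ("F", "60+"): 0.9}):
            std = bg.StandardPopulation(w)
            assert bg.direct_standardize(recs, "hypertension", std) == pytest.approx(20.0)

    def test_empirical_standard_reproduces_crude_rate(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(200):
            rows.append({
                "region_id": "R", "year": 2008,
                "sex": rng.choice(["M", "F"]),
                "age_group": rng.choice(["30-39", "40-49", "50-59"]),
                "hypertension": float(rng.random() < 0.3),
            })
        recs = make_records(rows)
        std = bg.StandardPopulation.from_records(recs)
        crude = 100.0 * recs["hypertension"].mean()
        assert bg.direct_standardize(recs, "hypertension", std) == pytest.approx(crude, abs=1e-10)

    def test_replication_invariance(self):
        recs = stratified_records([("M", "30-39", 7, 2), ("F", "40-49", 5, 1)])
        std = bg.StandardPopulation({("M", "30-39"): 0.4, ("F", "40-49"): 0.6})
        once = bg.direct_standardize(recs, "hypertension", std)
        thrice = bg.direct_standardize(
            pd.concat([recs] * 3, ignore_index=True), "hypertension", std
        )
        assert thrice == pytest.approx(once, abs=1e-12)

    def test_all_missing_rejected(self):
        recs = make_records(
            [{"region_id": "R", "year": 2008, "sex": "M", "age_group": "30-39"}]
        )
        with pytest.raises(ValueError, match="missing"):
            bg.direct_standardize(recs, "hypertension",
                                  bg.StandardPopulation({("M", "30-39"): 1.0}))

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bg.direct_standardize(make_records([]), "hypertension",
                                  bg.StandardPopulation({("M", "30-39"): 1.0}))


class TestBuildPanel:
    def eight_record_fixture(self):
        return make_records([
            {"region_id": "R", "year": 2008, "sex": "M", "age_group": "50-59",
             "hypertension": 1, "stroke": 0, "current_smoker": 1, "passive_home": 0,
             "passive_work": 0, "bmi": 24.0, "drinks_monthly": 1},
            {"region_id": "R", "year": 2008, "sex": "M", "age_group": "50-59",
             "hypertension": 0, "stroke": 0, "current_smoker": 1, "passive_home": 0,
             "passive_work": 1, "bmi": 22.0, "drinks_monthly": 0},
            {"region_id": "R", "year": 2008, "sex": "M", "age_group": "60-69",
             "hypertension": 1, "stroke": 1, "current_smoker": 0, "passive_home": 0,
             "passive_work": 0, "bmi": 25.0, "drinks_monthly": 1},
            {"region_id": "R", "year": 2008, "sex": "M", "age_group": "60-69",
             "hypertension": 1, "stroke": 0, "current_smoker": 0, "passive_home": 1,
             "passive_work": 0, "bmi": 23.0, "drinks_monthly": 0},
            {"region_id": "R", "year": 2008, "sex": "F", "age_group": "50-59",
             "hypertension": 0, "stroke": 0, "current_smoker": 0, "passive_home": 1,
             "passive_work": 0, "bmi": 21.0, "drinks_monthly": 0},
            {"region_id": "R", "year": 2008, "sex": "F", "age_group": "50-59",
             "hypertension": 0, "stroke": 0, "current_smoker": 0, "passive_home": 0,
             "passive_work": 0, "bmi": 26.0, "drinks_monthly": 1},
            {"region_id": "R", "year": 2008, "sex": "F", "age_group": "60-69",
             "hypertension": 1, "stroke": 0, "current_smoker": 0, "passive_home": 1,
             "passive_work": 0, "bmi": 27.0, "drinks_monthly": 0},
            {"region_id": "R", "year": 2008, "sex": "F", "age_group": "60-69",
             "hypertension": 0, "stroke": 1, "current_smoker": 1, "passive_home": 0,
             "passive_work": 0, "bmi": 24.0, "drinks_monthly": 1},
        ])

    def test_matches_brute_force_on_fixture(self):
        recs = self.eight_record_fixture()
        panel = bg.build_panel(recs, min_cell_size=1)
        # empirical standard: 2 respondents per stratum, weight 1/4 each;
        # every stratum rate is k/2 -> standardized = crude mean
        hyp = panel.prevalence.query("outcome == 'hypertension'").iloc[0]
        assert hyp["prevalence"] == pytest.approx(100 * 4 / 8)
        stroke = panel.prevalence.query("outcome == 'stroke'").iloc[0]
        assert stroke["prevalence"] == pytest.approx(100 * 2 / 8)
        cov = panel.covariates.iloc[0]
        assert cov["smoking_rate"] == pytest.approx(100 * 3 / 8)
        assert cov["mean_bmi"] == pytest.approx(24.0)
        assert cov["drinking_rate"] == pytest.approx(100 * 4 / 8)

    def test_duplication_leaves_panel_unchanged(self):
        recs = self.eight_record_fixture()
        p1 = bg.build_panel(recs, min_cell_size=1)
        p2 = bg.build_panel(pd.concat([recs] * 2, ignore_index=True), min_cell_size=1)
        pd.testing.assert_frame_equal(
            p1.prevalence.drop(columns=["n_respondents", "low_n"]),
            p2.prevalence.drop(columns=["n_respondents", "low_n"]),
        )

    def test_zero_case_cell_flagged_nonpositive(self):
        recs = self.eight_record_fixture()
        recs["stroke"] = 0.0
        panel = bg.build_panel(recs, min_cell_size=1)
        stroke = panel.prevalence.query("outcome == 'stroke'").iloc[0]
        assert stroke["prevalence"] == 0.0 and bool(stroke["nonpositive"])

    def test_missing_standard_year_rejected(self):
        recs = self.eight_record_fixture()
        std = bg.StandardPopulation({("M", "50-59"): 1.0})
        with pytest.raises(ValueError, match="2008"):
            bg.build_panel(recs, standard_by_year={2007: std})


class TestNormalityScreen:
    def make_panel(self, values):
        prev = pd.DataFrame({
            "region_id": [f"R{i}" for i in range(len(values))],
            "year": 2008, "outcome": "stroke", "prevalence": values,
            "n_respondents": 100, "nonpositive": False, "low_n": False,
        })
        cov = pd.DataFrame({"region_id": prev["region_id"], "year": 2008})
        return bg.RegionYearPanel(prev, cov)

    def test_skewed_gamma_flagged_non_normal(self):
        vals = np.random.default_rng(0).gamma(2.0, 1.0, 500)
        assert bg.normality_screen(self.make_panel(vals), "stroke")["verdict"] == "non-normal"

    def test_gaussian_passes(self):
        vals = 20 + np.random.default_rng(1).standard_normal(500)
        assert bg.normality_screen(self.make_panel(vals), "stroke")["verdict"] == "normal"

    def test_constant_values_flagged_degenerate(self):
        assert bg.normality_screen(self.make_panel([5.0] * 5), "stroke")["verdict"] == "degenerate"

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            bg.normality_screen(self.make_panel([1.0, 2.0]), "stroke")
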