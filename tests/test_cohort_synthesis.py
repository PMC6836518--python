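"""Synthetic patient generator, imputation rules and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest

from bridgesurv.cohort_synthesis import (CohortSpec, check_cohort_invariants,
                                         dichotomize_swallowing,
                                         generate_life_table,
                                         generate_tma_like_dataset,
                                         generate_virtual_cohort,
                                         impute_aspiration_pneumonia,
                                         sample_general_pop_6mwd,
                                         spearman_matrix)


class TestSpecValidation:
    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            CohortSpec(prev_falls=1.2)

    def test_severity_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortSpec(severity_probs=(0.5, 0.5, 0.5))

    def test_ap_probability_bound(self):
        with pytest.raises(ValueError):
            CohortSpec(ap_baseline_prev=0.2, ap_rr_given_dysphagia=9.1)


class TestTmaLikeDataset:
    def test_default_size_and_invariants(self):
        df = generate_tma_like_dataset(CohortSpec(n=102, seed=5))
        assert len(df) == 102
        check_cohort_invariants(df)
        assert (df["age"] >= 45.0).all()

    def test_reproducible(self):
        a = generate_tma_like_dataset(CohortSpec(seed=7))
        b = generate_tma_like_dataset(CohortSpec(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_dysphagia_prevalence(self):
        df = generate_tma_like_dataset(CohortSpec(n=500, prev_dysphagia=0.0, seed=1))
        assert (df["swallow_score"] == 0).all()
        assert (df["dysphagia"] == 0).all()

    def test_prevalences_concentrate(self):
        n = 100_000
        spec = CohortSpec(n=n, prev_falls=0.4, prev_dysphagia=0.5, seed=3)
        df = generate_tma_like_dataset(spec)
        for col, p in (("falls", 0.4), ("dysphagia", 0.5)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(df[col].mean() - p) < 3 * se

    def test_severity_forces_wheelchair_and_zero_walk(self):
        df = generate_tma_like_dataset(
            CohortSpec(n=300, severity_probs=(0.0, 0.0, 1.0), seed=2))
        assert (df["wheelchair"] == 1).all()
        assert (df["six_mwd"] == 0.0).all()


@pytest.mark.parametrize("score,expected", [(0.0, 0), (1.0, 1), (0.5, 0),
                                            (10.0, 1), (0.999, 0)])
def test_dichotomize_swallowing(score, expected):
    assert dichotomize_swallowing(score) == expected


def test_dichotomize_negative_rejected():
    with pytest.raises(ValueError):
        dichotomize_swallowing(-0.1)


class TestAspirationPneumonia:
    def test_frequencies_match_risk_ratio(self):
        spec = CohortSpec()
        rng = np.random.default_rng(11)
        n = 100_000
        with_dys = np.mean([impute_aspiration_pneumonia(1, spec, rng) for _ in range(n)])
        without = np.mean([impute_aspiration_pneumonia(0, spec, rng) for _ in range(n)])
        assert with_dys == pytest.approx(0.091, abs=3 * np.sqrt(0.091 * 0.909 / n))
        assert without == pytest.approx(0.010, abs=3 * np.sqrt(0.01 * 0.99 / n))

    def test_unit_risk_ratio_ignores_dysphagia(self):
        spec = CohortSpec(ap_rr_given_dysphagia=1.0)
        a = [impute_aspiration_pneumonia(1, spec, np.random.default_rng(s)) for s in range(200)]
        b = [impute_aspiration_pneumonia(0, spec, np.random.default_rng(s)) for s in range(200)]
        assert a == b


class TestSpearman:
    def test_self_correlation(self):
        df = pd.DataFrame({"x": np.arange(20.0), "y": np.arange(20.0) ** 2})
        mat = spearman_matrix(df, ["x", "y"])
        assert mat.loc["x", "x"] == 1.0
        assert mat.loc["x", "y"] == pytest.approx(1.0)  # monotone, no ties

    def test_anticorrelation(self):
        df = pd.DataFrame({"x": np.arange(20.0), "y": -np.arange(20.0)})
        assert spearman_matrix(df, ["x", "y"]).loc["x", "y"] == pytest.approx(-1.0)

    def test_constant_column_flagged_not_zero(self):
        df = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            mat = spearman_matrix(df, ["x", "c"])
        assert np.isnan(mat.loc["x", "c"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"x": [1.0, 2.0]}), ["x"])

    def test_wheelchair_walkdistance_structurally_negative(self):
        df = generate_tma_like_dataset(CohortSpec(n=2000, seed=4))
        mat = spearman_matrix(df, ["wheelchair", "six_mwd"])
        assert mat.loc["wheelchair", "six_mwd"] < 0

    def test_interdependence_screen_default_cohort(self):
        """Only wheelchair-6MWD (and possibly wheelchair-falls) correlate
        noticeably; every other predictor pair stays below |rho| = 0.3."""
        df = generate_tma_like_dataset(CohortSpec(n=5000, seed=6))
        variables = ["six_mwd", "dysphagia", "falls", "wheelchair",
                     "aspiration_pneumonia"]
        mat = spearman_matrix(df, variables)
        exempt = {frozenset({"wheelchair", "six_mwd"}),
                  frozenset({"wheelchair", "falls"})}
        for i, a in enumerate(variables):
            for b in variables[i + 1:]:
                if frozenset({a, b}) in exempt:
                    continue
                assert abs(mat.loc[a, b]) < 0.3, (a, b)
        assert mat.loc["wheelchair", "six_mwd"] < -0.3


class TestVirtualCohort:
    STUDY = {"age_mean": 66.0, "age_sd": 8.0, "prop_male": 0.7}

    def test_matches_study_age_sex(self):
        n = 50_000
        df = generate_virtual_cohort(CohortSpec(seed=8), self.STUDY, n=n)
        assert df["age"].mean() == pytest.approx(66.5, abs=1.0)  # truncation shifts up
        assert (df["sex"] == "male").mean() == pytest.approx(0.7, abs=0.01)
        check_cohort_invariants(df)

    def test_zero_prevalences_give_general_population_covariates(self):
        spec = CohortSpec(prev_falls=0.0, prev_dysphagia=0.0,
                          ap_baseline_prev=0.0, severity_probs=(1.0, 0.0, 0.0))
        df = generate_virtual_cohort(spec, self.STUDY, n=1000)
        assert df[["falls", "dysphagia", "aspiration_pneumonia",
                   "wheelchair"]].to_numpy().sum() == 0

    def test_walk_distance_declines_with_age(self):
        df = generate_virtual_cohort(CohortSpec(seed=9), self.STUDY, n=20_000)
        walkers = df[df["wheelchair"] == 0]
        slope = np.polyfit(walkers["age"], walkers["six_mwd"], 1)[0]
        assert slope < 0


class TestReference6MWD:
    def test_zero_sd_returns_band_mean(self):
        params = {"male": [(45, 121, 500.0, 0.0)]}
        assert sample_general_pop_6mwd(60.0, "male", params) == 500.0

    def test_missing_band_rejected(self):
        params = {"male": [(45, 55, 500.0, 10.0)]}
        with pytest.raises(KeyError):
            sample_general_pop_6mwd(70.0, "male", params)

    def test_floored_at_zero(self):
        params = {"male": [(45, 121, 5.0, 200.0)]}
        rng = np.random.default_rng(0)
        draws = sample_general_pop_6mwd(np.full(500, 60.0), "male", params, rng=rng)
        assert np.all(draws >= 0.0)

    def test_default_calibration_anchor(self):
        """Median walking deficit of the default synthetic cohort versus the
        reference distribution sits near the 281 m calibration anchor."""
        from bridgesurv.cohort_synthesis import attach_reference_6mwd
        spec = CohortSpec(n=50_000, seed=7)
        rng = np.random.default_rng(7)
        df = generate_virtual_cohort(spec, {"age_mean": spec.age_mean,
                                            "age_sd": spec.age_sd,
                                            "prop_male": spec.prop_male}, rng=rng)
        df = attach_reference_6mwd(df, rng=rng)
        assert np.median(df["d6mwd"]) == pytest.approx(281.0, abs=15.0)


class TestLifeTableFixture:
    def test_constant_hazard_when_shape_one(self):
        table = generate_life_table(1.0, 60.0)
        rates = table.for_sex("male")["death_rate"]
        assert rates.max() - rates.min() < 1e-12

    def test_larger_scale_means_lower_rates(self):
        male = generate_life_table(5.0, 80.0, sex="male")
        female = generate_life_table(5.0, 90.0, sex="female")
        assert (female.for_sex("female")["death_rate"].to_numpy()
                < male.for_sex("male")["death_rate"].to_numpy()).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_life_table(-1.0, 80.0)
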