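"""Statistical layer: response ratios, mixed models, group contrasts, power."""

import numpy as np
import pandas as pd
import pytest

from cerebroquant.config import default_config
from cerebroquant.stats import (
    detectable_difference,
    fit_group_differences,
    fit_mixed_response,
    fit_volume_response_assoc,
    power_sample_size,
    response_ratio,
)
from cerebroquant.synthetic.cohort import cohort_to_wide, generate_cohort


class TestResponseRatio:
    def test_lactate_example(self):
        r = response_ratio(0.53, 0.62, 98.0, 78.0)
        assert r.dvalue_per_dsat == pytest.approx(0.0045)

    def test_cbf_example(self):
        assert response_ratio(42.0, 50.0, 98.0, 78.0).dvalue_per_dsat == \
            pytest.approx(0.40)

    def test_no_change_is_zero(self):
        assert response_ratio(1.0, 1.0, 98.0, 80.0).dvalue_per_dsat == 0.0

    def test_non_positive_desaturation_rejected(self):
        with pytest.raises(ValueError, match="desaturation"):
            response_ratio(1.0, 2.0, 80.0, 80.0)

    def test_equals_two_point_regression_slope(self, wide_df):
        """The ratio is exactly the per-subject slope vs SaO2 (sign flipped)."""
        for _, row in wide_df.head(10).iterrows():
            slope = np.polyfit([row.sao2_normoxia, row.sao2_hypoxia],
                               [row.lactate_normoxia, row.lactate_hypoxia], 1)[0]
            assert row.lactate_ratio == pytest.approx(-slope, rel=1e-9)


class TestMixedModel:
    def test_noiseless_single_group_slope_exact(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(12):
            a = 1.5 + 0.1 * rng.standard_normal()
            for s in (98.0, 77.0 + 0.3 * i):
                rows.append(dict(subject_id=f"s{i}", group="healthy", sao2=s,
                                 lactate=a - 0.01 * s, age=50.0 + i, sex=i % 2,
                                 mrs_gm_fraction=0.5))
        with pytest.warns(UserWarning, match="single group"):
            fit = fit_mixed_response(pd.DataFrame(rows), "lactate")
        assert fit.slope_sao2 == pytest.approx(-0.0100, abs=1e-10)
        assert fit.residual_var == pytest.approx(0.0, abs=1e-12)

    def test_baseline_shift_invariance(self, long_df):
        """Adding a per-subject constant to both conditions leaves the
        saturation slope and interactions essentially unchanged: the random
        intercept absorbs baseline differences, so only the response to
        desaturation is tested.  (Invariance is exact in the large
        intercept-variance limit; partial pooling permits a ~2% shift.)"""
        fit0 = fit_mixed_response(long_df, "lactate", include_gm_covariate=True)
        shifted = long_df.copy()
        offs = {sid: 0.11 * i for i, sid in
                enumerate(shifted.subject_id.unique())}
        shifted["lactate"] = shifted["lactate"] + shifted.subject_id.map(offs)
        fit1 = fit_mixed_response(shifted, "lactate", include_gm_covariate=True)
        assert fit1.slope_sao2 == pytest.approx(fit0.slope_sao2, rel=0.02)
        for g in fit0.interaction:
            assert fit1.interaction[g]["estimate"] == pytest.approx(
                fit0.interaction[g]["estimate"], abs=0.02 * abs(fit0.slope_sao2))

    def test_row_order_invariance(self, long_df):
        fit0 = fit_mixed_response(long_df, "lactate", include_gm_covariate=True)
        shuffled = long_df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit1 = fit_mixed_response(shuffled, "lactate", include_gm_covariate=True)
        pd.testing.assert_frame_equal(
            fit0.coefficients.sort_index(), fit1.coefficients.sort_index(),
            atol=1e-8, rtol=1e-6)

    def test_interaction_sign_convention(self, long_df):
        """Albuminuria-minus-healthy lactate interaction is positive (blunted
        rise under desaturation) while the healthy slope is negative."""
        fit = fit_mixed_response(long_df, "lactate", include_gm_covariate=True)
        assert fit.slope_sao2 < 0
        assert fit.interaction["t1d_alb"]["estimate"] > 0
        ci = fit.interaction["t1d_alb"]
        assert ci["ci_low"] <= ci["estimate"] <= ci["ci_high"]

    def test_missing_response_column_rejected(self, long_df):
        with pytest.raises(ValueError, match="not found"):
            fit_mixed_response(long_df, "glucose")

    def test_unit_rescaling_rescales_coefficients(self, long_df):
        scaled = long_df.copy()
        scaled["lactate"] = scaled["lactate"] * 1000.0   # mmol/l -> umol/l
        a = fit_mixed_response(long_df, "lactate", include_gm_covariate=True)
        b = fit_mixed_response(scaled, "lactate", include_gm_covariate=True)
        assert b.slope_sao2 == pytest.approx(1000.0 * a.slope_sao2, rel=1e-6)


class TestGroupDifferences:
    def test_identical_groups_null_contrast(self, rng):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(60)],
            "group": ["healthy"] * 20 + ["t1d_no_alb"] * 20 + ["t1d_alb"] * 20,
            "tbv": 1100.0 + 50.0 * rng.standard_normal(60),
            "sex": rng.integers(0, 2, 60),
            "age": 45.0 + 10.0 * rng.standard_normal(60),
        })
        tab = fit_group_differences(df, "tbv")
        assert abs(tab.loc["t1d_alb_vs_healthy", "estimate"]) < 40.0
        assert tab.loc["t1d_alb_vs_healthy", "pvalue"] > 0.05

    def test_injected_albuminuria_deficit_recovered(self):
        """A direct -86 ml albuminuria effect with no confounding is
        recovered without bias over replicate cohorts."""
        ests = []
        for s in range(300):
            cfg = default_config(seed=5000 + s)
            w = cohort_to_wide(generate_cohort(cfg))
            w["tbv_mod"] = 1100.0 + np.random.default_rng(s).normal(0, 60, len(w))
            w.loc[w.group == "t1d_alb", "tbv_mod"] -= 86.0
            tab = fit_group_differences(w, "tbv_mod")
            ests.append(tab.loc["t1d_alb_vs_healthy", "estimate"])
        assert np.mean(ests) == pytest.approx(-86.0, rel=0.10)

    def test_pure_age_effect_leaves_contrast_unbiased(self, rng):
        """With balanced ages, an outcome driven purely by age yields a null
        adjusted group contrast."""
        n = 90
        age = 40.0 + 15.0 * rng.standard_normal(n)
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": (["healthy", "t1d_no_alb", "t1d_alb"] * (n // 3)),
            "age": age, "sex": rng.integers(0, 2, n),
            "y": -3.0 * age + rng.standard_normal(n),
        })
        tab = fit_group_differences(df, "y")
        assert abs(tab.loc["t1d_alb_vs_healthy", "estimate"]) < 1.0

    def test_constant_outcome_rejected(self, wide_df):
        df = wide_df.copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_group_differences(df, "flat")


class TestVolumeResponse:
    def test_partial_regression_matches_full_fit(self, wide_df):
        """Frisch-Waugh: the slope of the residualized scatter equals the
        covariate-adjusted regression slope."""
        res = fit_volume_response_assoc(wide_df, "tbv", "lactate_ratio")
        slope = np.polyfit(res.partial["ratio_resid"],
                           res.partial["volume_resid"], 1)[0]
        assert slope == pytest.approx(res.slope, rel=1e-6)

    def test_patients_only_subset(self, wide_df):
        res = fit_volume_response_assoc(wide_df, "tbv", "lactate_ratio",
                                        patients_only=True)
        assert res.n == (wide_df.group != "healthy").sum()
        assert (res.partial["group"] != "healthy").all()

    def test_null_association_small_t(self, rng):
        """A response unrelated to volume gives slope ~0 over replicates."""
        zs = []
        for s in range(100):
            g = np.random.default_rng(s)
            df = pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(52)],
                "group": ["healthy"] * 52,
                "vol": 1100 + 100 * g.standard_normal(52),
                "ratio": 0.01 + 0.005 * g.standard_normal(52),
                "sex": g.integers(0, 2, 52),
                "age": 45 + 12 * g.standard_normal(52),
                "mrs_gm_fraction": 0.55 + 0.05 * g.standard_normal(52),
            })
            r = fit_volume_response_assoc(df, "vol", "ratio")
            zs.append(r.slope / ((r.ci_high - r.ci_low) / 3.92))
        assert abs(np.mean(zs)) < 0.3

    def test_zero_variance_regressor_rejected(self, wide_df):
        df = wide_df.copy()
        df["lactate_ratio"] = 0.005
        with pytest.raises(ValueError, match="zero variance"):
            fit_volume_response_assoc(df, "tbv", "lactate_ratio")


class TestPower:
    def test_study_sample_size_reproduced(self):
        """sigma 10.8%, alpha 0.05, power 0.80 and the implied detectable
        difference (~13.5%) give 10 participants per group."""
        delta = detectable_difference(10.8, 0.05, 0.80, 10)
        assert delta == pytest.approx(13.53, abs=0.01)
        assert power_sample_size(10.8, 0.05, 0.80, delta) == 10

    def test_huge_effect_hits_floor(self):
        assert power_sample_size(10.8, 0.05, 0.80, 1e6) == 2

    def test_sd_scaling_quadruples_n(self):
        n1 = power_sample_size(10.0, 0.05, 0.80, 5.0)
        n4 = power_sample_size(20.0, 0.05, 0.80, 5.0)
        assert n1 * 4 - 3 <= n4 <= n1 * 4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_sample_size(10.0, 0.05, 0.80, 0.0)
        with pytest.raises(ValueError):
            power_sample_size(-1.0, 0.05, 0.80, 5.0)
        with pytest.raises(ValueError):
            power_sample_size(10.0, 1.5, 0.80, 5.0)
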