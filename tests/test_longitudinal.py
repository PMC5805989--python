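"""Random-intercept models, variance decomposition and permutation nulls."""

import numpy as np
import pandas as pd
import pytest

from contactdiaries.longitudinal import (
    ModelSpec,
    _permute_within_waves,
    accumulation_analysis,
    contribution_table,
    fit_random_intercept,
    percentage_contribution,
    quantile_consistency,
    variance_shares,
)

from conftest import rates_frame


def balanced_rates(n, k, sigma_b, sigma_w, seed, wave_effects=None):
    """Balanced panel with known Gaussian structure on the log1p scale."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0, sigma_b, n)
    eff = np.zeros(k) if wave_effects is None else np.asarray(wave_effects)
    y = b[:, None] + eff[None, :] + rng.normal(0, sigma_w, (n, k))
    return rates_frame(np.expm1(y)), y


def anova_two_way(y):
    """Closed-form balanced variance components with additive wave effects."""
    n, k = y.shape
    grand, rm, cm = y.mean(), y.mean(axis=1), y.mean(axis=0)
    sse = ((y - rm[:, None] - cm[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    msp = k * rm.var(ddof=1)
    return (msp - mse) / k, mse


class TestRandomInterceptFit:
    def test_balanced_reml_matches_closed_form_anova(self):
        rates, y = balanced_rates(150, 4, 0.9, 1.2, seed=3,
                                  wave_effects=[0.0, 0.3, -0.2, 0.1])
        fitted = fit_random_intercept(rates, ModelSpec("K", include_location=False))
        s2b, s2w = anova_two_way(y)
        assert fitted.sigma2_between == pytest.approx(s2b, rel=1e-6)
        assert fitted.sigma2_within == pytest.approx(s2w, rel=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rates, y = balanced_rates(120, 3, 0.7, 1.0, seed=8)
        fitted = fit_random_intercept(rates, ModelSpec("K", include_location=False))
        df = rates.copy()
        df["y"] = np.log1p(df["K"])
        sm = smf.mixedlm("y ~ C(wave)", df, groups=df["participant_id"]).fit(reml=True)
        assert fitted.sigma2_between == pytest.approx(
            float(np.asarray(sm.cov_re)[0, 0]), rel=1e-4
        )
        assert fitted.sigma2_within == pytest.approx(float(sm.scale), rel=1e-4)
        np.testing.assert_allclose(
            fitted.fixed_effects.to_numpy(), sm.fe_params.to_numpy(), rtol=1e-4
        )

    def test_independent_observations_give_boundary_between_variance(self):
        rates, _ = balanced_rates(2000, 2, 0.0, 1.0, seed=1)
        fitted = fit_random_intercept(rates, ModelSpec("K", include_location=False))
        total = fitted.sigma2_between + fitted.sigma2_within
        assert fitted.sigma2_between <= 1e-6 * total

    def test_rank_deficient_design_names_aliased_columns(self):
        rates, _ = balanced_rates(30, 2, 0.5, 1.0, seed=2)
        rates["wave"] = "R1"
        rates["weekday"] = np.where(rates.index % 2 == 0, "Mon", "Mon")
        # single-level factors drop out; duplicate a real covariate instead
        rates.loc[: len(rates) // 2, "weekday"] = "Tue"
        rates["age_group"] = np.where(rates["weekday"] == "Tue", "20-39", "40-64")
        with pytest.raises(ValueError, match="aliased"):
            fit_random_intercept(rates, ModelSpec("K", include_location=False))

    def test_too_few_participants_is_an_error(self):
        rates, _ = balanced_rates(1, 4, 0.5, 1.0, seed=0)
        with pytest.raises(ValueError):
            fit_random_intercept(rates, ModelSpec("K", include_location=False))


class TestVarianceShares:
    @pytest.mark.parametrize(
        "s2b,s2w,expected", [(1.0, 1.0, 0.5), (0.0, 2.0, 0.0), (3.0, 1.0, 0.75)]
    )
    def test_share_definition(self, s2b, s2w, expected):
        from contactdiaries.longitudinal import VarianceDecomposition

        vd = VarianceDecomposition(sigma2_between=s2b, sigma2_within=s2w)
        assert vd.between_share == pytest.approx(expected)
        assert vd.between_share + vd.within_share == pytest.approx(1.0)

    def test_recovery_on_synthetic_panel(self):
        rates, _ = balanced_rates(800, 4, np.sqrt(1.0), np.sqrt(2.0), seed=5)
        vd = variance_shares(
            fit_random_intercept(rates, ModelSpec("K", include_location=False))
        )
        assert vd.between_share == pytest.approx(1 / 3, abs=0.05)


class TestPercentageContribution:
    def _toy_fit(self, beta=0.8, seed=4):
        rng = np.random.default_rng(seed)
        n = 200
        rows = []
        for i in range(n):
            sex = "male" if i % 2 == 0 else "female"
            for j in range(2):
                y = 1.2 + (beta if sex == "female" else 0.0) + rng.normal(0, 0.3)
                rows.append({"participant_id": f"p{i}", "wave": f"R{j+1}",
                             "K": np.expm1(y), "L": 1, "D": np.nan,
                             "weekday": "Mon", "typical_day": "typical",
                             "age_years": 35.0, "age_group": "20-39", "sex": sex,
                             "household_size": 1, "K_home": 0, "K_schoolwork": 0,
                             "K_other": 0, "K_unknown_setting": 0})
        return fit_random_intercept(
            pd.DataFrame(rows), ModelSpec("K", include_location=False)
        )

    def test_comparator_profile_is_100_percent(self):
        fitted = self._toy_fit()
        comparator = {"age_group": "20-39", "sex": "male", "weekday": "Mon",
                      "wave": "R1"}
        assert percentage_contribution(fitted, {}, comparator) == pytest.approx(100.0)

    def test_single_binary_covariate_matches_hand_calculation(self):
        fitted = self._toy_fit()
        comparator = {"age_group": "20-39", "sex": "male", "weekday": "Mon",
                      "wave": "R1"}
        got = percentage_contribution(fitted, {"sex": "female"}, comparator)
        coefs = fitted.fixed_effects
        # treatment coding: intercept is the female reference level, the
        # single sex coefficient is the male offset
        a = coefs["Intercept"]
        beta_male = coefs[[c for c in coefs.index if "sex" in c][0]]
        expected = 100.0 * np.expm1(a) / np.expm1(a + beta_male)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_location_contributions_increase_with_location_count(self):
        from contactdiaries.io_model import derive_rates
        from contactdiaries.synthetic import SyntheticConfig, generate

        cfg = SyntheticConfig(n_households=400, location_coupling=0.9)
        rates = derive_rates(generate(cfg, seed=14))
        fitted = fit_random_intercept(rates, ModelSpec("K"))
        table = contribution_table(fitted)
        loc = table[table["covariate"] == "loc_cat"].set_index("level")
        values = loc.loc[["1", "2", "3", "4", "5", "6+"], "percent_of_comparator"]
        assert values.is_monotonic_increasing


class TestAccumulation:
    def test_constant_identical_series_has_zero_cv_everywhere(self):
        rates = rates_frame(np.full((20, 4), 7.0))
        res = accumulation_analysis(rates, "K", null_reps=50, seed=0)
        assert np.allclose(res.observed_cv, 0.0)
        assert np.allclose(res.null_mean, 0.0)

    def test_horizon_one_equals_plain_between_participant_cv(self):
        rng = np.random.default_rng(9)
        values = rng.poisson(10, size=(100, 4)).astype(float)
        res = accumulation_analysis(rates_frame(values), "K", null_reps=20, seed=0)
        w1 = values[:, 0]
        assert res.observed_cv[0] == pytest.approx(w1.std(ddof=1) / w1.mean())

    def test_persistent_participants_exceed_null_envelope(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0, 1.0, 150)
        values = np.expm1(2.0 + b[:, None] + rng.normal(0, 0.3, (150, 4)))
        res = accumulation_analysis(rates_frame(values), "K", null_reps=300, seed=1)
        assert res.observed_cv[3] > res.null_high[3]

    def test_independent_waves_fall_inside_envelope(self):
        rng = np.random.default_rng(4)
        values = np.expm1(rng.normal(2.0, 1.0, (150, 4)))
        res = accumulation_analysis(rates_frame(values), "K", null_reps=300, seed=1)
        assert res.null_low[3] <= res.observed_cv[3] <= res.null_high[3]

    def test_too_few_complete_participants_is_an_error(self):
        rates = rates_frame(np.ones((1, 4)))
        with pytest.raises(ValueError):
            accumulation_analysis(rates, "K", null_reps=10, seed=0)


class TestQuantileConsistency:
    def test_single_quantile_everyone_consistent(self):
        rng = np.random.default_rng(0)
        rates = rates_frame(rng.poisson(10, (50, 4)).astype(float))
        res = quantile_consistency(rates, "K", quantile_grid=(1,), null_reps=20, seed=0)
        assert res.observed_percent[0] == pytest.approx(100.0)
        assert np.allclose(res.null_mean, 100.0)

    def test_null_matches_independence_closed_form(self):
        rng = np.random.default_rng(1)
        values = rng.normal(10, 3, size=(400, 4))
        res = quantile_consistency(
            rates_frame(values), "K", quantile_grid=(2, 4), null_reps=400, seed=2
        )
        # closed form for 4 independent waves: 100·(1/q)³
        for j, q in enumerate((2, 4)):
            expected = 100.0 * (1 / q) ** 3
            se = res.null_percent_se(j) if hasattr(res, "null_percent_se") else None
            assert res.null_mean[j] == pytest.approx(expected, rel=0.15)
            assert res.independence_percent[j] == pytest.approx(expected)

    def test_persistent_participants_beat_null_at_every_grid_point(self):
        rng = np.random.default_rng(5)
        b = rng.normal(0, 1.2, 300)
        values = np.expm1(2.0 + b[:, None] + rng.normal(0, 0.5, (300, 4)))
        res = quantile_consistency(
            rates_frame(values), "K", quantile_grid=(2, 3, 4, 5), null_reps=200, seed=3
        )
        assert (res.observed_percent > res.null_high).all()

    def test_permutation_preserves_wave_marginals_exactly(self):
        rng = np.random.default_rng(6)
        values = rng.poisson(12, size=(80, 4)).astype(float)
        permuted = _permute_within_waves(values, rng)
        for j in range(4):
            assert sorted(values[:, j]) == sorted(permuted[:, j])
        assert not np.array_equal(values, permuted)
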