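import math

import numpy as np
import pandas as pd
import pytest

from burstloco.errors import InsufficientDataError, ValidationError
from burstloco.ontogeny import (boxcox_z, cohen_d_category, compare_groups,
                                compare_linear_quadratic, correlation_power,
                                fit_allometry, fit_growth_model,
                                fit_quadratic, invert_one_tailed_p,
                                one_tailed_pearson, repeatability_icc,
                                required_n, vertex)
from burstloco.simulate import CohortSimParams, simulate_cohort


def _peak_df(masses, values):
    return pd.DataFrame({"rabbit_id": [f"r{i}" for i in range(len(masses))],
                         "body_mass_kg": masses, "value": values})


class TestQuadraticFit:
    def test_exact_parabola_recovered(self):
        m = np.linspace(0.2, 1.4, 25)
        y = 5.0 + 3.0 * m - 4.0 * m**2
        fit = fit_quadratic(_peak_df(m, y), level="per-peak")
        np.testing.assert_allclose(fit.coef, [5.0, 3.0, -4.0], atol=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_linear_data_favours_linear_model(self):
        """AICc prefers the linear model on truly linear data in the large
        majority of noise realisations (the spurious-curvature win rate
        under the null is ~10%)."""
        m = np.linspace(0.2, 1.4, 40)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = 1.0 + 2.0 * m + rng.normal(0, 0.1, 40)
            lin, quad = compare_linear_quadratic(_peak_df(m, y),
                                                 level="per-peak")
            wins += lin.aicc < quad.aicc
        assert wins >= 7

    def test_quadratic_beats_linear_on_synthetic_cohort(self, default_cohort):
        trials = default_cohort.trials
        for level in ("per-peak", "per-trial"):
            lin, quad = compare_linear_quadratic(trials, level=level,
                                                 response_col="a_com")
            assert quad.aicc < lin.aicc

    def test_mixed_model_matches_statsmodels_homoscedastic(self):
        """Cross-check the in-package ML variance components against
        statsmodels MixedLM on a homoscedastic random-intercept design."""
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        n_g, n_per = 30, 6
        g = np.repeat(np.arange(n_g), n_per)
        mass = np.tile(np.linspace(0.3, 1.3, n_g), n_per)
        b = rng.normal(0, 0.5, n_g)
        y = 2.0 + 1.5 * mass[np.argsort(g)] * 0  # start flat
        mass = np.repeat(np.linspace(0.3, 1.3, n_g), n_per)
        y = 2.0 + 1.5 * mass + b[g] + rng.normal(0, 0.7, n_g * n_per)
        df = pd.DataFrame({"rabbit_id": g, "body_mass_kg": mass, "value": y})
        from burstloco.ontogeny import _fit_mixed
        beta, s0, c, sb, ll, r2, *_ = _fit_mixed(
            df, 1, "body_mass_kg", "value", "rabbit_id", fit_var_slope=False)
        ml = sm.MixedLM.from_formula("value ~ body_mass_kg", groups="rabbit_id",
                                     data=df).fit(reml=False)
        np.testing.assert_allclose(beta, ml.fe_params.values, rtol=1e-3)
        assert sb**2 == pytest.approx(float(ml.cov_re.iloc[0, 0]), rel=0.05)
        assert s0**2 == pytest.approx(ml.scale, rel=0.05)


class TestVertex:
    def test_constructed_vertex(self):
        m = np.linspace(0.3, 1.2, 20)
        y = 5.0 - (m - 0.74)**2
        fit = fit_quadratic(_peak_df(m, y), level="per-peak")
        assert fit.vertex_mass == pytest.approx(0.74, abs=1e-8)

    def test_no_interior_maximum_raises(self):
        m = np.linspace(0.3, 1.2, 20)
        fit = fit_quadratic(_peak_df(m, 1.0 + (m - 0.7)**2), level="per-peak")
        with pytest.raises(ValidationError, match="maximum"):
            fit.vertex_mass

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        m = np.linspace(0.3, 1.2, 30)
        y = 5.0 - 3.0 * (m - 0.8)**2 + rng.normal(0, 0.2, 30)
        v1 = fit_quadratic(_peak_df(m, y), level="per-peak").vertex_mass
        v2 = fit_quadratic(_peak_df(m + 0.5, y), level="per-peak").vertex_mass
        assert v2 - v1 == pytest.approx(0.5, abs=1e-4)

    def test_bootstrap_ci_covers_truth(self, default_cohort):
        quad = fit_quadratic(default_cohort.trials, level="per-peak",
                             response_col="a_com")
        est = vertex(quad, n_boot=400, seed=0)
        lo, hi = est.ci_mass_kg
        assert lo <= est.peak_mass_kg <= hi
        assert lo <= 0.74 <= hi

    def test_vertex_age_via_growth_model(self, default_cohort):
        # synthetic reference growth table: age = 140 * mass^(1/3)
        m = np.linspace(0.05, 1.5, 25)
        ref = pd.DataFrame({"age_days": 140 * np.cbrt(m), "body_mass_kg": m})
        growth = fit_growth_model(ref)
        quad = fit_quadratic(default_cohort.trials, level="per-peak",
                             response_col="a_com")
        est = vertex(quad, growth=growth, n_boot=200, seed=0)
        assert est.peak_age_days == pytest.approx(
            140 * est.peak_mass_kg ** (1 / 3), rel=0.01)
        assert est.ci_age_days[0] <= est.peak_age_days <= est.ci_age_days[1]


class TestGrowthModel:
    def test_exact_cubic_recovery(self):
        m = np.linspace(0.05, 1.5, 30)
        u = np.cbrt(m)
        age = 10 + 20 * u + 30 * u**2 + 40 * u**3
        g = fit_growth_model(pd.DataFrame({"age_days": age,
                                           "body_mass_kg": m}))
        np.testing.assert_allclose(g.coef, [10, 20, 30, 40], atol=1e-8)
        assert g.monotone
        assert g.predict_age(1.0) == pytest.approx(100.0)
        assert g.mae < 1e-8 and g.rmse < 1e-8

    def test_extrapolation_warns(self):
        m = np.linspace(0.2, 1.0, 10)
        g = fit_growth_model(pd.DataFrame({
            "age_days": 100 * np.cbrt(m), "body_mass_kg": m}))
        with pytest.warns(UserWarning, match="outside"):
            g.predict_age(2.0)

    def test_non_monotone_curve_flagged(self):
        m = np.linspace(0.05, 1.5, 30)
        u = np.cbrt(m)
        age = 100 - 120 * u + 50 * u**2  # dips then rises
        with pytest.warns(UserWarning, match="monotone"):
            g = fit_growth_model(pd.DataFrame({"age_days": age,
                                               "body_mass_kg": m}))
        assert not g.monotone


class TestAllometry:
    def test_exact_power_law(self):
        m = np.linspace(0.2, 1.4, 20)
        fit = fit_allometry(2.2 * m**1.32, m)
        assert fit.exponent == pytest.approx(1.32, abs=1e-9)
        assert fit.coefficient == pytest.approx(2.2, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_isometric_set_excludes_mechanical_similarity(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0.2, 1.4, 30)
        y = 3.0 * m**1.0 * 10 ** rng.normal(0, 0.05, 30)
        fit = fit_allometry(y, m)
        assert fit.verdicts["mechanical_1.33"] == "excluded"
        assert abs(fit.exponent - 1.0) < 0.15

    def test_two_points_infinite_ci(self):
        fit = fit_allometry([1.0, 2.0], [0.5, 1.0])
        assert fit.infinite_ci
        assert fit.exponent == pytest.approx(1.0)
        assert fit.exponent_ci == (-math.inf, math.inf)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            fit_allometry([1.0, -2.0, 3.0], [0.5, 1.0, 1.5])


class TestIcc:
    def test_limit_cases(self):
        df = pd.DataFrame({"rabbit_id": np.repeat(list("abcd"), 4),
                           "value": np.repeat([1.0, 2.0, 3.0, 4.0], 4)})
        icc, _ = repeatability_icc(df, n_boot=20, seed=0)
        assert icc > 0.99
        rng = np.random.default_rng(0)
        df["value"] = rng.permutation(df["value"].to_numpy())
        icc_null, _ = repeatability_icc(df, n_boot=20, seed=0)
        assert icc_null < 0.35

    def test_invariance_to_trial_permutation_and_offset(self, flat_cohort):
        trials = flat_cohort.trials.copy()
        icc0, _ = repeatability_icc(trials, n_boot=10, seed=0,
                                    value_col="a_com")
        rng = np.random.default_rng(1)
        shuffled = trials.copy()
        shuffled["a_com"] = shuffled.groupby("rabbit_id")["a_com"].transform(
            lambda s: rng.permutation(s.to_numpy()))
        icc1, _ = repeatability_icc(shuffled, n_boot=10, seed=0,
                                    value_col="a_com")
        assert icc1 == pytest.approx(icc0, abs=1e-7)
        trials["a_com"] += 100.0
        icc2, _ = repeatability_icc(trials, n_boot=10, seed=0,
                                    value_col="a_com")
        assert icc2 == pytest.approx(icc0, abs=1e-5)

    def test_singleton_rabbits_rejected(self):
        df = pd.DataFrame({"rabbit_id": list("abcd"), "value": [1, 2, 3, 4.0]})
        with pytest.raises(InsufficientDataError):
            repeatability_icc(df)


class TestCompareGroups:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p, d, cat = compare_groups(a, a.copy())
        assert d == pytest.approx(0.0)
        assert cat == "very small"

    def test_one_sd_shift_is_large(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(1, 1, 2000)
        _, p, d, cat = compare_groups(b, a)
        assert d == pytest.approx(1.0, abs=0.1)
        assert cat == "large"
        assert p < 1e-10

    def test_category_scale(self):
        assert cohen_d_category(1.27) == "very large"
        assert cohen_d_category(0.25) == "small"
        assert cohen_d_category(0.65) == "moderate"
        assert cohen_d_category(2.5) == "huge"


class TestBoxCoxZ:
    def test_standardization_contract(self):
        rng = np.random.default_rng(6)
        z, lam = boxcox_z(rng.normal(50, 5, 300))
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert abs(lam - 1.0) < 0.5

    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(7)
        _, lam = boxcox_z(rng.lognormal(0.0, 1.0, 500))
        assert abs(lam) < 0.15

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            boxcox_z(np.ones(10))
        with pytest.raises(ValidationError):
            boxcox_z(np.array([1.0, -2.0, 3.0]))


class TestPearsonAndPower:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = one_tailed_pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-30

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(300):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            ps.append(one_tailed_pearson(x, y)[1])
        ps = np.sort(ps)
        # Kolmogorov-Smirnov distance to uniform
        ks = np.max(np.abs(ps - (np.arange(1, 301) - 0.5) / 300))
        assert ks < 0.08

    def test_p_inversion_round_trip(self):
        r = invert_one_tailed_p(0.115, 15)
        assert r == pytest.approx(0.33, abs=0.01)
        # forward: t statistic with that r reproduces p
        from scipy import stats
        t = r * math.sqrt((15 - 2) / (1 - r**2))
        assert stats.t.sf(t, 13) == pytest.approx(0.115, abs=1e-9)

    def test_power_inversion_consistency(self):
        for r in (0.2, 0.33, 0.5):
            n = required_n(r, 0.8)
            assert correlation_power(r, n) >= 0.8
            assert correlation_power(r, n - 1) < 0.8

    def test_power_monotone_in_r(self):
        assert correlation_power(0.9, 15) > correlation_power(0.3, 15)
        assert correlation_power(0.99, 15) > 0.999

    def test_zero_r_unreachable(self):
        with pytest.raises(ValidationError):
            required_n(0.0, 0.8)
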