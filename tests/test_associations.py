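import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.special import expit

from matingkit.associations import (
    ancova,
    beta_regression,
    compress_boundary,
    gaussian_glm,
    pearson_correlation,
    select_link,
    variance_components,
)
from matingkit.depression import primary_selfing_rate


def beta_loglik_grid(y, x, link, b0s, b1s, phis):
    """Independent brute-force evaluation of the beta-regression likelihood."""
    best = -np.inf
    linkinv = {"logit": expit, "log": np.exp, "cloglog": lambda e: 1 - np.exp(-np.exp(e))}[link]
    for b0 in b0s:
        for b1 in b1s:
            mu = linkinv(b0 + b1 * x)
            if np.any((mu <= 0) | (mu >= 1)):
                continue
            for phi in phis:
                ll = scipy.stats.beta.logpdf(y, mu * phi, (1 - mu) * phi).sum()
                best = max(best, ll)
    return best


class TestVarianceComponents:
    def test_balanced_matches_ems_closed_form(self, rng):
        g, m = 25, 4
        plant = np.repeat(np.arange(g), m)
        y = rng.normal(0, np.sqrt(3.0), g)[plant] + rng.normal(0, 1.0, g * m)
        df = pd.DataFrame({"plant": plant, "herkogamy": y})
        vc = variance_components(df)
        ybar = df.groupby("plant")["herkogamy"].mean().to_numpy()
        msb = m * ((ybar - y.mean()) ** 2).sum() / (g - 1)
        msw = ((y - ybar[plant]) ** 2).sum() / (g * (m - 1))
        assert vc.sigma2_among == pytest.approx((msb - msw) / m, abs=1e-6)
        assert vc.sigma2_within == pytest.approx(msw, abs=1e-6)

    def test_unbalanced_matches_mixedlm(self, rng):
        import statsmodels.api as sm

        sizes = rng.integers(2, 7, 30)
        plant = np.repeat(np.arange(30), sizes)
        y = rng.normal(0, 1.5, 30)[plant] + rng.normal(0, 1.0, sizes.sum())
        vc = variance_components(pd.DataFrame({"plant": plant, "herkogamy": y}))
        fit = sm.MixedLM(y, np.ones((y.size, 1)), groups=plant).fit(reml=True)
        assert vc.sigma2_among == pytest.approx(float(np.asarray(fit.cov_re)[0, 0]), abs=1e-3)
        assert vc.sigma2_within == pytest.approx(float(fit.scale), abs=1e-3)

    def test_zero_among_component_truncated(self, rng):
        plant = np.repeat(np.arange(40), 5)
        y = rng.normal(0, 1.0, 200)  # no plant effect
        vc = variance_components(pd.DataFrame({"plant": plant, "herkogamy": y}))
        assert vc.sigma2_among >= 0.0
        assert vc.proportion_among < 0.1

    def test_single_flower_plants_error(self):
        df = pd.DataFrame({"plant": [1, 2, 3], "herkogamy": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="single-flower"):
            variance_components(df)


class TestBetaRegression:
    def test_three_point_grid_oracle(self):
        y = np.array([0.2, 0.5, 0.7])
        x = np.array([-1.0, 0.0, 1.0])
        fit = beta_regression(y, x, link="logit")
        grid_best = beta_loglik_grid(
            y, x, "logit",
            np.linspace(-1, 1, 41), np.linspace(-0.5, 1.5, 41), np.exp(np.linspace(0, 5, 41)),
        )
        assert fit.log_likelihood >= grid_best - 1e-4

    def test_constant_response_flat_slope(self):
        y = np.full(30, 0.5)
        x = np.linspace(-2, 2, 30)
        fit = beta_regression(y, x)
        assert fit.params.loc["x", "estimate"] == pytest.approx(0.0, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            beta_regression(np.array([0.2, 1.4]), np.array([0.0, 1.0]))

    def test_boundary_compression_only_when_needed(self):
        y = np.array([0.0, 0.5, 1.0, 0.25])
        yc, fired = compress_boundary(y)
        assert fired and np.all((yc > 0) & (yc < 1))
        y2, fired2 = compress_boundary(np.array([0.2, 0.8]))
        assert not fired2 and np.array_equal(y2, [0.2, 0.8])

    def test_boundary_values_fit_and_reported(self, rng):
        s = np.concatenate([[0.0, 1.0], rng.uniform(0.05, 0.95, 28)])
        x = rng.normal(0, 5, 30)
        fit = beta_regression(s, x)
        assert fit.extra["boundary_compressed"]

    def test_slope_recovery(self, rng):
        x = rng.normal(0, 5, 500)
        mu = expit(0.3 - 0.15 * x)
        y = rng.beta(mu * 25, (1 - mu) * 25)
        fit = beta_regression(y, x, link="logit")
        b1, se = fit.params.loc["x", "estimate"], fit.params.loc["x", "se"]
        assert b1 == pytest.approx(-0.15, abs=2 * se)
        assert fit.phi == pytest.approx(25, rel=0.2)


class TestLinkSelection:
    def test_log_generated_data_selects_log(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, 1000)
            mu = np.exp(-0.5 - 0.15 * x)
            y = rng.beta(mu * 40, (1 - mu) * 40)
            best, _ = select_link(y, x)
            wins += best.link == "log"
        assert wins > 5

    def test_aic_table_one_row_per_link(self, rng):
        y = rng.uniform(0.2, 0.8, 50)
        x = rng.normal(0, 1, 50)
        best, table = select_link(y, x)
        assert list(table["link"]) == ["cloglog", "logit", "log"]

    def test_single_link_returned_trivially(self, rng):
        y = rng.uniform(0.2, 0.8, 50)
        x = rng.normal(0, 1, 50)
        best, table = select_link(y, x, links=("logit",))
        assert best.link == "logit" and len(table) == 1

    def test_selection_invariant_to_order(self, rng):
        y = rng.uniform(0.1, 0.9, 80)
        x = rng.normal(0, 2, 80)
        b1, _ = select_link(y, x, links=("cloglog", "logit", "log"))
        b2, _ = select_link(y, x, links=("log", "cloglog", "logit"))
        assert b1.link == b2.link


class TestGaussianGLM:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = gaussian_glm(2 * x + 1, x)
        assert fit.params.loc["x", "estimate"] == pytest.approx(2.0)
        assert fit.params.loc["intercept", "estimate"] == pytest.approx(1.0)

    def test_slope_recovery_within_2se(self, rng):
        x = rng.normal(0, 2, 100)
        y = 0.7 * x + rng.normal(0, 1, 100)
        fit = gaussian_glm(y, x)
        assert fit.params.loc["x", "estimate"] == pytest.approx(0.7, abs=2 * fit.params.loc["x", "se"])

    def test_null_p_uniform(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            ps.append(gaussian_glm(y, x).params.loc["x", "p"])
        # type-I error near nominal 5%
        assert np.mean(np.asarray(ps) < 0.05) == pytest.approx(0.05, abs=0.04)

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError):
            gaussian_glm(np.arange(5.0), np.ones(5))


class TestAncova:
    def test_intercept_shift_detected_covariate_null(self, rng):
        cov = rng.normal(0, 1, 120)
        grp = np.repeat(["a", "b"], 60)
        y = 2.0 * (grp == "b") + rng.normal(0, 0.5, 120)
        fit = ancova(y, grp, cov)
        an = fit.extra["anova"]
        assert an.loc["C(group)", "PR(>F)"] < 1e-6
        assert an.loc["cov", "PR(>F)"] > 0.01

    def test_identical_groups_f_near_zero(self, rng):
        cov = rng.normal(0, 1, 100)
        y = 1.5 * cov + rng.normal(0, 1e-6, 100)
        grp = np.tile(["a", "b"], 50)
        fit = ancova(y, grp, cov)
        assert fit.extra["anova"].loc["C(group)", "F"] < 1.0

    def test_covariate_effect_recovered(self, rng):
        cov = rng.normal(0, 1, 100)
        grp = np.repeat(["a", "b"], 50)
        y = 1.0 * cov + rng.normal(0, 0.3, 100)
        fit = ancova(y, grp, cov)
        assert fit.params["estimate"]["cov"] == pytest.approx(1.0, abs=0.1)

    def test_single_group_error(self):
        with pytest.raises(ValueError):
            ancova(np.arange(4.0), ["a"] * 4, np.arange(4.0))


class TestPearson:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        fit = pearson_correlation(x, -x)
        assert fit.params.iloc[0]["estimate"] == pytest.approx(-1.0)
        assert fit.df == 8

    def test_independent_near_zero(self, rng):
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        assert abs(pearson_correlation(x, y).params.iloc[0]["estimate"]) < 0.1

    def test_tm_vs_r_near_perfect_negative(self):
        # the mortality correction is nearly affine in s at small delta, so
        # tm and r correlate at essentially -1 (as reported for field data)
        s = np.linspace(0.02, 0.98, 27)
        r = primary_selfing_rate(s, 0.09)
        fit = pearson_correlation(1 - s, r)
        assert fit.params.iloc[0]["estimate"] <= -0.999

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), np.arange(5.0))
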