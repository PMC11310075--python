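import numpy as np
import pandas as pd
import pytest

from allometree.allometry import (AllometryModelSpec, build_design, fit_bbm,
                                  group_slopes, marginal_slope,
                                  slope_mass_correlation)
from allometree.synthgen import generate_study
from allometree.treeio import match_and_prune


@pytest.fixture(scope="module")
def study():
    tree, table, truth, _ = generate_study(
        {"seed": 21, "tree": {"group_sizes": {"G1": 30, "G2": 30, "G3": 30}},
         "shifts": {}, "trends": {}})
    return tree, table, truth


class TestBuildDesign:
    def test_single_slope_columns(self, study):
        _, table, _ = study
        info = build_design(table, AllometryModelSpec("single"))
        assert info.names == ["intercept", "log_body"]
        assert info.X.shape == (len(table), 2)

    def test_quadratic_appends_squared_column(self, study):
        _, table, _ = study
        info = build_design(table, AllometryModelSpec("quadratic"))
        assert info.names[-1] == "log_body_sq"
        xc = table["log_body"].to_numpy() - info.x_mean
        assert np.allclose(info.X[:, 2], xc ** 2)

    def test_small_group_excluded_and_named(self, study):
        _, table, _ = study
        small = table.copy()
        small.loc[small.index[:30], "group"] = "G1"
        small.loc[small.index[30:49], "group"] = "tiny"   # 19 members
        small.loc[small.index[49:], "group"] = "G3"
        info = build_design(small, AllometryModelSpec(
            "multiple-slopes", min_group_size=20))
        assert "tiny" in info.report["dropped_groups"]
        assert info.report["dropped_groups"]["tiny"] == 19
        assert info.retained.sum() == len(table) - 19

    def test_threshold_is_inclusive(self, study):
        _, table, _ = study
        exactly = table.copy()  # groups of 30 >= 20 all kept
        info = build_design(exactly, AllometryModelSpec(
            "multiple-slopes", min_group_size=30))
        assert not info.report["dropped_groups"]

    def test_fewer_than_two_groups_rejected(self, study):
        _, table, _ = study
        lone = table.copy()
        lone["group"] = "only"
        with pytest.raises(ValueError, match="fewer than two groups"):
            build_design(lone, AllometryModelSpec("multiple-slopes"))


class TestFits:
    def test_centering_is_affine_invariant(self, study):
        tree, table, _ = study
        a = fit_bbm(tree, table, AllometryModelSpec(
            "quadratic", center_quadratic=True), engine="ml")
        b = fit_bbm(tree, table, AllometryModelSpec(
            "quadratic", center_quadratic=False), engine="ml")
        assert a.result.loglik == pytest.approx(b.result.loglik, abs=1e-6)
        assert np.allclose(a.beta, b.beta, atol=1e-6)
        x = table["log_body"].to_numpy()
        assert np.allclose(a.predict(x), b.predict(x), atol=1e-8)

    def test_quadratic_recovers_truth_ml(self, study):
        tree, table, truth = study
        fit = fit_bbm(tree, table, AllometryModelSpec("quadratic"),
                      engine="ml")
        se2 = fit.result.se()[2]
        assert abs(fit.curvature() - truth.beta2) < 4 * se2 + 0.01

    def test_orthogonal_covariate_leaves_curvature(self, study):
        """Adding a noise covariate barely moves β₂ (the BMR/MSP-style
        robustness property)."""
        tree, table, _ = study
        rng = np.random.default_rng(5)
        aug = table.copy()
        aug["noise_cov"] = rng.standard_normal(len(table))
        base = fit_bbm(tree, table, AllometryModelSpec("quadratic"),
                       engine="ml")
        plus = fit_bbm(tree, aug, AllometryModelSpec(
            "quadratic+covariates", covariates=("noise_cov",)), engine="ml")
        se2 = base.result.se()[2]
        assert abs(base.curvature() - plus.curvature()) < se2

    def test_bayes_engine_px_and_median(self, study):
        tree, table, truth = study
        fit = fit_bbm(tree, table, AllometryModelSpec("quadratic"),
                      engine="bayes", n_samples=3000, seed=2)
        assert fit.samples_beta.shape == (3000, 3)
        p = fit.px()
        assert 0 <= p["log_body_sq"] <= 0.5
        assert fit.predict([2.0]).shape == (1,)

    def test_asymptotic_variant_fits(self, study):
        tree, table, _ = study
        fit = fit_bbm(tree, table, AllometryModelSpec("asymptotic"),
                      engine="ml")
        assert fit.names == ["c", "d", "k"]
        assert np.isfinite(fit.r2)


class TestMarginalSlope:
    def make_fit(self, study, b1, b2):
        tree, table, _ = study
        fit = fit_bbm(tree, table, AllometryModelSpec("quadratic"),
                      engine="ml")
        fit.beta = np.array([0.0, b1, b2])
        return fit

    def test_no_curvature_flat_slope(self, study):
        fit = self.make_fit(study, 0.75, 0.0)
        out = marginal_slope(fit, x=[0.0, 5.0])
        assert np.allclose(out["slope"], 0.75)
        assert out["percent_reduction"] == 0.0

    def test_closed_form_reduction(self, study):
        fit = self.make_fit(study, 0.75, -0.019)
        out = marginal_slope(fit, x=[0.0, 8.0])
        assert out["slope"][0] == pytest.approx(0.75)
        assert out["slope"][1] == pytest.approx(0.446)
        # over x ∈ [0, 8] the slope falls 0.75 → 0.446, a 40.5% reduction
        red = 100 * (0.75 - 0.446) / 0.75
        assert red == pytest.approx(40.5, abs=0.1)


class TestSlopeMassCorrelation:
    def test_perfectly_decreasing_gives_minus_one(self):
        df = pd.DataFrame({"group": list("abcde"),
                           "slope": [5.0, 4.0, 3.0, 2.0, 1.0],
                           "median_log_body": [1.0, 2.0, 3.0, 4.0, 5.0]})
        rho, p, n = slope_mass_correlation(df)
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 120)  # two orderings of 5! are extreme

    def test_matches_rank_oracle(self, rng):
        slopes = rng.normal(size=5)
        mass = rng.normal(size=5)
        df = pd.DataFrame({"group": list("abcde"), "slope": slopes,
                           "median_log_body": mass})
        rho, p, _ = slope_mass_correlation(df)
        # brute-force Spearman: Pearson correlation of average ranks
        def ranks(v):
            order = np.argsort(v)
            r = np.empty(5)
            r[order] = np.arange(1, 6)
            return r
        oracle = np.corrcoef(ranks(slopes), ranks(mass))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exclusion_list(self):
        df = pd.DataFrame({"group": list("abcde"),
                           "slope": [5.0, 4.0, 3.0, 2.0, 90.0],
                           "median_log_body": [1.0, 2.0, 3.0, 4.0, 5.0]})
        rho_all, _, n_all = slope_mass_correlation(df)
        rho_ex, _, n_ex = slope_mass_correlation(df, exclude=("e",))
        assert n_all == 5 and n_ex == 4
        assert rho_ex == pytest.approx(-1.0)

    def test_group_slopes_extraction(self):
        tree, table, truth, _ = generate_study(
            {"seed": 31, "tree": {"group_sizes": {"G1": 25, "G2": 25, "G3": 25}},
             "shifts": {}, "trends": {}})
        tree, table, _ = match_and_prune(tree, table, 0)
        fit = fit_bbm(tree, table, AllometryModelSpec(
            "multiple-slopes", min_group_size=20), engine="ml")
        gs = group_slopes(fit)
        assert set(gs["group"]) == {"G1", "G2", "G3"}
        assert (gs["n"] == 25).all()
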