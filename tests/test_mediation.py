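"""Path regressions, wild bootstrap mechanics, indirect effects, contrasts."""

import numpy as np
import pandas as pd
import pytest

from affectmed import (
    BootstrapSpec,
    WildBootstrapMediation,
    effect_decomposition,
    fit_path,
    indirect_contrast,
    indirect_effect,
    partial_eta_sq,
    total_effect,
    wild_bootstrap_mediation,
)
from affectmed.mediation import _PathSystem, _design, _draw_weights, _ols


class TestFitPath:
    def test_identity_regression(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        data = pd.DataFrame({"y": x, "x": x})
        est = fit_path(data, "y", "x")
        assert est.beta == pytest.approx(1.0, abs=1e-10)
        assert est.partial_r2 > 0.999999

    def test_null_focal_rejection_rate(self):
        # |beta| < 1.96/sqrt(n) about 95% of the time under independence
        n, hits, reps = 400, 0, 300
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame({"y": rng.standard_normal(n),
                                 "x": rng.standard_normal(n)})
            est = fit_path(data, "y", "x")
            hits += abs(est.beta) < 1.96 / np.sqrt(n)
        assert 0.91 < hits / reps < 0.985

    def test_recovers_slope_under_confounding(self):
        rng = np.random.default_rng(1)
        n = 5000
        c = rng.standard_normal(n)
        x = 0.5 * c + rng.standard_normal(n)
        y = 0.2 * (x / x.std(ddof=1)) + 0.4 * c + rng.standard_normal(n)
        data = pd.DataFrame({"y": y, "x": x, "c": c})
        est = fit_path(data, "y", "x", ["c"])
        # y was built with a standardized slope of 0.2 before noise scaling
        expected = 0.2 / y.std(ddof=1)
        assert est.beta == pytest.approx(expected, abs=0.03)

    def test_binary_focal_is_mean_difference_in_sd_units(self):
        rng = np.random.default_rng(2)
        d = (rng.random(600) < 0.2).astype(float)
        y = 0.4 * d + rng.standard_normal(600)
        data = pd.DataFrame({"y": y, "d": d})
        est = fit_path(data, "y", "d")
        manual = (y[d == 1].mean() - y[d == 0].mean()) / y.std(ddof=1)
        assert est.beta == pytest.approx(manual, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        data = pd.DataFrame({"y": rng.standard_normal(40), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="collinear.*x"):
            fit_path(data, "y", "x", ["x2"])

    def test_missing_values_rejected(self):
        data = pd.DataFrame({"y": [1.0, np.nan, 2.0], "x": [0.0, 1.0, 0.5]})
        with pytest.raises(ValueError, match="incomplete"):
            fit_path(data, "y", "x")


class TestEffectSizes:
    def test_partial_eta_trivials(self):
        assert partial_eta_sq(0.0, 100) == 0.0
        assert partial_eta_sq(3.0, 97) == pytest.approx(9.0 / 106.0)
        with pytest.raises(ValueError):
            partial_eta_sq(1.0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_residual_on_residual_squared_correlation(self, seed):
        # partial eta^2 from the t statistic must equal the squared
        # correlation of (y | covariates) residuals with (x | covariates)
        # residuals, computed from scratch
        rng = np.random.default_rng(seed)
        n = 40
        data = pd.DataFrame({
            "y": rng.standard_normal(n),
            "x": rng.standard_normal(n),
            "c1": rng.standard_normal(n),
            "c2": (rng.random(n) < 0.5).astype(float),
        })
        est = fit_path(data, "y", "x", ["c1", "c2"])
        y, X, _ = _design(data, "y", "x", ["c1", "c2"])
        Z = np.delete(X, 1, axis=1)  # covariates + intercept only
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        rx = X[:, 1] - Z @ np.linalg.lstsq(Z, X[:, 1], rcond=None)[0]
        r2 = np.corrcoef(ry, rx)[0, 1] ** 2
        assert est.partial_eta2 == pytest.approx(r2, abs=1e-10)

    def test_indirect_effect_arithmetic(self):
        from affectmed.mediation import PathEstimate

        mk = lambda b, r2: PathEstimate(beta=b, se=0.1, t_stat=1.0, df_resid=10,
                                        partial_r2=r2, partial_eta2=r2)
        assert indirect_effect(mk(0.0, 0.1), mk(0.5, 0.2))[0] == 0.0
        prod, r2 = indirect_effect(mk(0.1, 0.02), mk(0.2, 0.02))
        assert prod == pytest.approx(0.02)
        assert r2 == pytest.approx(0.0004)


class TestWildBootstrapMechanics:
    def test_closed_form_equals_literal_refit(self):
        # the vectorised beta* = beta + h'(w*resid) must equal an explicit
        # OLS refit on y* = fitted + w*resid for every iteration
        rng = np.random.default_rng(4)
        n, B = 60, 25
        data = pd.DataFrame({
            "m": rng.standard_normal(n),
            "d": (rng.random(n) < 0.3).astype(float),
            "c": rng.standard_normal(n),
        })
        system = _PathSystem(data, "m", "d", ["c"])
        y, X, _ = _design(data, "m", "d", ["c"])
        beta_full, _, resid, _, _ = _ols(y, X)
        w = _draw_weights(np.random.default_rng(5), "rademacher", (n, B))
        fast = system.draws(w)
        for j in range(B):
            ystar = X @ beta_full + w[:, j] * resid
            slow = np.linalg.lstsq(X, ystar, rcond=None)[0][1]
            assert fast[j] == pytest.approx(slow, abs=1e-10)

    @pytest.mark.parametrize("scheme", ["rademacher", "mammen", "normal"])
    def test_weight_schemes_have_unit_variance_zero_mean(self, scheme):
        w = _draw_weights(np.random.default_rng(6), scheme, 200_000)
        assert abs(w.mean()) < 0.01
        assert w.var() == pytest.approx(1.0, abs=0.02)

    def test_rademacher_values(self):
        w = _draw_weights(np.random.default_rng(7), "rademacher", 1000)
        assert set(np.unique(w)) == {-1.0, 1.0}

    def test_same_seed_identical_ci(self, small_frame):
        spec = BootstrapSpec(n_iterations=2000, seed=9)
        r1 = wild_bootstrap_mediation(small_frame, "disgust_neutral", spec)
        r2 = wild_bootstrap_mediation(small_frame, "disgust_neutral", spec)
        assert r1.ci95 == r2.ci95

    def test_row_order_invariance(self, small_frame):
        spec = BootstrapSpec(n_iterations=1500, seed=10)
        shuffled = small_frame.sample(frac=1.0, random_state=3)
        r1 = wild_bootstrap_mediation(small_frame, "disgust_neutral", spec)
        r2 = wild_bootstrap_mediation(shuffled, "disgust_neutral", spec)
        assert r1.ci95 == r2.ci95
        assert r1.indirect == pytest.approx(r2.indirect, abs=1e-12)

    def test_mediator_substreams_are_independent_of_order(self, small_frame):
        spec = BootstrapSpec(n_iterations=1500, seed=11)
        direct = wild_bootstrap_mediation(small_frame, "fear_harm", spec)
        wild_bootstrap_mediation(small_frame, "disgust_neutral", spec)
        again = wild_bootstrap_mediation(small_frame, "fear_harm", spec)
        assert direct.ci95 == again.ci95

    def test_ci_endpoints_derivable_from_draws(self, small_frame):
        spec = BootstrapSpec(n_iterations=2000, seed=12)
        res = wild_bootstrap_mediation(small_frame, "sickness_infection", spec,
                                       keep_draws=True)
        lo, hi = np.quantile(res.draws, [0.025, 0.975])
        assert res.ci95 == (pytest.approx(lo), pytest.approx(hi))

    def test_low_iteration_count_warns(self, small_frame):
        with pytest.warns(UserWarning, match="fewer than 1000"):
            wild_bootstrap_mediation(
                small_frame, "disgust_neutral", BootstrapSpec(n_iterations=500)
            )

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BootstrapSpec(weight_scheme="jackknife").validate()
        with pytest.raises(ValueError):
            BootstrapSpec(ci_level=1.5).validate()

    def test_estimator_api(self, small_frame):
        from sklearn.base import clone

        est = WildBootstrapMediation(mediator="disgust_harm", n_iterations=1200,
                                     seed=13)
        est2 = clone(est)
        est2.fit(small_frame)
        assert hasattr(est2, "indirect_")
        assert est2.significant_ == (not est2.ci95_[0] <= 0 <= est2.ci95_[1])
        assert est2.r2_indirect_ == pytest.approx(
            est2.path_a_.partial_r2 * est2.path_b_.partial_r2
        )


class TestContrastsAndTotals:
    def test_self_contrast_degenerate(self, small_frame):
        con = indirect_contrast(small_frame, "disgust_neutral", "disgust_neutral",
                                BootstrapSpec(n_iterations=1000, seed=14))
        assert con.degenerate
        assert con.difference == 0.0
        assert con.ci95 == (0.0, 0.0)

    def test_contrast_point_estimate_matches_separate_fits(self, small_frame):
        spec = BootstrapSpec(n_iterations=1200, seed=15)
        con = indirect_contrast(small_frame, "disgust_neutral", "disgust_infection",
                                spec)
        r1 = wild_bootstrap_mediation(small_frame, "disgust_neutral", spec)
        r2 = wild_bootstrap_mediation(small_frame, "disgust_infection", spec)
        assert con.difference == pytest.approx(r1.indirect - r2.indirect, abs=1e-12)
        assert con.r2_difference == pytest.approx(
            r1.r2_indirect - r2.r2_indirect, abs=1e-12
        )

    def test_total_effect_decomposition_identity(self, random_regression_data):
        data = random_regression_data(seed=16, n=90, n_mediators=3)
        dec = effect_decomposition(data, ["m0", "m1", "m2"], outcome="disruption",
                                   exposure="diagnosed", covariates=["cov1", "cov2"])
        assert abs(dec["identity_gap"]) < 1e-8

    def test_total_effect_null_generator_is_small(self):
        rng = np.random.default_rng(17)
        n = 3000
        data = pd.DataFrame({
            "disruption": rng.standard_normal(n),
            "diagnosed": (rng.random(n) < 0.2).astype(float),
        })
        est, ci = total_effect(data, with_covariates=False,
                               spec=BootstrapSpec(n_iterations=1500, seed=18),
                               covariates=())
        assert abs(est.beta) < 3.0 / np.sqrt(n * 0.16)
        assert ci[0] <= est.beta <= ci[1]

    def test_covariate_adjustment_reduces_confounding_bias(self):
        # exposure and outcome share a confounder; adjusted estimate is
        # closer to the true null effect across seeds
        errs = {"adj": [], "raw": []}
        for seed in range(12):
            rng = np.random.default_rng(seed + 100)
            n = 1200
            c = rng.standard_normal(n)
            d = (rng.random(n) < 1 / (1 + np.exp(-c))).astype(float)
            y = 0.5 * c + rng.standard_normal(n)
            data = pd.DataFrame({"disruption": y, "diagnosed": d, "c": c})
            spec = BootstrapSpec(n_iterations=1000, seed=seed)
            adj, _ = total_effect(data, True, spec, covariates=("c",))
            raw, _ = total_effect(data, False, spec, covariates=("c",))
            errs["adj"].append(abs(adj.beta))
            errs["raw"].append(abs(raw.beta))
        assert np.mean(errs["adj"]) < np.mean(errs["raw"])

    def test_degenerate_residuals_raise(self):
        data = pd.DataFrame({
            "m": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "d": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        })
        data["y"] = data["m"]  # exact fit -> zero residuals in the b path
        with pytest.raises(ValueError, match="degenerate"):
            wild_bootstrap_mediation(
                data, "m", BootstrapSpec(n_iterations=1000), outcome="y",
                exposure="d", covariates=(),
            )
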