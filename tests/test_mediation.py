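import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import medgrowth as mg
from medgrowth.mediation import MedModSpec, percentile_bounds
from medgrowth.simulate import BDI_COLUMNS, TIMES


def _spec(B=200, seed=0, **kw):
    return MedModSpec(bootstrap_draws=B, bootstrap_seed=seed, **kw)


@pytest.fixture(scope="module")
def big_fit(big_trial):
    return mg.fit_medmod(big_trial, big_trial.true_class, _spec(), seed=0)


class TestFitMedmod:
    def test_recovers_generating_conditional_a_paths(self, big_fit):
        for k, truth in enumerate((5.03, 13.87)):
            assert abs(big_fit.a_g[k] - truth) < 3 * big_fit.a_se_g[k]

    def test_recovers_b_and_cprime(self, big_fit):
        assert abs(big_fit.b_g[0] - (-0.03)) < 3 * big_fit.b_se_g[0]
        assert abs(big_fit.cprime_g[0] - 0.37) < 3 * big_fit.cprime_se_g[0]

    def test_moderation_tests_null_for_b_and_cprime(self, big_fit):
        # the generator shares b and c' across classes
        assert abs(big_fit.b_diff) < 3 * big_fit.b_diff_se
        assert abs(big_fit.cprime_diff) < 3 * big_fit.cprime_diff_se

    def test_null_b_path_gives_null_indirect_effects(self):
        cfg = mg.default_config(n=5000, b_g=(0.0, 0.0), seed=41)
        d = mg.generate_dataset(cfg)
        fit = mg.fit_medmod(d, d.true_class, _spec(), seed=0)
        se_ie = np.abs(fit.a_g) * fit.b_se_g[0]
        assert np.all(np.abs(fit.ie_g) < 3 * se_ie)

    def test_degenerate_noise_free_outcome_matches_ols_on_computed_slopes(self):
        rng = np.random.default_rng(5)
        n = 600
        x = np.tile([0, 1], n // 2)
        g = np.repeat([1, 2], n // 2)
        m = 5 + 3 * rng.standard_normal(n) + 4 * x * (g - 1)
        beta0 = np.where(g == 1, -0.1, -0.5)
        eta0 = 12 + 2 * rng.standard_normal(n)
        eta1 = beta0 - 0.03 * m + 0.4 * x
        t = np.asarray(TIMES)
        Y = eta0[:, None] + eta1[:, None] * t + 0.002 * t**2 \
            + 1e-2 * rng.standard_normal((n, 6))
        d = pd.DataFrame({"arm": x, "delta_ffmq": m})
        for j, c in enumerate(BDI_COLUMNS):
            d[c] = Y[:, j]
        fit = mg.fit_medmod(d, g, _spec(), seed=0)
        # per-person exact slopes via OLS on each trajectory
        X_t = np.column_stack([np.ones(6), t, t**2])
        slopes = np.linalg.lstsq(X_t, Y.T, rcond=None)[0][1]
        D = np.column_stack([(g == 1).astype(float), (g == 2).astype(float), m, x])
        coef = np.linalg.lstsq(D, slopes, rcond=None)[0]
        assert fit.b_g[0] == pytest.approx(coef[2], abs=1e-4)
        assert fit.cprime_g[0] == pytest.approx(coef[3], abs=1e-4)

    def test_small_group_rejected(self, default_trial):
        labels = np.ones(len(default_trial), dtype=int)
        labels[:5] = 2
        with pytest.raises(ValueError):
            mg.fit_medmod(default_trial, labels, _spec(), seed=0)

    def test_unknown_covariate_rejected(self, default_trial):
        spec = dataclasses.replace(_spec(), covariates=("no_such_column",))
        with pytest.raises(KeyError):
            mg.fit_medmod(default_trial, default_trial.true_class, spec, seed=0)


class TestConstructionIdentities:
    def test_ie_is_product_and_index_is_difference(self, big_fit):
        ie = mg.conditional_indirect_effects(big_fit)
        np.testing.assert_array_equal(ie, big_fit.a_g * big_fit.b_g)
        assert mg.index_of_moderated_mediation(big_fit) == ie[1] - ie[0]

    def test_shared_b_index_equals_adiff_times_b(self, big_fit):
        idx = mg.index_of_moderated_mediation(big_fit)
        assert idx == pytest.approx(big_fit.a_diff * big_fit.b_g[0], abs=1e-12)

    def test_relabelling_groups_flips_index_and_adiff(self, default_trial):
        labels = default_trial.true_class.to_numpy()
        f1 = mg.fit_medmod(default_trial, labels, _spec(), seed=0)
        f2 = mg.fit_medmod(default_trial, 3 - labels, _spec(), seed=0)
        assert f2.index == pytest.approx(-f1.index, abs=1e-6)
        assert f2.a_diff == pytest.approx(-f1.a_diff, abs=1e-8)

    def test_zero_b_gives_zero_indirect_effects(self, big_fit):
        stub = dataclasses.replace(big_fit, b_g=np.zeros(2))
        np.testing.assert_array_equal(mg.conditional_indirect_effects(stub), 0.0)


class TestTotalEffect:
    def test_matches_mixture_decomposition_on_default_generator(self, big_trial):
        tot = mg.total_effect(big_trial, big_trial.true_class, _spec(), seed=0)
        cfg = mg.default_config()
        expected = sum(0.5 * (cfg.a_g[g] * cfg.b_g[g] + cfg.cprime_g[g])
                       for g in (0, 1))
        assert abs(tot["c"] - expected) < 3 * tot["se"]

    def test_null_b_makes_total_equal_direct(self):
        cfg = mg.default_config(n=5000, b_g=(0.0, 0.0), seed=43)
        d = mg.generate_dataset(cfg)
        fit = mg.fit_medmod(d, d.true_class, _spec(), seed=0)
        tot = mg.total_effect(d, d.true_class, _spec(), seed=0)
        se = np.hypot(tot["se"], fit.cprime_se_g[0])
        assert abs(tot["c"] - fit.cprime_g[0]) < 3 * se


class TestProjectedChange:
    def test_24_month_projection(self):
        assert mg.projected_change(-0.4161, 24) == pytest.approx(-9.9864)

    def test_zero_cases(self):
        assert mg.projected_change(0.0, 24) == 0.0
        assert mg.projected_change(-0.42, 0) == 0.0

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            mg.projected_change(-0.42, -1)


class TestAdjustCovariates:
    def test_empty_list_is_identity(self):
        spec = _spec()
        assert mg.adjust_covariates(spec, ()) == spec

    def test_irrelevant_covariates_barely_move_index(self, big_trial):
        rng = np.random.default_rng(6)
        d = big_trial.copy()
        d["noise_cov"] = rng.standard_normal(len(d))
        base = mg.fit_medmod(d, d.true_class, _spec(), seed=0)
        adj = mg.fit_medmod(d, d.true_class,
                            mg.adjust_covariates(_spec(), ("noise_cov",)), seed=0)
        se_idx = np.sqrt(base.b_g[0] ** 2 * base.a_diff_se**2
                         + base.a_diff**2 * base.b_se_g[0] ** 2)
        assert abs(adj.index - base.index) < 3 * se_idx

    def test_each_covariate_adds_two_params_per_equation(self, default_trial):
        spec = mg.adjust_covariates(_spec(), ("practice_level", "adm_discontinued"))
        fit = mg.fit_medmod(default_trial, default_trial.true_class, spec, seed=0)
        # mediator equation: one coefficient per covariate per group
        assert all(len(c) == 2 for c in fit.covariate_coefs["mediator"])
        # slope equation: 2 covariates x 2 groups
        assert len(fit.covariate_coefs["slope"]) == 4


class TestVarianceExplained:
    def test_mediator_r2_matches_closed_form(self, big_trial, big_fit):
        cfg = mg.default_config()
        table = mg.variance_explained(big_fit)
        for k, g in enumerate(big_fit.groups):
            sel = big_trial.true_class == g
            var_x = big_trial.loc[sel, "arm"].var(ddof=0)
            a = cfg.a_g[k]
            expect = a**2 * var_x / (a**2 * var_x + cfg.sigma_m**2)
            # MC tolerance: R² of a regression at n≈2500 per group
            assert abs(table.r2_mediator.iloc[k] - expect) < 0.03

    def test_null_a_paths_give_null_mediator_r2(self):
        cfg = mg.default_config(n=4000, a_g=(0.0, 0.0), seed=44)
        d = mg.generate_dataset(cfg)
        fit = mg.fit_medmod(d, d.true_class, _spec(), seed=0)
        assert np.all(fit.r2_mediator_g < 0.01)

    def test_vanishing_disturbance_gives_r2_near_one(self):
        cfg = mg.default_config(n=2000, sigma_m=1e-6, seed=45)
        d = mg.generate_dataset(cfg)
        fit = mg.fit_medmod(d, d.true_class, _spec(), seed=0)
        assert np.all(fit.r2_mediator_g > 0.999)


class TestBootstrap:
    def test_reproducible_given_seed(self, default_trial):
        labels = default_trial.true_class
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = mg.bootstrap_ci(default_trial, labels, _spec(B=200, seed=3))
            b2 = mg.bootstrap_ci(default_trial, labels, _spec(B=200, seed=3))
        assert b1.ci == b2.ci
        np.testing.assert_array_equal(b1.draws["index"], b2.draws["index"])

    def test_interval_covers_point_estimate_and_flags_sign(self, default_trial):
        labels = default_trial.true_class
        fit = mg.fit_medmod(default_trial, labels, _spec(), seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot = mg.bootstrap_ci(default_trial, labels, _spec(B=200, seed=4))
        lo, hi = boot.ci["index"]
        assert lo <= fit.index <= hi
        assert boot.significant["index"] == (not lo <= 0 <= hi)
        assert boot.n_failed == 0

    def test_too_few_draws_rejected(self, default_trial):
        with pytest.raises(ValueError):
            mg.bootstrap_ci(default_trial, default_trial.true_class, _spec(B=50))

    def test_percentile_bounds_are_order_statistics(self):
        draws = np.arange(1000, dtype=float)
        lo, hi = percentile_bounds(draws)
        assert lo in draws and hi in draws
        assert lo == 24.0 and hi == 974.0

    def test_degenerate_identical_draws_collapse_interval(self):
        lo, hi = percentile_bounds(np.full(500, 1.23))
        assert (lo, hi) == (1.23, 1.23)

    def test_percentile_interval_matches_analytic_for_sample_mean(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(50)
        means = np.array([rng.choice(x, 50).mean() for _ in range(2000)])
        lo, hi = percentile_bounds(means)
        assert lo == pytest.approx(x.mean() - 1.96 / np.sqrt(50), abs=0.05)
        assert hi == pytest.approx(x.mean() + 1.96 / np.sqrt(50), abs=0.05)
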