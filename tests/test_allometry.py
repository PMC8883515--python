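import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ocwmass import (
    AllometricModelSpec,
    ModelTerm,
    compare_models,
    fit_free_exponent,
    fit_model,
    transform_predictor,
)
from ocwmass import test_group_allometry as group_allometry  # avoid pytest collection
from ocwmass.allometry import RankDeficientError
from .conftest import make_dataset


class TestTransformPredictor:
    def test_two_thirds_power_of_42mm(self):
        # (ln 42)^(2/3) = 3.737670^(2/3) = 2.408430 by direct evaluation
        assert transform_predictor(42.0, 2 / 3) == pytest.approx(2.408430, abs=1e-5)

    def test_power_one_is_plain_log(self):
        x = np.array([2.0, 10.0, 250.0])
        assert np.allclose(transform_predictor(x, 1.0), np.log(x))

    @pytest.mark.parametrize("p", [1 / 3, 1 / 2, 2 / 3, 3 / 4])
    def test_x_equals_e_maps_to_one_for_every_power(self, p):
        assert transform_predictor(math.e, p) == pytest.approx(1.0)

    def test_fractional_power_requires_x_above_one(self):
        with pytest.raises(ValueError, match="x > 1"):
            transform_predictor(0.5, 2 / 3)

    def test_quadratic_yields_two_columns(self):
        cols = transform_predictor(np.array([math.e, math.e ** 2]), "quadratic")
        assert np.allclose(cols, [[1, 1], [2, 4]])


class TestFitModel:
    def test_noise_free_recovery_of_slope_and_intercept(self, noise_free_species):
        fit = fit_model(noise_free_species, AllometricModelSpec.power(2 / 3))
        assert fit.params["ln_ocw^2/3"] == pytest.approx(7.69289, abs=1e-8)
        assert fit.params["intercept"] == pytest.approx(-8.19502, abs=1e-8)
        assert fit.see == pytest.approx(0.0, abs=1e-10)

    def test_three_point_fit_matches_hand_solved_normal_equations(self):
        # x = e^1, e^2, e^3; ln y = 2, 3, 5  =>  slope 3/2, intercept 1/3
        data = pd.DataFrame(
            {"ocw": np.exp([1.0, 2.0, 3.0]), "body_mass": np.exp([2.0, 3.0, 5.0])}
        )
        fit = fit_model(data, AllometricModelSpec.power(1.0))
        assert fit.params["ln_ocw"] == pytest.approx(1.5)
        assert fit.params["intercept"] == pytest.approx(1.0 / 3.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_fixed_exponent_fit_equals_closed_form_least_squares(self, seed):
        """Oracle equivalence: OLS on the transformed design must equal the
        normal-equation solution on random small instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        p = rng.choice([1.0, 1 / 3, 1 / 2, 2 / 3, 3 / 4])
        x = np.exp(rng.uniform(0.5, 5.5, n))
        y = np.exp(rng.normal(5.0, 2.0, n))
        data = pd.DataFrame({"ocw": x, "body_mass": y})
        t = np.log(x) ** p
        X = np.column_stack([np.ones(n), t])
        beta = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
        if abs(np.linalg.det(X.T @ X)) < 1e-8:
            return
        fit = fit_model(data, AllometricModelSpec.power(float(p)))
        assert fit.params["intercept"] == pytest.approx(beta[0], rel=1e-8, abs=1e-8)
        assert fit.params[fit.params.index[1]] == pytest.approx(beta[1], rel=1e-8, abs=1e-8)

    def test_aic_matches_formula_oracle(self, noisy_species):
        fit = fit_model(noisy_species, AllometricModelSpec.power(2 / 3))
        rss = float(np.sum(fit.resid ** 2))
        n = fit.n
        ll = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1)
        assert fit.loglik == pytest.approx(ll)
        assert fit.aic == pytest.approx(2 * 3 - 2 * ll)  # 2 coefficients + variance
        assert fit.bic == pytest.approx(math.log(n) * 3 - 2 * ll)

    def test_aic_differences_invariant_to_response_scaling(self, noisy_species):
        specs = [AllometricModelSpec.power(1.0), AllometricModelSpec.power(2 / 3)]
        fits = [fit_model(noisy_species, s) for s in specs]
        scaled = noisy_species.assign(body_mass=noisy_species.body_mass * 1e3)
        fits_scaled = [fit_model(scaled, s) for s in specs]
        d0 = fits[0].aic - fits[1].aic
        d1 = fits_scaled[0].aic - fits_scaled[1].aic
        assert d0 == pytest.approx(d1, abs=1e-6)

    def test_zero_variance_predictor_is_explicit_error(self):
        data = pd.DataFrame({"ocw": [10.0] * 8, "body_mass": np.arange(1.0, 9.0)})
        with pytest.raises(ValueError, match="zero variance"):
            fit_model(data, AllometricModelSpec.power(2 / 3))

    def test_rank_deficient_design_names_collinear_terms(self, noisy_species):
        data = noisy_species.assign(dup=lambda d: 1.0 * (d.body_mass > d.body_mass.median()),
                                    dup2=lambda d: 1.0 * (d.body_mass > d.body_mass.median()))
        spec = AllometricModelSpec(terms=(ModelTerm("ocw", 2 / 3),),
                                   covariates=("dup", "dup2"))
        with pytest.raises(RankDeficientError, match="dup"):
            fit_model(data, spec)

    def test_covariate_dummy_shifts_intercept(self):
        ds = make_dataset(
            n_species=120,
            residual_sd_log=0.1,
            morphotype_fractions={"rabbit_like": 0.3},
            morphotype_shifts={"rabbit_like": 0.7},
            seed=5,
        )
        spec = AllometricModelSpec(terms=(ModelTerm("ocw", 2 / 3),),
                                   covariates=("rabbit_like",))
        fit = fit_model(ds.species, spec)
        lo, hi = fit.conf_int.loc["rabbit_like"]
        assert lo < 0.7 < hi


class TestFreeExponent:
    def test_noise_free_exponent_recovered(self):
        ds = make_dataset(exponent_b=0.7, seed=3)
        fit = fit_free_exponent(ds.species)
        assert fit.converged
        assert fit.b == pytest.approx(0.7, abs=1e-6)

    def test_constrained_exponent_reproduces_ols(self, noisy_species):
        ols = fit_model(noisy_species, AllometricModelSpec.power(2 / 3))
        nls = fit_free_exponent(noisy_species, fix_exponent=2 / 3)
        assert nls.a == pytest.approx(ols.params["ln_ocw^2/3"], abs=1e-10)
        assert nls.c == pytest.approx(ols.params["intercept"], abs=1e-10)

    def test_optimum_matches_grid_search_oracle(self):
        ds = make_dataset(n_species=25, residual_sd_log=0.35, exponent_b=0.6, seed=9)
        data = ds.species
        lx = np.log(data.ocw.values)
        y = np.log(data.body_mass.values)

        def rss_for(b):
            X = np.column_stack([lx ** b, np.ones(len(y))])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            return float(np.sum((y - X @ beta) ** 2))

        grid = np.arange(0.1, 1.2001, 0.001)
        b_grid = grid[int(np.argmin([rss_for(b) for b in grid]))]
        fit = fit_free_exponent(data)
        assert abs(fit.b - b_grid) <= 0.001 + 1e-9
        assert np.sum(fit.resid ** 2) <= rss_for(b_grid) + 1e-9

    def test_small_sample_refused(self):
        data = pd.DataFrame({"ocw": [10.0, 20.0, 30.0], "body_mass": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="4 observations"):
            fit_free_exponent(data)


class TestCompareModels:
    def test_duplicate_specs_give_identical_rows(self, noisy_species):
        spec = AllometricModelSpec.power(2 / 3)
        table = compare_models(noisy_species, [spec, spec])
        a, b = table.iloc[0], table.iloc[1]
        for col in ("aic", "bic", "loglik", "r2_adj", "pct_pe", "cf", "pct_see"):
            assert a[col] == b[col]

    def test_power_model_beats_linear_on_curved_data(self):
        ds = make_dataset(n_species=300, residual_sd_log=0.39, seed=21)
        table = compare_models(
            ds.species,
            [AllometricModelSpec.power(1.0, name="linear"),
             AllometricModelSpec.power(2 / 3, name="2/3")],
        ).set_index("model")
        assert table.loc["2/3", "aic"] < table.loc["linear", "aic"]

    def test_fit_failures_annotate_rather_than_abort(self, noisy_species):
        bad = AllometricModelSpec(terms=(ModelTerm("no_such_column", 2 / 3),))
        table = compare_models(noisy_species, [AllometricModelSpec.power(2 / 3), bad])
        assert table.iloc[0]["error"] == ""
        assert table.iloc[1]["error"] != ""


class TestGroupAllometry:
    def test_null_case_rarely_significant(self):
        pvals = []
        for seed in range(20):
            ds = make_dataset(n_species=80, residual_sd_log=0.3, seed=100 + seed)
            res = group_allometry(ds.species, 1000.0, term="slope")
            pvals.append(res.p)
        assert np.mean(np.array(pvals) < 0.05) <= 0.25

    def test_intercept_shift_recovered_within_ci(self):
        ds = make_dataset(
            n_species=200,
            residual_sd_log=0.3,
            morphotype_fractions={"rabbit_like": 0.3},
            morphotype_shifts={"rabbit_like": 0.7},
            seed=42,
        )
        res = group_allometry(ds.species, "rabbit_like", term="intercept")
        se = res.coefficient / res.t
        assert res.coefficient - 1.96 * se < 0.7 < res.coefficient + 1.96 * se
        assert res.p < 0.001

    def test_empty_group_names_the_side(self, noisy_species):
        with pytest.raises(ValueError, match="above-threshold"):
            group_allometry(noisy_species, 1e12, term="slope")

    def test_slope_difference_detected_on_log_linear_spec(self):
        # curved data fitted log-linearly: size classes get different slopes
        ds = make_dataset(n_species=300, residual_sd_log=0.39, seed=13)
        res = group_allometry(
            ds.species, 1000.0, term="slope", spec=AllometricModelSpec.power(1.0)
        )
        assert res.p < 0.01
        assert res.coefficient < 0  # larger size class has the shallower slope
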