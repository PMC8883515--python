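import math

import dendropy
import numpy as np
import pandas as pd
import pytest

import ocwmass as m
from ocwmass import (
    AllometricModelSpec,
    brownian_vcv,
    estimate_lambda,
    fit_model,
    fit_pgls,
    lambda_vcv,
    ou_vcv,
    pgls_over_trees,
    simulate_tree,
)
from .conftest import make_dataset, star_tree


class TestBrownianVCV:
    def test_star_tree_gives_identity(self):
        cov = brownian_vcv(star_tree(list("ABCD"))).matrix
        assert np.allclose(cov, np.eye(4))

    def test_hand_read_three_taxon_tree(self, tree_abc):
        V = brownian_vcv(tree_abc).to_frame()
        assert V.loc["A", "B"] == 1.0
        assert V.loc["A", "C"] == 0.0
        assert V.loc["A", "A"] == 2.0 and V.loc["C", "C"] == 2.0

    def test_random_trees_are_positive_semidefinite(self):
        for seed in range(5):
            V = brownian_vcv(simulate_tree(40, seed=seed)).matrix
            assert np.linalg.eigvalsh(V).min() > -1e-10


class TestOUVCV:
    def test_cherry_ratio_is_exp_minus_alpha_distance(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        M = ou_vcv(tree, alpha=0.5).to_frame()
        # patristic distance 2, alpha 0.5 -> off/diag = e^-1
        assert M.loc["A", "B"] / M.loc["A", "A"] == pytest.approx(math.exp(-1))

    def test_large_alpha_approaches_independence(self):
        tree = simulate_tree(20, seed=1)
        M = ou_vcv(tree, alpha=500.0).matrix
        off = M[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 1e-6
        assert np.allclose(np.diag(M), 1.0)

    def test_small_alpha_preserves_brownian_entry_ordering(self):
        tree = simulate_tree(15, seed=2)
        B = brownian_vcv(tree).matrix
        M = ou_vcv(tree, alpha=1e-6).matrix
        iu = np.triu_indices(15, k=1)
        assert (np.argsort(B[iu]) == np.argsort(M[iu])).all()

    def test_non_ultrametric_tree_refused(self, tree_abc):
        tree = dendropy.Tree.get(data="((A:1,B:2):1,C:2);", schema="newick")
        with pytest.raises(ValueError, match="ultrametric"):
            ou_vcv(tree, alpha=1.0)

    def test_nonpositive_alpha_refused(self, tree_abc):
        with pytest.raises(ValueError):
            ou_vcv(tree_abc, alpha=0.0)


class TestLambda:
    def test_lambda_zero_is_diagonal(self, tree_abc):
        M = lambda_vcv(tree_abc, 0.0).matrix
        assert np.allclose(M, np.diag(np.diag(M)))

    def test_lambda_bounds_enforced(self, tree_abc):
        with pytest.raises(ValueError):
            lambda_vcv(tree_abc, 1.2)

    def test_unmatched_species_reported(self):
        tree = simulate_tree(12, seed=0)
        vals = pd.Series(np.zeros(12), index=[f"ghost{i}" for i in range(12)])
        with pytest.raises(ValueError, match="ghost0"):
            estimate_lambda(vals, tree)

    def test_tree_independent_data_estimates_lambda_near_zero(self):
        lams = []
        rng = np.random.default_rng(1)
        for seed in range(15):
            tree = simulate_tree(50, seed=seed)
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            vals = pd.Series(rng.standard_normal(50), index=labels)
            lams.append(estimate_lambda(vals, tree).lam)
        assert np.mean(lams) < 0.15

    def test_brownian_data_estimates_lambda_near_one(self):
        lams = []
        rng = np.random.default_rng(2)
        for seed in range(15):
            tree = simulate_tree(50, seed=seed)
            cov = brownian_vcv(tree)
            L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(50))
            vals = pd.Series(L @ rng.standard_normal(50), index=cov.labels)
            lams.append(estimate_lambda(vals, tree).lam)
        assert np.mean(lams) > 0.9


class TestExternalOracles:
    """Frozen cross-checks against an independent reference implementation
    (R: phytools::phylosig and nlme::gls with an ape corBrownian structure),
    computed once on the fixed 12-tip fixture below and recorded here."""

    def test_lambda_matches_phytools_on_frozen_fixture(self):
        # phytools::phylosig(..., method="lambda", test=TRUE) on this exact
        # tree/trait: lambda=0.644004, logL=-11.917706, logL0=-13.739146,
        # P=0.0563095
        tree = m.simulate_tree(12, seed=42)
        cov = m.brownian_vcv(tree)
        vals = pd.Series(
            [0.064233, -0.377135, 0.042406, -0.295292, -1.539220, -1.331143,
             -2.189420, -1.499232, -2.106822, -1.264080, -1.402386, -0.433068],
            index=cov.labels,
        )
        res = m.estimate_lambda(vals, tree)
        assert res.lam == pytest.approx(0.644004, abs=1e-5)
        assert res.loglik == pytest.approx(-11.917706, abs=1e-5)
        assert res.loglik0 == pytest.approx(-13.739146, abs=1e-5)
        assert res.p == pytest.approx(0.0563095, abs=1e-6)

    def test_brownian_pgls_matches_r_gls_on_frozen_fixture(self):
        # nlme::gls(log(bm) ~ log(ocw)^(2/3), corBrownian, method="ML") on
        # this exact tree/data: intercept -8.62767778 (SE 1.400557484),
        # slope 7.88371130 (SE 0.469481471), logLik -14.93565
        tree = m.simulate_tree(12, seed=42)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        data = pd.DataFrame(
            {
                "species": labels,
                "ocw": [6.858, 11.977, 96.086, 42.818, 7.076, 24.71, 29.271,
                        9.013, 75.129, 7.605, 21.171, 33.637],
                "body_mass": [36.77, 284.828, 287235.365, 28348.662, 56.755,
                              4677.368, 13542.244, 114.396, 205145.298,
                              116.559, 3719.989, 12099.053],
            }
        )
        fit = m.fit_pgls(data, tree, kind="brownian")
        assert fit.params["intercept"] == pytest.approx(-8.62767778, abs=1e-6)
        assert fit.params["ln_ocw^2/3"] == pytest.approx(7.88371130, abs=1e-6)
        assert fit.bse["intercept"] == pytest.approx(1.400557484, abs=1e-6)
        assert fit.bse["ln_ocw^2/3"] == pytest.approx(0.469481471, abs=1e-6)
        assert fit.loglik == pytest.approx(-14.93565, abs=1e-4)


class TestPGLS:
    def test_star_tree_pgls_equals_ols_exactly(self, noisy_species):
        tree = star_tree(noisy_species.species)
        ols = fit_model(noisy_species, AllometricModelSpec.power(2 / 3))
        gls = fit_pgls(noisy_species, tree, kind="brownian")
        assert np.allclose(gls.params.values, ols.params.values, atol=1e-10)

    def test_three_taxon_fit_matches_direct_gls_formula(self, tree_abc):
        data = pd.DataFrame(
            {"species": ["A", "B", "C"], "ocw": [10.0, 30.0, 90.0],
             "body_mass": [200.0, 2000.0, 50000.0]}
        )
        gls = fit_pgls(data, tree_abc, spec=AllometricModelSpec.power(1.0))
        V = brownian_vcv(tree_abc).to_frame().loc[["A", "B", "C"], ["A", "B", "C"]].values
        X = np.column_stack([np.ones(3), np.log(data.ocw)])
        y = np.log(data.body_mass.values)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(gls.params.values, beta, atol=1e-10)

    def test_lambda_endpoints_recover_ols_and_brownian(self, noisy_species):
        tree = simulate_tree(len(noisy_species), seed=5)
        data = noisy_species.assign(species=[lf.taxon.label for lf in tree.leaf_node_iter()])
        ols = fit_model(data, AllometricModelSpec.power(2 / 3))
        lam0 = fit_pgls(data, tree, kind="lambda", lam=0.0)
        lam1 = fit_pgls(data, tree, kind="lambda", lam=1.0)
        bro = fit_pgls(data, tree, kind="brownian")
        assert np.allclose(lam0.params.values, ols.params.values, atol=1e-8)
        assert np.allclose(lam1.params.values, bro.params.values, atol=1e-10)

    def test_coefficients_invariant_to_covariance_rescaling(self, tree_abc):
        data = pd.DataFrame(
            {"species": ["A", "B", "C"], "ocw": [10.0, 30.0, 90.0],
             "body_mass": [200.0, 2000.0, 50000.0]}
        )
        # scaling every branch length scales V but not the GLS solution
        scaled = dendropy.Tree.get(data="((A:5,B:5):5,C:10);", schema="newick")
        a = fit_pgls(data, tree_abc, spec=AllometricModelSpec.power(1.0))
        b = fit_pgls(data, scaled, spec=AllometricModelSpec.power(1.0))
        assert np.allclose(a.params.values, b.params.values, atol=1e-10)

    def test_joint_lambda_estimation_tracks_residual_structure(self):
        iid = make_dataset(n_species=150, residual_sd_log=0.39, lambda_signal=0.0, seed=61)
        bro = make_dataset(n_species=150, residual_sd_log=0.39, lambda_signal=1.0, seed=61)
        lam_iid = fit_pgls(iid.species, iid.tree, kind="lambda").parameters["lambda"]
        lam_bro = fit_pgls(bro.species, bro.tree, kind="lambda").parameters["lambda"]
        assert lam_iid < 0.2
        assert lam_bro > 0.5

    def test_ou_profiling_estimates_alpha(self):
        ds = make_dataset(n_species=40, residual_sd_log=0.3, lambda_signal=0.0, seed=17)
        fit = fit_pgls(ds.species, ds.tree, kind="ou")
        assert fit.parameters["alpha"] > 0
        assert np.isfinite(fit.loglik)

    def test_per_tree_summaries_have_one_row_per_tree(self):
        ds = make_dataset(n_species=30, residual_sd_log=0.3, seed=19)
        trees = [ds.tree] * 3
        table = pgls_over_trees(ds.species, trees)
        assert len(table) == 3
        assert table["aic"].nunique() == 1  # identical trees, identical fits
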