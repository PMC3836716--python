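import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import Lasso, lasso_path

from pathsgl.data import GenotypeMatrix, PhenotypeTable
from pathsgl.mapping import PathwayCollection
from pathsgl.sgl import (
    SGLConfig,
    SGLProblem,
    fit_lasso,
    fit_sgl_bcgd,
    fit_sgl_cgd,
    group_entry_lambda,
    kkt_max_violation,
    lambda_max,
    match_lasso_size,
    preprocess,
    sgl_objective,
    soft_threshold,
)

from conftest import make_problem
from oracles import (
    admm_sgl,
    entry_lambda_bisect,
    expanded_design,
    sgl_objective_expanded,
)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,t,expect",
        [(0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (2.0, 0.0, 2.0)],
    )
    def test_scalar_cases(self, z, t, expect):
        assert soft_threshold(np.array([z]), t)[0] == pytest.approx(expect)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        st.floats(0, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_shrinks_toward_zero_and_keeps_sign(self, zs, t):
        z = np.array(zs)
        s = soft_threshold(z, t)
        assert (np.abs(s) <= np.abs(z) + 1e-12).all()
        assert (s * z >= 0).all()
        if t == 0:
            np.testing.assert_allclose(s, z)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)


class TestPreprocess:
    def test_centred_y_without_covariates_unchanged(self, rng, small_genotypes):
        y = rng.standard_normal(small_genotypes.n_samples)
        y -= y.mean()
        coll = PathwayCollection([np.arange(30)], ["p"])
        prob = preprocess(small_genotypes, PhenotypeTable(y), coll)
        np.testing.assert_allclose(prob.y, y, atol=1e-12)
        assert np.abs(prob.X.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(prob.X.var(axis=0), 1.0, atol=1e-10)

    def test_covariate_equal_to_y_gives_zero_residual(self, rng, small_genotypes):
        import pandas as pd

        y = rng.standard_normal(small_genotypes.n_samples)
        ph = PhenotypeTable(y, covariates=pd.DataFrame({"c": y}))
        coll = PathwayCollection([np.arange(30)], ["p"])
        prob = preprocess(small_genotypes, ph, coll)
        assert np.abs(prob.y).max() < 1e-10

    def test_residual_orthogonal_to_covariates(self, rng):
        import pandas as pd

        G = GenotypeMatrix(
            rng.binomial(2, 0.3, size=(20, 5)).astype(float),
            [f"s{j}" for j in range(5)],
        )
        C = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        ph = PhenotypeTable(y, covariates=pd.DataFrame(C))
        coll = PathwayCollection([np.arange(5)], ["p"])
        prob = preprocess(G, ph, coll)
        assert np.abs(C.T @ prob.y).max() < 1e-10

    def test_zero_variance_snps_dropped_and_groups_remapped(self, rng):
        vals = rng.binomial(2, 0.4, size=(30, 4)).astype(float)
        vals[:, 2] = 1.0  # monomorphic
        G = GenotypeMatrix(vals, ["a", "b", "c", "d"])
        y = PhenotypeTable(rng.standard_normal(30))
        coll = PathwayCollection([np.array([0, 2]), np.array([1, 3])], ["p1", "p2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            prob = preprocess(G, y, coll)
        assert prob.X.shape[1] == 3
        assert prob.snp_ids == ["a", "b", "d"]
        groups = {n: g.tolist() for n, g in zip(prob.pathways.names, prob.pathways.groups)}
        assert groups == {"p1": [0], "p2": [1, 2]}

    def test_all_zero_variance_errors(self):
        G = GenotypeMatrix(np.ones((10, 2)), ["a", "b"])
        coll = PathwayCollection([np.arange(2)], ["p"])
        with pytest.raises(ValueError, match="zero variance"):
            preprocess(G, PhenotypeTable(np.zeros(10)), coll)


class TestGroupEntryLambda:
    def test_orthogonal_response_gives_zero(self, rng):
        Xl = np.eye(10)[:, :3]
        v = np.zeros(10)
        v[5] = 1.0
        assert group_entry_lambda(Xl, v, 0.9, 1.0) == 0.0

    def test_single_snp_alpha_one_closed_form(self, rng):
        x = rng.standard_normal(40)
        v = rng.standard_normal(40)
        assert group_entry_lambda(x[:, None], v, 1.0, 2.0) == pytest.approx(
            abs(x @ v)
        )

    def test_alpha_zero_closed_form(self, rng):
        Xl = rng.standard_normal((40, 4))
        v = rng.standard_normal(40)
        assert group_entry_lambda(Xl, v, 0.0, 1.7) == pytest.approx(
            np.linalg.norm(Xl.T @ v) / 1.7
        )

    def test_alpha_zero_weight_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            group_entry_lambda(np.ones((5, 2)), np.ones(5), 0.0, 0.0)

    @pytest.mark.parametrize("alpha", [0.3, 0.8, 0.95])
    def test_matches_bisection_oracle(self, rng, alpha):
        for _ in range(10):
            Xl = rng.standard_normal((30, 3))
            v = rng.standard_normal(30)
            w = rng.uniform(0.5, 3.0)
            ours = group_entry_lambda(Xl, v, alpha, w)
            oracle = entry_lambda_bisect(Xl, v, alpha, w)
            assert ours == pytest.approx(oracle, abs=1e-8)


class TestLambdaMax:
    def test_zero_response(self, rng):
        prob = make_problem(rng)
        prob.y[:] = 0.0
        assert lambda_max(prob, SGLConfig(alpha=0.9)) == 0.0

    def test_definitional_emptiness_and_entry(self, rng):
        prob = make_problem(rng, beta={1: 1.0, 12: 0.8})
        for alpha in (1.0, 0.9, 0.0):
            hi = SGLConfig(fraction_of_lambda_max=1.0001, alpha=alpha)
            lo = SGLConfig(fraction_of_lambda_max=0.99, alpha=alpha)
            assert fit_sgl_bcgd(prob, hi).n_selected_pathways == 0
            assert fit_sgl_cgd(prob, hi).n_selected_pathways == 0
            assert fit_sgl_cgd(prob, lo).n_selected_pathways >= 1

    def test_equals_max_of_per_group_bisections(self, rng):
        prob = make_problem(rng, beta={5: 0.5})
        cfg = SGLConfig(alpha=0.85)
        oracle = max(
            entry_lambda_bisect(
                prob.group_matrix(l), prob.y, cfg.alpha, prob.pathways.weights[l]
            )
            for l in range(prob.pathways.n_pathways)
        )
        assert lambda_max(prob, cfg) == pytest.approx(oracle, rel=1e-10)


class TestBcgd:
    def test_alpha_one_matches_sklearn_lasso(self, rng):
        prob = make_problem(rng, n=50, groups=((0, 10), (10, 20)), beta={2: 1.0})
        cfg = SGLConfig(fraction_of_lambda_max=0.4, alpha=1.0, tol=1e-10)
        lam = cfg.resolve_lambda(prob)
        fit = fit_sgl_bcgd(prob, cfg)
        sk = Lasso(alpha=lam / prob.n_samples, fit_intercept=False, tol=1e-12,
                   max_iter=100000).fit(prob.X, prob.y)
        beta_ours = np.zeros(prob.X.shape[1])
        for l, sl in enumerate(prob.expanded.group_slices):
            beta_ours[prob.pathways.groups[l]] += fit.beta[sl]
        np.testing.assert_allclose(beta_ours, sk.coef_, atol=1e-6)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.95])
    def test_objective_matches_admm_oracle_disjoint(self, rng, alpha):
        prob = make_problem(
            rng, n=30, groups=((0, 4), (4, 8), (8, 12)), beta={0: 1.2, 5: -0.9}
        )
        cfg = SGLConfig(fraction_of_lambda_max=0.5, alpha=alpha, tol=1e-10)
        lam = cfg.resolve_lambda(prob)
        fit = fit_sgl_bcgd(prob, cfg)
        Xe = expanded_design(prob)
        sl = prob.expanded.group_slices
        w = prob.pathways.weights
        z = admm_sgl(Xe, prob.y, sl, w, lam, alpha)
        o_ours = sgl_objective_expanded(Xe, prob.y, sl, w, lam, alpha, fit.beta)
        o_admm = sgl_objective_expanded(Xe, prob.y, sl, w, lam, alpha, z)
        assert o_ours <= o_admm + 1e-6 * max(1.0, abs(o_admm))

    def test_objective_monotone_nonincreasing(self, rng):
        prob = make_problem(
            rng,
            overlap_groups=[np.arange(0, 14), np.arange(10, 24), np.arange(20, 34)],
            beta={3: 1.0, 11: 0.8, 22: -0.6},
        )
        cfg = SGLConfig(fraction_of_lambda_max=0.3, alpha=0.6)
        fit = fit_sgl_bcgd(prob, cfg)
        tr = np.array(fit.objective_trace)
        assert (np.diff(tr) <= 1e-9 * np.maximum(1.0, np.abs(tr[:-1]))).all()

    def test_kkt_on_random_overlapping_instances(self, rng):
        for i in range(5):
            prob = make_problem(
                rng,
                n=40,
                overlap_groups=[
                    np.arange(0, 12),
                    np.arange(8, 22),
                    np.arange(18, 30),
                ],
                beta={1: 1.0, 9: -0.7},
            )
            cfg = SGLConfig(fraction_of_lambda_max=0.4, alpha=0.7, tol=1e-8)
            fit = fit_sgl_bcgd(prob, cfg)
            assert kkt_max_violation(prob, cfg, fit) <= 10 * cfg.tol * max(
                1.0, np.abs(prob.X.T @ prob.y).max()
            )

    def test_alpha_zero_selects_whole_groups(self, rng):
        prob = make_problem(rng, beta={1: 1.5, 3: 1.0})
        cfg = SGLConfig(fraction_of_lambda_max=0.5, alpha=0.0)
        fit = fit_sgl_bcgd(prob, cfg)
        assert fit.n_selected_pathways >= 1
        for l in fit.selected_pathways:
            # group lasso: all coefficients in a selected group are nonzero
            bl = fit.beta[prob.expanded.group_slices[l]]
            assert (bl != 0).all()


class TestCgd:
    def test_single_active_disjoint_matches_bcgd(self, rng):
        prob = make_problem(rng, beta={2: 2.0, 5: 1.5}, noise=0.5)
        cfg = SGLConfig(fraction_of_lambda_max=0.8, alpha=0.9)
        fc = fit_sgl_cgd(prob, cfg)
        fb = fit_sgl_bcgd(prob, cfg)
        assert fc.selected_pathways == [0]
        assert fb.selected_pathways == [0]
        np.testing.assert_array_equal(fc.selected_snps, fb.selected_snps)

    def test_duplicated_pathways_symmetric(self, rng):
        g = np.arange(0, 10)
        prob = make_problem(
            rng, overlap_groups=[g, g.copy()], beta={2: 1.2}, noise=0.8
        )
        cfg = SGLConfig(fraction_of_lambda_max=0.6, alpha=0.8)
        fit = fit_sgl_cgd(prob, cfg)
        assert fit.selected_pathways in ([], [0, 1])
        if fit.selected_pathways:
            np.testing.assert_array_equal(
                fit.selected_snps_by_pathway[0], fit.selected_snps_by_pathway[1]
            )

    def test_partially_overlapping_causal_cgd_keeps_both(self, rng):
        # construction with nested causal sets: strong SNPs shared by both
        # pathways plus weaker ones private to the second; the independence
        # assumption keeps both pathways while joint optimisation explains
        # the shared signal once and drops the weaker pathway
        rng = np.random.default_rng(7)
        N, P = 500, 50
        X = rng.standard_normal((N, P))
        X = (X - X.mean(0)) / X.std(0)
        g1 = np.arange(0, 20)
        g2 = np.arange(10, 40)  # shares 10..19 with g1
        beta = np.zeros(P)
        beta[[12, 14, 16]] = 1.0  # strong shared causal SNPs
        beta[[25, 30]] = 0.25  # weak causal SNPs private to pathway 2
        y = X @ beta + rng.standard_normal(N)
        y -= y.mean()
        coll = PathwayCollection([g1, g2], ["p1", "p2"])
        prob = SGLProblem(X, y, coll)
        cfg = SGLConfig(fraction_of_lambda_max=0.6, alpha=0.8)
        fc = fit_sgl_cgd(prob, cfg)
        fb = fit_sgl_bcgd(prob, cfg)
        assert set(fc.selected_pathways) == {0, 1}
        assert set(fb.selected_pathways) < set(fc.selected_pathways)

    def test_order_invariance(self, rng):
        prob = make_problem(
            rng,
            overlap_groups=[np.arange(0, 12), np.arange(8, 20), np.arange(15, 28)],
            beta={2: 1.0, 17: 0.8},
        )
        cfg = SGLConfig(fraction_of_lambda_max=0.5, alpha=0.85)
        fit1 = fit_sgl_cgd(prob, cfg)
        perm = [2, 0, 1]
        coll2 = PathwayCollection(
            [prob.pathways.groups[i] for i in perm],
            [prob.pathways.names[i] for i in perm],
            prob.pathways.weights[perm],
        )
        prob2 = SGLProblem(prob.X, prob.y, coll2)
        fit2 = fit_sgl_cgd(prob2, cfg)
        assert {perm[l] for l in fit2.selected_pathways} == set(fit1.selected_pathways)
        np.testing.assert_array_equal(fit1.selected_snps, fit2.selected_snps)

    def test_lambda_path_nesting(self, rng):
        prob = make_problem(rng, beta={1: 0.8, 11: 0.6, 21: 0.4}, noise=1.0)
        prev = None
        for frac in (0.95, 0.8, 0.6, 0.4):
            cfg = SGLConfig(fraction_of_lambda_max=frac, alpha=0.9)
            sel = set(fit_sgl_cgd(prob, cfg).selected_pathways)
            if prev is not None:
                assert prev <= sel
            prev = sel


class TestLassoBaseline:
    def test_fit_lasso_matches_sklearn(self, rng):
        X = rng.standard_normal((60, 25))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 3] * 1.5 - X[:, 10] + rng.standard_normal(60)
        y -= y.mean()
        lam = 0.3 * np.abs(X.T @ y).max()
        ours = fit_lasso(X, y, lam, tol=1e-10)
        sk = Lasso(alpha=lam / 60, fit_intercept=False, tol=1e-12,
                   max_iter=100000).fit(X, y)
        np.testing.assert_allclose(ours, sk.coef_, atol=1e-6)

    def test_zero_target_empty(self, rng):
        X = rng.standard_normal((20, 5))
        assert match_lasso_size(X, rng.standard_normal(20), 0).size == 0

    def test_saturation_bound(self, rng):
        X = rng.standard_normal((15, 40))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.standard_normal(15)
        y -= y.mean()
        sel = match_lasso_size(X, y, 40, lambda_min_ratio=1e-4)
        assert sel.size <= 14  # lasso saturates at N-1 active predictors

    def test_matches_grid_scan_with_independent_solver(self, rng):
        X = rng.standard_normal((100, 30))
        X = (X - X.mean(0)) / X.std(0)
        beta = np.zeros(30)
        beta[[2, 7, 11, 19]] = [1.0, -0.8, 0.6, 0.5]
        y = X @ beta + rng.standard_normal(100)
        y -= y.mean()
        n_target = 6
        sel = match_lasso_size(X, y, n_target, n_grid=100, lambda_min_ratio=1e-3)
        assert sel.size <= n_target
        # replicate the documented scan rule with sklearn as the solver
        lmax = np.abs(X.T @ y).max()
        grid = np.geomspace(lmax, lmax * 1e-3, 100)
        best = np.array([], dtype=int)
        for lam in grid:
            sk = Lasso(alpha=lam / 100, fit_intercept=False, tol=1e-12,
                       max_iter=100000).fit(X, y)
            s = np.flatnonzero(np.abs(sk.coef_) > 1e-10)
            if s.size > n_target:
                break
            if s.size > best.size:
                best = s
        np.testing.assert_array_equal(sel, best)
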