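import numpy as np
import pytest

from survldm import (Covariates, dist_combined_omnibus, gower_center,
                     ldm_test, make_permutation_plan, mirkat_adjusted_test,
                     mirkat_s_test, mirkat_score, permanova_fl_test)
from survldm.transforms import DistanceMatrix, TaxonMatrix, distance_matrix


def euclid_dist(Z):
    return distance_matrix(TaxonMatrix(Z, "relabund"), "euclidean")


class TestPseudoF:
    def test_single_column_equals_univariate_regression_f(self):
        # Euclidean distances of one centered column: pseudo-F is the
        # classical regression F of z on the (unit) regressor
        rng = np.random.default_rng(1)
        n = 20
        z = rng.normal(size=n)
        z -= z.mean()
        r = rng.normal(size=n)
        plan = make_permutation_plan(n, 10, seed=0)
        res = permanova_fl_test(euclid_dist(z[:, None]), None, r, plan)
        rt = (r - r.mean()) / np.linalg.norm(r - r.mean())
        R2 = float(rt @ z) ** 2 / (z @ z)
        F_expected = R2 / (1 - R2) * (n - 2)
        assert res.F == pytest.approx(F_expected, rel=1e-8)

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(2)
        n = 4
        Z = rng.normal(size=(n, 3))
        r = rng.normal(size=n)
        X = rng.normal(size=(n, 1))
        X -= X.mean(axis=0)
        D = euclid_dist(Z)
        plan = make_permutation_plan(n, 1, seed=0, exhaustive=True)
        res = permanova_fl_test(D, Covariates(X, ["x"], centered=True), r,
                                plan)

        # independent loop oracle
        D2 = D.D ** 2
        C = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * C @ D2 @ C
        design = np.column_stack([np.ones(n), X])

        def pseudo_f(vec):
            v = np.asarray(vec, float)
            v = v - v.mean()
            coef, *_ = np.linalg.lstsq(design, v, rcond=None)
            v = v - design @ coef
            v = v / np.linalg.norm(v)
            q = v @ G @ v
            basis = X / np.linalg.norm(X)
            T0 = np.trace(G) - float(basis[:, 0] @ G @ basis[:, 0])
            return q / ((T0 - q) / (n - 1 - 2))

        F_obs = pseudo_f(r)
        nulls = [pseudo_f(r[list(p)]) for p in plan.permutations]
        p_expected = (1 + sum(f >= F_obs - 1e-12 for f in nulls)) / (plan.B + 1)
        assert res.p == pytest.approx(p_expected, abs=1e-12)

    def test_too_few_degrees_of_freedom(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(3, 2))
        X = rng.normal(size=(3, 1))
        X -= X.mean(axis=0)
        plan = make_permutation_plan(3, 5, seed=0)
        with pytest.raises(ValueError, match="degrees of freedom"):
            permanova_fl_test(euclid_dist(Z), Covariates(X, ["x"], centered=True),
                              rng.normal(size=3), plan)


class TestMirkatScore:
    def test_hand_quadratic_form(self):
        K = np.array([[2.0, -1.0, -1.0],
                      [-1.0, 2.0, -1.0],
                      [-1.0, -1.0, 2.0]])
        r = np.array([1.0, 0.0, -1.0])
        assert mirkat_score(K, r) == pytest.approx(6.0)

    def test_zero_residual(self):
        assert mirkat_score(np.eye(3), np.zeros(3)) == 0.0

    def test_linear_kernel_equals_global_u_squared(self):
        # M' (ZZ') M = sum_j (sum_i M_i Z_ij)^2 for centered Z
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(25, 7))
        Z -= Z.mean(axis=0)
        M = rng.normal(size=25)
        Q = mirkat_score(Z @ Z.T, M)
        U = M @ Z
        assert Q == pytest.approx((U ** 2).sum(), rel=1e-8)


class TestMirkatSTest:
    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(5)
        n = 4
        Z = rng.normal(size=(n, 3))
        M = rng.normal(size=n)
        K = gower_center(euclid_dist(Z))
        plan = make_permutation_plan(n, 1, seed=0, exhaustive=True)
        res = mirkat_s_test(K, M, plan)
        Q_obs = float(M @ K.K @ M)
        nulls = [float(M[list(p)] @ K.K @ M[list(p)])
                 for p in plan.permutations]
        p_expected = (1 + sum(q >= Q_obs - 1e-12 for q in nulls)) / (plan.B + 1)
        assert res.p == pytest.approx(p_expected, abs=1e-12)

    def test_uniform_pvalues_under_exhaustive_permutation(self):
        # treating each relabeling as observed, the p-values are exactly
        # the uniform grid {2/25, ..., 25/25} (identity is among the nulls)
        rng = np.random.default_rng(6)
        n = 4
        Z = rng.normal(size=(n, 2))
        M = rng.normal(size=n)
        K = gower_center(euclid_dist(Z))
        plan = make_permutation_plan(n, 1, seed=0, exhaustive=True)
        ps = sorted(mirkat_s_test(K, M[list(p)], plan).p
                    for p in plan.permutations)
        expected = sorted((1 + k) / 25 for k in range(1, 25))
        np.testing.assert_allclose(ps, expected)


class TestMirkatAdjusted:
    def test_reduces_to_unadjusted_without_covariates(self):
        rng = np.random.default_rng(7)
        n = 15
        Z = rng.normal(size=(n, 4))
        M = rng.normal(size=n)
        M -= M.mean()
        K = gower_center(euclid_dist(Z))
        plan = make_permutation_plan(n, 200, seed=1)
        assert mirkat_adjusted_test(K, None, M, plan).p == \
            mirkat_s_test(K, M, plan).p

    def test_exhaustive_matches_brute_force_with_covariate(self):
        rng = np.random.default_rng(8)
        n = 4
        Z = rng.normal(size=(n, 2))
        r = rng.normal(size=n)
        X = rng.normal(size=(n, 1))
        X -= X.mean(axis=0)
        K = gower_center(euclid_dist(Z))
        plan = make_permutation_plan(n, 1, seed=0, exhaustive=True)
        res = mirkat_adjusted_test(K, Covariates(X, ["x"], centered=True), r,
                                   plan)
        basis = X / np.linalg.norm(X)

        def q(vec):
            v = np.asarray(vec, float)
            v = v - v.mean()
            v = v - basis @ (basis.T @ v)
            v = v / np.linalg.norm(v)
            return float(v @ K.K @ v)

        Q_obs = q(r)
        nulls = [q(r[list(p)]) for p in plan.permutations]
        p_expected = (1 + sum(x >= Q_obs - 1e-12 for x in nulls)) / (plan.B + 1)
        assert res.p == pytest.approx(p_expected, abs=1e-12)


class TestCrossMethodAgreement:
    def test_ldm_global_matches_mirkat_s_linear_kernel(self):
        # no covariates + Euclidean distance on centered data: the LDM
        # global F and the kernel score are monotone transforms of the same
        # quadratic form, so shared-plan p-values coincide
        rng = np.random.default_rng(9)
        n = 18
        Z = rng.normal(size=(n, 5))
        Zc = Z - Z.mean(axis=0)
        M = rng.normal(size=n)
        M -= M.mean()
        plan = make_permutation_plan(n, 300, seed=2)
        ldm = ldm_test(TaxonMatrix(Zc, "relabund", centered=True), None, M,
                       plan)
        K = gower_center(euclid_dist(Zc))
        mk = mirkat_s_test(K, M, plan)
        assert ldm.p_global == pytest.approx(mk.p)

    def test_permanova_euclidean_matches_ldm_global(self):
        rng = np.random.default_rng(10)
        n = 16
        Z = rng.normal(size=(n, 6))
        Zc = Z - Z.mean(axis=0)
        r = rng.normal(size=n)
        plan = make_permutation_plan(n, 250, seed=3)
        ldm = ldm_test(TaxonMatrix(Zc, "relabund", centered=True), None, r,
                       plan)
        pfl = permanova_fl_test(euclid_dist(Zc), None, r, plan)
        assert pfl.p == pytest.approx(ldm.p_global)


class TestDistOmnibus:
    def test_single_component_identity(self):
        rng = np.random.default_rng(11)
        n = 12
        Z = rng.normal(size=(n, 3))
        r = rng.normal(size=n)
        plan = make_permutation_plan(n, 100, seed=4)
        res = permanova_fl_test(euclid_dist(Z), None, r, plan)
        assert float(dist_combined_omnibus([res]).pvalue) == \
            pytest.approx(res.p)

    def test_duplicate_components_within_rank_unit(self):
        rng = np.random.default_rng(12)
        n = 12
        Z = rng.normal(size=(n, 3))
        r = rng.normal(size=n)
        plan = make_permutation_plan(n, 100, seed=5)
        res = permanova_fl_test(euclid_dist(Z), None, r, plan)
        import copy
        twin = copy.deepcopy(res)
        twin.global_stat.label = "twin"
        comb = float(dist_combined_omnibus([res, twin]).pvalue)
        assert abs(comb - res.p) <= 1 / (plan.B + 1) + 1e-12

    def test_mismatched_plans_rejected(self):
        rng = np.random.default_rng(13)
        n = 10
        Z = rng.normal(size=(n, 3))
        r = rng.normal(size=n)
        a = permanova_fl_test(euclid_dist(Z), None, r,
                              make_permutation_plan(n, 50, seed=1))
        b = permanova_fl_test(euclid_dist(Z), None, r,
                              make_permutation_plan(n, 50, seed=2))
        with pytest.raises(ValueError, match="plan"):
            dist_combined_omnibus([a, b])
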