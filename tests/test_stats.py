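"""First-principles statistics against brute-force and library oracles."""
import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dbck import stats
from dbck.stats import (ExploratoryFactorAnalysis, bartlett_sphericity,
                        extract_factors, kmo, pearson_regression, run_efa,
                        ttest2, varimax, varimax_criterion)


def planted_loadings_data(rng, n=500, p=21, k=3, loading=0.7):
    lam = np.zeros((p, k))
    for j in range(p):
        lam[j, j % k] = loading
    factors = rng.normal(size=(n, k))
    noise = rng.normal(size=(n, p)) * np.sqrt(1 - loading ** 2)
    return factors @ lam.T + noise, lam


class TestPearsonRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        rep = pearson_regression(x, 2 * x + 1)
        assert rep.r == 1.0
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(1.0)
        assert rep.p_two_tailed == 0.0

    def test_anticorrelated(self):
        x = np.arange(8.0)
        assert pearson_regression(x, -x).r == -1.0

    def test_against_brute_force_formula(self):
        """Direct product-moment formula written out independently."""
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0, 9.0])
        y = np.array([2.1, 1.9, 3.5, 5.0, 6.1, 8.4])
        n = len(x)
        num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
        den = np.sqrt((n * np.sum(x ** 2) - np.sum(x) ** 2) *
                      (n * np.sum(y ** 2) - np.sum(y) ** 2))
        rep = pearson_regression(x, y)
        assert rep.r == pytest.approx(num / den, abs=1e-12)
        assert rep.r2 == pytest.approx(rep.r ** 2, abs=1e-12)

    def test_against_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        rep = pearson_regression(x, y)
        r_sp, p_sp = scipy.stats.pearsonr(x, y)
        fit = scipy.stats.linregress(x, y)
        assert rep.r == pytest.approx(r_sp, abs=1e-12)
        assert rep.p_two_tailed == pytest.approx(p_sp, abs=1e-12)
        assert rep.slope == pytest.approx(fit.slope, abs=1e-12)
        assert rep.intercept == pytest.approx(fit.intercept, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50), st.floats(-100, 100),
           st.floats(0.1, 50), st.floats(-100, 100))
    def test_r_invariant_under_positive_affine_maps(self, ax, bx, ay, by):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        r0 = pearson_regression(x, y).r
        r1 = pearson_regression(ax * x + bx, ay * y + by).r
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_regression(np.ones(5), np.arange(5.0))


class TestTtest2:
    def test_identical_groups(self):
        res = ttest2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_hand_computed_pooled_formula(self):
        x = np.array([4.2, 5.1, 6.3, 5.9, 4.8])
        y = np.array([3.1, 3.9, 4.4, 3.3, 4.0])
        nx = ny = 5
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / \
            (nx + ny - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        res = ttest2(x, y)
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.df == 8

    def test_against_scipy_both_variants(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 2, 9)
        for welch in (False, True):
            res = ttest2(x, y, welch=welch)
            ref = scipy.stats.ttest_ind(x, y, equal_var=not welch)
            assert res.t == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ttest2([1.0], [1.0, 2.0])


class TestBartlett:
    def test_identity_gives_zero(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), 100)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_df_formula(self):
        _, df, _ = bartlett_sphericity(np.eye(4), 50)
        assert df == 6

    def test_against_direct_evaluation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 5))
        X[:, 1] += 0.7 * X[:, 0]
        corr = np.corrcoef(X, rowvar=False)
        n, p = 80, 5
        chi2_direct = -(n - 1 - (2 * p + 5) / 6) * np.log(
            np.linalg.det(corr))
        chi2, df, pval = bartlett_sphericity(corr, n)
        assert chi2 == pytest.approx(chi2_direct, abs=1e-10)
        assert pval == pytest.approx(
            scipy.stats.chi2.sf(chi2_direct, p * (p - 1) // 2), abs=1e-12)

    def test_singular_matrix_flagged(self):
        corr = np.ones((3, 3))
        with pytest.warns(UserWarning, match="singular"):
            chi2, _, p = bartlett_sphericity(corr, 50)
        assert np.isinf(chi2)
        assert p == 0.0


class TestKmo:
    def test_two_variables_exactly_half(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        overall, per_var = kmo(corr)
        assert overall == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(per_var, 0.5, atol=1e-12)

    def test_identity_correlation_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            kmo(np.eye(4))

    def test_against_partial_correlation_oracle(self):
        """Brute-force oracle: partial correlations computed by explicitly
        regressing out all other variables."""
        rng = np.random.default_rng(3)
        X, _ = planted_loadings_data(rng, n=300, p=6, k=2)
        corr = np.corrcoef(X, rowvar=False)
        p = corr.shape[0]
        partial = np.zeros((p, p))
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                others = [k for k in range(p) if k not in (i, j)]
                # residualize variables i and j on the others
                A = np.column_stack([X[:, others],
                                     np.ones(len(X))])
                ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
                rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
                partial[i, j] = np.corrcoef(ri, rj)[0, 1]
        off = ~np.eye(p, dtype=bool)
        kmo_oracle = (corr[off] ** 2).sum() / (
            (corr[off] ** 2).sum() + (partial[off] ** 2).sum())
        overall, _ = kmo(corr)
        assert overall == pytest.approx(kmo_oracle, abs=1e-10)


class TestExtractFactors:
    def test_identity_correlation(self):
        eigval, loadings = extract_factors(np.eye(5), 2)
        assert np.allclose(eigval, 1.0)
        assert np.allclose(loadings.T @ loadings, np.eye(2), atol=1e-10)

    def test_compound_symmetry_closed_form(self):
        """Rank-1 planted factor (loading 0.8 on 4 variables): the first
        eigenvalue is 1 + 3·0.64 and the first loading column is uniform
        at sqrt(eig)/2."""
        r = 0.64
        corr = np.full((4, 4), r)
        np.fill_diagonal(corr, 1.0)
        eigval, loadings = extract_factors(corr, 1)
        assert eigval[0] == pytest.approx(1 + 3 * r, abs=1e-12)
        assert np.allclose(eigval[1:], 1 - r, atol=1e-12)
        expected = np.sqrt(1 + 3 * r) / 2
        assert np.allclose(loadings[:, 0], expected, atol=1e-12)
        # the PCA loading overestimates the planted 0.8 by design
        assert loadings[0, 0] == pytest.approx(0.8, abs=0.06)

    def test_reconstruction_error_bounded_by_discarded_eigenvalues(self):
        rng = np.random.default_rng(4)
        X, _ = planted_loadings_data(rng, n=400, p=9, k=2)
        corr = np.corrcoef(X, rowvar=False)
        eigval, loadings = extract_factors(corr, 3)
        residual = corr - loadings @ loadings.T
        assert np.linalg.norm(residual, 2) <= eigval[3] + 1e-10

    def test_principal_axis_recovers_planted_loading_exactly(self):
        """For compound symmetry with loading 0.8 the reduced matrix is
        rank one, so principal-axis factoring converges to 0.8 exactly
        (where PCA overestimates)."""
        corr = np.full((4, 4), 0.64)
        np.fill_diagonal(corr, 1.0)
        _, loadings = extract_factors(corr, 1, method="paf")
        assert np.allclose(loadings[:, 0], 0.8, atol=1e-7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            extract_factors(np.eye(3), 4)
        with pytest.raises(ValueError):
            extract_factors(np.eye(3), 2, method="ml")


def _hill_climb_varimax(L, n_angles=181, sweeps=200):
    """Independent oracle: per-pair exhaustive angle grid search followed
    by a bounded 1-D refinement, repeated until no pair improves."""
    from scipy.optimize import minimize_scalar
    L = L.copy()
    k = L.shape[1]
    grid = np.linspace(-np.pi / 4, np.pi / 4, n_angles)
    step = grid[1] - grid[0]

    def rotated_pair(mat, i, j, ang):
        c, s = np.cos(ang), np.sin(ang)
        out = mat.copy()
        out[:, [i, j]] = out[:, [i, j]] @ np.array([[c, -s], [s, c]])
        return out

    for _ in range(sweeps):
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                base = varimax_criterion(L)
                gains = np.array([
                    varimax_criterion(rotated_pair(L, i, j, a)) - base
                    for a in grid])
                best = grid[int(np.argmax(gains))]
                res = minimize_scalar(
                    lambda a: -varimax_criterion(rotated_pair(L, i, j, a)),
                    bounds=(best - step, best + step), method="bounded",
                    options={"xatol": 1e-12})
                if -res.fun - base > 1e-12:
                    L = rotated_pair(L, i, j, float(res.x))
                    improved = True
        if not improved:
            break
    return L


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = 0.8
        L[3:, 1] = 0.7
        rotated, R = varimax(L)
        assert varimax_criterion(rotated) == pytest.approx(
            varimax_criterion(L), abs=1e-12)
        # rotation is a signed permutation
        assert np.allclose(np.abs(R), np.eye(2), atol=1e-8)

    def test_single_factor_unchanged(self):
        L = np.random.default_rng(5).normal(size=(7, 1))
        rotated, R = varimax(L)
        assert np.array_equal(rotated, L)
        assert R.shape == (1, 1)

    def test_never_decreases_criterion_and_preserves_communality(self):
        """The rotation is monotone in the criterion it optimizes: the
        raw criterion without Kaiser normalization, the row-normalized
        criterion with it."""
        rng = np.random.default_rng(6)

        def normalized_criterion(mat):
            h = np.sqrt((mat ** 2).sum(axis=1, keepdims=True))
            return varimax_criterion(mat / np.where(h == 0, 1.0, h))

        for _ in range(5):
            L = rng.normal(size=(8, 3))
            raw, R0 = varimax(L, kaiser_normalize=False)
            assert varimax_criterion(raw) >= varimax_criterion(L) - 1e-12
            rotated, R = varimax(L, kaiser_normalize=True)
            assert normalized_criterion(rotated) >= \
                normalized_criterion(L) - 1e-12
            for rot, out in ((R0, raw), (R, rotated)):
                assert np.allclose(rot.T @ rot, np.eye(3), atol=1e-10)
                assert np.allclose((out ** 2).sum(axis=1),
                                   (L ** 2).sum(axis=1), atol=1e-10)
                assert np.allclose(L @ rot, out, atol=1e-10)

    def test_matches_hill_climb_oracle(self):
        rng = np.random.default_rng(7)
        L = rng.normal(size=(8, 3))
        rotated, _ = varimax(L, kaiser_normalize=False)
        oracle = _hill_climb_varimax(L)
        assert varimax_criterion(rotated) == pytest.approx(
            varimax_criterion(oracle), abs=1e-8)

    def test_matches_statsmodels(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors
        rng = np.random.default_rng(8)
        L = rng.normal(size=(10, 3))
        rotated, _ = varimax(L, kaiser_normalize=False)
        sm_rotated, _ = rotate_factors(L, "varimax")
        assert varimax_criterion(rotated) == pytest.approx(
            varimax_criterion(sm_rotated), abs=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            varimax(np.array([[np.nan, 1.0], [0.0, 1.0]]))


class TestRunEfa:
    def test_planted_three_factor_recovery(self):
        rng = np.random.default_rng(9)
        X, lam = planted_loadings_data(rng, n=500, p=21, k=3, loading=0.7)
        res = run_efa(X)
        assert res.n_factors == 3
        mask = res.significant_mask
        groups = sorted(tuple(sorted(np.nonzero(mask[:, j])[0]))
                        for j in range(3))
        planted = sorted(tuple(sorted(np.nonzero(lam[:, j])[0]))
                         for j in range(3))
        assert groups == planted

    def test_independent_noise_warns(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 4))
        with pytest.warns(UserWarning):
            ExploratoryFactorAnalysis(X, n_factors=1).fit()

    def test_n_not_greater_than_p_rejected(self):
        with pytest.raises(ValueError):
            ExploratoryFactorAnalysis(np.zeros((5, 5)))

    def test_result_invariants_and_summary(self):
        rng = np.random.default_rng(12)
        X, _ = planted_loadings_data(rng, n=300, p=12, k=2)
        import pandas as pd
        df = pd.DataFrame(X, columns=[f"m{i}" for i in range(12)])
        res = ExploratoryFactorAnalysis(df).fit()
        p = 12
        assert res.bartlett_df == p * (p - 1) // 2
        assert np.allclose(res.rotation_matrix.T @ res.rotation_matrix,
                           np.eye(res.n_factors), atol=1e-10)
        assert np.allclose((res.loadings_rotated ** 2).sum(axis=1),
                           (res.loadings_unrotated ** 2).sum(axis=1),
                           atol=1e-10)
        text = res.summary()
        assert "KMO" in text and "Bartlett" in text and "m0" in text

    def test_star_conventions(self):
        assert stats.p_value_stars(2e-5) == "****"
        assert stats.p_value_stars(0.004) == "**"
        assert stats.p_value_stars(0.2) == "ns"
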