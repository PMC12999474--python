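"""Factor-analysis stage: diagnostics, extraction, rotation, bootstrap.

The promax rotation is checked against values frozen from R's
``factanal(..., rotation="promax")`` on a deterministically generated
fixture; KMO/Bartlett/VIF are checked against naive textbook-formula
oracles implemented here from scratch.
"""

import numpy as np
import pytest

from speechdims import synthetic
from speechdims.factors import (
    FactorAnalysisError,
    align_to,
    average_solution,
    bartlett_sphericity,
    bootstrap_efa,
    congruence_matrix,
    factor_scores,
    fit_efa,
    kmo,
    screen_features,
    select_n_factors,
    tucker_congruence,
    varimax,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def vif_oracle(X):
    """VIF via the correlation-matrix inverse (diagonal identity)."""
    R = np.corrcoef(X, rowvar=False)
    return np.diag(np.linalg.inv(R))


def kmo_oracle(R):
    """Overall KMO from partial correlations computed by explicit regression.

    The partial correlation of variables i and j given the rest is obtained
    from the correlation of regression residuals (Cramer's construction),
    independent of the inverse-scaling shortcut in the implementation.
    """
    p = R.shape[0]
    Q = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rest = [m for m in range(p) if m not in (i, j)]
            if rest:
                Rrr = R[np.ix_(rest, rest)]
                ri = np.linalg.solve(Rrr, R[np.ix_(rest, [i])]).ravel()
                rj = np.linalg.solve(Rrr, R[np.ix_(rest, [j])]).ravel()
                num = R[i, j] - R[i, rest] @ rj
                den = np.sqrt((1 - R[i, rest] @ ri) * (1 - R[j, rest] @ rj))
                Q[i, j] = Q[j, i] = num / den
            else:
                Q[i, j] = Q[j, i] = R[i, j]
    mask = ~np.eye(p, dtype=bool)
    r2 = np.sum(R[mask] ** 2)
    q2 = np.sum(Q[mask] ** 2)
    return r2 / (r2 + q2)


def bartlett_oracle(R, n):
    p = R.shape[0]
    return -(n - 1 - (2 * p + 5) / 6) * np.log(np.linalg.det(R))


def random_spd_correlation(rng, p):
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T / (p + 3)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------

class TestScreen:
    def test_orthogonal_columns_unit_vif(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 4))
        s = screen_features(X)
        assert np.all(s.vif < 1.05)
        assert s.flags == []

    def test_duplicated_column_infinite_vif(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        X = np.column_stack([X, X[:, 0]])
        s = screen_features(X)
        assert np.isinf(s.vif).any()
        assert any("singular" in f for f in s.flags)

    def test_vif_matches_inverse_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((200, 5))
        X = base @ rng.standard_normal((5, 5)) + 0.5 * rng.standard_normal((200, 5))
        s = screen_features(X)
        assert np.allclose(s.vif, vif_oracle(X), atol=1e-8)

    def test_high_correlation_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        X = np.column_stack([x, x + 0.1 * rng.standard_normal(100),
                             rng.standard_normal(100)])
        s = screen_features(X)
        assert s.max_abs_offdiag > 0.8
        assert any("0.80" in f for f in s.flags)


# ---------------------------------------------------------------------------
# KMO / Bartlett
# ---------------------------------------------------------------------------

class TestSuitability:
    def test_kmo_two_variable_is_half(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert kmo(R)["overall"] == pytest.approx(0.5)

    def test_kmo_identity_degenerate(self):
        with pytest.raises(FactorAnalysisError):
            kmo(np.eye(4))

    def test_kmo_matches_regression_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            p = int(rng.integers(3, 7))
            R = random_spd_correlation(rng, p)
            assert kmo(R)["overall"] == pytest.approx(kmo_oracle(R), abs=1e-8)

    def test_bartlett_identity_is_zero(self):
        res = bartlett_sphericity(np.eye(5), 100)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_bartlett_formula_example(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = bartlett_sphericity(R, 10)
        assert res["chi2"] == pytest.approx(7.5 * -np.log(0.75), abs=1e-10)
        assert res["df"] == 1

    def test_bartlett_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = int(rng.integers(2, 7))
            R = random_spd_correlation(rng, p)
            n = int(rng.integers(p + 2, 500))
            res = bartlett_sphericity(R, n)
            assert res["chi2"] == pytest.approx(bartlett_oracle(R, n), abs=1e-8)
            assert res["df"] == p * (p - 1) // 2


# ---------------------------------------------------------------------------
# Factor-number selection
# ---------------------------------------------------------------------------

class TestSelectK:
    def test_three_factor_data(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=500, seed=42)
        res = select_n_factors(X, seed=0)
        assert res["k"] == 3
        assert set(res["votes"]) == {"kaiser", "parallel_analysis", "map"}

    def test_pure_noise_votes_transparent(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((300, 8))
        with pytest.raises(FactorAnalysisError, match="votes"):
            select_n_factors(X, seed=1)


# ---------------------------------------------------------------------------
# Extraction & rotation
# ---------------------------------------------------------------------------

class TestFitEfa:
    def test_one_factor_closed_form(self):
        R = np.full((3, 3), 0.49)
        np.fill_diagonal(R, 1.0)
        for method in ("uls", "ml", "paf"):
            sol = fit_efa(R, 1, method=method, is_correlation=True)
            assert np.allclose(sol.loadings.ravel(), [0.7, 0.7, 0.7], atol=1e-3)
            assert np.allclose(sol.uniquenesses, 0.51, atol=2e-3)

    def test_promax_of_orthogonal_structure_stays_orthogonal(self):
        # population correlation matrix of an exactly orthogonal structure:
        # the oblique rotation should not introduce factor correlation
        L, _ = synthetic.table_like_loading_design(p=12, k=2, phi_offdiag=0.0)
        R = L @ L.T + np.diag(1 - np.sum(L ** 2, axis=1))
        pro = fit_efa(R, 2, rotation="promax", is_correlation=True)
        var = fit_efa(R, 2, rotation="varimax", is_correlation=True)
        assert np.all(np.abs(pro.factor_correlations - np.eye(2)) < 1e-3)
        aligned, _, _ = align_to(var.loadings, pro.loadings)
        assert np.max(np.abs(aligned - var.loadings)) < 1e-3

    def test_promax_matches_frozen_r_factanal(self):
        # fixture generated deterministically; expected values frozen from
        # R factanal(X, 2, rotation="promax") on the same matrix
        rng = np.random.default_rng(7)
        n = 500
        F = rng.multivariate_normal([0, 0], [[1, .5], [.5, 1]], size=n)
        L = np.zeros((8, 2))
        L[:4, 0] = [.8, .7, .75, .65]
        L[4:, 1] = [.8, .7, .75, .65]
        E = rng.standard_normal(8 * n).reshape(n, 8)
        X = F @ L.T + E * np.sqrt(1 - np.sum(L ** 2, 1))
        sol = fit_efa(X, 2, method="ml", rotation="promax")
        r_pattern = np.array([
            [-0.039, 0.771], [0.037, 0.657], [0.023, 0.757], [-0.001, 0.631],
            [0.814, -0.014], [0.626, 0.004], [0.723, 0.043], [0.682, -0.030],
        ])
        aligned, phi, _ = align_to(r_pattern, sol.loadings,
                                   sol.factor_correlations)
        assert np.max(np.abs(aligned - r_pattern)) < 5e-3
        assert phi[0, 1] == pytest.approx(0.4720891, abs=2e-3)

    def test_recovery_congruence(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=500, seed=21)
        sol = fit_efa(X, 3)
        aligned, _, _ = align_to(L, sol.loadings, sol.factor_correlations)
        C = congruence_matrix(L, aligned)
        assert np.all(np.diag(C) >= 0.95)

    def test_rotation_does_not_change_fit(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=800, seed=5)
        none = fit_efa(X, 3, rotation="none")
        pro = fit_efa(X, 3, rotation="promax")
        assert np.max(np.abs(none.implied_correlation()
                             - pro.implied_correlation())) < 1e-6

    def test_reconstruction_error_small(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=1000, seed=6)
        sol = fit_efa(X, 3)
        R = np.corrcoef(X, rowvar=False)
        # residuals are bounded by correlation sampling noise (~n^{-1/2});
        # the max over 153 off-diagonal entries sits near 2.5 sigma
        assert np.max(np.abs(R - sol.implied_correlation())) < 0.08
        assert np.mean(np.abs(R - sol.implied_correlation())) < 0.015

    def test_heywood_clamped_and_flagged(self):
        # a variable almost fully explained drives its uniqueness to zero
        rng = np.random.default_rng(8)
        f = rng.standard_normal(120)
        X = np.column_stack([
            f + 0.01 * rng.standard_normal(120),
            f + 0.7 * rng.standard_normal(120),
            f + 0.8 * rng.standard_normal(120),
            rng.standard_normal(120),
        ])
        sol = fit_efa(X, 1, method="ml")
        assert np.all(sol.uniquenesses >= 1e-3 - 1e-12)
        assert sol.heywood

    def test_invalid_k_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 4))
        with pytest.raises(FactorAnalysisError):
            fit_efa(X, 4)

    def test_communalities_consistent_with_uniquenesses(self,
                                                        three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=400, seed=13)
        sol = fit_efa(X, 3)
        h2 = np.diag(sol.loadings @ sol.factor_correlations @ sol.loadings.T)
        assert np.allclose(h2, 1 - sol.uniquenesses, atol=1e-6)
        assert np.all((sol.communalities >= 0) & (sol.communalities <= 1))


class TestVarimax:
    def test_matches_loading_magnitudes_of_simple_structure(self):
        L, _ = synthetic.table_like_loading_design(p=10, k=2, phi_offdiag=0.0)
        rng = np.random.default_rng(4)
        T = np.linalg.qr(rng.standard_normal((2, 2)))[0]
        # normalize=False: Kaiser row normalisation is degenerate when rows
        # within a factor are exactly proportional, as in this noiseless
        # fixture (real loading matrices are not)
        rotated, _ = varimax(L @ T, normalize=False)
        aligned, _, _ = align_to(L, rotated)
        assert np.max(np.abs(aligned - L)) < 1e-4


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

class TestAlignment:
    def test_sign_flip_restored(self, three_factor_design):
        L, _ = three_factor_design
        flipped = L * np.array([-1, 1, -1])
        aligned, _, cong = align_to(L, flipped)
        assert np.allclose(aligned, L)
        assert cong == pytest.approx(1.0)

    def test_permutation_restored(self, three_factor_design):
        L, _ = three_factor_design
        permuted = L[:, [2, 0, 1]]
        aligned, _, _ = align_to(L, permuted)
        assert np.allclose(aligned, L)

    def test_tucker_congruence_bounds(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x, y = rng.standard_normal((2, 9))
            assert -1 - 1e-12 <= tucker_congruence(x, y) <= 1 + 1e-12
        assert tucker_congruence(np.ones(4), np.ones(4)) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Bootstrap & averaging
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_same_seed_identical(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=250, seed=30)
        b1 = bootstrap_efa(X, 3, B=60, seed=77)
        b2 = bootstrap_efa(X, 3, B=60, seed=77)
        assert np.array_equal(b1.mean_loadings, b2.mean_loadings)
        assert np.array_equal(b1.loading_ci, b2.loading_ci)

    def test_ci_bounds_bracket_mean(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=250, seed=31)
        b = bootstrap_efa(X, 3, B=120, seed=5)
        lo, hi = b.loading_ci[..., 0], b.loading_ci[..., 1]
        assert np.all(lo <= b.mean_loadings + 1e-9)
        assert np.all(b.mean_loadings <= hi + 1e-9)
        assert b.n_dropped == 0

    def test_degenerate_resampling_reported(self):
        # nearly-constant column: resamples that miss the one informative
        # row have zero variance and must be dropped and accounted for
        rng = np.random.default_rng(6)
        X = rng.standard_normal((8, 3))
        X[:, 2] = 0.0
        X[0, 2] = 1.0
        with pytest.raises(FactorAnalysisError, match="resamples"):
            bootstrap_efa(X, 1, B=100, seed=2)


class TestAverageSolution:
    def test_agreement_in_well_specified_case(self):
        R = np.full((6, 6), 0.49)
        np.fill_diagonal(R, 1.0)
        rng = np.random.default_rng(14)
        F = rng.standard_normal(3000)
        X = 0.7 * F[:, None] + np.sqrt(0.51) * rng.standard_normal((3000, 6))
        avg = average_solution(X, 1, methods=("uls", "ml"))
        uls = fit_efa(X, 1, method="uls")
        assert np.max(np.abs(avg.loadings - uls.loadings)) < 1e-3
        assert avg.method == "average"

    def test_average_close_to_truth(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=600, seed=40)
        avg = average_solution(X, 3, methods=("uls", "ml", "paf"))
        aligned, _, _ = align_to(L, avg.loadings)
        assert np.all(np.diag(congruence_matrix(L, aligned)) >= 0.95)

    def test_needs_two_methods(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=200, seed=41)
        with pytest.raises(FactorAnalysisError):
            average_solution(X, 3, methods=("uls",))


# ---------------------------------------------------------------------------
# Factor scores
# ---------------------------------------------------------------------------

class TestFactorScores:
    def test_scores_track_generating_latent(self):
        rng = np.random.default_rng(15)
        f = rng.standard_normal(500)
        X = 0.7 * f[:, None] + np.sqrt(0.51) * rng.standard_normal((500, 6))
        sol = fit_efa(X, 1)
        s = factor_scores(sol, X)
        assert abs(np.corrcoef(s[:, 0], f)[0, 1]) > 0.9
        assert s.mean(axis=0) == pytest.approx(0.0, abs=1e-12)
        assert s.std(axis=0, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_row_equivariance_under_permutation(self, three_factor_design):
        L, phi = three_factor_design
        X = synthetic.simulate_factor_model(L, phi, n=120, seed=16)
        sol = fit_efa(X, 3)
        rng = np.random.default_rng(17)
        perm = rng.permutation(120)
        s_full = factor_scores(sol, X)
        s_perm = factor_scores(sol, X[perm])
        assert np.allclose(s_perm, s_full[perm], atol=1e-10)

    def test_zero_variance_input_rejected(self):
        sol = fit_efa(np.full((3, 3), 0.49) + np.diag([0.51] * 3), 1,
                      is_correlation=True)
        X = np.ones((10, 3))
        with pytest.raises(FactorAnalysisError):
            factor_scores(sol, X)

    def test_bartlett_scores_also_track_latent(self):
        rng = np.random.default_rng(18)
        f = rng.standard_normal(500)
        X = 0.7 * f[:, None] + np.sqrt(0.51) * rng.standard_normal((500, 6))
        sol = fit_efa(X, 1)
        s = factor_scores(sol, X, method="bartlett")
        assert abs(np.corrcoef(s[:, 0], f)[0, 1]) > 0.9
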