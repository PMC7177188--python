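"""Dictionary learning: sparse coding, dictionary updates, model selection."""

import numpy as np
import pytest

from dfcstates import states, synth
from dfcstates.states import (
    bic_score,
    default_lambda_grid,
    fit_dictionary,
    kkt_residual,
    nested_cv_select,
    per_state_error,
    sparse_code,
    update_dictionary,
)


def _lasso_oracle(C, D, lam):
    """Independent convex solver for 0.5||c - Da||^2 + lam ||a||_1."""
    from sklearn.linear_model import Lasso

    n = D.shape[0]
    model = Lasso(alpha=lam / n, fit_intercept=False, tol=1e-14, max_iter=200000)
    model.fit(D, C)
    return model.coef_.T


class TestSparseCode:
    def test_lam_zero_orthonormal_is_projection(self, rng):
        D, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        C = rng.standard_normal((8, 5))
        np.testing.assert_allclose(sparse_code(C, D, 0.0), D.T @ C, atol=1e-10)

    def test_large_lam_kills_solution(self, rng):
        D = rng.standard_normal((6, 3))
        D /= np.linalg.norm(D, axis=0)
        C = rng.standard_normal((6, 4))
        lam = float(np.abs(D.T @ C).max()) + 1e-6
        np.testing.assert_array_equal(sparse_code(C, D, lam), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_convex_solver(self, seed):
        rng = np.random.default_rng(seed)
        M, k = int(rng.integers(4, 21)), int(rng.integers(2, 6))
        D = rng.standard_normal((M, k))
        D /= np.linalg.norm(D, axis=0)
        C = rng.standard_normal((M, 6))
        lam = float(rng.uniform(0.05, 0.5))
        A = sparse_code(C, D, lam, tol=1e-9)
        np.testing.assert_allclose(A, _lasso_oracle(C, D, lam), atol=1e-5)

    def test_kkt_residual_small_on_fixtures(self, rng):
        D = rng.standard_normal((10, 4))
        D /= np.linalg.norm(D, axis=0)
        C = rng.standard_normal((10, 7))
        for lam in (0.05, 0.3, 1.0):
            A = sparse_code(C, D, lam)
            assert kkt_residual(C, D, A, lam) <= 1e-5

    def test_nonneg_solution_is_nonnegative_and_optimal(self, rng):
        D = rng.standard_normal((10, 4))
        D /= np.linalg.norm(D, axis=0)
        C = rng.standard_normal((10, 7))
        A = sparse_code(C, D, 0.2, nonneg=True)
        assert (A >= 0).all()
        assert kkt_residual(C, D, A, 0.2, nonneg=True) <= 1e-5

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sparse_code(np.array([[np.nan]]), np.array([[1.0]]), 0.1)


class TestDictionaryUpdate:
    def test_identity_weights_give_normalized_data_columns(self, rng):
        C = rng.standard_normal((8, 3))
        A = np.eye(3)
        D = update_dictionary(C, A, rng.standard_normal((8, 3)))
        np.testing.assert_allclose(D, C / np.linalg.norm(C, axis=0), atol=1e-10)

    def test_update_never_increases_fit_error(self, rng):
        for _ in range(5):
            C = rng.standard_normal((12, 20))
            D = rng.standard_normal((12, 4))
            D /= np.linalg.norm(D, axis=0)
            A = sparse_code(C, D, 0.1)
            before = np.linalg.norm(C - D @ A) ** 2
            after = np.linalg.norm(C - update_dictionary(C, A, D) @ A) ** 2
            assert after <= before + 1e-10

    def test_exact_factorization_is_fixed_point(self, rng):
        D = rng.standard_normal((10, 3))
        D /= np.linalg.norm(D, axis=0)
        A = np.abs(rng.standard_normal((3, 15))) + 0.5
        C = D @ A
        np.testing.assert_allclose(update_dictionary(C, A, D), D, atol=1e-10)

    def test_dead_state_reseeded_from_worst_column(self, rng):
        C = rng.standard_normal((10, 6))
        D = rng.standard_normal((10, 2))
        D /= np.linalg.norm(D, axis=0)
        A = np.zeros((2, 6))
        A[0] = rng.standard_normal(6)  # state 1 dead
        D_new = update_dictionary(C, A, D)
        worst = np.argmax(((C - D @ A) ** 2).sum(axis=0))
        np.testing.assert_allclose(
            D_new[:, 1], C[:, worst] / np.linalg.norm(C[:, worst]), atol=1e-12
        )


class TestFitDictionary:
    def test_recovers_planted_states(self, small_factor_problem):
        p = small_factor_problem
        model = fit_dictionary(p.C, 3, 0.1, seed=0)
        corrs = []
        for i in range(3):
            best = max(abs(np.corrcoef(model.D[:, i], p.D_true[:, j])[0, 1])
                       for j in range(3))
            corrs.append(best)
        assert np.mean(corrs) >= 0.9

    def test_exact_low_rank_fit_at_lam_zero(self, rng):
        D = rng.standard_normal((15, 4))
        A = rng.standard_normal((4, 30))
        C = D @ A
        model = fit_dictionary(C, 4, 0.0, seed=1)
        assert model.E_total < 1e-6 * np.linalg.norm(C) ** 2

    def test_same_seed_identical(self, small_factor_problem):
        p = small_factor_problem
        a = fit_dictionary(p.C, 3, 0.2, seed=3)
        b = fit_dictionary(p.C, 3, 0.2, seed=3)
        np.testing.assert_array_equal(a.D, b.D)
        np.testing.assert_array_equal(a.A, b.A)

    def test_objective_monotone_across_alternations(self, small_factor_problem):
        model = fit_dictionary(small_factor_problem.C, 3, 0.2, seed=0)
        diffs = np.diff(model.objective_history)
        assert (diffs <= 1e-8 * np.abs(model.objective_history[:-1])).all()

    def test_unit_norm_columns(self, small_factor_problem):
        model = fit_dictionary(small_factor_problem.C, 3, 0.2, seed=0)
        np.testing.assert_allclose(np.linalg.norm(model.D, axis=0), 1.0, atol=1e-10)

    def test_sign_canonicalization_makes_weight_sums_nonnegative(self, small_factor_problem):
        model = fit_dictionary(small_factor_problem.C, 3, 0.2, seed=0)
        assert (model.A.sum(axis=1) >= 0).all()

    def test_k_larger_than_T_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_dictionary(rng.standard_normal((10, 3)), 5, 0.1)

    def test_restarts_never_worse_in_objective(self, small_factor_problem):
        p = small_factor_problem

        def obj(m):
            return 0.5 * m.E_total + 0.2 * np.abs(m.A).sum()

        single = obj(fit_dictionary(p.C, 3, 0.2, seed=5))
        multi = obj(fit_dictionary(p.C, 3, 0.2, seed=5, n_restarts=3))
        assert multi <= single + 1e-9

    def test_sparsity_monotone_in_lambda(self, small_factor_problem):
        p = small_factor_problem
        nnz = []
        for lam in default_lambda_grid():  # decreasing lambda
            model = fit_dictionary(p.C, 3, lam, seed=0)
            nnz.append(np.count_nonzero(model.A))
        # sparsest at lam=1, densest at the grid's end; allow small jitter
        total = p.C.shape[1] * 3
        for a, b in zip(nnz, nnz[1:]):
            assert a <= b + 0.02 * total

    def test_hdf5_round_trip(self, small_factor_problem, tmp_path):
        model = fit_dictionary(small_factor_problem.C, 3, 0.2, seed=0)
        model.to_hdf5(tmp_path / "m.h5")
        back = states.StateModel.from_hdf5(tmp_path / "m.h5")
        np.testing.assert_allclose(back.D, model.D)
        assert back.k == 3 and back.lam == 0.2


class TestPerStateError:
    def test_exact_rank_one_gives_zero(self, rng):
        d = rng.standard_normal(10)
        d /= np.linalg.norm(d)
        a = rng.standard_normal(20)
        C = np.outer(d, a)
        E = per_state_error(d[:, None], a[None, :], C)
        assert E[0] == pytest.approx(0.0, abs=1e-18)

    def test_zero_weights_give_full_energy(self, rng):
        C = rng.standard_normal((10, 20))
        D = rng.standard_normal((10, 2))
        E = per_state_error(D, np.zeros((2, 20)), C)
        np.testing.assert_allclose(E, np.linalg.norm(C) ** 2)

    def test_matches_loop_oracle(self, rng):
        C = rng.standard_normal((8, 12))
        D = rng.standard_normal((8, 3))
        A = rng.standard_normal((3, 12))
        E = per_state_error(D, A, C)
        for i in range(3):
            expected = sum(
                (C[m, t] - D[m, i] * A[i, t]) ** 2
                for m in range(8) for t in range(12)
            )
            assert E[i] == pytest.approx(expected, rel=1e-10)


class TestBIC:
    def _model(self, D, A, lam=0.1):
        return states.StateModel(
            D=D, A=A, k=D.shape[1], lam=lam, E_total=0.0,
            E_per_state=np.zeros(D.shape[1]), seed=0, n_iter=1,
        )

    def test_matches_hand_computed_formula(self, rng):
        D = rng.standard_normal((6, 2))
        D /= np.linalg.norm(D, axis=0)
        C_val = rng.standard_normal((6, 4))
        lam = 0.2
        model = self._model(D, np.zeros((2, 4)), lam)
        A_val = sparse_code(C_val, D, lam)
        rss = np.linalg.norm(C_val - D @ A_val) ** 2
        n = C_val.size
        expected = n * np.log(rss / n) + (2 * 6 + np.count_nonzero(A_val)) * np.log(n)
        assert bic_score(model, C_val) == pytest.approx(expected, rel=1e-8)

    def test_doubling_residuals_adds_n_ln4(self, rng):
        # pure formula algebra: n ln(4 RSS / n) = n ln(RSS/n) + n ln 4
        n, rss = 120, 3.7
        assert n * np.log(4 * rss / n) == pytest.approx(n * np.log(rss / n) + n * np.log(4))

    def test_zero_residual_returns_minus_inf(self, rng):
        D = rng.standard_normal((6, 2))
        D /= np.linalg.norm(D, axis=0)
        model = self._model(D, np.zeros((2, 4)), lam=0.0)
        with pytest.warns(UserWarning):
            assert bic_score(model, np.zeros((6, 4))) == float("-inf")


class TestNestedCV:
    def test_default_lambda_grid_matches_printed_endpoints(self):
        grid = default_lambda_grid()
        assert grid.shape == (10,)
        assert grid[0] == pytest.approx(1.0)
        assert grid[-1] == pytest.approx(0.1259, abs=5e-5)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, 10 ** (-1 / 10))

    def test_single_candidate_returned_unchanged(self, small_factor_problem):
        sel = nested_cv_select(small_factor_problem.C, k_grid=[3],
                               lam_grid=np.array([0.2]), seed=0)
        assert sel.k_opt == 3 and sel.lam_opt == 0.2
        assert all(choice == (3, 0.2) for choice in sel.fold_choices)

    def test_selects_planted_state_count_small_grid(self):
        p = synth.gen_sparse_factor_problem(M=40, T=100, k=3, noise_sd=0.05, seed=2)
        sel = nested_cv_select(p.C, k_grid=[3, 4, 5],
                               lam_grid=np.array([0.3, 0.15]), seed=0)
        assert sel.k_opt == 3

    def test_too_few_columns_rejected(self, rng):
        with pytest.raises(ValueError):
            nested_cv_select(rng.standard_normal((10, 8)), k_grid=[2],
                             lam_grid=np.array([0.1]))

    def test_empty_grid_rejected(self, small_factor_problem):
        with pytest.raises(ValueError):
            nested_cv_select(small_factor_problem.C, k_grid=[],
                             lam_grid=np.array([0.1]))
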