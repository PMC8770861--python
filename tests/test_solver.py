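"""Solver contracts: objective assembly, linear-system updates, the
alternating fit, and the baseline variants."""

import numpy as np
import pytest

from fglgnscca import (
    DataMatrix,
    HyperParams,
    default_structures,
    fit_fglgnscca,
    fit_fglscca,
    fit_l1scca,
    make_truth,
    simulate,
)
from fglgnscca.solver import (
    SolverError,
    objective,
    solve_u_update,
    solve_v_update,
)
from fglgnscca.structures import (
    PenaltyState,
    StructurePack,
    _huber_norm,
    build_chain_weights,
    build_connectivity_laplacian,
    build_feature_graph,
)


def _instance(n=60, p=8, q=6, seed=0, noise=0.5):
    truth = make_truth(p, q)
    X, Y = simulate(n, truth, noise, seed=seed)
    sx, sy = default_structures(X, Y)
    return X, Y, sx, sy


class TestObjective:
    def test_zero_loadings_value(self):
        X, Y, sx, sy = _instance()
        hp = HyperParams(gamma1=3.0, gamma2=0.5)
        val = objective(np.zeros(8), np.zeros(6), X, Y, sx, sy, hp)
        assert val == pytest.approx(-(3.0 + 0.5) / 2, abs=1e-12)

    def test_even_in_u_when_v_zero(self, rng):
        X, Y, sx, sy = _instance()
        u = rng.standard_normal(8)
        hp = HyperParams()
        a = objective(u, np.zeros(6), X, Y, sx, sy, hp)
        b = objective(-u, np.zeros(6), X, Y, sx, sy, hp)
        assert a == pytest.approx(b, rel=1e-12)

    def test_sign_flip_changes_only_bilinear_term(self, rng):
        X, Y, sx, sy = _instance()
        u, v = rng.standard_normal(8), rng.standard_normal(6)
        hp = HyperParams()
        xu, yv = X.values @ u, Y.values @ v
        bilinear = float(xu @ yv)
        a = objective(u, v, X, Y, sx, sy, hp)
        b = objective(u, -v, X, Y, sx, sy, hp)
        assert b - a == pytest.approx(2 * bilinear, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_termwise_summation_oracle(self, seed):
        # independent loop-based recomputation of every term
        X, Y, sx, sy = _instance(seed=seed)
        r = np.random.default_rng(seed)
        u, v = r.standard_normal(8), r.standard_normal(6)
        hp = HyperParams(lambda1=1.3, lambda2=0.7, gamma1=2.0, gamma2=0.4)
        xu, yv = X.values @ u, Y.values @ v
        expect = -float(xu @ yv)
        expect += 0.5 * hp.gamma1 * (float(xu @ xu) - 1)
        expect += 0.5 * hp.gamma2 * (float(yv @ yv) - 1)
        for i, w in enumerate(sx.chain.w):
            s = np.sqrt(u[i] ** 2 + u[i + 1] ** 2)
            expect += hp.lambda1 * w * float(_huber_norm(np.asarray(s), hp.eps))
        for j, k, w in sy.graph.edges:
            s = np.sqrt(v[j] ** 2 + v[k] ** 2)
            expect += hp.lambda2 * w * float(_huber_norm(np.asarray(s), hp.eps))
        for side, vec, lap, lam in (
            ("u", u, sx.laplacian.C, hp.lambda1_gn),
            ("v", v, sy.laplacian.C, hp.lambda2_gn),
        ):
            quad = sum(
                lap[i, j] * (vec[i] - vec[j]) ** 2
                for i in range(lap.shape[0])
                for j in range(i + 1, lap.shape[0])
            )
            expect += 0.5 * lam * quad
        assert objective(u, v, X, Y, sx, sy, hp) == pytest.approx(
            expect, abs=1e-10
        )

    def test_dimension_mismatch(self):
        X, Y, sx, sy = _instance()
        with pytest.raises(ValueError):
            objective(np.zeros(7), np.zeros(6), X, Y, sx, sy, HyperParams())


class TestLinearUpdates:
    def test_identity_system_returns_rhs(self, rng):
        # lam1=1, D_X = I, gamma1 = 0, no Laplacian -> A = I
        X, Y, sx, sy = _instance()
        sx_plain = StructurePack(chain=sx.chain)  # no Laplacian
        hp = HyperParams(gamma1=0.0, lambda1_gn=0.0, lambda2_gn=0.0)
        state = PenaltyState(dX=np.ones(8), dY=np.ones(6))
        v = rng.standard_normal(6)
        u = solve_u_update(v, X, Y, sx_plain, state, hp)
        expected = X.values.T @ (Y.values @ v)
        assert np.allclose(u, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_residual_contract_and_dense_inverse_oracle(self, seed):
        X, Y, sx, sy = _instance(p=5, q=5, seed=seed)
        r = np.random.default_rng(seed)
        hp = HyperParams()
        u0, v0 = r.standard_normal(5), r.standard_normal(5)
        from fglgnscca.structures import update_penalty_state

        state = update_penalty_state(u0, v0, sx, sy, hp.eps)
        u = solve_u_update(v0, X, Y, sx, state, hp)
        A = (
            hp.lambda1 * np.diag(state.dX)
            + hp.gamma1 * X.values.T @ X.values
            + hp.lambda1_gn * sx.laplacian.L
        )
        b = X.values.T @ Y.values @ v0
        assert np.linalg.norm(A @ u - b) / np.linalg.norm(b) < 1e-8
        assert np.allclose(u, np.linalg.inv(A) @ b, atol=1e-8)

        v = solve_v_update(u0, X, Y, sy, state, hp)
        B = (
            hp.lambda2 * np.diag(state.dY)
            + hp.gamma2 * Y.values.T @ Y.values
            + hp.lambda2_gn * sy.laplacian.L
        )
        b2 = Y.values.T @ X.values @ u0
        assert np.linalg.norm(B @ v - b2) / np.linalg.norm(b2) < 1e-8
        assert np.allclose(v, np.linalg.inv(B) @ b2, atol=1e-8)


class TestFitFglgnscca:
    def test_scale_constraints_hold_every_sweep(self):
        X, Y, sx, sy = _instance(n=60, p=12, q=8)
        sol = fit_fglgnscca(X, Y, sx, sy, HyperParams())
        assert sol.diagnostics["scale_violation"] < 1e-8
        assert abs(sol.u @ X.values.T @ X.values @ sol.u - 1) < 1e-8
        assert abs(sol.v @ Y.values.T @ Y.values @ sol.v - 1) < 1e-8

    def test_noiseless_rank_one_gives_near_perfect_cc(self):
        truth = make_truth(20, 10)
        X, Y = simulate(100, truth, 0.0, seed=1)
        sx, sy = default_structures(X, Y)
        sol = fit_fglgnscca(X, Y, sx, sy, HyperParams())
        assert abs(sol.cc_train) >= 0.99

    def test_converges_and_trace_bookkeeping(self):
        X, Y, sx, sy = _instance(n=100, p=20, q=10, seed=2)
        sol = fit_fglgnscca(X, Y, sx, sy, HyperParams())
        assert sol.converged
        assert len(sol.objective_trace) == sol.n_iter
        assert sol.n_iter <= 100

    def test_objective_trace_non_increasing(self):
        X, Y, sx, sy = _instance(n=100, p=20, q=10, seed=0)
        sol = fit_fglgnscca(X, Y, sx, sy, HyperParams())
        assert np.all(np.diff(sol.objective_trace) <= 1e-6)

    def test_deterministic_given_seed(self):
        X, Y, sx, sy = _instance(n=80, p=15, q=9, seed=4)
        hp = HyperParams(seed=7)
        a = fit_fglgnscca(X, Y, sx, sy, hp)
        b = fit_fglgnscca(X, Y, sx, sy, hp)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)

    def test_sign_canonicalized(self):
        X, Y, sx, sy = _instance(n=80, p=15, q=9, seed=4)
        sol = fit_fglgnscca(X, Y, sx, sy, HyperParams())
        assert sol.u[np.argmax(np.abs(sol.u))] > 0

    def test_all_zero_data_fails_with_diagnostic(self):
        vals = np.full((20, 5), 3.0)  # constant -> zeroed by standardization
        X = DataMatrix.from_values(vals)
        Y = DataMatrix.from_values(vals[:, :4])
        sx = StructurePack(chain=build_chain_weights(X))
        sy = StructurePack(
            graph=build_feature_graph(Y, "chain_plus_corr", 0.5)
        )
        with pytest.raises(SolverError):
            fit_fglgnscca(X, Y, sx, sy, HyperParams())

    def test_ridge_cca_limit_matches_eigen_oracle(self):
        # no structured penalties, n >> p, q: must align with exact CCA
        r = np.random.default_rng(3)
        n, p, q = 1500, 10, 8
        z = r.standard_normal((n, 1))
        X = DataMatrix.from_values(
            z @ r.standard_normal((1, p)) + r.standard_normal((n, p))
        )
        Y = DataMatrix.from_values(
            z @ r.standard_normal((1, q)) + r.standard_normal((n, q))
        )
        hp = HyperParams(lambda1=0, lambda2=0, lambda1_gn=0, lambda2_gn=0)
        sol = fit_fglgnscca(X, Y, StructurePack(), StructurePack(), hp)
        Sxx = X.values.T @ X.values
        Syy = Y.values.T @ Y.values
        Sxy = X.values.T @ Y.values
        M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
        w, V = np.linalg.eig(M)
        u_cca = np.real(V[:, np.argmax(np.real(w))])
        r_proj = abs(
            np.corrcoef(X.values @ sol.u, X.values @ u_cca)[0, 1]
        )
        assert r_proj >= 0.95


class TestFglscca:
    def test_identical_to_fglgnscca_with_zero_graphnet(self):
        X, Y, sx, sy = _instance(n=80, p=15, q=9, seed=6)
        hp = HyperParams(lambda1_gn=0.0, lambda2_gn=0.0)
        a = fit_fglgnscca(X, Y, sx, sy, hp)
        b = fit_fglscca(X, Y, sx, sy, HyperParams())
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)

    def test_zero_laplacian_equals_removed_laplacian(self):
        X, Y, sx, sy = _instance(n=80, p=15, q=9, seed=6)
        hp = HyperParams()
        sx_no = StructurePack(chain=sx.chain, laplacian=None)
        sy_no = StructurePack(graph=sy.graph, laplacian=None)
        a = fit_fglscca(X, Y, sx, sy, hp)
        b = fit_fglscca(X, Y, sx_no, sy_no, hp)
        assert np.allclose(a.u, b.u, atol=1e-12)


class TestL1scca:
    def test_slack_budgets_recover_leading_singular_pair(self):
        X, Y, _, _ = _instance(n=100, p=12, q=9, seed=8, noise=0.3)
        p, q = 12, 9
        sol = fit_l1scca(X, Y, np.sqrt(p), np.sqrt(q))
        U, s, Vt = np.linalg.svd(X.values.T @ Y.values)
        cos_u = abs(sol.u @ U[:, 0])
        cos_v = abs(sol.v @ Vt[0])
        assert cos_u > 1 - 1e-6 and cos_v > 1 - 1e-6

    def test_unit_norm_contract(self):
        X, Y, _, _ = _instance(n=60, p=10, q=7, seed=9)
        sol = fit_l1scca(X, Y, 2.0, 2.0)
        assert abs(np.linalg.norm(sol.u) - 1) < 1e-10
        assert abs(np.linalg.norm(sol.v) - 1) < 1e-10

    def test_sparsity_budget_respected(self):
        X, Y, _, _ = _instance(n=60, p=30, q=7, seed=9)
        sol = fit_l1scca(X, Y, 1.5, 1.5)
        assert np.sum(np.abs(sol.u)) <= 1.5 + 1e-6

    def test_infeasible_budget_rejected(self):
        X, Y, _, _ = _instance()
        with pytest.raises(ValueError):
            fit_l1scca(X, Y, 0.5, 2.0)

    def test_deterministic(self):
        X, Y, _, _ = _instance(n=60, p=10, q=7, seed=2)
        a = fit_l1scca(X, Y, 2.0, 2.0, seed=3)
        b = fit_l1scca(X, Y, 2.0, 2.0, seed=3)
        assert np.array_equal(a.u, b.u)
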