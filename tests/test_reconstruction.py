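"""Subtraction, basis learning, and the group-sparse solver contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from bcgomp.core import Recording, ValidationError
from bcgomp.estimators import GroupSparseReconstructor
from bcgomp.reconstruction import (
    EegBasis,
    default_mu_grid,
    l21_norm,
    learn_basis,
    prox_l21,
    reconstruct_all,
    subtract_reconstruct,
)

matrices = hnp.arrays(np.float64, (5, 7),
                      elements=st.floats(-100, 100, allow_nan=False))


class TestSubtract:
    def test_zero_estimate_returns_input(self):
        rng = np.random.default_rng(0)
        Y = Recording(rng.standard_normal((3, 20)))
        out = subtract_reconstruct(Y, Recording(np.zeros((3, 20))))
        np.testing.assert_array_equal(out.data, Y.data)

    def test_exact_inversion_of_generative_model(self):
        rng = np.random.default_rng(1)
        bcg = rng.standard_normal((4, 30))
        eeg = rng.standard_normal((4, 30))
        Y = bcg + eeg
        out = subtract_reconstruct(Recording(Y), Recording(bcg))
        # bitwise identical to the elementwise-difference oracle
        np.testing.assert_array_equal(out.data, Y - bcg)
        np.testing.assert_allclose(out.data, eeg, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            subtract_reconstruct(Recording(np.zeros((2, 5))),
                                 Recording(np.zeros((2, 6))))


class TestLearnBasis:
    def test_sinusoid_lies_in_two_dim_pca_subspace(self):
        t = np.arange(250 * 20) / 250.0
        rec = Recording(np.sin(2 * np.pi * 9 * t)[None, :], fs=250.0)
        basis = learn_basis(rec, L=250, m=2, method="pca")
        seg = rec.data[0, :250]
        proj = basis.B @ (basis.B.T @ seg)
        assert np.linalg.norm(seg - proj) / np.linalg.norm(seg) < 1e-3

    def test_dct_orthonormal_complete(self):
        rng = np.random.default_rng(2)
        rec = Recording(rng.standard_normal((1, 200)), fs=250.0)
        basis = learn_basis(rec, L=32, m=32, method="dct")
        G = basis.B.T @ basis.B
        assert np.abs(G - np.eye(32)).max() < 1e-10

    def test_unit_norm_columns(self):
        rng = np.random.default_rng(3)
        rec = Recording(rng.standard_normal((2, 1500)), fs=250.0)
        basis = learn_basis(rec, L=50, m=10, method="pca")
        assert np.abs(np.linalg.norm(basis.B, axis=0) - 1).max() < 1e-12

    def test_too_many_atoms(self):
        rec = Recording(np.zeros((1, 2000)))
        with pytest.raises(ValidationError):
            learn_basis(rec, L=50, m=51)


class TestProxL21:
    def test_tau_zero_is_identity(self):
        V = np.random.default_rng(4).standard_normal((4, 6))
        np.testing.assert_array_equal(prox_l21(V, 0.0), V)

    def test_small_rows_zeroed(self):
        V = np.array([[0.3, 0.4], [3.0, 4.0]])
        out = prox_l21(V, 1.0)
        assert np.all(out[0] == 0)

    def test_closed_form_row(self):
        out = prox_l21(np.array([[3.0, 4.0]]), 1.0)
        np.testing.assert_allclose(out, [[2.4, 3.2]], atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(matrices, matrices)
    def test_non_expansive(self, U, V):
        dU = np.linalg.norm(prox_l21(U, 1.7) - prox_l21(V, 1.7))
        assert dU <= np.linalg.norm(U - V) + 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(matrices, matrices, st.floats(-10, 10))
    def test_l21_norm_properties(self, U, V, a):
        assert l21_norm(U + V) <= l21_norm(U) + l21_norm(V) + 1e-9
        assert abs(l21_norm(a * U) - abs(a) * l21_norm(U)) <= 1e-8 * (
            1 + abs(a) * l21_norm(U))


def kkt_residual(B, Y, C, mu):
    """Max row-wise violation of the l2,1 subgradient condition."""
    G = B.T @ (Y - B @ C) / mu
    viol = 0.0
    for i in range(C.shape[0]):
        ni = np.linalg.norm(C[i])
        if ni > 1e-12:
            viol = max(viol, np.linalg.norm(G[i] - C[i] / ni))
        else:
            viol = max(viol, max(0.0, np.linalg.norm(G[i]) - 1.0))
    return viol


class TestGroupSparseSolver:
    def test_fidelity_limit_recovers_projection(self):
        rng = np.random.default_rng(5)
        L = 16
        Q, _ = np.linalg.qr(rng.standard_normal((L, L)))
        basis = EegBasis(B=Q, origin="pca")
        y = rng.standard_normal(3 * L)
        solver = GroupSparseReconstructor(basis=basis, mu=1e-9, tol=1e-12,
                                          max_iter=2000)
        recon, sol = solver.transform(y)
        assert np.linalg.norm(recon - y) / np.linalg.norm(y) < 1e-3

    def test_penalty_limit_zeroes_everything(self):
        rng = np.random.default_rng(6)
        L = 16
        Q, _ = np.linalg.qr(rng.standard_normal((L, L)))
        basis = EegBasis(B=Q)
        solver = GroupSparseReconstructor(basis=basis, mu=1e9)
        recon, sol = solver.transform(rng.standard_normal(2 * L))
        assert np.all(sol.C_eeg == 0)
        assert np.all(recon == 0)

    def test_objective_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        B = rng.standard_normal((8, 4))
        B /= np.linalg.norm(B, axis=0)
        basis = EegBasis(B=B)
        solver = GroupSparseReconstructor(basis=basis, mu=0.5)
        sol = solver.solve_segments(rng.standard_normal((8, 6)))
        tr = np.asarray(sol.objective_trace)
        assert np.all(np.diff(tr) <= 1e-12 * max(tr[0], 1))
        assert np.all(tr >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_and_random_search_optimality(self, seed):
        rng = np.random.default_rng(seed)
        L, m, n = 8, 4, 6
        B = rng.standard_normal((L, m))
        B /= np.linalg.norm(B, axis=0)
        basis = EegBasis(B=B)
        Y = rng.standard_normal((L, n))
        mu = 0.3
        solver = GroupSparseReconstructor(basis=basis, mu=mu, tol=1e-14,
                                          max_iter=20000)
        sol = solver.solve_segments(Y)

        def objective(C):
            return l21_norm(C) + ((Y - B @ C) ** 2).sum() / (2 * mu)

        f_star = objective(sol.C_eeg)
        # random feasible competitors never beat the solver
        for _ in range(2000):
            Cr = sol.C_eeg + 0.3 * rng.standard_normal((m, n)) * \
                rng.integers(0, 2, (m, 1))
            assert f_star <= objective(Cr) + 1e-9
        assert kkt_residual(B, Y, sol.C_eeg, mu) < 1e-4

    def test_mu_must_be_positive(self):
        basis = EegBasis(B=np.eye(4))
        with pytest.raises(ValidationError):
            GroupSparseReconstructor(basis=basis, mu=0.0).transform(
                np.ones(8))

    def test_trailing_remainder_passthrough(self):
        basis = EegBasis(B=np.eye(4))
        y = np.arange(10, dtype=float)
        recon, _ = GroupSparseReconstructor(basis=basis,
                                            mu=1e9).transform(y)
        np.testing.assert_array_equal(recon[8:], y[8:])


class TestReconstructAll:
    def test_subtract_equals_direct(self):
        rng = np.random.default_rng(8)
        Y = Recording(rng.standard_normal((3, 40)))
        Xb = Recording(rng.standard_normal((3, 40)))
        out = reconstruct_all(Y, Xb, method="subtract")
        np.testing.assert_array_equal(out.data,
                                      subtract_reconstruct(Y, Xb).data)

    def test_noiseless_exact_bcg_both_methods_below_1pct(self):
        """With the exact artifact and a basis spanning the clean signal,
        both routes recover the signal to < 1% error."""
        rng = np.random.default_rng(9)
        L, n = 50, 30
        t = np.arange(L * n) / 250.0
        eeg = (10 * np.sin(2 * np.pi * 5 * t)
               + 4 * np.sin(2 * np.pi * 9 * t))[None, :]
        bcg = 50 * rng.standard_normal((1, L * n))
        Y = Recording(bcg + eeg)
        basis = learn_basis(Recording(eeg), L=L, m=6, method="pca")
        sub = reconstruct_all(Y, Recording(bcg), method="subtract")
        opt = reconstruct_all(Y, Recording(bcg), basis=basis,
                              method="optimize", mu=1e-6)
        for out in (sub, opt):
            err = np.linalg.norm(out.data - eeg) / np.linalg.norm(eeg)
            assert err < 0.01

    def test_optimize_beats_subtract_on_noisy_estimate(self):
        """Broadband estimation error is suppressed by the prior basis for
        a well-chosen mu (grid-searched, as in validation practice)."""
        rng = np.random.default_rng(10)
        L, n = 50, 60
        t = np.arange(L * n) / 250.0
        eeg = (10 * np.sin(2 * np.pi * 5 * t)
               + 4 * np.sin(2 * np.pi * 9 * t))[None, :]
        bcg = 50 * rng.standard_normal((1, L * n))
        bcg_hat = bcg + 3 * rng.standard_normal(bcg.shape)  # noisy estimate
        Y = Recording(bcg + eeg)
        basis = learn_basis(Recording(eeg), L=L, m=6, method="pca")
        sub = reconstruct_all(Y, Recording(bcg_hat), method="subtract")
        err_sub = np.linalg.norm(sub.data - eeg) / np.linalg.norm(eeg)
        errs = []
        for mu in default_mu_grid(sub.data, m=6, L=L):
            opt = reconstruct_all(Y, Recording(bcg_hat), basis=basis,
                                  method="optimize", mu=float(mu))
            errs.append(np.linalg.norm(opt.data - eeg)
                        / np.linalg.norm(eeg))
        assert min(errs) <= err_sub

    def test_optimize_without_basis_rejected(self):
        Y = Recording(np.zeros((1, 10)))
        with pytest.raises(ValidationError):
            reconstruct_all(Y, Y, method="optimize")

    def test_scale_covariance(self):
        rng = np.random.default_rng(11)
        L = 20
        B = rng.standard_normal((L, 5))
        B /= np.linalg.norm(B, axis=0)
        basis = EegBasis(B=B)
        Y = Recording(rng.standard_normal((1, 3 * L)))
        Xb = Recording(rng.standard_normal((1, 3 * L)))
        a = 7.0
        out1 = reconstruct_all(Y, Xb, basis=basis, method="optimize",
                               mu=0.4)
        # the fidelity weight must scale with the data so the two terms
        # keep their balance: mu -> a * mu
        out2 = reconstruct_all(Y.copy_with(a * Y.data),
                               Xb.copy_with(a * Xb.data), basis=basis,
                               method="optimize", mu=0.4 * a)
        np.testing.assert_allclose(out2.data, a * out1.data, rtol=1e-6,
                                   atol=1e-8)
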