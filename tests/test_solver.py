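"""Proximal operators, IALM decomposition and the reconstruction drivers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lps_dmri import (
    CasoratiMatrix,
    DynamicImageSequence,
    EncodingOperator,
    MaskSpec,
    SolverConfig,
    default_lambda,
    default_mu0,
    forward,
    ialm_rpca,
    radial_mask,
    reconstruct,
    soft_threshold,
    svt,
    to_casorati,
)
from lps_dmri.datamodel import KTData, SamplingMask


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "v, tau, expected",
        [(3.0, 1.0, 2.0), (0.5, 1.0, 0.0), (-2.0, 0.5, -1.5), (0.0, 1.0, 0.0)],
    )
    def test_real_values(self, v, tau, expected):
        assert soft_threshold(v, tau) == pytest.approx(expected)

    def test_phase_preserved(self):
        v = 4.0 * np.exp(1j * np.pi / 3)
        out = soft_threshold(v, 1.0)
        assert out == pytest.approx(3.0 * np.exp(1j * np.pi / 3))

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)

    def test_prox_oracle_grid_search(self, rng):
        """soft_threshold minimises tau*|u| + 0.5*|u - v|^2 (brute force)."""
        for _ in range(10):
            v = complex(rng.normal(), rng.normal())
            tau = rng.uniform(0.1, 1.5)
            got = complex(soft_threshold(v, tau))
            grid = np.linspace(-3, 3, 121)
            U = grid[:, None] + 1j * grid[None, :]
            F = tau * np.abs(U) + 0.5 * np.abs(U - v) ** 2
            best = U.flat[np.argmin(F)]
            assert abs(got - best) < 0.1  # grid resolution
            f_got = tau * abs(got) + 0.5 * abs(got - v) ** 2
            assert f_got <= F.min() + 1e-9

    @given(st.integers(0, 1000))
    def test_nonexpansive(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=6) + 1j * rng.normal(size=6)
        b = rng.normal(size=6) + 1j * rng.normal(size=6)
        tau = rng.uniform(0, 2)
        assert np.linalg.norm(
            soft_threshold(a, tau) - soft_threshold(b, tau)
        ) <= np.linalg.norm(a - b) + 1e-12


class TestSvt:
    def test_diagonal_example(self):
        D = np.diag([3.0, 1.0])
        np.testing.assert_allclose(svt(D, 2.0), np.diag([1.0, 0.0]), atol=1e-12)

    def test_threshold_above_spectrum_zeroes(self, rng):
        D = rng.normal(size=(5, 4))
        tau = np.linalg.norm(D, 2) + 1.0
        assert np.abs(svt(D, tau)).max() < 1e-12

    def test_zero_threshold_is_identity(self, rng):
        D = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        np.testing.assert_allclose(svt(D, 0.0), D, atol=1e-12)

    def test_output_rank(self, rng):
        U, _, Vh = np.linalg.svd(rng.normal(size=(8, 8)))
        D = (U * np.array([5.0, 3.0, 1.0, 0.1] + [0.0] * 4)) @ Vh
        out = svt(D, 0.5)
        assert np.linalg.matrix_rank(out, tol=1e-8) == 3

    def test_prox_oracle_perturbation(self, rng):
        """F(svt(D, tau)) <= F(svt(D, tau) + delta) for random perturbations."""
        def F(A, D, tau):
            return tau * np.linalg.norm(A, "nuc") + 0.5 * np.linalg.norm(A - D) ** 2

        for _ in range(5):
            D = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
            tau = rng.uniform(0.2, 2.0)
            A = svt(D, tau)
            f0 = F(A, D, tau)
            for _ in range(100):
                delta = 0.05 * (rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6)))
                assert f0 <= F(A + delta, D, tau) + 1e-10

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svt(np.array([[np.inf, 0.0], [0.0, 1.0]]), 1.0)

    def test_nonexpansive(self, rng):
        A = rng.normal(size=(5, 5))
        B = rng.normal(size=(5, 5))
        assert np.linalg.norm(svt(A, 0.7) - svt(B, 0.7)) <= np.linalg.norm(A - B) + 1e-12


class TestDefaults:
    def test_default_lambda_values(self):
        assert default_lambda(256, 256, 25) == pytest.approx(1 / 256)
        assert default_lambda(1, 1, 30) == pytest.approx(30 ** -0.5)
        assert default_lambda(2, 3, 6) == pytest.approx(6 ** -0.5)

    def test_default_mu0_diag(self):
        X = CasoratiMatrix(np.diag([2.0, 1.0]), (2, 1, 2))
        assert default_mu0(X) == pytest.approx(0.75)

    def test_default_mu0_scaling(self, rng):
        X = rng.normal(size=(6, 4))
        assert default_mu0(3.0 * X) == pytest.approx(default_mu0(X) / 3.0)

    def test_default_mu0_power_iteration_oracle(self, rng):
        X = rng.normal(size=(10, 5))
        v = rng.normal(size=5)
        for _ in range(500):
            v = X.T @ (X @ v)
            v /= np.linalg.norm(v)
        sigma_max = np.linalg.norm(X @ v)
        assert default_mu0(X) == pytest.approx(1.5 / sigma_max, abs=1e-8)

    def test_default_mu0_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            default_mu0(np.zeros((3, 3)))


class TestIalmRpca:
    def test_rank_one_no_sparse_part(self, rng):
        # incoherent rank-1 matrix (bounded positive factors): identifiable,
        # so the whole signal must land in A and none in E
        u = rng.uniform(0.5, 1.5, size=100)
        v = rng.uniform(0.5, 1.5, size=100)
        X = np.outer(u, v)
        res = ialm_rpca(X, SolverConfig(transform="identity"))
        assert res.converged
        nX = np.linalg.norm(X)
        assert np.linalg.norm(res.A.matrix - X) / nX < 1e-5
        assert np.linalg.norm(res.E.matrix) / nX < 1e-5
        assert res.rank_history[-1] == 1

    def test_exact_recovery_planted(self, rng):
        A0 = rng.normal(size=(100, 5)) @ rng.normal(size=(5, 100))
        E0 = np.zeros((100, 100))
        support = rng.choice(100 * 100, size=500, replace=False)
        E0.flat[support] = rng.choice([-1.0, 1.0], 500) * 3 * np.abs(A0).mean()
        res = ialm_rpca(A0 + E0, SolverConfig(lam=0.1, transform="identity"))
        assert res.converged
        assert np.linalg.norm(res.A.matrix - A0) / np.linalg.norm(A0) < 1e-4
        assert res.rank_history[-1] == 5  # planted rank recovered

    def test_zero_matrix_trivial(self):
        res = ialm_rpca(np.zeros((4, 4)))
        assert res.iterations == 1
        assert np.abs(res.A.matrix).max() == 0
        assert np.abs(res.E.matrix).max() == 0

    def test_feasibility_identity_every_iteration(self, rng):
        """X - A_k - E_k equals (L_k - L_{k-1}) / mu_{k-1}, elementwise."""
        X = rng.normal(size=(20, 10)) + 1j * rng.normal(size=(20, 10))
        cfg = SolverConfig(transform="identity", record_multipliers=True, max_iter=40)
        res = ialm_rpca(X, cfg)
        mu0 = default_mu0(X)
        assert len(res.gap_history) == len(res.multiplier_history) >= 2
        for k in range(1, len(res.multiplier_history)):
            mu_k = mu0 * cfg.rho**k  # mu at iteration index k (0-based)
            diff = (res.multiplier_history[k] - res.multiplier_history[k - 1]) / mu_k
            np.testing.assert_allclose(res.gap_history[k], diff, atol=1e-10)
            # and the recorded residual is its norm
            assert res.residual_history[k] == pytest.approx(
                np.linalg.norm(res.gap_history[k]) / np.linalg.norm(X), rel=1e-10
            )

    def test_mu_schedule_and_residual_tolerance(self, rng):
        X = rng.normal(size=(30, 10))
        res = ialm_rpca(X, SolverConfig(transform="identity"))
        assert res.converged
        assert res.residual_history[-1] < 1e-7
        assert all(np.isfinite(res.residual_history))

    def test_nonconvergence_flagged_not_raised(self, rng):
        X = rng.normal(size=(20, 10))
        res = ialm_rpca(X, SolverConfig(max_iter=2, transform="identity"))
        assert not res.converged
        assert res.iterations == 2

    def test_temporal_fourier_unitary(self, rng):
        from lps_dmri.solver import _temporal_transform

        M = rng.normal(size=(12, 8)) + 1j * rng.normal(size=(12, 8))
        T = _temporal_transform(M, "temporal_fourier")
        assert np.linalg.norm(T) == pytest.approx(np.linalg.norm(M), rel=1e-12)
        back = _temporal_transform(T, "temporal_fourier", inverse=True)
        np.testing.assert_allclose(back, M, atol=1e-12)

    def test_rank_bounded(self, small_phantom):
        X = to_casorati(small_phantom.X0)
        res = ialm_rpca(X, SolverConfig(max_iter=30))
        assert all(r <= min(X.matrix.shape) for r in res.rank_history)


class TestReconstruct:
    def test_full_mask_recovers_ground_truth(self, small_phantom):
        nx, ny, nt = small_phantom.X0.shape
        y = forward(small_phantom.X0, EncodingOperator.full(nx, ny, nt))
        for mode in ("plain", "data_consistency"):
            res = reconstruct(y, SolverConfig(mode=mode))
            rel = np.linalg.norm(
                res.reconstruction.values - small_phantom.X0.values
            ) / np.linalg.norm(small_phantom.X0.values)
            assert rel < 1e-4

    def test_plain_mode_reproduces_zero_filled(self, small_phantom):
        nx, ny, nt = small_phantom.X0.shape
        mask = radial_mask(
            MaskSpec(scheme="radial", nx=nx, ny=ny, nt=nt, n_spokes=16, seed=0)
        )
        y = forward(small_phantom.X0, EncodingOperator(mask))
        res = reconstruct(y, SolverConfig(mode="plain", tol=1e-7))
        x0 = res.zero_filled.values
        rel = np.linalg.norm(res.reconstruction.values - x0) / np.linalg.norm(x0)
        assert rel < 1e-6

    def test_reconstruction_equals_a_plus_e(self, small_phantom):
        from lps_dmri import from_casorati
        from lps_dmri.datamodel import CasoratiMatrix

        nx, ny, nt = small_phantom.X0.shape
        mask = radial_mask(
            MaskSpec(scheme="radial", nx=nx, ny=ny, nt=nt, n_spokes=16, seed=0)
        )
        y = forward(small_phantom.X0, EncodingOperator(mask))
        res = reconstruct(y, SolverConfig(n_dc=25))
        rebuilt = from_casorati(
            CasoratiMatrix(
                res.decomposition.A.matrix + res.decomposition.E.matrix, (nx, ny, nt)
            )
        )
        assert np.array_equal(rebuilt.values, res.reconstruction.values)

    def test_empty_mask_rejected(self):
        mask = SamplingMask(np.zeros((4, 4, 2), dtype=np.uint8))
        y = KTData(samples=np.zeros((4, 4, 2), dtype=complex), mask=mask)
        with pytest.raises(ValueError, match="empty"):
            reconstruct(y)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(rho=1.0)
        with pytest.raises(ValueError):
            SolverConfig(lam=-1.0)
        with pytest.raises(ValueError):
            SolverConfig(transform="wavelet")
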