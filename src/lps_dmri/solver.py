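"""Low-rank + sparse decomposition by inexact augmented Lagrange multipliers.

The spatiotemporal (Casorati) matrix ``X`` of a dynamic series is split
into a low-rank background ``A`` and a sparse dynamic component ``E`` by
solving the RPCA problem

    min_{A,E}  ||A||_* + lambda ||T E||_1   s.t.  A + E = X,

where ``T`` is a sparsifying transform acting along time (the unitary
temporal Fourier transform by default — periodic cardiac motion is sparse
in x-f space — or the identity).  The augmented Lagrangian

    ||A||_* + lambda ||T E||_1 + <L, X - A - E> + (mu/2) ||X - A - E||_F^2

is minimised by alternating exact proximal updates with a growing penalty:

    A_{k+1} = SVT_{1/mu_k}(X - E_k + L_k / mu_k)
    E_{k+1} = T^{-1} shrink_{lambda/mu_k}( T (X - A_{k+1} + L_k / mu_k) )
    L_{k+1} = L_k + mu_k (X - A_{k+1} - E_{k+1})
    mu_{k+1} = rho * mu_k,          rho > 1,

stopping when the relative feasibility residual
``||X - A_k - E_k||_F / ||X||_F`` falls below ``tol``.  A nondecreasing,
divergent-sum ``{mu_k}`` makes ``(A_k, E_k)`` converge to an optimal pair,
and the residual equals ``(L_k - L_{k-1}) / mu_{k-1}`` at every step.

Defaults: ``mu0 = 1.5 / ||X||_2``, ``rho = 1.2``, ``tol = 1e-7`` and
``lambda = max(nx*ny, nt)^{-1/2}``.

Two reconstruction drivers wrap the decomposition for undersampled k-t
data: a *plain* mode that decomposes the zero-filled image once (driving
the residual to tol returns A + E equal to the zero-filled image, so its
value is the A/E separation), and a *data-consistency* mode that
alternates warm-started decomposition steps with replacement of the
measured k-space samples under one monotone penalty continuation, which
is what actually removes aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .datamodel import (
    CasoratiMatrix,
    DynamicImageSequence,
    KTData,
    from_casorati,
    to_casorati,
)
from .encoding import EncodingOperator, adjoint, fft2c, ifft2c

__all__ = [
    "SolverConfig",
    "DecompositionResult",
    "ReconResult",
    "soft_threshold",
    "svt",
    "default_lambda",
    "default_mu0",
    "ialm_rpca",
    "reconstruct",
]


def soft_threshold(v: np.ndarray | complex | float, tau: float) -> np.ndarray:
    """Magnitude soft-thresholding, the proximal operator of ``tau * |.|_1``.

    Elementwise ``(v/|v|) * max(|v| - tau, 0)``; phase (sign) is preserved
    and entries with ``|v| <= tau`` map to exactly zero (including v = 0,
    avoiding the 0/0).
    """
    if tau < 0:
        raise ValueError("threshold tau must be >= 0")
    v = np.asarray(v)
    mag = np.abs(v)
    shrunk = np.maximum(mag - tau, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mag > 0, v * (shrunk / np.where(mag > 0, mag, 1.0)), 0.0)
    return out


def svt(D: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding, the proximal operator of ``tau * ||.||_*``.

    Computes ``U shrink_tau(Sigma) V^H`` from an economy SVD.  Singular
    values exactly equal to the threshold shrink to zero; ``svt(D, 0)``
    returns ``D`` to machine precision.
    """
    if tau < 0:
        raise ValueError("threshold tau must be >= 0")
    D = np.asarray(D)
    if not np.all(np.isfinite(D)):
        raise ValueError("svt requires finite entries")
    U, s, Vh = np.linalg.svd(D, full_matrices=False)
    s_shrunk = np.maximum(s - tau, 0.0)
    return (U * s_shrunk) @ Vh


def default_lambda(nx: int, ny: int, nt: int) -> float:
    """Sparsity weight ``max(nx*ny, nt)^(-1/2)``."""
    if min(nx, ny, nt) < 1:
        raise ValueError("dimensions must be positive")
    return float(max(nx * ny, nt)) ** -0.5


def default_mu0(X: CasoratiMatrix | np.ndarray) -> float:
    """Initial penalty ``1.5 / ||X||_2`` (spectral norm)."""
    mat = X.matrix if isinstance(X, CasoratiMatrix) else np.asarray(X)
    sigma_max = np.linalg.norm(mat, 2)
    if sigma_max == 0:
        raise ValueError("default_mu0 undefined for an all-zero matrix")
    return 1.5 / float(sigma_max)


@dataclass
class SolverConfig:
    """Parameters of the IALM decomposition and reconstruction drivers.

    ``lam`` and ``mu0`` default to ``None`` meaning "derive from the data"
    (``default_lambda`` / ``default_mu0``).  ``transform`` selects the
    sparsifying basis applied along time; ``mode`` selects the
    reconstruction driver.  ``dc_weight`` is the data-fidelity weight of
    the soft k-space replacement used when the measurements are noisy.
    """

    lam: float | None = None
    mu0: float | None = None
    rho: float = 1.2
    tol: float = 1e-7
    max_iter: int = 500
    transform: str = "temporal_fourier"
    mode: str = "data_consistency"
    n_dc: int = 120
    outer_tol: float = 1e-6
    dc_weight: float = 0.5
    record_multipliers: bool = False

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.mu0 is not None and self.mu0 <= 0:
            raise ValueError("mu0 must be > 0")
        if self.rho <= 1:
            raise ValueError("rho must be > 1")
        if self.tol <= 0 or self.outer_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.transform not in ("identity", "temporal_fourier"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.mode not in ("plain", "data_consistency"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_dc < 1:
            raise ValueError("n_dc must be >= 1")
        if self.dc_weight <= 0:
            raise ValueError("dc_weight must be > 0")


@dataclass
class DecompositionResult:
    """Output of one IALM run on a Casorati matrix."""

    A: CasoratiMatrix
    E: CasoratiMatrix
    multiplier: np.ndarray
    iterations: int
    residual_history: list[float]
    rank_history: list[int]
    converged: bool
    multiplier_history: list[np.ndarray] = field(default_factory=list)
    gap_history: list[np.ndarray] = field(default_factory=list)

    @property
    def reconstruction_matrix(self) -> np.ndarray:
        return self.A.matrix + self.E.matrix


@dataclass
class ReconResult:
    """Reconstruction of a dynamic series from undersampled k-t data."""

    reconstruction: DynamicImageSequence
    decomposition: DecompositionResult
    zero_filled: DynamicImageSequence
    config: SolverConfig
    outer_iterations: int = 1
    outer_residuals: list[float] = field(default_factory=list)


def _temporal_transform(M: np.ndarray, transform: str, inverse: bool = False) -> np.ndarray:
    """Apply T (or its inverse) along the time axis (rows of length nt)."""
    if transform == "identity":
        return M
    if inverse:
        return np.fft.ifft(M, axis=1, norm="ortho")
    return np.fft.fft(M, axis=1, norm="ortho")


def sparsity_proxy(E: np.ndarray, rel_tol: float = 1e-8) -> float:
    """Fraction of entries with magnitude above ``rel_tol * max|E|``."""
    peak = np.abs(E).max()
    if peak == 0:
        return 0.0
    return float(np.mean(np.abs(E) > rel_tol * peak))


def ialm_rpca(
    X: CasoratiMatrix | np.ndarray,
    config: SolverConfig | None = None,
    log: Callable[[dict], None] | None = None,
) -> DecompositionResult:
    """Decompose ``X`` into low-rank ``A`` plus sparse ``E`` by IALM.

    Non-convergence within ``max_iter`` is reported through the
    ``converged`` flag, never raised.
    """
    if config is None:
        config = SolverConfig()
    if isinstance(X, CasoratiMatrix):
        mat = X.matrix
        origin_shape = X.origin_shape
    else:
        mat = np.asarray(X)
        origin_shape = (mat.shape[0], 1, mat.shape[1])
    if not np.all(np.isfinite(mat)):
        raise ValueError("ialm_rpca requires finite entries")
    mat = mat.astype(np.complex128)
    n1, n2 = mat.shape

    norm_X = np.linalg.norm(mat)
    if norm_X == 0:
        zero = np.zeros_like(mat)
        return DecompositionResult(
            A=CasoratiMatrix(zero, origin_shape),
            E=CasoratiMatrix(zero.copy(), origin_shape),
            multiplier=zero.copy(),
            iterations=1,
            residual_history=[0.0],
            rank_history=[0],
            converged=True,
        )

    lam = config.lam if config.lam is not None else float(max(n1, n2)) ** -0.5
    mu = config.mu0 if config.mu0 is not None else default_mu0(mat)

    # Standard IALM dual start: L0 = X / max(||X||_2, ||X||_inf / lambda).
    sigma_max = np.linalg.norm(mat, 2)
    scale = max(sigma_max, np.abs(mat).max() / lam)
    L = mat / scale
    E = np.zeros_like(mat)
    A = np.zeros_like(mat)

    residual_history: list[float] = []
    rank_history: list[int] = []
    multiplier_history: list[np.ndarray] = []
    gap_history: list[np.ndarray] = []
    converged = False
    iterations = 0

    mu0 = mu
    for k in range(config.max_iter):
        mu = mu0 * config.rho**k  # exact schedule mu_k = mu0 * rho^k
        # SVT step, inlined so the singular values also give rank(A_k).
        U, s, Vh = np.linalg.svd(mat - E + L / mu, full_matrices=False)
        s_shrunk = np.maximum(s - 1.0 / mu, 0.0)
        A = (U * s_shrunk) @ Vh
        rank = int(np.count_nonzero(s_shrunk))

        residual_in = mat - A + L / mu
        E = _temporal_transform(
            soft_threshold(_temporal_transform(residual_in, config.transform), lam / mu),
            config.transform,
            inverse=True,
        )
        if config.transform == "identity":
            E = np.asarray(E)

        gap = mat - A - E
        L = L + mu * gap
        if config.record_multipliers:
            multiplier_history.append(L.copy())
            gap_history.append(gap.copy())

        residual = float(np.linalg.norm(gap) / norm_X)
        residual_history.append(residual)
        rank_history.append(rank)
        iterations = k + 1
        if log is not None:
            log(
                {
                    "iter": iterations,
                    "rank": rank,
                    "sparsity": sparsity_proxy(E),
                    "residual": residual,
                    "mu": mu,
                }
            )
        if residual < config.tol:
            converged = True
            break

    return DecompositionResult(
        A=CasoratiMatrix(A, origin_shape),
        E=CasoratiMatrix(E, origin_shape),
        multiplier=L,
        iterations=iterations,
        residual_history=residual_history,
        rank_history=rank_history,
        converged=converged,
        multiplier_history=multiplier_history,
        gap_history=gap_history,
    )


def _data_consistency_step(
    xhat: np.ndarray, y: KTData, weight: float | None
) -> np.ndarray:
    """Replace estimated k-space by the measurements at sampled locations.

    Hard replacement for noiseless data; when `weight` is given (noisy
    data) the sampled entries become the weighted average
    ``(F xhat + weight * y) / (1 + weight)``.
    """
    k_est = fft2c(xhat)
    sampled = y.mask.boolean()
    if weight is None:
        k_est[sampled] = y.samples[sampled]
    else:
        k_est[sampled] = (k_est[sampled] + weight * y.samples[sampled]) / (1.0 + weight)
    return ifft2c(k_est)


def reconstruct(
    y: KTData,
    config: SolverConfig | None = None,
    log: Callable[[dict], None] | None = None,
) -> ReconResult:
    """Reconstruct a dynamic series from undersampled k-t measurements.

    ``mode='plain'`` decomposes the zero-filled image once.
    ``mode='data_consistency'`` alternates a warm-started decomposition
    step with k-space replacement of the measured samples (hard when the
    data are noiseless, weighted-average otherwise) under a single
    penalty continuation, until the iterate stabilises; the returned
    reconstruction is the final low-rank + sparse estimate ``A + E``.
    """
    if config is None:
        config = SolverConfig()
    if y.mask.indicator.sum() == 0:
        raise ValueError("cannot reconstruct from an empty sampling mask")
    op = EncodingOperator(mask=y.mask)
    zero_filled = adjoint(y, op)
    nx, ny, nt = zero_filled.shape
    lam = config.lam if config.lam is not None else default_lambda(nx, ny, nt)

    if config.mode == "plain":
        dec = ialm_rpca(to_casorati(zero_filled), replace(config, lam=lam), log=log)
        recon = from_casorati(
            CasoratiMatrix(dec.reconstruction_matrix, dec.A.origin_shape)
        )
        return ReconResult(
            reconstruction=recon,
            decomposition=dec,
            zero_filled=zero_filled,
            config=config,
            outer_iterations=1,
            outer_residuals=[],
        )

    # Data-consistency mode: one warm-started IALM step per outer
    # iteration interleaved with k-space replacement, with a single
    # monotone penalty continuation mu_n = mu0 * rho^n across the loop.
    # Early iterations (large thresholds) regularise hard and fill the
    # unsampled k-space from the low-rank + sparse model; as mu grows the
    # iterate becomes feasible and data-consistent.
    weight = config.dc_weight if y.noise_sigma > 0 else None
    X = zero_filled.values
    Xm = np.reshape(X, (nx * ny, nt), order="F")
    norm0 = float(np.linalg.norm(Xm))
    if norm0 == 0:
        raise ValueError("cannot reconstruct from all-zero measurements")
    mu0 = config.mu0 if config.mu0 is not None else default_mu0(Xm)
    E = np.zeros_like(Xm)
    L = np.zeros_like(Xm)
    A = np.zeros_like(Xm)
    outer_residuals: list[float] = []
    residual_history: list[float] = []
    rank_history: list[int] = []
    for n in range(config.n_dc):
        mu = mu0 * config.rho**n
        Xm = np.reshape(X, (nx * ny, nt), order="F")
        U, s, Vh = np.linalg.svd(Xm - E + L / mu, full_matrices=False)
        s_shrunk = np.maximum(s - 1.0 / mu, 0.0)
        A = (U * s_shrunk) @ Vh
        E = _temporal_transform(
            soft_threshold(
                _temporal_transform(Xm - A + L / mu, config.transform), lam / mu
            ),
            config.transform,
            inverse=True,
        )
        L = L + mu * (Xm - A - E)
        residual_history.append(float(np.linalg.norm(Xm - A - E) / norm0))
        rank_history.append(int(np.count_nonzero(s_shrunk)))
        xhat = np.reshape(A + E, (nx, ny, nt), order="F")
        X_next = _data_consistency_step(xhat, y, weight)
        change = float(
            np.linalg.norm(X_next - X) / max(np.linalg.norm(X), np.finfo(float).tiny)
        )
        outer_residuals.append(change)
        if log is not None:
            log(
                {
                    "iter": n + 1,
                    "rank": rank_history[-1],
                    "sparsity": sparsity_proxy(E),
                    "residual": residual_history[-1],
                    "mu": mu,
                    "dc_change": change,
                }
            )
        X = X_next
        # Stop only once the iterate is stable AND A + E is feasible
        # (residual small), since the returned reconstruction is A + E.
        if change < config.outer_tol and residual_history[-1] < config.outer_tol:
            break
    dec = DecompositionResult(
        A=CasoratiMatrix(A, (nx, ny, nt)),
        E=CasoratiMatrix(E, (nx, ny, nt)),
        multiplier=L,
        iterations=len(outer_residuals),
        residual_history=residual_history,
        rank_history=rank_history,
        converged=bool(
            outer_residuals
            and outer_residuals[-1] < config.outer_tol
            and residual_history[-1] < config.outer_tol
        ),
    )
    recon = from_casorati(CasoratiMatrix(dec.reconstruction_matrix, (nx, ny, nt)))
    return ReconResult(
        reconstruction=recon,
        decomposition=dec,
        zero_filled=zero_filled,
        config=config,
        outer_iterations=len(outer_residuals),
        outer_residuals=outer_residuals,
    )
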