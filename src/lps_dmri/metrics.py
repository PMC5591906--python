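"""Reconstruction-quality metrics: energy-normalised PSNR and global SSIM.

``psnr`` is the energy-normalised variant

    PSNR = -10 log10( ||Xhat - X||_F^2 / ||X||_F^2 )   [dB]

computed on magnitudes over the whole 2D+t array: 0 dB means the error
energy equals the signal energy, and each factor-of-10 energy reduction
adds 10 dB.  Note this normalises by signal energy, not peak^2; the
conventional peak-based definition is available as :func:`peak_psnr`.

``ssim_frame`` is the structural similarity index with *global* (single
window) statistics over the frame:

    SSIM = (2 mu_R mu_F + c1)(2 cov_RF + c2)
           / ((mu_R^2 + mu_F^2 + c1)(sigma_R^2 + sigma_F^2 + c2)),

with c1 = (K1 L)^2, c2 = (K2 L)^2 and the usual constants K1 = 0.01,
K2 = 0.03, L = 255 (8-bit grey levels).  Magnitude frames are rescaled
to [0, L] by the reference peak before comparison.  The common 11x11
sliding-window mean SSIM is offered as a clearly separate option
(:func:`ssim_frame_windowed`), delegating to scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DynamicImageSequence

__all__ = [
    "SsimParams",
    "psnr",
    "peak_psnr",
    "ssim_frame",
    "ssim_series",
    "ssim_frame_windowed",
]


@dataclass
class SsimParams:
    """SSIM stabilisation constants and dynamic range."""

    K1: float = 0.01
    K2: float = 0.03
    L: float = 255.0

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0 or self.L <= 0:
            raise ValueError("K1, K2 and L must all be positive")

    @property
    def c1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.K2 * self.L) ** 2


def _magnitudes(
    xhat: DynamicImageSequence | np.ndarray, x: DynamicImageSequence | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    a = xhat.magnitude() if isinstance(xhat, DynamicImageSequence) else np.abs(np.asarray(xhat))
    b = x.magnitude() if isinstance(x, DynamicImageSequence) else np.abs(np.asarray(x))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(xhat: DynamicImageSequence | np.ndarray, x: DynamicImageSequence | np.ndarray) -> float:
    """Energy-normalised PSNR in dB; +inf for a perfect reconstruction."""
    mag_hat, mag_ref = _magnitudes(xhat, x)
    signal = float(np.sum(mag_ref**2))
    if signal == 0:
        raise ValueError("PSNR undefined for an all-zero reference")
    err = float(np.sum((mag_hat - mag_ref) ** 2))
    if err == 0:
        return float("inf")
    return -10.0 * np.log10(err / signal)


def peak_psnr(
    xhat: DynamicImageSequence | np.ndarray, x: DynamicImageSequence | np.ndarray
) -> float:
    """Conventional peak-based PSNR, -10 log10(MSE / peak^2), in dB."""
    mag_hat, mag_ref = _magnitudes(xhat, x)
    peak = float(mag_ref.max())
    if peak == 0:
        raise ValueError("peak PSNR undefined for an all-zero reference")
    mse = float(np.mean((mag_hat - mag_ref) ** 2))
    if mse == 0:
        return float("inf")
    return -10.0 * np.log10(mse / peak**2)


def _rescaled(frame_r: np.ndarray, frame_f: np.ndarray, L: float) -> tuple[np.ndarray, np.ndarray]:
    peak = frame_f.max()
    if peak == 0:
        return frame_r, frame_f
    return frame_r * (L / peak), frame_f * (L / peak)


def ssim_frame(
    xr: np.ndarray,
    xf: np.ndarray,
    params: SsimParams | None = None,
    rescale: bool = True,
) -> float:
    """Global (single-window) SSIM between two magnitude frames.

    With ``rescale`` both frames are mapped to [0, L] by the reference
    frame's peak so the constants match the 8-bit convention.
    """
    if params is None:
        params = SsimParams()
    a = np.abs(np.asarray(xr, dtype=np.complex128)).astype(np.float64)
    b = np.abs(np.asarray(xf, dtype=np.complex128)).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if rescale:
        a, b = _rescaled(a, b, params.L)
    mu_r, mu_f = a.mean(), b.mean()
    var_r, var_f = a.var(), b.var()
    cov = float(np.mean((a - mu_r) * (b - mu_f)))
    num = (2 * mu_r * mu_f + params.c1) * (2 * cov + params.c2)
    den = (mu_r**2 + mu_f**2 + params.c1) * (var_r + var_f + params.c2)
    return float(num / den)


def ssim_series(
    xr: DynamicImageSequence | np.ndarray,
    xf: DynamicImageSequence | np.ndarray,
    params: SsimParams | None = None,
    rescale: bool = True,
) -> np.ndarray:
    """Per-frame global SSIM of a dynamic series, in frame order."""
    mag_r, mag_f = _magnitudes(xr, xf)
    nt = mag_r.shape[2]
    return np.array(
        [ssim_frame(mag_r[:, :, t], mag_f[:, :, t], params, rescale) for t in range(nt)]
    )


def ssim_frame_windowed(
    xr: np.ndarray,
    xf: np.ndarray,
    params: SsimParams | None = None,
    rescale: bool = True,
) -> float:
    """11x11 Gaussian-free sliding-window mean SSIM (scikit-image).

    This is the common local variant, *not* the global single-window
    definition used elsewhere in this package.
    """
    from skimage.metrics import structural_similarity

    if params is None:
        params = SsimParams()
    a = np.abs(np.asarray(xr)).astype(np.float64)
    b = np.abs(np.asarray(xf)).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if rescale:
        a, b = _rescaled(a, b, params.L)
    return float(
        structural_similarity(
            b, a, data_range=params.L, K1=params.K1, K2=params.K2, win_size=11
        )
    )
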