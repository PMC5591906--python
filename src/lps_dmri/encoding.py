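"""The MRI measurement operator ``M = R F`` and its adjoint.

``forward`` applies, per temporal frame, a centred unitary 2D Fourier
transform (DC at the grid centre, ``norm="ortho"`` so Parseval holds
exactly) followed by elementwise multiplication with the binary sampling
mask.  ``adjoint`` is the zero-filled reconstruction: inverse centred
unitary FFT of the zero-filled k-space — the standard naive baseline for
undersampled data.

With a full mask the operator is unitary, so ``adjoint(forward(x)) == x``
to machine precision; in general ``M^H M`` is an orthogonal projection in
the image domain.

Measurement noise is additive complex Gaussian, applied independently to
the real and imaginary parts of *sampled* locations only (unsampled
entries of the container stay exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DynamicImageSequence, KTData, SamplingMask

__all__ = ["EncodingOperator", "forward", "adjoint", "add_noise", "fft2c", "ifft2c"]


def fft2c(frames: np.ndarray) -> np.ndarray:
    """Centred unitary 2D FFT over the first two axes."""
    shifted = np.fft.ifftshift(frames, axes=(0, 1))
    spec = np.fft.fft2(shifted, axes=(0, 1), norm="ortho")
    return np.fft.fftshift(spec, axes=(0, 1))


def ifft2c(spectra: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    shifted = np.fft.ifftshift(spectra, axes=(0, 1))
    img = np.fft.ifft2(shifted, axes=(0, 1), norm="ortho")
    return np.fft.fftshift(img, axes=(0, 1))


@dataclass
class EncodingOperator:
    """Masked per-frame Fourier encoding of a dynamic series."""

    mask: SamplingMask

    @classmethod
    def full(cls, nx: int, ny: int, nt: int) -> "EncodingOperator":
        return cls(mask=SamplingMask.full(nx, ny, nt))


def forward(x: DynamicImageSequence, op: EncodingOperator) -> KTData:
    """Simulate acquisition: ``Y = R F X``; unsampled entries are exactly 0."""
    if x.shape != op.mask.shape:
        raise ValueError(f"image shape {x.shape} != mask shape {op.mask.shape}")
    samples = fft2c(x.values) * op.mask.indicator
    return KTData(samples=samples, mask=op.mask)


def adjoint(y: KTData, op: EncodingOperator | None = None) -> DynamicImageSequence:
    """Zero-filled reconstruction ``M^H Y``: inverse FFT of zero-filled k-space."""
    mask = op.mask if op is not None else y.mask
    if y.shape != mask.shape:
        raise ValueError(f"k-space shape {y.shape} != mask shape {mask.shape}")
    return DynamicImageSequence(values=ifft2c(y.samples * mask.indicator))


def add_noise(y: KTData, sigma: float, seed: int = 0) -> KTData:
    """Add i.i.d. complex Gaussian noise (std `sigma` per real/imag channel)
    to the sampled k-space locations; unsampled locations stay zero."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return KTData(samples=y.samples.copy(), mask=y.mask, noise_sigma=y.noise_sigma)
    rng = np.random.default_rng(seed)
    sampled = y.mask.boolean()
    noise = rng.normal(0.0, sigma, y.shape) + 1j * rng.normal(0.0, sigma, y.shape)
    noisy = y.samples + np.where(sampled, noise, 0.0)
    return KTData(samples=noisy, mask=y.mask, noise_sigma=float(np.hypot(y.noise_sigma, sigma)))
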