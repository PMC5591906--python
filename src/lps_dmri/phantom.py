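"""Synthetic dynamic-MRI phantom with planted low-rank + sparse structure.

The phantom emulates the structure of a cardiac cine series — temporally
correlated anatomy plus a small, spatially localised dynamic component —
with *known* ground truth:

* background ``A0``: a sum of ``background_rank`` separable terms
  (smooth random spatial map x smooth temporal weight).  The first term
  is an elliptical "torso" with a constant temporal weight; the Casorati
  matrix of ``A0`` has rank exactly ``background_rank``.
* dynamic part ``E0``: ``n_dynamic`` bright ellipses whose centres and
  radii oscillate periodically over the ``nt`` frames (one full cycle, a
  beating-ventricle caricature), zero outside the recorded
  ``dynamic_support`` and occupying at most 15% of the voxels.

``X0 = A0 + E0`` exactly, magnitudes are scaled so ``max |X0| = 255``,
and an optional linear phase roll across the field of view makes the
data genuinely complex (a per-pixel unit phase, so planted rank and
support are unchanged).  Everything is deterministic given the seed.

:func:`end_to_end_case` runs the full protocol on a phantom —
undersample, optionally add noise, reconstruct, score — and returns the
bundle of intermediate products and quality numbers, so acquisition,
decomposition and reconstruction are all testable against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

from .datamodel import DynamicImageSequence, KTData, to_casorati
from .encoding import EncodingOperator, add_noise, forward
from .metrics import psnr, ssim_series
from .sampling import MaskSpec, make_mask
from .solver import ReconResult, SolverConfig, reconstruct

__all__ = ["PhantomConfig", "PhantomGroundTruth", "generate_phantom", "end_to_end_case"]


@dataclass
class PhantomConfig:
    """Geometry, rank and motion parameters of the synthetic phantom."""

    nx: int = 64
    ny: int = 64
    nt: int = 16
    background_rank: int = 3
    n_dynamic: int = 2
    motion_amplitude: float = 4.0
    dynamic_intensity: float = 120.0
    phase_roll: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nt) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 1 <= self.background_rank <= min(self.nx * self.ny, self.nt):
            raise ValueError("background_rank must lie in [1, min(nx*ny, nt)]")
        if self.n_dynamic < 0:
            raise ValueError("n_dynamic must be >= 0")
        if self.dynamic_intensity < 0 or self.motion_amplitude < 0:
            raise ValueError("motion and intensity parameters must be >= 0")


@dataclass
class PhantomGroundTruth:
    """Phantom with exact decomposition ``X0 = A0 + E0`` and known support."""

    X0: DynamicImageSequence
    A0: DynamicImageSequence
    E0: DynamicImageSequence
    dynamic_support: np.ndarray
    config: PhantomConfig


def _ellipse(nx: int, ny: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0).astype(np.float64)


def _smooth_map(rng: np.random.Generator, nx: int, ny: int) -> np.ndarray:
    """Band-limited random spatial map in [0, 1], zero-mean-ish texture."""
    raw = rng.normal(size=(nx, ny))
    sm = gaussian_filter(raw, sigma=max(nx, ny) / 12.0)
    sm -= sm.min()
    peak = sm.max()
    return sm / peak if peak > 0 else sm


def generate_phantom(config: PhantomConfig | None = None) -> PhantomGroundTruth:
    """Build the phantom; raises if the dynamic support exceeds 15% of voxels."""
    if config is None:
        config = PhantomConfig()
    rng = np.random.default_rng(config.seed)
    nx, ny, nt, r = config.nx, config.ny, config.nt, config.background_rank

    # Background: r separable terms; first is the static torso.
    torso = _ellipse(nx, ny, (nx - 1) / 2, (ny - 1) / 2, 0.42 * nx, 0.46 * ny)
    torso = gaussian_filter(torso, sigma=1.5)
    spatial = [torso]
    temporal = [np.ones(nt)]
    t_axis = np.arange(nt)
    for i in range(1, r):
        spatial.append(_smooth_map(rng, nx, ny) * torso)
        freq = i  # whole cycles over the series: periodic, x-f sparse
        phase = rng.uniform(0, 2 * np.pi)
        temporal.append(0.35 / i * (1.0 + 0.8 * np.sin(2 * np.pi * freq * t_axis / nt + phase)))
    A0 = np.zeros((nx, ny, nt))
    for s_map, w in zip(spatial, temporal):
        A0 += s_map[:, :, None] * w[None, None, :]

    # Dynamic component: oscillating bright ellipses inside the torso.
    E0 = np.zeros((nx, ny, nt))
    support = np.zeros((nx, ny, nt), dtype=bool)
    for j in range(config.n_dynamic):
        angle = 2 * np.pi * j / max(config.n_dynamic, 1) + rng.uniform(0, np.pi / 4)
        cx0 = (nx - 1) / 2 + 0.18 * nx * np.cos(angle)
        cy0 = (ny - 1) / 2 + 0.18 * ny * np.sin(angle)
        rx0 = 0.07 * nx + rng.uniform(0, 0.02 * nx)
        ry0 = 0.08 * ny + rng.uniform(0, 0.02 * ny)
        phase = rng.uniform(0, 2 * np.pi)
        # radius pulsation scales with the motion amplitude (in cells),
        # so motion_amplitude = 0 yields a perfectly static object
        pulse = min(0.3, 0.05 * config.motion_amplitude)
        for t in range(nt):
            osc = np.sin(2 * np.pi * t / nt + phase)
            cx = cx0 + config.motion_amplitude * osc
            cy = cy0 + config.motion_amplitude * np.cos(2 * np.pi * t / nt + phase)
            rx = rx0 * (1.0 + pulse * osc)
            ry = ry0 * (1.0 - pulse * osc)
            blob = _ellipse(nx, ny, cx, cy, max(rx, 1.0), max(ry, 1.0))
            E0[:, :, t] += config.dynamic_intensity / 255.0 * blob
            support[:, :, t] |= blob > 0

    support_fraction = support.mean()
    if support_fraction > 0.15:
        raise ValueError(
            f"dynamic support covers {support_fraction:.1%} of voxels (> 15%); "
            "reduce n_dynamic, object size or motion_amplitude"
        )

    # Common scale so max |X0| = 255; optional linear phase roll makes the
    # data complex without changing planted rank or support.
    X0 = A0 + E0
    peak = np.abs(X0).max()
    scale = 255.0 / peak
    A0 *= scale
    E0 *= scale
    if config.phase_roll:
        x = np.arange(nx)[:, None, None]
        y = np.arange(ny)[None, :, None]
        phase_map = np.exp(1j * 2 * np.pi * (0.6 * x / nx + 0.4 * y / ny))
        A0 = A0 * phase_map
        E0 = E0 * phase_map
    X0 = A0 + E0

    return PhantomGroundTruth(
        X0=DynamicImageSequence(X0),
        A0=DynamicImageSequence(A0),
        E0=DynamicImageSequence(E0),
        dynamic_support=support,
        config=config,
    )


def sparse_correlation(E: np.ndarray, E0: np.ndarray, support: np.ndarray) -> float:
    """Normalised (cosine) correlation of |E| with |E0| over the support."""
    a = np.abs(E)[support].ravel()
    b = np.abs(E0)[support].ravel()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


@dataclass
class ScenarioBundle:
    """Everything produced by one end-to-end phantom experiment."""

    truth: PhantomGroundTruth
    ktdata: KTData
    recon: ReconResult
    psnr_recon: float
    psnr_zero_filled: float
    ssim_recon: np.ndarray
    e_correlation: float
    extras: dict[str, Any] = field(default_factory=dict)


def end_to_end_case(
    config: PhantomConfig | None = None,
    mask_spec: MaskSpec | None = None,
    sigma: float = 0.0,
    solver_config: SolverConfig | None = None,
    noise_seed: int | None = None,
) -> ScenarioBundle:
    """Phantom -> mask -> acquire (+noise) -> reconstruct -> score.

    Fully seeded: phantom and mask carry their own seeds; the noise seed
    defaults to ``mask_spec.seed + 1``.
    """
    if config is None:
        config = PhantomConfig()
    truth = generate_phantom(config)
    if mask_spec is None:
        mask_spec = MaskSpec(
            scheme="radial", nx=config.nx, ny=config.ny, nt=config.nt,
            n_spokes=max(1, config.nx // 4), seed=config.seed,
        )
    if (mask_spec.nx, mask_spec.ny, mask_spec.nt) != truth.X0.shape:
        raise ValueError("mask grid does not match the phantom grid")
    mask = make_mask(mask_spec)
    op = EncodingOperator(mask=mask)
    y = forward(truth.X0, op)
    if sigma > 0:
        seed = noise_seed if noise_seed is not None else mask_spec.seed + 1
        y = add_noise(y, sigma, seed=seed)
    result = reconstruct(y, solver_config)

    recon_psnr = psnr(result.reconstruction, truth.X0)
    zf_psnr = psnr(result.zero_filled, truth.X0)
    ssim_vals = ssim_series(result.reconstruction, truth.X0)
    nx, ny, nt = truth.X0.shape
    E_img = np.reshape(result.decomposition.E.matrix, (nx, ny, nt), order="F")
    e_corr = sparse_correlation(E_img, truth.E0.values, truth.dynamic_support)

    return ScenarioBundle(
        truth=truth,
        ktdata=y,
        recon=result,
        psnr_recon=recon_psnr,
        psnr_zero_filled=zf_psnr,
        ssim_recon=ssim_vals,
        e_correlation=e_corr,
        extras={
            "sampling_ratio": mask.sampling_ratio,
            "planted_rank": config.background_rank,
            "recovered_rank": result.decomposition.rank_history[-1]
            if result.decomposition.rank_history
            else 0,
            "casorati_rank_X0": to_casorati(truth.X0).rank,
        },
    )
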