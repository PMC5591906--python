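"""k-t undersampling mask generators.

Two Cartesian-grid trajectories are provided:

* **Cartesian variable-density lines** — each frame is fully sampled
  along the readout (kx) axis and keeps ``round(ny / R)`` phase-encode
  (ky) lines: a small central band is always acquired and the remaining
  lines are drawn without replacement with probability proportional to a
  zero-centred Gaussian over ky (width ``ny/6``), so the sampling density
  is maximal at the k-space centre.
* **Pseudo-radial spokes** — ``n_spokes`` straight lines through the
  k-space centre at equally spaced angles over [0, pi), rasterized to the
  Cartesian grid by nearest-cell rounding of points stepped along each
  spoke (one dominant-axis cell per step).  An optional per-frame angular offset of
  ``(pi/n_spokes) * t/nt`` (or golden-angle increments) decorrelates the
  frames.

Both generators are deterministic given the seed, always include the DC
sample (grid centre, index ``(nx//2, ny//2)``) in every frame, and by
default vary from frame to frame — temporal incoherence of the aliasing
is what low-rank + sparse reconstruction exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import SamplingMask

__all__ = ["MaskSpec", "cartesian_mask", "radial_mask", "sampling_ratio", "make_mask"]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))  # ~111.25 degrees


@dataclass
class MaskSpec:
    """Parameters of a mask generator run.

    Exactly one of ``acceleration`` (Cartesian) / ``n_spokes`` (radial)
    drives the generator, depending on ``scheme``.
    """

    scheme: str
    nx: int
    ny: int
    nt: int
    acceleration: float | None = None
    n_spokes: int | None = None
    center_fraction: float = 1.0 / 32.0
    vary_per_frame: bool = True
    golden_angle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("cartesian", "radial"):
            raise ValueError(f"unknown mask scheme {self.scheme!r}")
        if min(self.nx, self.ny, self.nt) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0 <= self.center_fraction < 1:
            raise ValueError("center_fraction must lie in [0, 1)")
        if self.scheme == "cartesian":
            if self.acceleration is None:
                raise ValueError("cartesian scheme requires an acceleration factor")
            if self.acceleration < 1:
                raise ValueError("acceleration must be >= 1")
        else:
            if self.n_spokes is None:
                raise ValueError("radial scheme requires a spoke count")
            if self.n_spokes < 1:
                raise ValueError("n_spokes must be >= 1")


def cartesian_mask(spec: MaskSpec) -> SamplingMask:
    """Variable-density random phase-encode line mask.

    Keeps exactly ``round(ny / acceleration)`` ky lines per frame, so the
    sampling ratio is ``round(ny/R)/ny`` independent of the seed.
    """
    if spec.scheme != "cartesian":
        raise ValueError("spec.scheme must be 'cartesian'")
    ny = spec.ny
    if spec.acceleration > ny:
        raise ValueError(f"acceleration {spec.acceleration} exceeds ny={ny}")
    n_lines = int(round(ny / spec.acceleration))
    n_lines = max(1, min(ny, n_lines))

    center = ny // 2  # DC line under the centred-FFT convention
    n_band = max(1, int(round(spec.center_fraction * ny)))
    n_band = min(n_band, n_lines)
    lo = center - (n_band - 1) // 2
    band = np.arange(lo, lo + n_band)

    ky = np.arange(ny)
    weights = np.exp(-0.5 * ((ky - center) / (ny / 6.0)) ** 2)
    weights[band] = 0.0

    rng = np.random.default_rng(spec.seed)
    indicator = np.zeros((spec.nx, ny, spec.nt), dtype=np.uint8)
    n_extra = n_lines - n_band
    lines_t0: np.ndarray | None = None
    for t in range(spec.nt):
        if t == 0 or spec.vary_per_frame:
            if n_extra > 0:
                p = weights / weights.sum()
                extra = rng.choice(ny, size=n_extra, replace=False, p=p)
            else:
                extra = np.empty(0, dtype=int)
            lines_t0 = np.concatenate([band, extra])
        assert lines_t0 is not None
        indicator[:, lines_t0, t] = 1
    return SamplingMask(
        indicator=indicator,
        scheme="cartesian",
        params={
            "acceleration": float(spec.acceleration),
            "center_fraction": spec.center_fraction,
            "seed": spec.seed,
        },
    )


def _rasterize_spoke(nx: int, ny: int, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Grid cells crossed by a line through the k-space centre at `angle`.

    Points are stepped along the spoke so the dominant axis advances one
    cell per step and both coordinates are rounded to the nearest cell
    (round-half-up for determinism); out-of-grid points are discarded.
    """
    cx, cy = nx // 2, ny // 2
    c, s = np.cos(angle), np.sin(angle)
    step = 1.0 / max(abs(c), abs(s))
    half_len = 0.5 * float(np.hypot(nx, ny))
    t = np.arange(-half_len, half_len, step)
    x = np.floor(cx + t * c + 0.5).astype(int)
    y = np.floor(cy + t * s + 0.5).astype(int)
    keep = (x >= 0) & (x < nx) & (y >= 0) & (y < ny)
    return x[keep], y[keep]


def radial_mask(spec: MaskSpec) -> SamplingMask:
    """Pseudo-radial mask: equally spaced spokes rasterized to the grid.

    A spoke count large enough to cover the grid simply saturates the
    mask; it is never an error.
    """
    if spec.scheme != "radial":
        raise ValueError("spec.scheme must be 'radial'")
    n_spokes = int(spec.n_spokes)  # type: ignore[arg-type]
    indicator = np.zeros((spec.nx, spec.ny, spec.nt), dtype=np.uint8)
    base_angles = np.arange(n_spokes) * np.pi / n_spokes
    for t in range(spec.nt):
        if spec.vary_per_frame:
            if spec.golden_angle:
                offset = (t * GOLDEN_ANGLE) % np.pi
            else:
                offset = (np.pi / n_spokes) * (t / spec.nt)
        else:
            offset = 0.0
        for angle in base_angles + offset:
            ix, iy = _rasterize_spoke(spec.nx, spec.ny, angle)
            indicator[ix, iy, t] = 1
        indicator[spec.nx // 2, spec.ny // 2, t] = 1  # DC always acquired
    return SamplingMask(
        indicator=indicator,
        scheme="radial",
        params={"n_spokes": n_spokes, "seed": spec.seed},
    )


def make_mask(spec: MaskSpec) -> SamplingMask:
    """Dispatch to the generator named by ``spec.scheme``."""
    return cartesian_mask(spec) if spec.scheme == "cartesian" else radial_mask(spec)


def sampling_ratio(mask: SamplingMask) -> float:
    """Acquired fraction of the full k-t grid, in (0, 1]."""
    return mask.sampling_ratio
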