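"""Core data containers for dynamic-MRI series and k-t space data.

A dynamic 2D acquisition is represented three ways:

* :class:`DynamicImageSequence` — a complex array indexed ``(x, y, t)``,
  the image series ``X = [x_1 | ... | x_T]``.
* :class:`CasoratiMatrix` — the same data reshaped to a ``(nx*ny, nt)``
  matrix with one column per temporal frame.  Temporal redundancy of the
  series appears as (approximate) low rank of this matrix, which is the
  object the RPCA solver decomposes.
* :class:`KTData` — undersampled complex k-space measurements together
  with the binary :class:`SamplingMask` that produced them.

The Casorati flattening order is fixed: each frame is flattened
column-major (Fortran order), i.e. the x index varies fastest.  The
round-trip ``from_casorati(to_casorati(seq))`` is bit-exact.

Containers are HDF5: dataset ``/kspace`` (complex128), ``/mask`` (uint8),
with ``scheme``, ``acceleration``, ``seed`` and ``noise_sigma`` stored as
root attributes.  Magnitude series can be exported to NIfTI-1 and single
frames to PNG for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np

__all__ = [
    "DynamicImageSequence",
    "CasoratiMatrix",
    "SamplingMask",
    "KTData",
    "to_casorati",
    "from_casorati",
    "save_ktdata",
    "load_ktdata",
    "save_sequence_nifti",
    "load_sequence_nifti",
    "save_frame_png",
]


class FormatError(ValueError):
    """A container file is missing a required dataset or attribute."""


@dataclass
class DynamicImageSequence:
    """Complex 2D+time image series, indexed ``(x, y, t)``.

    Parameters
    ----------
    values : ndarray
        Complex array of shape ``(nx, ny, nt)``.  Real input is promoted.
    pixel_scale : float
        Nominal dynamic range of the magnitudes (default 255, the 8-bit
        grey-level convention the SSIM constants assume).
    """

    values: np.ndarray
    pixel_scale: float = 255.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a (nx, ny, nt) array, got ndim={self.values.ndim}"
            )
        if not np.issubdtype(self.values.dtype, np.complexfloating):
            self.values = self.values.astype(np.complex128)
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite (no NaN/Inf)")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def nx(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def nt(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        """Magnitude image series, real ``(nx, ny, nt)``."""
        return np.abs(self.values)

    def frame(self, t: int) -> np.ndarray:
        """Complex frame ``t`` as an ``(nx, ny)`` array."""
        return self.values[:, :, t]


@dataclass
class CasoratiMatrix:
    """Space x time matrix view of an image sequence.

    ``matrix`` has shape ``(nx*ny, nt)``; column ``t`` is frame ``t``
    flattened column-major.  ``origin_shape`` records ``(nx, ny, nt)`` so
    the reshaping is invertible.
    """

    matrix: np.ndarray
    origin_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("Casorati matrix must be 2-D")
        nx, ny, nt = self.origin_shape
        if self.matrix.shape != (nx * ny, nt):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"origin_shape {self.origin_shape}"
            )

    @property
    def rank(self) -> int:
        """Numerical rank (SVD, default tolerance)."""
        return int(np.linalg.matrix_rank(self.matrix))


@dataclass
class SamplingMask:
    """Binary k-t sampling indicator, indexed ``(kx, ky, t)``.

    ``scheme`` is one of ``cartesian``, ``radial``, ``full``, ``custom``;
    ``params`` keeps the generator inputs (acceleration / spoke count /
    seed) so masks are reproducible.
    """

    indicator: np.ndarray
    scheme: str = "custom"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator)
        if self.indicator.ndim != 3:
            raise ValueError("mask indicator must be (kx, ky, t)")
        uniq = np.unique(self.indicator)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask indicator entries must be 0 or 1")
        self.indicator = self.indicator.astype(np.uint8)
        if self.scheme not in ("cartesian", "radial", "full", "custom"):
            raise ValueError(f"unknown mask scheme {self.scheme!r}")
        if self.scheme == "full" and not np.all(self.indicator == 1):
            raise ValueError("scheme='full' requires an all-ones indicator")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape  # type: ignore[return-value]

    @property
    def sampling_ratio(self) -> float:
        """Fraction of k-t samples acquired, in (0, 1]."""
        return float(self.indicator.sum()) / self.indicator.size

    def boolean(self) -> np.ndarray:
        return self.indicator.astype(bool)

    @classmethod
    def full(cls, nx: int, ny: int, nt: int) -> "SamplingMask":
        return cls(np.ones((nx, ny, nt), dtype=np.uint8), scheme="full")


@dataclass
class KTData:
    """Undersampled complex k-t measurements with their mask.

    ``samples`` is exactly zero wherever the mask indicator is zero —
    the container stores zero-filled k-space, which is what the adjoint
    (zero-filled reconstruction) operates on directly.
    """

    samples: np.ndarray
    mask: SamplingMask
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.shape != self.mask.shape:
            raise ValueError(
                f"samples shape {self.samples.shape} != mask shape {self.mask.shape}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        unsampled = self.mask.indicator == 0
        if np.any(self.samples[unsampled] != 0):
            raise ValueError("samples must be exactly zero at unsampled locations")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.samples.shape  # type: ignore[return-value]


def to_casorati(seq: DynamicImageSequence) -> CasoratiMatrix:
    """Reshape an image sequence into its Casorati (space x time) matrix.

    Column ``t`` is frame ``t`` flattened in Fortran order (x fastest).
    The operation is a pure relabelling: bit-exact and lossless.
    """
    nx, ny, nt = seq.shape
    mat = np.reshape(seq.values, (nx * ny, nt), order="F")
    return CasoratiMatrix(matrix=mat, origin_shape=(nx, ny, nt))


def from_casorati(mat: CasoratiMatrix, pixel_scale: float = 255.0) -> DynamicImageSequence:
    """Inverse of :func:`to_casorati`; bit-exact."""
    nx, ny, nt = mat.origin_shape
    values = np.reshape(mat.matrix, (nx, ny, nt), order="F")
    return DynamicImageSequence(values=values, pixel_scale=pixel_scale)


def _mask_to_h5(grp: h5py.File, mask: SamplingMask) -> None:
    grp.create_dataset("mask", data=mask.indicator, dtype=np.uint8)
    grp.attrs["scheme"] = mask.scheme
    for key in ("acceleration", "n_spokes", "seed", "center_fraction"):
        if key in mask.params and mask.params[key] is not None:
            grp.attrs[key] = mask.params[key]


def _mask_from_h5(grp: h5py.File) -> SamplingMask:
    if "mask" not in grp:
        raise FormatError("container is missing required dataset '/mask'")
    if "scheme" not in grp.attrs:
        raise FormatError("container is missing required attribute 'scheme'")
    params = {
        key: grp.attrs[key]
        for key in ("acceleration", "n_spokes", "seed", "center_fraction")
        if key in grp.attrs
    }
    return SamplingMask(
        indicator=np.asarray(grp["mask"]),
        scheme=str(grp.attrs["scheme"]),
        params=params,
    )


def save_ktdata(data: KTData, path: str | Path) -> None:
    """Write k-t data to an HDF5 container (datasets ``/kspace``, ``/mask``)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=data.samples, dtype=np.complex128)
        _mask_to_h5(f, data.mask)
        f.attrs["noise_sigma"] = data.noise_sigma


def load_ktdata(path: str | Path) -> KTData:
    """Read k-t data written by :func:`save_ktdata`; round-trip is bit-exact."""
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise FormatError("container is missing required dataset '/kspace'")
        samples = np.asarray(f["kspace"], dtype=np.complex128)
        mask = _mask_from_h5(f)
        noise_sigma = float(f.attrs.get("noise_sigma", 0.0))
    return KTData(samples=samples, mask=mask, noise_sigma=noise_sigma)


def save_sequence_h5(seq: DynamicImageSequence, path: str | Path, name: str = "image") -> None:
    """Store a complex image sequence in HDF5 (dataset ``/<name>``)."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        f.create_dataset(name, data=seq.values, dtype=np.complex128)
        f[name].attrs["pixel_scale"] = seq.pixel_scale


def load_sequence_h5(path: str | Path, name: str = "image") -> DynamicImageSequence:
    with h5py.File(path, "r") as f:
        if name not in f:
            raise FormatError(f"container is missing required dataset '/{name}'")
        values = np.asarray(f[name], dtype=np.complex128)
        pixel_scale = float(f[name].attrs.get("pixel_scale", 255.0))
    return DynamicImageSequence(values=values, pixel_scale=pixel_scale)


def save_sequence_nifti(seq: DynamicImageSequence, path: str | Path) -> None:
    """Export the magnitude series as a NIfTI-1 volume (x, y, t)."""
    import nibabel as nib

    img = nib.Nifti1Image(seq.magnitude().astype(np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def load_sequence_nifti(path: str | Path, pixel_scale: float = 255.0) -> DynamicImageSequence:
    """Load a magnitude series from NIfTI-1 (real-valued, zero phase)."""
    import nibabel as nib

    data = np.asarray(nib.load(str(path)).get_fdata())
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"expected a 2D+time NIfTI volume, got ndim={data.ndim}")
    return DynamicImageSequence(values=data.astype(np.complex128), pixel_scale=pixel_scale)


def save_frame_png(seq: DynamicImageSequence, t: int, path: str | Path) -> None:
    """Export one magnitude frame as an 8-bit PNG (scaled to the frame max)."""
    import imageio.v3 as iio

    frame = np.abs(seq.frame(t))
    peak = frame.max()
    scaled = np.zeros_like(frame) if peak == 0 else frame / peak * 255.0
    iio.imwrite(str(path), scaled.astype(np.uint8))
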