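"""Casorati reshaping, container round-trips and type invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lps_dmri import (
    CasoratiMatrix,
    DynamicImageSequence,
    KTData,
    SamplingMask,
    from_casorati,
    load_ktdata,
    save_ktdata,
    to_casorati,
)
from lps_dmri.datamodel import (
    FormatError,
    load_sequence_nifti,
    save_frame_png,
    save_sequence_nifti,
)


class TestCasorati:
    def test_column_major_flattening(self):
        frame = np.array([[1.0, 2.0], [3.0, 4.0]])
        seq = DynamicImageSequence(values=frame[:, :, None])
        mat = to_casorati(seq)
        np.testing.assert_array_equal(mat.matrix[:, 0], [1, 3, 2, 4])
        assert mat.origin_shape == (2, 2, 1)

    def test_inverse_of_flattening_example(self):
        mat = CasoratiMatrix(np.array([[1.0], [3.0], [2.0], [4.0]]), (2, 2, 1))
        seq = from_casorati(mat)
        np.testing.assert_array_equal(seq.frame(0), [[1, 2], [3, 4]])

    @given(
        nx=st.integers(1, 6),
        ny=st.integers(1, 6),
        nt=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    def test_round_trip_bit_exact(self, nx, ny, nt, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(nx, ny, nt)) + 1j * rng.normal(size=(nx, ny, nt))
        seq = DynamicImageSequence(values=vals)
        back = from_casorati(to_casorati(seq))
        assert np.array_equal(back.values, seq.values)

    def test_identical_frames_give_rank_one(self, rng):
        frame = rng.normal(size=(5, 4))
        seq = DynamicImageSequence(values=np.repeat(frame[:, :, None], 6, axis=2))
        mat = to_casorati(seq)
        assert mat.rank == 1
        # scalar multiples of one frame stay rank 1, general bound holds
        assert mat.rank <= min(5 * 4, 6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CasoratiMatrix(np.zeros((4, 1)), origin_shape=(3, 3, 2))


class TestTypes:
    def test_sequence_rejects_nonfinite(self):
        vals = np.ones((2, 2, 2), dtype=complex)
        vals[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            DynamicImageSequence(values=vals)

    def test_mask_entries_binary(self):
        with pytest.raises(ValueError):
            SamplingMask(indicator=2 * np.ones((2, 2, 1)))

    def test_full_mask_ratio_is_one(self):
        assert SamplingMask.full(4, 4, 3).sampling_ratio == 1.0

    def test_ktdata_zero_off_mask(self):
        mask = SamplingMask(np.zeros((2, 2, 1), dtype=np.uint8))
        with pytest.raises(ValueError, match="zero"):
            KTData(samples=np.ones((2, 2, 1), dtype=complex), mask=mask)

    def test_ktdata_negative_sigma_rejected(self):
        mask = SamplingMask.full(2, 2, 1)
        with pytest.raises(ValueError):
            KTData(samples=np.ones((2, 2, 1), dtype=complex), mask=mask, noise_sigma=-1)


class TestContainers:
    def _random_ktdata(self, rng, nx=6, ny=6, nt=3):
        ind = (rng.uniform(size=(nx, ny, nt)) < 0.5).astype(np.uint8)
        ind[nx // 2, ny // 2, :] = 1
        samples = (rng.normal(size=ind.shape) + 1j * rng.normal(size=ind.shape)) * ind
        mask = SamplingMask(ind, scheme="custom", params={"seed": 3})
        return KTData(samples=samples, mask=mask, noise_sigma=1.5)

    def test_hdf5_round_trip_bit_exact(self, rng, tmp_path):
        data = self._random_ktdata(rng)
        path = tmp_path / "kt.h5"
        save_ktdata(data, path)
        loaded = load_ktdata(path)
        assert np.array_equal(loaded.samples, data.samples)
        assert np.array_equal(loaded.mask.indicator, data.mask.indicator)
        assert loaded.mask.scheme == data.mask.scheme
        assert loaded.noise_sigma == data.noise_sigma

    def test_dimensions_survive_round_trip(self, rng, tmp_path):
        data = self._random_ktdata(rng, nx=16, ny=16, nt=4)
        path = tmp_path / "kt.h5"
        save_ktdata(data, path)
        assert load_ktdata(path).shape == (16, 16, 4)

    def test_missing_mask_dataset_raises_format_error(self, rng, tmp_path):
        import h5py

        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace", data=np.zeros((2, 2, 1), dtype=complex))
        with pytest.raises(FormatError, match="mask"):
            load_ktdata(path)

    def test_missing_kspace_raises_format_error(self, tmp_path):
        import h5py

        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("mask", data=np.ones((2, 2, 1), dtype=np.uint8))
        with pytest.raises(FormatError, match="kspace"):
            load_ktdata(path)

    def test_nifti_and_png_export(self, random_sequence, tmp_path):
        nii = tmp_path / "series.nii.gz"
        save_sequence_nifti(random_sequence, nii)
        loaded = load_sequence_nifti(nii)
        np.testing.assert_allclose(
            loaded.magnitude(), random_sequence.magnitude(), rtol=1e-12
        )
        png = tmp_path / "frame.png"
        save_frame_png(random_sequence, 0, png)
        assert png.stat().st_size > 0
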