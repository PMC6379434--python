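"""Data model, imzML round-trips, ion images and mean spectra."""

import uuid

import numpy as np
import pytest

from msi3d.core import (
    CENTROID,
    PROFILE,
    GridMetadata,
    MassSpectrum,
    MsiDataset,
    MzInterval,
    PixelCoordinate,
    bin_spectrum,
    dataset_mean_spectrum,
    extract_ion_image,
    read_imzml,
    write_imzml,
)


class TestMassSpectrum:
    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValueError, match="increasing"):
            MassSpectrum([500.0, 499.0], [1.0, 1.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            MassSpectrum([500.0], [1.0, 2.0])

    def test_empty_spectrum_is_valid(self):
        s = MassSpectrum([], [])
        assert len(s) == 0 and s.tic == 0.0

    def test_negative_coordinates_rejected(self):
        with pytest.raises(ValueError):
            PixelCoordinate(-1, 0, 0)


class TestImzmlRoundTrip:
    def test_round_trip_identity_2x2(self, centroid_dataset, tmp_path):
        """Write then read reproduces the dataset within float32 intensity
        precision (m/z is stored at full 64-bit precision)."""
        path = write_imzml(centroid_dataset, tmp_path / "rt.imzML")
        back = read_imzml(path)
        assert len(back) == len(centroid_dataset)
        for coord, orig in centroid_dataset.spectra.items():
            got = back.spectra[coord]
            np.testing.assert_array_equal(got.mz, orig.mz)
            np.testing.assert_allclose(got.intensity, orig.intensity, rtol=1e-7)
            assert got.mode == CENTROID

    def test_empty_spectrum_round_trip(self, tiny_grid, tmp_path):
        ds = MsiDataset(
            spectra={
                PixelCoordinate(0, 0): MassSpectrum([500.0], [1.0]),
                PixelCoordinate(1, 0): MassSpectrum([], []),
            },
            grid=tiny_grid,
        )
        back = read_imzml(write_imzml(ds, tmp_path / "empty.imzML"))
        assert len(back.spectra[PixelCoordinate(1, 0)]) == 0

    def test_single_pixel(self, tiny_grid, tmp_path):
        ds = MsiDataset(
            spectra={PixelCoordinate(0, 0): MassSpectrum([500.0], [2.0])},
            grid=tiny_grid,
        )
        back = read_imzml(write_imzml(ds, tmp_path / "one.imzML"))
        assert len(back) == 1

    def test_mixed_modes_rejected(self, tiny_grid):
        with pytest.raises(ValueError, match="mixed"):
            MsiDataset(
                spectra={
                    PixelCoordinate(0, 0): MassSpectrum([500.0], [1.0], mode=CENTROID),
                    PixelCoordinate(1, 0): MassSpectrum([500.0], [1.0], mode=PROFILE),
                },
                grid=tiny_grid,
            )

    def test_profile_unequal_axes_rejected(self, tiny_grid, tmp_path):
        ds = MsiDataset(
            spectra={
                PixelCoordinate(0, 0): MassSpectrum([500.0, 501.0], [1.0, 1.0], mode=PROFILE),
                PixelCoordinate(1, 0): MassSpectrum([500.0, 502.0], [1.0, 1.0], mode=PROFILE),
            },
            grid=tiny_grid,
        )
        with pytest.raises(ValueError, match="m/z axis"):
            write_imzml(ds, tmp_path / "bad.imzML")

    def test_missing_ibd_fails(self, centroid_dataset, tmp_path):
        path = write_imzml(centroid_dataset, tmp_path / "x.imzML")
        path.with_suffix(".ibd").unlink()
        with pytest.raises(FileNotFoundError):
            read_imzml(path)

    def test_checksum_mismatch_warns_but_reads(self, centroid_dataset, tmp_path):
        path = write_imzml(centroid_dataset, tmp_path / "chk.imzML")
        ibd = path.with_suffix(".ibd")
        data = bytearray(ibd.read_bytes())
        data[-1] ^= 0xFF
        ibd.write_bytes(bytes(data))
        with pytest.warns(RuntimeWarning, match="checksum"):
            back = read_imzml(path)
        assert len(back) == len(centroid_dataset)

    def test_fixed_uuid_gives_identical_files(self, centroid_dataset, tmp_path):
        u = uuid.UUID(int=42)
        p1 = write_imzml(centroid_dataset, tmp_path / "a" / "s.imzML", file_uuid=u)
        p2 = write_imzml(centroid_dataset, tmp_path / "b" / "s.imzML", file_uuid=u)
        assert p1.with_suffix(".ibd").read_bytes() == p2.with_suffix(".ibd").read_bytes()
        # XML differs only in the embedded output directory
        x1 = p1.read_text().replace(str(p1.parent), "DIR")
        x2 = p2.read_text().replace(str(p2.parent), "DIR")
        assert x1 == x2

    def test_coordinates_are_zero_based_internally(self, centroid_dataset, tmp_path):
        path = write_imzml(centroid_dataset, tmp_path / "coords.imzML")
        back = read_imzml(path)
        assert set(back.spectra) == set(centroid_dataset.spectra)


class TestIonImage:
    def test_half_open_window_hand_example(self, tiny_grid):
        """Centroids at 885.50 and 885.90 against window [885.30, 885.80):
        only the first falls inside."""
        ds = MsiDataset(
            spectra={
                PixelCoordinate(0, 0): MassSpectrum([885.50, 885.90], [10.0, 5.0]),
                PixelCoordinate(1, 0): MassSpectrum([400.0], [1.0]),
            },
            grid=tiny_grid,
        )
        img = extract_ion_image(ds, MzInterval(885.55, 0.5))
        assert img.values[0, 0] == 10.0
        assert img.values[0, 1] == 0.0

    def test_empty_window_gives_zero_image(self, centroid_dataset):
        img = extract_ion_image(centroid_dataset, MzInterval(1500.0, 0.5))
        assert np.nansum(img.values) == 0.0

    def test_interval_outside_range_fails(self, centroid_dataset):
        with pytest.raises(ValueError, match="outside"):
            extract_ion_image(centroid_dataset, MzInterval(1600.2, 0.5))

    def test_missing_pixels_are_nan_not_zero(self, tiny_grid):
        ds = MsiDataset(
            spectra={PixelCoordinate(1, 1): MassSpectrum([500.0], [1.0])},
            grid=tiny_grid,
        )
        img = extract_ion_image(ds, MzInterval(500.0, 0.5))
        assert np.isnan(img.values[0, 0]) and img.values[1, 1] == 1.0

    def test_partition_sums_to_tic(self, centroid_dataset):
        """Summing ion images over a disjoint partition of the m/z range
        reproduces each pixel's TIC (additivity / conservation)."""
        edges = np.linspace(400.0, 1600.0, 25)
        parts = [
            MzInterval((a + b) / 2, b - a, lo=a, hi=b)
            for a, b in zip(edges[:-1], edges[1:])
        ]
        total = sum(
            np.nan_to_num(extract_ion_image(centroid_dataset, p).values)
            for p in parts
        )
        for c, s in centroid_dataset.spectra.items():
            assert total[c.y, c.x] == pytest.approx(s.tic)


class TestMeanSpectrum:
    BINS = [MzInterval(c, 1.0) for c in (500.0, 600.0, 700.0, 800.0, 885.75)]

    def test_single_pixel_returns_own_binned_spectrum(self, tiny_grid):
        ds = MsiDataset(
            spectra={PixelCoordinate(0, 0): MassSpectrum([500.0, 500.3], [1.0, 2.0])},
            grid=tiny_grid,
        )
        m = dataset_mean_spectrum(ds, [MzInterval(500.0, 1.0)])
        assert m.intensity[0] == pytest.approx(3.0)

    def test_two_pixel_mean(self, tiny_grid):
        ds = MsiDataset(
            spectra={
                PixelCoordinate(0, 0): MassSpectrum([500.0], [2.0]),
                PixelCoordinate(1, 0): MassSpectrum([500.1], [4.0]),
            },
            grid=tiny_grid,
        )
        m = dataset_mean_spectrum(ds, [MzInterval(500.0, 1.0)])
        assert m.intensity[0] == pytest.approx(3.0)

    def test_matches_bruteforce_oracle(self, centroid_dataset):
        """Mean spectrum equals an explicit loop over pixels and bins."""
        got = dataset_mean_spectrum(centroid_dataset, self.BINS)
        specs = list(centroid_dataset.spectra.values())
        for j, b in enumerate(self.BINS):
            acc = 0.0
            for s in specs:
                acc += sum(
                    i for m, i in zip(s.mz, s.intensity) if b.lo <= m < b.hi
                )
            assert got.intensity[j] == pytest.approx(acc / len(specs))

    def test_empty_dataset_fails(self, tiny_grid):
        with pytest.raises(ValueError, match="empty"):
            dataset_mean_spectrum(MsiDataset(spectra={}, grid=tiny_grid), self.BINS)

    def test_overlapping_bins_rejected(self, centroid_dataset):
        with pytest.raises(ValueError, match="overlap"):
            dataset_mean_spectrum(
                centroid_dataset, [MzInterval(500.0, 1.0), MzInterval(500.5, 1.0)]
            )


def test_grid_metadata_validation():
    with pytest.raises(ValueError):
        GridMetadata(pixel_pitch_xy=0.0)
    with pytest.raises(ValueError):
        GridMetadata(section_thickness=200.0, section_spacing_z=150.0)
    with pytest.raises(ValueError):
        GridMetadata(mz_range=(1600.0, 400.0))
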