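"""Core data model for mass spectrometry imaging (MSI) data.

An MSI experiment records one mass spectrum per pixel of a regular 2D grid;
serial tissue sections stack those grids into a (sparse, anisotropic) 3D
volume.  This module defines the in-memory containers — :class:`MassSpectrum`,
:class:`MsiDataset`, :class:`IonImage` — together with imzML 1.1 reading and
writing (via :mod:`pyimzml`), extracted-ion-image computation, and dataset
mean spectra.

Conventions
-----------
* Internal pixel coordinates are 0-based with ``x`` = column, ``y`` = row and
  ``z`` = section index; imzML serialization is 1-based per the format.
* m/z interval windows are half-open ``[lo, hi)`` so that a partition of the
  axis double-counts nothing.
* Pixels absent from a dataset (outside the tissue outline) are *missing*:
  they are not stored, and ion images render them as NaN — distinct from a
  measured intensity of zero.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

PROFILE = "profile"
CENTROID = "centroid"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MassSpectrum:
    """One pixel's spectrum: paired m/z (Da, strictly ascending) and
    non-negative intensity arrays, in either ``profile`` or ``centroid`` mode.
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = CENTROID

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1D arrays of equal length")
        if self.mode not in (PROFILE, CENTROID):
            raise ValueError(f"unknown spectrum mode {self.mode!r}")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        if not np.isfinite(self.tic):
            raise ValueError("total ion count must be finite")

    @property
    def tic(self) -> float:
        """Total ion count (sum of intensities)."""
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return self.mz.size

    def __eq__(self, other: object) -> bool:  # value semantics, used in tests
        if not isinstance(other, MassSpectrum):
            return NotImplemented
        return (
            self.mode == other.mode
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )


@dataclass(frozen=True)
class PixelCoordinate:
    """0-based grid position: x = column, y = row, z = section index."""

    x: int
    y: int
    z: int = 0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.z < 0:
            raise ValueError("pixel coordinates must be non-negative")


@dataclass(frozen=True)
class GridMetadata:
    """Acquisition geometry.

    Defaults follow a typical fast MALDI-ToF imaging protocol: 50 µm pixel
    pitch, 10 µm section thickness with sections retained every 150 µm, and
    an m/z 400–1600 acquisition window.
    """

    pixel_pitch_xy: float = 50.0
    section_thickness: float = 10.0
    section_spacing_z: float = 150.0
    mz_range: Tuple[float, float] = (400.0, 1600.0)

    def __post_init__(self) -> None:
        if self.pixel_pitch_xy <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.section_spacing_z < self.section_thickness:
            raise ValueError("section spacing must be >= section thickness")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must satisfy low < high")


@dataclass(frozen=True)
class MzInterval:
    """Half-open m/z window ``[lo, hi)``.

    By default the window is symmetric, ``center ± width/2``; explicit
    ``lo``/``hi`` bounds may be given for asymmetric windows (adjacent peaks
    closer than the minimum width share the midpoint boundary).
    """

    center: float
    width: float
    lo: float = field(default=None)  # type: ignore[assignment]
    hi: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("interval width must be non-negative")
        if self.lo is None:
            object.__setattr__(self, "lo", self.center - self.width / 2.0)
        if self.hi is None:
            object.__setattr__(self, "hi", self.center + self.width / 2.0)
        if not (self.lo <= self.center < self.hi or self.lo == self.hi == self.center):
            raise ValueError("interval must contain its center in [lo, hi)")

    def contains(self, mz: np.ndarray) -> np.ndarray:
        mz = np.asarray(mz)
        return (mz >= self.lo) & (mz < self.hi)


@dataclass
class MsiDataset:
    """Spectra of one section on a regular grid, plus grid metadata.

    All spectra share one mode; coordinates are unique by construction
    (dict keys).  ``group_label`` carries the biological contrast
    (``metastasizing`` / ``non_metastasizing``) when known.
    """

    spectra: Dict[PixelCoordinate, MassSpectrum]
    grid: GridMetadata = field(default_factory=GridMetadata)
    section_id: str = "section0"
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        modes = {s.mode for s in self.spectra.values() if len(s) > 0}
        if len(modes) > 1:
            raise ValueError(f"mixed spectrum modes in dataset: {modes}")

    @property
    def mode(self) -> str:
        for s in self.spectra.values():
            if len(s) > 0:
                return s.mode
        return CENTROID

    @property
    def shape(self) -> Tuple[int, int]:
        """Bounding grid shape (n_rows, n_cols) = (max_y+1, max_x+1)."""
        if not self.spectra:
            return (0, 0)
        ys = max(c.y for c in self.spectra) + 1
        xs = max(c.x for c in self.spectra) + 1
        return (ys, xs)

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class IonImage:
    """Per-pixel summed intensity inside one m/z interval.

    ``values`` is a (rows, cols) float array over the section's bounding
    grid; missing pixels hold NaN (distinct from a measured 0).
    """

    values: np.ndarray
    interval: Optional[MzInterval] = None
    section_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ion image must be 2D")

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


# ---------------------------------------------------------------------------
# binning helpers
# ---------------------------------------------------------------------------

def bin_spectrum(s: MassSpectrum, bins: Sequence[MzInterval]) -> np.ndarray:
    """Summed intensity of ``s`` inside each half-open interval."""
    if len(s) == 0:
        return np.zeros(len(bins))
    edges_lo = np.array([b.lo for b in bins])
    edges_hi = np.array([b.hi for b in bins])
    # spectra m/z are sorted: use searchsorted per interval
    lo_idx = np.searchsorted(s.mz, edges_lo, side="left")
    hi_idx = np.searchsorted(s.mz, edges_hi, side="left")
    csum = np.concatenate([[0.0], np.cumsum(s.intensity)])
    return csum[hi_idx] - csum[lo_idx]


def extract_ion_image(dataset: MsiDataset, interval: MzInterval) -> IonImage:
    """Extracted-ion image: per pixel, sum of intensities with m/z in
    ``[lo, hi)``.  Pixels with spectra but no signal in the window get 0;
    pixels absent from the dataset get NaN.
    """
    lo_ok = interval.lo >= dataset.grid.mz_range[0]
    hi_ok = interval.hi <= dataset.grid.mz_range[1]
    if not (lo_ok and hi_ok):
        raise ValueError(
            f"interval [{interval.lo}, {interval.hi}) outside dataset m/z range "
            f"{dataset.grid.mz_range}"
        )
    ny, nx = dataset.shape
    values = np.full((ny, nx), np.nan)
    for coord, spec in dataset.spectra.items():
        values[coord.y, coord.x] = float(bin_spectrum(spec, [interval])[0])
    return IonImage(values=values, interval=interval, section_id=dataset.section_id)


def dataset_mean_spectrum(
    dataset_or_datasets, bins: Sequence[MzInterval]
) -> MassSpectrum:
    """Mean binned spectrum: one centroid per interval at the bin center,
    intensity = mean over all pixels of the within-bin summed intensity.
    """
    datasets = (
        [dataset_or_datasets]
        if isinstance(dataset_or_datasets, MsiDataset)
        else list(dataset_or_datasets)
    )
    _check_disjoint(bins)
    n = 0
    acc = np.zeros(len(bins))
    for ds in datasets:
        for spec in ds.spectra.values():
            acc += bin_spectrum(spec, bins)
            n += 1
    if n == 0:
        raise ValueError("cannot take the mean spectrum of an empty dataset")
    centers = np.array([b.center for b in bins])
    order = np.argsort(centers)
    return MassSpectrum(centers[order], (acc / n)[order], mode=CENTROID)


def _check_disjoint(bins: Sequence[MzInterval]) -> None:
    ivs = sorted(bins, key=lambda b: b.lo)
    for a, b in zip(ivs, ivs[1:]):
        if b.lo < a.hi:
            raise ValueError(f"overlapping intervals at {a.hi:.4f}/{b.lo:.4f}")


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def write_imzml(dataset: MsiDataset, path, file_uuid=None) -> Path:
    """Write an imzML/ibd pair.

    m/z values are stored as 64-bit floats and intensities as 32-bit floats.
    Centroid data is written in *processed* mode (per-pixel m/z axes);
    profile data in *continuous* mode, which requires every spectrum to share
    one m/z axis.

    ``file_uuid`` (a :class:`uuid.UUID`) overrides the randomly generated
    file identifier so that repeated writes of the same dataset are
    byte-identical; the ibd header and the recorded SHA-1 are patched
    consistently.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if not dataset.spectra:
        raise ValueError("refusing to write an empty dataset")
    mode = dataset.mode
    if mode == PROFILE:
        axes = [s.mz for s in dataset.spectra.values() if len(s)]
        for ax in axes[1:]:
            if ax.shape != axes[0].shape or not np.array_equal(ax, axes[0]):
                raise ValueError(
                    "profile spectra must share one m/z axis for continuous imzML"
                )
        imzml_mode = "continuous"
    else:
        imzml_mode = "processed"

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with ImzMLWriter(
        str(path),
        mode=imzml_mode,
        spec_type=mode,
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
        polarity="negative",
    ) as w:
        for coord in sorted(dataset.spectra, key=lambda c: (c.z, c.y, c.x)):
            s = dataset.spectra[coord]
            # imzML coordinates are 1-based
            coords_1b = (coord.x + 1, coord.y + 1, coord.z + 1)
            if len(s) > 0:
                w.addSpectrum(s.mz, s.intensity, coords_1b)
            else:
                _add_empty_spectrum(w, coords_1b)
        written_uuid = w.uuid
    if file_uuid is not None:
        _patch_file_uuid(path, written_uuid, file_uuid)
    return path


def _add_empty_spectrum(writer, coords) -> None:
    """Record a zero-length spectrum (a pixel with no detected signal).

    pyimzml's ``addSpectrum`` computes min/max over the arrays and cannot
    take empty input, so the bookkeeping entry is appended directly with
    zero lengths and zeroed summary statistics.
    """
    from pyimzml.ImzMLWriter import _Spectrum

    empty = np.array([], dtype=float)
    mz_offset, mz_len, mz_enc_len = writer._encode_and_write(
        empty, writer.mz_dtype, writer.mz_compression
    )
    int_offset, int_len, int_enc_len = writer._encode_and_write(
        empty, writer.intensity_dtype, writer.intensity_compression
    )
    writer.spectra.append(
        _Spectrum(
            coords, mz_len, mz_offset, mz_enc_len,
            int_len, int_offset, int_enc_len,
            0.0, 0.0, 0.0, 0.0, 0.0, [],
        )
    )


def _patch_file_uuid(path: Path, old_uuid, new_uuid) -> None:
    """Replace the file UUID (ibd header + imzML cvParam) and refresh the
    recorded ibd SHA-1."""
    import hashlib

    ibd = path.with_suffix(".ibd")
    data = bytearray(ibd.read_bytes())
    if data[:16] != old_uuid.bytes:  # pragma: no cover - format drift guard
        raise RuntimeError("unexpected ibd header; cannot patch UUID")
    data[:16] = new_uuid.bytes
    ibd.write_bytes(bytes(data))
    new_sha = hashlib.sha1(bytes(data)).hexdigest().upper()
    xml = path.read_text()
    old_tag = ("{%s}" % old_uuid).upper()
    new_tag = ("{%s}" % new_uuid).upper()
    xml = xml.replace(old_tag, new_tag)
    xml = re.sub(
        r'(accession="IMS:1000091"[^/]*value=")[0-9A-Fa-f]+(")',
        r"\g<1>" + new_sha + r"\g<2>",
        xml,
    )
    path.write_text(xml)


def read_imzml(path, grid: Optional[GridMetadata] = None) -> MsiDataset:
    """Read an imzML/ibd pair into an :class:`MsiDataset`.

    The spectrum mode is inferred from the file's declared spectrum type;
    1-based imzML coordinates are converted to the 0-based internal
    convention.  A missing ibd file is an error; an ibd SHA-1 that does not
    match the declared checksum produces a warning but parsing proceeds.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"missing ibd file for {path}: {ibd}")
    parser = ImzMLParser(str(path))
    mode = CENTROID
    try:
        names = {p[0] for p in parser.metadata.file_description.cv_params}
        if "profile spectrum" in names:
            mode = PROFILE
        _verify_ibd_checksum(parser, ibd)
    except AttributeError:  # pragma: no cover - metadata layout variations
        pass

    spectra: Dict[PixelCoordinate, MassSpectrum] = {}
    for i, (x, y, z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        spectra[PixelCoordinate(x - 1, y - 1, z - 1)] = MassSpectrum(
            np.asarray(mz, dtype=float), np.asarray(inten, dtype=float), mode=mode
        )
    if hasattr(parser, "m"):  # close mmap handle
        try:
            parser.m.close()
        except Exception:  # pragma: no cover
            pass
    return MsiDataset(spectra=spectra, grid=grid or GridMetadata(), section_id=path.stem)


def _verify_ibd_checksum(parser, ibd: Path) -> None:
    """Warn (do not fail) when the ibd SHA-1 differs from the declared one."""
    import hashlib

    declared = None
    for p in parser.metadata.file_description.cv_params:
        if p[1] == "IMS:1000091":
            declared = str(p[2]).strip().lower()
    if not declared:
        return
    actual = hashlib.sha1(ibd.read_bytes()).hexdigest().lower()
    if actual != declared:
        warnings.warn(
            f"ibd checksum mismatch for {ibd.name}: declared {declared}, "
            f"computed {actual}; proceeding",
            RuntimeWarning,
        )


# ---------------------------------------------------------------------------
# image export
# ---------------------------------------------------------------------------

def save_ion_image_png(img: IonImage, path, cmap: str = "viridis") -> Path:
    """Write an 8-bit PNG of an ion image plus a sidecar text file recording
    the value→color scaling (min/max mapped to 0..255; NaN pixels black).
    """
    import imageio.v3 as iio
    from matplotlib import colormaps

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = img.values
    finite = np.isfinite(vals)
    vmin = float(np.nanmin(vals)) if finite.any() else 0.0
    vmax = float(np.nanmax(vals)) if finite.any() else 1.0
    span = (vmax - vmin) or 1.0
    norm = np.clip((vals - vmin) / span, 0.0, 1.0)
    rgba = colormaps[cmap](norm)
    rgba[~finite] = (0.0, 0.0, 0.0, 1.0)
    iio.imwrite(path, (rgba[..., :3] * 255).astype(np.uint8))
    sidecar = path.with_suffix(path.suffix + ".scale.txt")
    center = img.interval.center if img.interval else float("nan")
    sidecar.write_text(
        f"section_id\t{img.section_id}\n"
        f"interval_center_da\t{center}\n"
        f"value_at_color_0\t{vmin}\n"
        f"value_at_color_255\t{vmax}\n"
        f"colormap\t{cmap}\n"
        f"missing_pixels\tblack\n"
    )
    return path
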