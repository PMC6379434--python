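"""Spectral preprocessing: baseline removal, TIC normalization, peak picking,
m/z interval construction, and hotspot clipping for display.

The preprocessing chain mirrors common MSI practice: profile spectra are
baseline-corrected by an iterative smoothing-and-minimum envelope, every
spectrum is scaled to a common total ion count (TIC), peaks are picked on a
mean spectrum, and each peak center receives an m/z interval of at least
500 mDa (to absorb run-to-run peak shifts) for all downstream binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np
from scipy import ndimage

from .core import CENTROID, PROFILE, IonImage, MassSpectrum, MzInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables for the per-spectrum and dataset-level preprocessing.

    baseline_kernel_width : Da
        Moving-average kernel of the baseline envelope iteration.
    baseline_iterations : int
        Rounds of {smooth, elementwise-minimum}.
    tic_target : float
        Common TIC after normalization; any positive constant is equivalent
        for cross-sample comparison, 1.0 yields relative abundances.
    peak_snr : float
        Detection threshold in units of the local noise level.
    min_interval_width : Da
        Minimum (and nominal) per-peak interval width, default 500 mDa.
    noise_window : Da
        Sliding window for the MAD-based noise estimate.
    """

    baseline_kernel_width: float = 5.0
    baseline_iterations: int = 20
    tic_target: float = 1.0
    peak_snr: float = 3.0
    min_interval_width: float = 0.5
    noise_window: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_kernel_width",
            "baseline_iterations",
            "tic_target",
            "peak_snr",
            "min_interval_width",
            "noise_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ClipQuantiles:
    """Display clipping bounds: values outside the [low, high] quantiles are
    set to the quantile values (default 0% / 99%, i.e. hotspot removal only).
    """

    low: float = 0.0
    high: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 1.0):
            raise ValueError("require 0 <= low < high <= 1")


# ---------------------------------------------------------------------------
# per-spectrum operations
# ---------------------------------------------------------------------------

def _moving_average(y: np.ndarray, size: int) -> np.ndarray:
    """Boxcar smoothing with reflected edges (constants are fixed points)."""
    size = max(1, int(size))
    return ndimage.uniform_filter1d(y, size=size, mode="reflect")


def _kernel_points(width_da: float, mz: np.ndarray) -> int:
    dx = float(np.median(np.diff(mz)))
    k = int(round(width_da / dx))
    return max(3, k | 1)  # odd, >= 3


def remove_baseline(s: MassSpectrum, cfg: PreprocessConfig) -> MassSpectrum:
    """Subtract a baseline envelope estimated by iterative convolution.

    The estimate starts at the spectrum itself and is refined by repeating
    {convolve with a moving-average kernel of ``baseline_kernel_width``;
    take the elementwise minimum with the previous estimate}.  A constant
    offset is a fixed point of this iteration and is removed exactly (up to
    edge effects); peaks narrower than the kernel are eroded away so the
    envelope slides under them.  Output = max(spectrum - envelope, 0).
    """
    if s.mode != PROFILE:
        raise ValueError("baseline removal is defined for profile spectra only")
    if len(s) == 0:
        return s
    steps = np.diff(s.mz)
    if steps.size and (steps.max() - steps.min()) > 1e-6 * steps.mean():
        raise ValueError("baseline removal requires a uniformly sampled m/z axis")
    k = _kernel_points(cfg.baseline_kernel_width, s.mz)
    baseline = s.intensity.astype(float).copy()
    for _ in range(cfg.baseline_iterations):
        baseline = np.minimum(_moving_average(baseline, k), baseline)
    corrected = np.clip(s.intensity - baseline, 0.0, None)
    return MassSpectrum(s.mz.copy(), corrected, mode=PROFILE)


def tic_normalize(s: MassSpectrum, target: float = 1.0) -> MassSpectrum:
    """Scale intensities so their sum equals ``target`` (m/z unchanged).

    An all-zero spectrum cannot be normalized; it is returned unchanged and
    the event is logged.
    """
    tic = s.tic
    if tic <= 0:
        logger.warning("tic_normalize: zero-TIC spectrum left unchanged")
        return MassSpectrum(s.mz.copy(), s.intensity.copy(), mode=s.mode)
    return MassSpectrum(s.mz.copy(), s.intensity * (target / tic), mode=s.mode)


# ---------------------------------------------------------------------------
# peak picking and intervals
# ---------------------------------------------------------------------------

def _sliding_mad_noise(detail: np.ndarray, window_pts: int) -> np.ndarray:
    """1.4826 x sliding median absolute deviation of the detail residual."""
    window_pts = max(3, int(window_pts) | 1)
    med = ndimage.median_filter(detail, size=window_pts, mode="reflect")
    mad = ndimage.median_filter(np.abs(detail - med), size=window_pts, mode="reflect")
    return 1.4826 * mad


def pick_peaks(mean: MassSpectrum, cfg: PreprocessConfig) -> List[float]:
    """Detect peak centers on a profile-mode (mean) spectrum.

    Noise is estimated as 1.4826 x the sliding-window MAD of the detail
    residual (spectrum minus its moving average, window ``noise_window``).
    Candidate peaks are local maxima of a lightly smoothed trace (short
    boxcar, ~0.05 Da) whose height exceeds ``peak_snr`` x noise; the short
    smoothing suppresses single-sample noise exceedances while leaving
    resolved peaks intact.  Centers are refined by 3-point parabolic
    interpolation and returned sorted ascending.
    """
    if mean.mode != PROFILE:
        raise ValueError("peak picking expects a profile-mode spectrum")
    y = mean.intensity.astype(float)
    if len(mean) < 3 or not np.any(y > 0):
        return []
    mz = mean.mz
    dx = float(np.median(np.diff(mz)))
    noise_pts = max(3, int(round(cfg.noise_window / dx)))
    detail = y - _moving_average(y, noise_pts)
    noise = _sliding_mad_noise(detail, noise_pts)
    noise = np.maximum(noise, 1e-12 * max(y.max(), 1.0))

    det_pts = max(3, int(round(0.05 / dx)) | 1)
    yd = _moving_average(y, det_pts)
    is_max = np.zeros_like(yd, dtype=bool)
    is_max[1:-1] = (yd[1:-1] > yd[:-2]) & (yd[1:-1] >= yd[2:])
    candidates = np.flatnonzero(is_max & (yd > cfg.peak_snr * noise))

    centers: List[float] = []
    for i in candidates:
        if 0 < i < len(yd) - 1:
            a, b, c = yd[i - 1], yd[i], yd[i + 1]
            denom = a - 2 * b + c
            shift = 0.0 if denom == 0 else 0.5 * (a - c) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
        else:  # pragma: no cover - boundary candidates excluded above
            shift = 0.0
        centers.append(float(mz[i] + shift * dx))
    return sorted(centers)


def build_intervals(
    centers: Sequence[float], cfg: PreprocessConfig
) -> List[MzInterval]:
    """One half-open interval per peak center, nominal width
    ``min_interval_width``; where adjacent centers are closer than that, the
    facing boundary moves to the midpoint so intervals never overlap.
    """
    centers = [float(c) for c in centers]
    if sorted(centers) != centers:
        raise ValueError("peak centers must be sorted ascending")
    if len(set(centers)) != len(centers):
        raise ValueError("duplicate peak centers")
    w2 = cfg.min_interval_width / 2.0
    out: List[MzInterval] = []
    for i, c in enumerate(centers):
        lo = c - w2
        hi = c + w2
        if i > 0:
            lo = max(lo, (centers[i - 1] + c) / 2.0)
        if i < len(centers) - 1:
            hi = min(hi, (c + centers[i + 1]) / 2.0)
        out.append(MzInterval(center=c, width=cfg.min_interval_width, lo=lo, hi=hi))
    return out


# ---------------------------------------------------------------------------
# display clipping
# ---------------------------------------------------------------------------

def hotspot_clip(img: IonImage, q: ClipQuantiles = ClipQuantiles()) -> IonImage:
    """Clip image values to the [low, high] quantiles of the finite pixels
    (linear-interpolation quantile convention).  Used to keep rare hotspot
    pixels from dominating the display color scale.
    """
    vals = img.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("hotspot_clip needs at least one finite pixel")
    lo = float(np.quantile(vals[finite], q.low))
    hi = float(np.quantile(vals[finite], q.high))
    clipped = vals.copy()
    clipped[finite] = np.clip(vals[finite], lo, hi)
    return IonImage(values=clipped, interval=img.interval, section_id=img.section_id)
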