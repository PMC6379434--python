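"""ROC/AUC screening of m/z intervals between two labeled spectrum
populations, with Mann-Whitney U testing.

The AUC used here is the rank-sum (Mann-Whitney) AUC: the probability that
a random intensity from sample A exceeds one from sample B, ties counted
half.  Orientation is fixed throughout: **sample A is the non-metastasizing
group**, so AUC > 0.5 means higher intensity in non-metastasizing tissue and
an interval with AUC >= ``auc_high`` (default 0.6) is called *decreased in
the metastasizing group*; AUC <= ``auc_low`` (default 0.4) is called
*increased*.  Threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import MassSpectrum, MzInterval, bin_spectrum

DECREASED = "decreased_in_metastasizing"
INCREASED = "increased_in_metastasizing"
NONE = "none"


@dataclass(frozen=True)
class ScreenConfig:
    auc_high: float = 0.6
    auc_low: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 < self.auc_low < self.auc_high < 1.0):
            raise ValueError("require 0 < auc_low < auc_high < 1")


@dataclass
class RocResult:
    interval: MzInterval
    auc: float
    u_statistic: float
    p_value: float
    direction: str
    n_a: int
    n_b: int


def roc_auc(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-based AUC: [#(a>b pairs) + 0.5 #(ties)] / (n_a * n_b).

    Computed from the rank sum in O(n log n).  Sample ``a`` is the
    non-metastasizing group by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("roc_auc requires two non-empty samples")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u_a / (a.size * b.size))


def mann_whitney(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Mann-Whitney U for sample A and a two-sided p-value from the normal
    approximation with tie correction and continuity correction.

    When every value across both samples is tied the statistic carries no
    information and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    u_a = roc_auc(a, b) * n_a * n_b
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:  # all values identical
        return float(u_a), 1.0
    mu = n_a * n_b / 2.0
    z = (abs(u_a - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return float(u_a), p


def _direction(auc: float, cfg: ScreenConfig) -> str:
    if auc >= cfg.auc_high:
        return DECREASED
    if auc <= cfg.auc_low:
        return INCREASED
    return NONE


def _as_matrix(spectra, intervals: Sequence[MzInterval]) -> np.ndarray:
    """Accept an (n_pixels, n_intervals) array or a list of MassSpectrum."""
    if isinstance(spectra, np.ndarray):
        mat = np.asarray(spectra, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(intervals):
            raise ValueError("intensity matrix shape does not match intervals")
        return mat
    rows = [bin_spectrum(s, intervals) for s in spectra]
    if not rows:
        return np.empty((0, len(intervals)))
    return np.vstack(rows)


def screen_markers(
    pixels_a,
    pixels_b,
    intervals: Sequence[MzInterval],
    cfg: ScreenConfig = ScreenConfig(),
) -> List[RocResult]:
    """Screen every interval for group discrimination.

    ``pixels_a`` / ``pixels_b`` are the pooled TIC-normalized tumor-region
    spectra of the non-metastasizing and metastasizing groups (lists of
    :class:`MassSpectrum`, or precomputed (n_pixels, n_intervals) matrices).
    Returns one :class:`RocResult` per interval, sorted by |AUC - 0.5|
    descending (strongest discrimination first).
    """
    mat_a = _as_matrix(pixels_a, intervals)
    mat_b = _as_matrix(pixels_b, intervals)
    if mat_a.shape[0] == 0 or mat_b.shape[0] == 0:
        raise ValueError("both groups need at least one tumor spectrum")
    results: List[RocResult] = []
    for j, interval in enumerate(intervals):
        a, b = mat_a[:, j], mat_b[:, j]
        auc = roc_auc(a, b)
        u, p = mann_whitney(a, b)
        results.append(
            RocResult(
                interval=interval,
                auc=auc,
                u_statistic=u,
                p_value=p,
                direction=_direction(auc, cfg),
                n_a=a.size,
                n_b=b.size,
            )
        )
    results.sort(key=lambda r: abs(r.auc - 0.5), reverse=True)
    return results


def markers_only(results: Sequence[RocResult]) -> List[RocResult]:
    """The subset of screen results crossing either AUC threshold."""
    return [r for r in results if r.direction != NONE]


def marker_table(results: Sequence[RocResult], bh_flag: bool = False):
    """Screen results as a DataFrame (TSV-ready).  With ``bh_flag`` an extra
    Benjamini-Hochberg 5%-FDR column is added for the Mann-Whitney p-values
    (informational; the AUC rule itself applies no multiplicity correction).
    """
    import pandas as pd

    df = pd.DataFrame(
        {
            "interval_center": [r.interval.center for r in results],
            "auc": [r.auc for r in results],
            "u": [r.u_statistic for r in results],
            "p": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "n_A": [r.n_a for r in results],
            "n_B": [r.n_b for r in results],
        }
    )
    if bh_flag and len(df):
        p = df["p"].to_numpy()
        m = p.size
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        # step-up: reject all hypotheses up to the largest k with p_(k) <= k/m * q
        passed = np.minimum.accumulate(ranked[::-1])[::-1] <= 0.05
        flags = np.zeros(m, dtype=bool)
        flags[order] = passed
        df["bh_significant_5fdr"] = flags
    return df
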