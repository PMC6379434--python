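"""Spatial segmentation: ion-image denoising, pixel-feature construction,
bisecting k-means clustering into a binary region tree, region labeling
against reference masks, and per-region mean spectra.

Bisecting k-means recursively applies 2-means, each round splitting the leaf
with the largest within-cluster scatter, and yields a binary hierarchy of
nested subregions — each defined by its mean interval profile.  The distance
between pixel profiles is 1 - Pearson correlation (scale-robust, the usual
choice for MSI spectra); this is realized by embedding each row as its
z-scored, L2-normalized profile, in which squared Euclidean distance equals
2 x (1 - correlation), so standard Lloyd iterations apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import (
    CENTROID,
    IonImage,
    MassSpectrum,
    MsiDataset,
    MzInterval,
    PixelCoordinate,
    bin_spectrum,
    extract_ion_image,
)

GREY = "grey_matter"
WHITE = "white_matter"
TUMOR = "tumor"
BACKGROUND = "background"
REGION_LABELS = (GREY, WHITE, TUMOR, BACKGROUND)


# ---------------------------------------------------------------------------
# image denoising
# ---------------------------------------------------------------------------

def denoise_image(img: IonImage, radius: int = 1) -> IonImage:
    """Median filter over the (2r+1)^2 neighborhood, restricted to finite
    pixels.  Edge-preserving: an ideal step edge is unchanged, an isolated
    hotspot is replaced by its neighborhood value.  Missing (NaN) pixels
    stay missing and do not contribute to their neighbors' medians.
    ``radius=0`` returns the image unchanged.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return IonImage(img.values.copy(), img.interval, img.section_id)
    v = img.values
    ny, nx = v.shape
    padded = np.full((ny + 2 * radius, nx + 2 * radius), np.nan)
    padded[radius : radius + ny, radius : radius + nx] = v
    # stack all (2r+1)^2 shifted views and take the NaN-aware median
    stack = np.stack(
        [
            padded[dy : dy + ny, dx : dx + nx]
            for dy in range(2 * radius + 1)
            for dx in range(2 * radius + 1)
        ]
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighborhoods
        out = np.nanmedian(stack, axis=0)
    out[~np.isfinite(v)] = np.nan
    return IonImage(out, img.interval, img.section_id)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Pixels x intervals matrix of denoised, TIC-normalized intensities.

    Row order is stable: ``pixels[i]`` is the (dataset_index, coordinate)
    behind row ``i`` of ``values``.
    """

    values: np.ndarray
    pixels: List[Tuple[int, PixelCoordinate]]
    intervals: List[MzInterval]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pixels), len(self.intervals)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite")


def build_features(
    datasets: Sequence[MsiDataset],
    intervals: Sequence[MzInterval],
    radius: int = 1,
) -> FeatureMatrix:
    """Per interval: extract the ion image of each section, median-denoise
    it, then gather per-pixel values into rows.  Expects preprocessed
    (baseline-removed, TIC-normalized) datasets; ``radius=0`` bypasses
    denoising so rows equal the raw binned values.
    """
    if not intervals:
        raise ValueError("interval list must not be empty")
    pixels: List[Tuple[int, PixelCoordinate]] = []
    blocks: List[np.ndarray] = []
    for di, ds in enumerate(datasets):
        coords = sorted(ds.spectra, key=lambda c: (c.z, c.y, c.x))
        pixels.extend((di, c) for c in coords)
        # bin once per pixel, then denoise per interval on the section image
        binned = np.array([bin_spectrum(ds.spectra[c], intervals) for c in coords])
        if radius > 0 and coords:
            ny, nx = ds.shape
            block = np.empty_like(binned)
            for j, interval in enumerate(intervals):
                img = np.full((ny, nx), np.nan)
                for i, c in enumerate(coords):
                    img[c.y, c.x] = binned[i, j]
                den = denoise_image(
                    IonImage(img, interval, ds.section_id), radius
                ).values
                block[:, j] = [den[c.y, c.x] for c in coords]
            blocks.append(block)
        else:
            blocks.append(binned.reshape(len(coords), len(intervals)))
    values = (
        np.vstack(blocks) if pixels else np.empty((0, len(intervals)))
    )
    return FeatureMatrix(values=values, pixels=pixels, intervals=list(intervals))


# ---------------------------------------------------------------------------
# bisecting k-means
# ---------------------------------------------------------------------------

@dataclass
class SegmentationNode:
    """A node of the binary segmentation hierarchy."""

    row_indices: np.ndarray
    mean_profile: np.ndarray
    children: Tuple["SegmentationNode", "SegmentationNode"] | Tuple[()] = ()
    label: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def size(self) -> int:
        return int(self.row_indices.size)


@dataclass
class SegmentationTree:
    root: SegmentationNode
    feature_matrix: FeatureMatrix

    def leaves(self) -> List[SegmentationNode]:
        out: List[SegmentationNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(node.children[::-1])
        return out

    def leaf_assignment(self) -> np.ndarray:
        """leaf index per row, in ``leaves()`` order."""
        assign = np.full(len(self.feature_matrix.pixels), -1, dtype=int)
        for li, leaf in enumerate(self.leaves()):
            assign[leaf.row_indices] = li
        return assign

    def to_text(self, indent: str = "  ") -> str:
        lines: List[str] = []

        def walk(node: SegmentationNode, depth: int) -> None:
            tag = node.label or ("leaf" if node.is_leaf else "node")
            lines.append(f"{indent * depth}{tag}: {node.size} pixels")
            for ch in node.children:
                walk(ch, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _correlation_embedding(values: np.ndarray) -> np.ndarray:
    """Rows mapped so squared Euclidean distance = 2(1 - Pearson corr).

    Constant rows (zero variance, correlation undefined) map to the zero
    vector, which sits at distance 1 from every proper profile.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    emb = centered / safe
    emb[norms[:, 0] == 0] = 0.0
    return emb


def _two_means(
    emb: np.ndarray, rng: np.random.Generator, restarts: int = 10, max_iter: int = 100
) -> Tuple[np.ndarray, float]:
    """2-means on embedded rows; returns (bool assignment, SSE).  Best of
    ``restarts`` random initializations, deterministic given the generator.
    """
    n = emb.shape[0]
    best_sse = np.inf
    best_assign: Optional[np.ndarray] = None
    for _ in range(restarts):
        i, j = rng.choice(n, size=2, replace=False)
        centers = emb[[i, j]].copy()
        assign = np.zeros(n, dtype=bool)
        for _ in range(max_iter):
            d0 = ((emb - centers[0]) ** 2).sum(axis=1)
            d1 = ((emb - centers[1]) ** 2).sum(axis=1)
            new_assign = d1 < d0
            if new_assign.all() or (~new_assign).all():
                break
            if (new_assign == assign).all() and _ > 0:
                break
            assign = new_assign
            centers[0] = emb[~assign].mean(axis=0)
            centers[1] = emb[assign].mean(axis=0)
        if assign.all() or (~assign).all():
            continue
        d0 = ((emb - centers[0]) ** 2).sum(axis=1)
        d1 = ((emb - centers[1]) ** 2).sum(axis=1)
        sse = float(np.where(assign, d1, d0).sum())
        if sse < best_sse:
            best_sse = sse
            best_assign = assign.copy()
    if best_assign is None:  # degenerate: could not split
        return np.zeros(n, dtype=bool), np.inf
    return best_assign, best_sse


def _node_sse(emb: np.ndarray, rows: np.ndarray) -> float:
    sub = emb[rows]
    return float(((sub - sub.mean(axis=0)) ** 2).sum())


def bisecting_kmeans(
    fm: FeatureMatrix,
    max_leaves: int = 8,
    min_leaf: int = 50,
    seed: int = 0,
) -> SegmentationTree:
    """Build the binary segmentation tree.

    Repeatedly splits the leaf with the largest within-cluster sum of
    squared (correlation-embedded) deviations by 2-means with 10 restarts,
    until ``max_leaves`` is reached or no splittable leaf (> ``min_leaf``
    pixels, non-zero scatter) remains.  Deterministic for a given seed.
    Single-row or constant inputs yield a single-leaf tree.
    """
    import warnings as _warnings

    values = fm.values
    n = values.shape[0]
    if n == 0:
        raise ValueError("feature matrix has no rows")
    emb = _correlation_embedding(values)
    root = SegmentationNode(
        row_indices=np.arange(n), mean_profile=values.mean(axis=0)
    )
    tree = SegmentationTree(root=root, feature_matrix=fm)
    if n < 2:
        _warnings.warn("fewer than 2 pixels: returning a single-leaf tree")
        return tree
    rng = np.random.default_rng(seed)
    while True:
        leaves = tree.leaves()
        if len(leaves) >= max_leaves:
            break
        splittable = [
            (leaf, _node_sse(emb, leaf.row_indices))
            for leaf in leaves
            if leaf.size > min_leaf
        ]
        splittable = [(leaf, sse) for leaf, sse in splittable if sse > 0]
        if not splittable:
            break
        leaf, _ = max(splittable, key=lambda t: t[1])
        assign, sse = _two_means(emb[leaf.row_indices], rng)
        if not assign.any() or assign.all() or not np.isfinite(sse):
            break
        left_rows = leaf.row_indices[~assign]
        right_rows = leaf.row_indices[assign]
        leaf.children = (
            SegmentationNode(left_rows, values[left_rows].mean(axis=0)),
            SegmentationNode(right_rows, values[right_rows].mean(axis=0)),
        )
    return tree


# ---------------------------------------------------------------------------
# labeling and mean spectra
# ---------------------------------------------------------------------------

def label_regions(
    tree: SegmentationTree,
    reference_masks: Dict[str, Set[PixelCoordinate]],
) -> SegmentationTree:
    """Label each leaf with the reference mask of maximal Jaccard overlap.

    Masks map region label -> set of pixel coordinates; a tie is broken
    toward the smaller mask, and a leaf overlapping no mask is labeled
    ``background``.  Labels are attached in place and the tree returned.
    """
    keys = set()
    for la, pa in reference_masks.items():
        for lb, pb in reference_masks.items():
            if la < lb and pa & pb:
                raise ValueError(f"reference masks {la} and {lb} overlap")
        keys.add(la)
    pixel_coords = [c for _, c in tree.feature_matrix.pixels]
    for leaf in tree.leaves():
        leaf_set = {pixel_coords[i] for i in leaf.row_indices}
        best: Tuple[float, int, Optional[str]] = (0.0, 0, None)
        for label, mask in reference_masks.items():
            inter = len(leaf_set & mask)
            if inter == 0:
                continue
            union = len(leaf_set | mask)
            jac = inter / union
            # tie -> smaller mask wins: compare (jaccard, -mask_size)
            cand = (jac, -len(mask), label)
            if (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
        leaf.label = best[2] or BACKGROUND
    return tree


def label_image(tree: SegmentationTree, dataset_index: int, shape: Tuple[int, int]) -> np.ndarray:
    """Per-pixel string-label image for one section (missing pixels '')."""
    out = np.full(shape, "", dtype=object)
    coords = tree.feature_matrix.pixels
    assign = tree.leaf_assignment()
    leaves = tree.leaves()
    for row, (di, c) in enumerate(coords):
        if di == dataset_index:
            out[c.y, c.x] = leaves[assign[row]].label or ""
    return out


def mean_spectrum(
    datasets: Sequence[MsiDataset],
    pixels: Set[PixelCoordinate],
    intervals: Sequence[MzInterval],
) -> MassSpectrum:
    """Arithmetic mean, per interval, of the (preprocessed) intensities of
    the member pixels, pooled over all datasets containing them.
    """
    if not pixels:
        raise ValueError("pixel set must be non-empty")
    acc = np.zeros(len(intervals))
    n = 0
    found: Set[PixelCoordinate] = set()
    for ds in datasets:
        for c in pixels:
            spec = ds.spectra.get(c)
            if spec is not None:
                acc += bin_spectrum(spec, intervals)
                n += 1
                found.add(c)
    missing = pixels - found
    if missing:
        raise KeyError(f"{len(missing)} pixels absent from the datasets")
    centers = np.array([iv.center for iv in intervals])
    order = np.argsort(centers)
    return MassSpectrum(centers[order], (acc / n)[order], mode=CENTROID)


def masks_to_rle(masks: Dict[str, Set[PixelCoordinate]]) -> str:
    """Region masks as run-length-encoded text (one line per run:
    label, z, y, x_start, run_length)."""
    lines = ["label\tz\ty\tx_start\trun_length"]
    for label in sorted(masks):
        coords = sorted(masks[label], key=lambda c: (c.z, c.y, c.x))
        run_start = None
        prev = None
        for c in coords + [None]:
            if (
                prev is not None
                and c is not None
                and c.z == prev.z
                and c.y == prev.y
                and c.x == prev.x + 1
            ):
                prev = c
                continue
            if prev is not None and run_start is not None:
                lines.append(
                    f"{label}\t{run_start.z}\t{run_start.y}\t{run_start.x}\t"
                    f"{prev.x - run_start.x + 1}"
                )
            run_start = c
            prev = c
    return "\n".join(lines) + "\n"
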