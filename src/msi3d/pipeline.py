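"""Config-driven orchestration of the full analysis workflow.

Stages: read (or generate) sections -> TIC normalization -> peak picking on
the pooled mean spectrum -> interval construction -> per-brain feature
matrices with image denoising -> bisecting k-means segmentation -> region
labeling against reference masks -> serial-section registration and volume
assembly -> pooled tumor-spectrum ROC/AUC screening between the two groups
-> accurate-mass annotation of the markers -> report and table output.

Everything is deterministic given (config, seed): the only randomness in
the analysis itself is the k-means initialization, which is seeded.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import annotate as ann
from . import discriminant as disc
from . import phantom as ph
from . import preprocess as pp
from . import segmentation as seg
from . import volume as vol
from .core import (
    MassSpectrum,
    MsiDataset,
    MzInterval,
    PixelCoordinate,
    bin_spectrum,
    extract_ion_image,
    read_imzml,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one run.  ``manifest`` points at an imzML suite written
    by :func:`msi3d.phantom.write_phantom_suite` (with its mask files);
    when absent the phantom suite is generated in memory."""

    phantom: ph.PhantomConfig = field(default_factory=ph.PhantomConfig)
    manifest: Optional[Path] = None
    masks_dir: Optional[Path] = None
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    screening: disc.ScreenConfig = field(default_factory=disc.ScreenConfig)
    registration: vol.RegistrationConfig = field(
        default_factory=lambda: vol.RegistrationConfig(
            rotation_bound=3.0, rotation_step=1.0, shift_bound=4
        )
    )
    max_leaves: int = 8
    min_leaf: int = 50
    denoise_radius: int = 1
    histogram_step: float = 0.01
    tol_ppm: float = 10.0
    seed: int = 0
    outdir: Optional[Path] = None

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = PipelineConfig()
        if "phantom" in raw:
            cfg.phantom = ph.PhantomConfig(**raw["phantom"])
        if "preprocess" in raw:
            cfg.preprocess = pp.PreprocessConfig(**raw["preprocess"])
        if "screening" in raw:
            cfg.screening = disc.ScreenConfig(**raw["screening"])
        if "registration" in raw:
            cfg.registration = vol.RegistrationConfig(**raw["registration"])
        for key in (
            "max_leaves",
            "min_leaf",
            "denoise_radius",
            "histogram_step",
            "tol_ppm",
            "seed",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        for key in ("manifest", "masks_dir", "outdir"):
            if raw.get(key):
                setattr(cfg, key, Path(raw[key]))
        return cfg


@dataclass
class RunReport:
    """Per-stage counts, timings and the result tables."""

    seed: int
    spectra_read: int = 0
    spectra_used: int = 0
    spectra_excluded: int = 0
    exclusions: Dict[str, int] = field(default_factory=dict)
    peaks_picked: int = 0
    n_intervals: int = 0
    leaves_per_brain: Dict[str, int] = field(default_factory=dict)
    ari_per_brain: Dict[str, float] = field(default_factory=dict)
    tumor_pixels_per_group: Dict[str, int] = field(default_factory=dict)
    n_markers: int = 0
    marker_table: Optional[object] = None
    annotation_table: Optional[object] = None
    timings: Dict[str, float] = field(default_factory=dict)

    def consistent(self) -> bool:
        return self.spectra_read == self.spectra_used + self.spectra_excluded

    def to_text(self) -> str:
        lines = [
            f"seed\t{self.seed}",
            f"spectra_read\t{self.spectra_read}",
            f"spectra_used\t{self.spectra_used}",
            f"spectra_excluded\t{self.spectra_excluded}",
        ]
        for reason, n in self.exclusions.items():
            lines.append(f"excluded[{reason}]\t{n}")
        lines += [
            f"peaks_picked\t{self.peaks_picked}",
            f"n_intervals\t{self.n_intervals}",
        ]
        for b, n in self.leaves_per_brain.items():
            lines.append(f"leaves[{b}]\t{n}")
        for b, a in self.ari_per_brain.items():
            lines.append(f"ari[{b}]\t{a:.4f}")
        for g, n in self.tumor_pixels_per_group.items():
            lines.append(f"tumor_pixels[{g}]\t{n}")
        lines.append(f"n_markers\t{self.n_markers}")
        for stage, dt in self.timings.items():
            lines.append(f"time[{stage}]_s\t{dt:.2f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def load_manifest(manifest_path: Path) -> List[ph.PhantomBrain]:
    """Read a phantom suite back from its manifest TSV."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    brains: Dict[str, ph.PhantomBrain] = {}
    lines = manifest_path.read_text().strip().splitlines()[1:]
    for line in lines:
        brain_id, group, z, fname = line.split("\t")
        ds = read_imzml(root / fname)
        ds.group_label = group
        ds.section_id = Path(fname).stem
        if brain_id not in brains:
            brains[brain_id] = ph.PhantomBrain(brain_id, group, [])
        brains[brain_id].sections.append(ds)
    return list(brains.values())


def load_masks_rle(path: Path) -> Dict[str, Set[PixelCoordinate]]:
    """Parse run-length-encoded region masks written by the truth report."""
    out: Dict[str, Set[PixelCoordinate]] = {}
    for line in Path(path).read_text().strip().splitlines()[1:]:
        label, z, y, x0, n = line.split("\t")
        pixels = out.setdefault(label, set())
        for dx in range(int(n)):
            pixels.add(PixelCoordinate(int(x0) + dx, int(y), int(z)))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def tic_normalize_brains(
    brains: Sequence[ph.PhantomBrain], target: float = 1.0
) -> Tuple[List[ph.PhantomBrain], Dict[str, int]]:
    """TIC-normalize every spectrum; zero-TIC spectra are excluded."""
    exclusions = {"zero_tic": 0}
    out: List[ph.PhantomBrain] = []
    for brain in brains:
        sections = []
        for ds in brain.sections:
            spectra = {}
            for c, s in ds.spectra.items():
                if s.tic <= 0:
                    exclusions["zero_tic"] += 1
                    continue
                spectra[c] = pp.tic_normalize(s, target)
            sections.append(
                MsiDataset(
                    spectra=spectra,
                    grid=ds.grid,
                    section_id=ds.section_id,
                    group_label=ds.group_label,
                )
            )
        out.append(ph.PhantomBrain(brain.brain_id, brain.group, sections))
    return out, exclusions


def pooled_mean_profile(
    brains: Sequence[ph.PhantomBrain], mz_range: Tuple[float, float], step: float
) -> MassSpectrum:
    """Histogram all centroids (intensity-weighted) onto a uniform axis:
    the pooled mean spectrum used for peak picking."""
    lo, hi = mz_range
    edges = np.arange(lo, hi + step, step)
    acc = np.zeros(edges.size - 1)
    n = 0
    for brain in brains:
        for ds in brain.sections:
            specs = list(ds.spectra.values())
            if not specs:
                continue
            mz = np.concatenate([s.mz for s in specs])
            w = np.concatenate([s.intensity for s in specs])
            acc += np.histogram(mz, bins=edges, weights=w)[0]
            n += len(specs)
    if n == 0:
        raise ValueError("no spectra to pool")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return MassSpectrum(centers, acc / n, mode="profile")


def tumor_matrix(
    brains: Sequence[ph.PhantomBrain],
    masks_by_brain: Dict[str, Dict[str, Set[PixelCoordinate]]],
    intervals: Sequence[MzInterval],
    group: str,
) -> np.ndarray:
    """Pooled (tumor pixels x intervals) intensity matrix for one group."""
    rows = []
    for brain in brains:
        if brain.group != group:
            continue
        tumor = masks_by_brain[brain.brain_id][seg.TUMOR]
        for ds in brain.sections:
            for c, s in ds.spectra.items():
                if c in tumor:
                    rows.append(bin_spectrum(s, intervals))
    if not rows:
        raise ValueError(f"group {group!r} has no tumor spectra")
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full workflow and (optionally) write all outputs."""
    report = RunReport(seed=cfg.seed)
    t0 = time.time()

    # --- input ------------------------------------------------------------
    if cfg.manifest is not None:
        brains = load_manifest(cfg.manifest)
        masks_dir = cfg.masks_dir or Path(cfg.manifest).parent
        masks_by_brain = {}
        for brain in brains:
            group, b = brain.brain_id.rsplit("_brain", 1)
            masks_by_brain[brain.brain_id] = load_masks_rle(
                Path(masks_dir) / f"masks_{group}_brain{b}.tsv"
            )
        gt = None
    else:
        phantom_cfg = ph.PhantomConfig(
            **{**cfg.phantom.__dict__, "seed": cfg.seed}
        )
        brains, gt = ph.make_phantom(phantom_cfg)
        masks_by_brain = {
            brain.brain_id: gt.masks(brain.group, b % cfg.phantom.n_brains_per_group)
            for b, brain in enumerate(brains)
        }
    report.spectra_read = sum(len(ds) for br in brains for ds in br.sections)
    report.timings["input"] = time.time() - t0

    # --- preprocessing ----------------------------------------------------
    t0 = time.time()
    brains, exclusions = tic_normalize_brains(brains, cfg.preprocess.tic_target)
    report.exclusions = exclusions
    report.spectra_excluded = sum(exclusions.values())
    report.spectra_used = report.spectra_read - report.spectra_excluded
    report.timings["preprocess"] = time.time() - t0

    # --- peak picking and intervals ---------------------------------------
    t0 = time.time()
    mz_range = brains[0].sections[0].grid.mz_range
    mean_profile = pooled_mean_profile(brains, mz_range, cfg.histogram_step)
    centers = pp.pick_peaks(mean_profile, cfg.preprocess)
    intervals = pp.build_intervals(centers, cfg.preprocess)
    report.peaks_picked = len(centers)
    report.n_intervals = len(intervals)
    if not intervals:
        raise RuntimeError("peak picking found no peaks: cannot continue")
    report.timings["peaks"] = time.time() - t0

    # --- segmentation per brain -------------------------------------------
    t0 = time.time()
    trees: Dict[str, seg.SegmentationTree] = {}
    for bi, brain in enumerate(brains):
        fm = seg.build_features(brain.sections, intervals, radius=cfg.denoise_radius)
        tree = seg.bisecting_kmeans(
            fm, max_leaves=cfg.max_leaves, min_leaf=cfg.min_leaf,
            seed=cfg.seed * 1000 + bi,
        )
        seg.label_regions(tree, masks_by_brain[brain.brain_id])
        trees[brain.brain_id] = tree
        report.leaves_per_brain[brain.brain_id] = len(tree.leaves())
        report.ari_per_brain[brain.brain_id] = segmentation_ari(
            tree, masks_by_brain[brain.brain_id]
        )
    report.timings["segmentation"] = time.time() - t0

    # --- registration and volume ------------------------------------------
    t0 = time.time()
    volumes: Dict[str, vol.Volume3D] = {}
    ref = cfg.registration.reference_interval
    for brain in brains:
        images = [
            seg.denoise_image(extract_ion_image(ds, ref), cfg.denoise_radius)
            for ds in brain.sections
        ]
        transforms = vol.register_stack(images, cfg.registration)
        volumes[brain.brain_id] = vol.build_volume(
            list(zip(brain.sections, transforms)), ref,
            grid=brain.sections[0].grid,
        )
    report.timings["registration"] = time.time() - t0

    # --- screening ---------------------------------------------------------
    t0 = time.time()
    mat_a = tumor_matrix(brains, masks_by_brain, intervals, ph.NON_METASTASIZING)
    mat_b = tumor_matrix(brains, masks_by_brain, intervals, ph.METASTASIZING)
    report.tumor_pixels_per_group = {
        ph.NON_METASTASIZING: mat_a.shape[0],
        ph.METASTASIZING: mat_b.shape[0],
    }
    results = disc.screen_markers(mat_a, mat_b, intervals, cfg.screening)
    markers = disc.markers_only(results)
    report.n_markers = len(markers)
    report.marker_table = disc.marker_table(markers)
    report.timings["screening"] = time.time() - t0

    # --- annotation ---------------------------------------------------------
    t0 = time.time()
    # the ten marker species plus the alkyl-ether isomer of the plasmalogen,
    # so the isomeric pair is reported as one dual assignment
    panel_species = [
        ann.parse_lipid(n)
        for n in ph.DEFAULT_MARKER_NAMES_DECREASED
        + ph.DEFAULT_MARKER_NAMES_INCREASED
        + ("PE(O-18:2/18:1)",)
    ]
    annotated = ann.match_peaks(
        [m.interval.center for m in markers],
        panel_species,
        tol_ppm=cfg.tol_ppm,
        aucs=[m.auc for m in markers],
    )
    report.annotation_table = ann.annotation_table(annotated)
    report.timings["annotation"] = time.time() - t0

    # --- output -------------------------------------------------------------
    if cfg.outdir is not None:
        write_outputs(cfg, report, brains, trees, volumes)
    return report


def segmentation_ari(
    tree: seg.SegmentationTree, masks: Dict[str, Set[PixelCoordinate]]
) -> float:
    """Adjusted Rand index between leaf labels and the reference regions,
    over the pixels covered by the masks."""
    from sklearn.metrics import adjusted_rand_score

    coord_label = {}
    for label, pixels in masks.items():
        for c in pixels:
            coord_label[c] = label
    leaves = tree.leaves()
    assign = tree.leaf_assignment()
    truth, pred = [], []
    for row, (_, c) in enumerate(tree.feature_matrix.pixels):
        if c in coord_label:
            truth.append(coord_label[c])
            pred.append(leaves[assign[row]].label or f"leaf{assign[row]}")
    if not truth:
        return float("nan")
    return float(adjusted_rand_score(truth, pred))


def write_outputs(cfg, report, brains, trees, volumes) -> None:
    """Marker/annotation TSVs, run report, per-brain tree text, label PNGs
    and volume slice stacks."""
    from .core import IonImage, save_ion_image_png

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# msi3d run, seed={cfg.seed}\n"
    mt = outdir / "marker_table.tsv"
    mt.write_text(header + report.marker_table.to_csv(sep="\t", index=False))
    at = outdir / "annotation_table.tsv"
    at.write_text(header + report.annotation_table.to_csv(sep="\t", index=False))
    (outdir / "run_report.txt").write_text(header + report.to_text())
    code = {seg.BACKGROUND: 0, seg.GREY: 1, seg.WHITE: 2, seg.TUMOR: 3}
    for brain in brains:
        tree = trees[brain.brain_id]
        (outdir / f"tree_{brain.brain_id}.txt").write_text(tree.to_text() + "\n")
        for z, ds in enumerate(brain.sections):
            shape = ds.shape
            labels = seg.label_image(tree, z, shape)
            img = np.full(shape, np.nan)
            for (yy, xx), lab in np.ndenumerate(labels):
                if lab:
                    img[yy, xx] = code.get(lab, 0)
            save_ion_image_png(
                IonImage(img, section_id=ds.section_id),
                outdir / f"labels_{brain.brain_id}_z{z:02d}.png",
            )
        vol.export_volume(volumes[brain.brain_id], outdir / f"volume_{brain.brain_id}")
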