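"""Phantom multi-brain 3D-MSI generator with machine-readable ground truth.

The generator emulates the study design the analysis pipeline is built for:
two groups of whole mouse brains ("metastasizing" vs "non_metastasizing",
three per group), each cut into serial sagittal sections on a 50 µm grid
with 150 µm section spacing, each pixel carrying a negative-mode lipid
spectrum over m/z 400-1600.  Geometry is schematic, not anatomical: the
brain outline is an ellipse, white matter an elliptical band inside it, and
the tumor an ellipsoid spanning contiguous sections in the posterior
("cerebellar") corner.

Each pixel's spectrum holds one centroid per panel species at the species
m/z (plus a small per-pixel mass jitter), with intensity

    region base abundance x lognormal noise (median 1, CV = ``noise_cv``).

Ten panel species are *planted* group markers: in metastasizing tumor
pixels their intensity is multiplied by a factor solved (by bisection on
the two-lognormal ordering probability) so that the population AUC of
non-metastasizing vs metastasizing tumor intensities equals a configured
target — six species decreased in the metastasizing group, four increased,
mirroring the marker structure the screening stage must recover.  All other
species are nulls (true AUC 0.5).  Rare hotspot pixels get one species
multiplied 50x; sections are randomly shifted/rotated (recorded as ground
truth) to exercise registration.
"""

from __future__ import annotations

import math
import uuid as uuid_module
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import norm

from .annotate import LipidSpecies, monoisotopic_mz, parse_lipid
from .core import (
    CENTROID,
    PROFILE,
    GridMetadata,
    MassSpectrum,
    MsiDataset,
    PixelCoordinate,
    write_imzml,
)
from .segmentation import BACKGROUND, GREY, TUMOR, WHITE
from .volume import RigidTransform2D

METASTASIZING = "metastasizing"
NON_METASTASIZING = "non_metastasizing"

#: structural channels: abundant lipid signals used for registration (790.5,
#: present throughout the tissue) and as a white-matter channel (888.6)
REFERENCE_MZ = 790.5
WHITE_MATTER_MZ = 888.6

#: the ten marker species planted by default: six decreased and four
#: increased in the metastasizing group
DEFAULT_MARKER_NAMES_DECREASED = (
    "PA(16:0_18:1)",
    "PA(18:0_20:4)",
    "PE(P-18:1/18:1)",
    "PE(16:0_20:4)",
    "PE(18:1/18:1)",
    "PS(16:0_18:1)",
)
DEFAULT_MARKER_NAMES_INCREASED = (
    "PS(18:0_22:6)",
    "PI(18:0_20:4)",
    "PIP(18:0_20:4)",
    "PIP2(18:0_20:4)",
)
# population AUC targets (non-metastasizing vs metastasizing tumor pixels);
# >0.5 = decreased in metastasizing.  Chosen with a clear margin outside the
# screening band [0.4, 0.6] so recovery is a property of the method, not of
# sampling luck at phantom sample sizes.
DEFAULT_AUC_DECREASED = (0.70, 0.69, 0.68, 0.67, 0.66, 0.65)
DEFAULT_AUC_INCREASED = (0.30, 0.31, 0.33, 0.34)


@dataclass(frozen=True)
class PanelSpecies:
    """One panel entry: a named lipid (or an anonymous decoy center) with
    region-specific base abundances."""

    mz: float
    abundance: Tuple[float, float, float]  # (grey, white, tumor)
    name: Optional[str] = None

    def base(self, region: str) -> float:
        return {GREY: self.abundance[0], WHITE: self.abundance[1], TUMOR: self.abundance[2]}[region]


@dataclass(frozen=True)
class PlantedEffect:
    species_index: int
    target_auc: float
    direction: str  # decreased_in_metastasizing | increased_in_metastasizing


def default_panel(n_decoys: int = 50) -> List[PanelSpecies]:
    """Ten marker lipids at their computed [M-H]- m/z, two structural
    channels, and decoy centers spread over m/z 400-1600.

    The panel is a fixed function of its arguments (decoy placement uses an
    internal constant seed) so that "the default panel" is identical across
    phantom seeds.
    """
    entries: List[PanelSpecies] = []
    for name in DEFAULT_MARKER_NAMES_DECREASED + DEFAULT_MARKER_NAMES_INCREASED:
        mz = monoisotopic_mz(parse_lipid(name))
        entries.append(PanelSpecies(mz=mz, abundance=(2.0, 1.0, 6.0), name=name))
    entries.append(PanelSpecies(mz=REFERENCE_MZ, abundance=(8.0, 2.0, 3.0), name=None))
    entries.append(PanelSpecies(mz=WHITE_MATTER_MZ, abundance=(1.5, 8.0, 1.0), name=None))

    rng = np.random.default_rng(1900218)  # panel layout constant, not cfg.seed
    taken = [e.mz for e in entries]
    homes = [GREY, WHITE, TUMOR]
    placed = 0
    while placed < max(0, n_decoys - 2):
        c = float(rng.uniform(401.0, 1599.0))
        if min(abs(c - t) for t in taken) < 1.5:
            continue
        home = homes[placed % 3]
        ab = {GREY: (6.0, 1.0, 1.0), WHITE: (1.0, 6.0, 1.0), TUMOR: (1.0, 1.0, 6.0)}[home]
        entries.append(PanelSpecies(mz=c, abundance=ab, name=None))
        taken.append(c)
        placed += 1
    entries.sort(key=lambda e: e.mz)
    return entries


def default_planted_effects(panel: Sequence[PanelSpecies]) -> List[PlantedEffect]:
    by_name = {e.name: i for i, e in enumerate(panel) if e.name}
    effects = []
    for name, auc in zip(DEFAULT_MARKER_NAMES_DECREASED, DEFAULT_AUC_DECREASED):
        effects.append(PlantedEffect(by_name[name], auc, "decreased_in_metastasizing"))
    for name, auc in zip(DEFAULT_MARKER_NAMES_INCREASED, DEFAULT_AUC_INCREASED):
        effects.append(PlantedEffect(by_name[name], auc, "increased_in_metastasizing"))
    return effects


@dataclass
class PhantomConfig:
    """Phantom study conditions.  Defaults give six brains (three per
    group), eight sections each on a 40x30 grid, a 62-species panel with the
    ten planted markers, 20% multiplicative intensity noise, 1/1000 hotspot
    pixels and up to 2 px / 2 deg of section-to-section jitter."""

    n_brains_per_group: int = 3
    sections_per_brain: int = 8
    grid_shape: Tuple[int, int] = (40, 30)  # (nx, ny)
    species_panel: List[PanelSpecies] = field(default_factory=default_panel)
    planted_effects: Optional[List[PlantedEffect]] = None  # None -> defaults
    noise_cv: float = 0.2
    baseline_amplitude: float = 5.0
    hotspot_rate: float = 0.001
    jitter_shift: float = 2.0   # max |dx|,|dy| in pixels
    jitter_rotation: float = 2.0  # max |theta| in degrees
    mz_jitter: float = 0.02     # per-pixel centroid mass jitter (Da, 1 s.d.)
    seed: int = 0
    grid: GridMetadata = field(default_factory=GridMetadata)

    def __post_init__(self) -> None:
        if self.planted_effects is None:
            self.planted_effects = default_planted_effects(self.species_panel)
        for eff in self.planted_effects:
            if not 0 <= eff.species_index < len(self.species_panel):
                raise ValueError(f"planted species index {eff.species_index} outside panel")
            if 0.4 <= eff.target_auc <= 0.6 and self.noise_cv > 0:
                raise ValueError("planted true AUCs must lie outside [0.4, 0.6]")


@dataclass
class GroundTruth:
    """Everything the test harness needs: per-section region label arrays
    (coded 0=background, 1=grey, 2=white, 3=tumor), the equivalent mask
    sets, true per-section jitter transforms, the panel, planted markers
    with their solved scale factors, and per-region expected intensities."""

    label_arrays: Dict[Tuple[str, int], List[np.ndarray]]
    transforms: Dict[Tuple[str, int], List[RigidTransform2D]]
    panel: List[PanelSpecies]
    planted: List[PlantedEffect]
    planted_scales: List[float]

    REGION_CODES = {BACKGROUND: 0, GREY: 1, WHITE: 2, TUMOR: 3}

    def masks(self, group: str, brain: int) -> Dict[str, Set[PixelCoordinate]]:
        """Region label -> pixel set (z = section index) for one brain."""
        out: Dict[str, Set[PixelCoordinate]] = {GREY: set(), WHITE: set(), TUMOR: set()}
        for z, arr in enumerate(self.label_arrays[(group, brain)]):
            for label, code in ((GREY, 1), (WHITE, 2), (TUMOR, 3)):
                ys, xs = np.nonzero(arr == code)
                out[label].update(PixelCoordinate(int(x), int(y), z) for x, y in zip(xs, ys))
        return out

    def tumor_pixels(self, group: str, brain: int) -> Set[PixelCoordinate]:
        return self.masks(group, brain)[TUMOR]


@dataclass
class PhantomBrain:
    brain_id: str
    group: str
    sections: List[MsiDataset]


# ---------------------------------------------------------------------------
# effect-size solver
# ---------------------------------------------------------------------------

def lognormal_sigma(cv: float) -> float:
    """Shape parameter of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


def ordering_probability(scale: float, sigma: float) -> float:
    """P(A > s*B) for iid lognormal(mu, sigma) variables A, B: the population
    AUC of group A against group B when B is multiplied by ``scale``."""
    if sigma <= 0:
        return 1.0 if scale < 1 else (0.0 if scale > 1 else 0.5)
    return float(norm.cdf(-math.log(scale) / (sigma * math.sqrt(2.0))))


def solve_scale_for_auc(target_auc: float, sigma: float, tol: float = 1e-10) -> float:
    """Bisection on the scale factor so the two-lognormal ordering
    probability hits ``target_auc``.  With zero noise any factor on the
    correct side gives a degenerate AUC of 0 or 1; 0.8 / 1.25 are returned.
    """
    if not 0.0 < target_auc < 1.0:
        raise ValueError("target AUC must be in (0, 1)")
    if sigma <= 0:
        return 0.8 if target_auc > 0.5 else 1.25
    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        p = ordering_probability(mid, sigma)
        if abs(p - target_auc) < tol:
            return mid
        # ordering probability decreases in the scale factor
        if p > target_auc:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _region_codes_section(
    nx: int, ny: int, nz: int, z: int, t: RigidTransform2D
) -> np.ndarray:
    """Region code array for one section, evaluated in anatomy coordinates
    (the section's observed frame is the anatomy frame moved by ``t``)."""
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    # invert: anatomy = R(-theta) (p - c - d) + c
    th = math.radians(t.theta)
    c, s = math.cos(th), math.sin(th)
    px = xs - cx - t.dx
    py = ys - cy - t.dy
    ax = c * px + s * py + cx
    ay = -s * px + c * py + cy

    brain_a, brain_b = 0.46 * nx, 0.44 * ny
    r2 = ((ax - cx) / brain_a) ** 2 + ((ay - cy) / brain_b) ** 2
    codes = np.zeros((ny, nx), dtype=np.int8)
    codes[r2 <= 1.0] = 1  # grey matter fills the outline
    band = (r2 >= 0.45**2) & (r2 <= 0.65**2)
    codes[band & (codes > 0)] = 2  # white-matter band

    tz_c = (nz - 1) / 2.0
    tz_r = 0.42 * nz
    tx_c, ty_c = 0.70 * nx, 0.63 * ny
    tx_r, ty_r = 0.21 * nx, 0.24 * ny
    u = (z - tz_c) / tz_r
    if abs(u) < 1.0:
        shrink = math.sqrt(1.0 - u * u)
        t2 = ((ax - tx_c) / (tx_r * shrink)) ** 2 + ((ay - ty_c) / (ty_r * shrink)) ** 2
        codes[(t2 <= 1.0) & (codes > 0)] = 3  # tumor, clipped to the outline
    return codes


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def make_phantom(cfg: PhantomConfig) -> Tuple[List[PhantomBrain], GroundTruth]:
    """Generate the phantom suite.  Exactly reproducible from (cfg, seed)."""
    rng = np.random.default_rng(cfg.seed)
    nx, ny = cfg.grid_shape
    nz = cfg.sections_per_brain
    panel = cfg.species_panel
    centers = np.array([e.mz for e in panel])
    sigma = lognormal_sigma(cfg.noise_cv)
    scales = [solve_scale_for_auc(e.target_auc, sigma) for e in cfg.planted_effects]
    planted_idx = np.array([e.species_index for e in cfg.planted_effects], dtype=int)
    scale_vec = np.ones(len(panel))
    scale_vec[planted_idx] = scales
    base = np.zeros((4, len(panel)))  # rows: background, grey, white, tumor
    for j, e in enumerate(panel):
        base[1, j], base[2, j], base[3, j] = e.abundance

    brains: List[PhantomBrain] = []
    label_arrays: Dict[Tuple[str, int], List[np.ndarray]] = {}
    transforms: Dict[Tuple[str, int], List[RigidTransform2D]] = {}
    for group in (NON_METASTASIZING, METASTASIZING):
        for b in range(cfg.n_brains_per_group):
            sections: List[MsiDataset] = []
            labels_b: List[np.ndarray] = []
            trans_b: List[RigidTransform2D] = []
            for z in range(nz):
                t = RigidTransform2D(
                    dx=float(rng.uniform(-cfg.jitter_shift, cfg.jitter_shift)),
                    dy=float(rng.uniform(-cfg.jitter_shift, cfg.jitter_shift)),
                    theta=float(
                        rng.uniform(-cfg.jitter_rotation, cfg.jitter_rotation)
                    ),
                )
                codes = _region_codes_section(nx, ny, nz, z, t)
                ys, xs = np.nonzero(codes > 0)
                n_pix = ys.size
                means = base[codes[ys, xs]]  # (n_pix, n_species)
                noise = np.exp(sigma * rng.standard_normal((n_pix, len(panel))))
                intensities = means * noise
                if group == METASTASIZING:
                    tumor_rows = codes[ys, xs] == 3
                    intensities[tumor_rows] *= scale_vec
                hot = rng.random(n_pix) < cfg.hotspot_rate
                for i in np.nonzero(hot)[0]:
                    intensities[i, rng.integers(len(panel))] *= 50.0
                mzs = centers + cfg.mz_jitter * rng.standard_normal(
                    (n_pix, len(panel))
                )
                spectra = {}
                for i in range(n_pix):
                    order = np.argsort(mzs[i])
                    spectra[PixelCoordinate(int(xs[i]), int(ys[i]), z)] = MassSpectrum(
                        mzs[i][order], intensities[i][order], mode=CENTROID
                    )
                sections.append(
                    MsiDataset(
                        spectra=spectra,
                        grid=cfg.grid,
                        section_id=f"{group}_brain{b}_z{z:02d}",
                        group_label=group,
                    )
                )
                labels_b.append(codes)
                trans_b.append(t)
            brains.append(PhantomBrain(f"{group}_brain{b}", group, sections))
            label_arrays[(group, b)] = labels_b
            transforms[(group, b)] = trans_b

    gt = GroundTruth(
        label_arrays=label_arrays,
        transforms=transforms,
        panel=list(panel),
        planted=list(cfg.planted_effects),
        planted_scales=scales,
    )
    return brains, gt


def render_profile(
    centroids: MassSpectrum,
    mz_axis: np.ndarray,
    resolving_power: float = 15000.0,
    baseline: Optional[np.ndarray] = None,
) -> MassSpectrum:
    """Render a centroid spectrum as a profile spectrum: Gaussian peaks with
    FWHM = m/z / resolving_power on a given uniform axis, plus an optional
    additive baseline.  Used to exercise baseline removal and peak picking.
    """
    mz_axis = np.asarray(mz_axis, dtype=float)
    y = np.zeros_like(mz_axis)
    for c, h in zip(centroids.mz, centroids.intensity):
        fwhm = c / resolving_power
        s = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        y += h * np.exp(-0.5 * ((mz_axis - c) / s) ** 2)
    if baseline is not None:
        y = y + np.asarray(baseline, dtype=float)
    return MassSpectrum(mz_axis, y, mode=PROFILE)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_phantom_suite(
    brains: Sequence[PhantomBrain], outdir, seed: int = 0
) -> List[Path]:
    """Write every section as an imzML/ibd pair under ``outdir`` plus a
    manifest TSV (brain_id, group, z, path).  File UUIDs are derived from
    the seed so the output is byte-identical for identical (cfg, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = ["brain_id\tgroup\tz\tpath"]
    counter = 0
    for brain in brains:
        for z, ds in enumerate(brain.sections):
            fname = outdir / f"{brain.brain_id}_z{z:02d}.imzML"
            file_uuid = uuid_module.UUID(int=(int(seed) << 32) + counter)
            write_imzml(ds, fname, file_uuid=file_uuid)
            manifest.append(f"{brain.brain_id}\t{brain.group}\t{z}\t{fname.name}")
            paths.append(fname)
            counter += 1
    (outdir / "manifest.tsv").write_text("\n".join(manifest) + "\n")
    return paths


def truth_report(gt: GroundTruth, outdir) -> Dict[str, Path]:
    """Write ground truth as TSV: planted markers with directions and scale
    factors, per-section true transforms, and run-length-encoded region
    masks per brain."""
    from .segmentation import masks_to_rle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}

    lines = ["species\tmz\tdirection\ttarget_auc\tscale_factor"]
    for eff, s in zip(gt.planted, gt.planted_scales):
        entry = gt.panel[eff.species_index]
        lines.append(
            f"{entry.name or 'decoy'}\t{entry.mz:.4f}\t{eff.direction}\t"
            f"{eff.target_auc}\t{s:.6f}"
        )
    p = outdir / "planted_markers.tsv"
    p.write_text("\n".join(lines) + "\n")
    out["markers"] = p

    lines = ["group\tbrain\tz\tdx_px\tdy_px\ttheta_deg"]
    for (group, b), ts in sorted(gt.transforms.items()):
        for z, t in enumerate(ts):
            lines.append(f"{group}\t{b}\t{z}\t{t.dx:.4f}\t{t.dy:.4f}\t{t.theta:.4f}")
    p = outdir / "section_transforms.tsv"
    p.write_text("\n".join(lines) + "\n")
    out["transforms"] = p

    for (group, b) in sorted(gt.label_arrays):
        p = outdir / f"masks_{group}_brain{b}.tsv"
        p.write_text(masks_to_rle(gt.masks(group, b)))
        out[f"masks_{group}_{b}"] = p
    return out
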