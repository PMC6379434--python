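# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `msi3d`, module by module.

## Data model and conventions

An MSI section is a map from 0-based pixel coordinates (x = column,
y = row, z = section index) to a `MassSpectrum` (m/z strictly ascending,
intensities ≥ 0, profile or centroid mode).  Acquisition geometry defaults
to 50 µm pixel pitch, 10 µm section thickness with sections retained every
150 µm, and an m/z 400–1600 window — a typical fast MALDI-ToF imaging
protocol.  imzML serialization is 1-based per the format convention, with
64-bit m/z and 32-bit intensities (the common practice that bounds file
size); centroid data uses the *processed* dialect, profile data the
*continuous* dialect.  Pixels outside the tissue outline are stored as
absent and rendered as NaN in ion images — a deliberate distinction from a
measured zero, because tissue outlines are irregular.  All m/z interval
windows are half-open `[lo, hi)` so a partition of the axis double-counts
nothing.

## Preprocessing

**Baseline removal (profile mode).**  The baseline estimate starts at the
spectrum itself and is refined by iterating {convolve with a moving-average
kernel; take the elementwise minimum with the previous estimate}; the
corrected spectrum is `max(signal − baseline, 0)`.  A constant offset is an
exact fixed point of the iteration (reflected-edge smoothing preserves
constants), and the minimum propagates inter-peak floor values under peaks
narrower than the kernel, so isolated peaks on a flat background are left
essentially untouched.  Defaults: kernel 5 Da, 20 iterations — wide enough
to slide under chemical-noise peaks, and empirically at convergence (the
envelope under synthetic peaks reaches machine precision well before 20
rounds).  Requires a uniformly sampled m/z axis.

**TIC normalization.**  Each spectrum is scaled so its total ion count
equals a common target, default 1.0 (relative abundances).  Cross-specimen
comparability only requires the target to be identical, so any positive
constant is equivalent.  All-zero spectra cannot be normalized; they are
returned unchanged and logged (the pipeline excludes and itemizes them).

**Peak picking.**  Run on a pooled mean spectrum rather than per pixel:
peak sets then coincide across pixels and sections, which is what
interval-based binning needs.  (For centroid data the pipeline forms this
mean spectrum by intensity-weighted histogramming onto a 0.01 Da grid.)
The noise level is 1.4826 × the sliding-window median absolute deviation of
the detail residual (spectrum minus its moving average; both windows 10 Da).
Candidate peaks are local maxima of a lightly smoothed trace — a short
boxcar of ~0.05 Da — whose height exceeds `peak_snr` × noise (default 3).
Detecting on the smoothed trace while estimating noise from the raw
residual is intentional: a raw local-maximum rule at 3σ fires on ~10⁻³ of
pure-noise samples, whereas the short smoothing cuts single-sample noise
excursions by √(window) and drives the null false-positive rate below
10⁻⁴ per point without biasing the centers of resolved peaks.  Centers are
refined by 3-point parabolic interpolation.

**Intervals.**  One window per peak center with a minimum width of 500 mDa
(absorbing inter-run peak shifts); where two adjacent centers are closer
than the minimum width, the facing boundary moves to their midpoint so
windows never overlap.  Such windows are asymmetric about their centers,
which is why `MzInterval` carries explicit bounds.

**Hotspot clipping (display only).**  Image values outside the low/high
quantiles (defaults 0% / 99%) are set to the quantile values, computed over
finite pixels with linear interpolation between order statistics (stated
explicitly because quantile conventions differ).

## Segmentation

Ion images are denoised with an edge-preserving median filter (radius 1 by
default) restricted to finite pixels; missing pixels stay missing.  A
median filter was chosen as the parameter-light edge-preserving operator —
structured variational denoising is out of scope.

Pixel features are the denoised, TIC-normalized interval intensities.
Bisecting *k*-means repeatedly splits the leaf with the largest
within-cluster scatter by 2-means (10 restarts, best SSE, deterministic
given the seed) until `max_leaves` (default 8) is reached or no leaf
exceeds `min_leaf` (default 50) pixels.  The distance between pixel
profiles is 1 − Pearson correlation — scale-robust and standard for MSI
spectra — realized by embedding each row as its centered, L2-normalized
profile, in which squared Euclidean distance equals 2(1 − r); Lloyd
iterations then apply unchanged, and the partition is invariant to any
global positive rescaling of the features.  Constant rows (undefined
correlation) embed at the origin.  The result is a binary tree whose
leaves partition the pixels at every stage.

Region labeling is the supervised half of the "semi-supervised"
segmentation: each leaf takes the reference mask (grey matter, white
matter, tumor) with maximal Jaccard overlap, ties broken toward the
smaller mask, and leaves overlapping no mask become background.  In the
original workflow this step was histology-guided; here reference masks
(phantom ground truth, or user-supplied masks for real data) replace the
interactive choice so runs are reproducible.

## 3D assembly

Serial sections are registered on the ion image of a reference channel
(default m/z 790.5 ± 0.25 Da, an abundant structural lipid present
throughout the tissue).  Each section is aligned to its predecessor by
exhaustive search over integer shifts (±10 px) and a coarse rotation grid
(default ±10° in 1° steps; the pipeline narrows this to the jitter scale),
scoring by normalized cross-correlation of the overlap; chaining the
pairwise transforms places every section in the frame of the first.
Chained (neighbor-to-neighbor) registration was chosen over registration
to a global template because serial sections deform gradually; drift is
bounded in tests by construction.  All-zero images return the identity
flagged low-confidence.

Sections are resampled into a common padded frame by nearest neighbor — not
interpolation, so categorical label images stay valid — and stacked with
the 150 µm section spacing as the z step.  Virtual sections honor the
anisotropic voxel (50 × 50 × 150 µm): sagittal slices are the stacking
planes themselves, while coronal/transversal slices replicate each section
⌈150/50⌉ = 3 voxels thick before slicing.

## Marker screening

For every m/z interval, the samples are the per-pixel interval intensities
of the pooled tumor-region spectra of each group — all tumor pixels of all
specimens in a group form one sample, the literal population-level reading
of a pooled two-group comparison.  (Per-specimen stratification is a
caller-side variation; the pipeline pools.)  The screen statistic is the
rank-based ROC AUC with sample A fixed as the non-metastasizing group, so
AUC > 0.5 always means "higher in non-metastasizing": intervals with
AUC ≥ 0.6 are called decreased in the metastasizing group and AUC ≤ 0.4
increased, both comparisons inclusive.  No multiplicity correction is
applied to the AUC rule itself; two-sided Mann–Whitney p-values (normal
approximation with tie and continuity corrections, cross-checked against
scipy) are attached per interval, with optional Benjamini–Hochberg
flagging off by default.

## Lipid annotation

Elemental formulas are assembled from shorthand names: a glycerophosphate
core C₃H₉O₆P; per chain, acyl (c:d) adds C_cH_{2c−2d−2}O, alkyl O-(c:d)
adds C_cH_{2c−2d}, and alkenyl P-(c:d) is treated as O-(c:d+1) — the
standard shorthand equivalence that makes a plasmalogen isomeric with its
alkyl-ether form carrying one more counted double bond; head groups add
nothing (PA), C₂H₅N (PE), C₃H₅NO₂ (PS), C₆H₁₀O₅ (PI), plus one or two
HPO₃ for PIP/PIP₂.  Monoisotopic [M−H]⁻ m/z is the neutral mass minus a
proton, where the proton is an H atom minus an electron — the electron
mass is required to land reference values at the fourth decimal.  Masses
are reported to 4 decimals and ppm errors (|theo − meas|/theo × 10⁶) to 1
decimal.  Candidate matching groups panel species by formula, so isomeric
pairs are reported as one dual assignment.

Internal consistency of the calculator: a CH₂ homolog step adds
14.01565 Da, a double bond removes 2.01565 Da, and each inositol
phosphorylation adds 79.96633 Da.  Of the ten reference marker species,
seven printed theoretical masses agree with the component-assembled values
exactly at 4 decimals; for PA(18:0_20:4), PIP(18:0_20:4) and
PIP₂(18:0_20:4) the printed values differ from the assembled ones by
0.2–0.6 mDa (723.4968 vs 723.4970, 965.5156 vs 965.5162, 1045.4820 vs
1045.4825).  The calculator follows the assembly rules; the discrepancy is
documented rather than forced to match, since the provenance of those three
printed values is unclear.

## Phantom generator

The phantom emulates the study design the pipeline targets: two groups
(metastasizing / non-metastasizing), three brains per group, eight serial
sections per brain on a 40 × 30 grid at the default acquisition geometry.
Geometry is schematic, not anatomical: the brain outline is an ellipse
(~46% × 44% semi-axes of the grid), white matter an elliptical band at
45–65% normalized radius, and the tumor an ellipsoid in the posterior
("cerebellar") corner spanning the central sections, clipped to the
outline — roughly 800 tumor pixels per brain, ≥ 2000 pooled per group.

The species panel holds 60 centroids: the ten marker lipids at their
computed [M−H]⁻ masses, two structural channels (m/z 790.5, abundant
everywhere and used for registration; m/z 888.6, white-matter-dominant),
and 48 decoys spread over 400–1600 Da with ≥ 1.5 Da spacing, each assigned
a home region (grey/white/tumor, base abundance 6 at home vs 1 elsewhere;
markers 6 in tumor, 2 grey, 1 white).  Panel layout uses an internal
constant seed so "the default panel" is identical across phantom seeds.

Per pixel and species, intensity = region base × lognormal noise with
median 1 and CV `noise_cv` (default 0.2 — lognormal because MSI
intensities are positive and right-skewed; the CV is a testability choice,
as real within-group variances are not published).  In metastasizing tumor
pixels the ten planted species are scaled by a factor solved by bisection
on the two-lognormal ordering probability Φ(−ln s/(σ√2)) so the population
AUC of non-metastasizing vs metastasizing tumor intensities equals its
target.  Default targets are 0.70/0.69/0.68/0.67/0.66/0.65 for the six
decreased species and 0.30/0.31/0.33/0.34 for the four increased —
mirroring the 6-down/4-up marker structure while keeping every true AUC a
clear margin outside the 0.6/0.4 decision band, so that recovery at
phantom sample sizes (~2.5 × 10³ tumor spectra per group, versus ~10⁵–10⁶
in a full animal study) reflects the method rather than sampling luck.
Hotspot pixels (rate 10⁻³) have one randomly chosen species multiplied by
50 — a single-species artifact survives TIC normalization and therefore
actually exercises image denoising, unlike a whole-spectrum factor, which
normalization would cancel exactly.  Sections are jittered by up to ±2 px
and ±2° (recorded as ground truth); membership is evaluated through the
inverse transform, so the ground-truth masks live in the observed frame.
Centroid m/z values get 0.02 Da (1 s.d.) per-pixel jitter, which the
≥ 500 mDa intervals absorb.  Everything is drawn from one generator seeded
by the config, and file UUIDs derive from the seed, so identical
(config, seed) produce byte-identical imzML output.

Profile-mode rendering (Gaussian peaks at a configurable resolving power
plus an additive baseline) is provided for small spectra to exercise
baseline removal and peak picking; the suite-scale phantom is centroid
mode to keep file sizes small.

What the phantom does *not* model: realistic lipidomes and isotope
envelopes, in-source fragmentation, detector saturation, mass-calibration
drift beyond the per-pixel jitter, and anatomical geometry.  Passing tests
therefore demonstrate correctness of the algorithms under controlled
effect sizes and noise, not performance on real tissue.

## Pipeline

Stage order: read/generate → TIC normalization (zero-TIC spectra excluded
and itemized) → pooled mean spectrum → peak picking → intervals →
per-brain features with denoising → bisecting k-means → labeling against
reference masks → chained registration and volume assembly → pooled
tumor-spectrum screening → annotation (tolerance 10 ppm by default, wide
enough for interval centers estimated from binned ToF-scale data) → tables
and report.  Tumor-region selection uses the reference masks rather than a
manually chosen cluster so automated runs are reproducible; the
segmentation tree and its labels are still computed, exported, and scored
(adjusted Rand index) against the same masks.  The only stochastic
analysis step is k-means initialization, seeded per brain from the run
seed, so runs are deterministic given (config, seed).

Problem sizes used by the test suite and the acceptance script: the
default phantom (36k spectra, 60 intervals) for screening and
segmentation checks, with 20 and 5 replicate seeds respectively; reduced
phantoms (1 brain per group, 4 sections, 24 × 18 grid) for end-to-end
pipeline tests; 10⁴-point profile spectra for baseline/peak-picking
checks; 10³ random instances for the AUC oracle comparison.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation between order statistics (numpy default).
- 2-means restarts that collapse to one cluster are discarded; if every
  restart collapses (e.g. identical rows) the leaf is not split.
- Empty spectra are valid (a pixel with no detected signal) and round-trip
  through imzML; all-zero images register as identity with a
  low-confidence flag; all-tied Mann–Whitney samples return p = 1.
- Baseline removal rejects centroid input and non-uniform axes rather than
  guessing a resampling.
- Registration searches integer shifts and a 1° rotation grid; accuracy is
  bounded by one pixel / one grid step by construction, which matches the
  jitter scale the phantom plants.

## Known limitations

- No deformable registration; real cryosections deform non-rigidly.
- Screening treats pixels as exchangeable within a group (no per-animal
  random effects); with three animals per group, animal-level confounding
  cannot be excluded by the statistic itself.
- The annotation panel is the species list it is given — there is no
  database search, isotope-pattern scoring, or MS/MS evidence.
- Peak picking on the pooled mean spectrum can miss species confined to
  very few pixels.
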