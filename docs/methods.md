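# Methods

`t6sspipe` quantifies fluorescent-focus formation by Type VI secretion system
(T6SS) reporter fusions in rod-shaped bacteria imaged by wide-field
fluorescence microscopy. It has two halves: an analysis pipeline
(segmentation, punctum detection, per-cell statistics, co-localization,
tracking) and a seeded synthetic-image generator that provides ground truth
for every stage. This note documents the models, the defaults and the design
choices; numbers quoted as "recovered" are those the test suite and
`scripts/acceptance.py` compute at run time.

## The synthetic field model

**Cell geometry.** Cells are 2D spherocylinders (capsules) extended into 3D
by a circular cross-section: a point (x, y, z) is inside the cell when its
distance to the axis segment, combined in quadrature with its offset from
the cell mid-plane, is below the half-width. Defaults: length 2.0–3.5 µm
(uniform), width 0.8 µm — typical dimensions for *S. marcescens*-like rods.
All cells share one mid-plane (default 1.2 µm), on which the z stack is
centred.

**Layouts.** `isolated` places cells by rejection sampling with a minimum
boundary-to-boundary separation (default 1.0 µm, capsule–capsule distance
computed exactly from segment–segment distances); `microcolony` grows a
packing by proposing lateral or pole-to-pole neighbours of an existing cell
with similar orientation, allowing contact but bounding overlap
(`overlap_tol_um`, default 0.2 µm). Placement is bounded rejection-and-retry;
an overfull field raises a "field too crowded" error. No growth or division
is modelled: a microcolony is a static packing.

**Channels.** A `ChannelModel` describes one fluorophore:

* `cytoplasmic_foci` — uniform photon density in the cell body, plus foci
  (the sheath-reporter pattern: bright puncta over diffuse background);
* `foci_only` — like the above with weak diffuse background;
* `membrane_patchy` / `membrane_foci` — the photon density confined to a
  shell at the cell surface (thickness 0.15 µm), optionally modulated by
  random surface patches; `membrane_foci` places the puncta on the surface.

Per-cell focus counts are i.i.d. draws from an explicit pmf or Poisson with
a given mean. The default sheath-channel pmf is (0.690, 0.277, 0.030, 0.002)
renormalized — 69/28/3/0.2% of cells with 0/1/2/3 foci, mean ≈ 0.343 — and
the isolated-cell variant is (0.54, 0.39, 0.07), mean 0.53. These are the
published population and single-cell distributions the generator is
calibrated to.

**Resolvability (hard core).** Those published counts are counts of
*resolved* puncta; two foci closer than the optical resolution limit
(0.272 µm, the PSF FWHM) are one punctum by definition. The generator
therefore keeps same-channel foci of one cell at least 0.272 µm apart
(uniform placement conditional on resolvability; the constraint is
configurable and `0` disables it). Without it, a channel carrying ~0.9 foci
per cell loses ~5% of its foci to sub-resolution pair merging at detection,
and no pipeline could recover the density the generator was calibrated to.

**Two-channel structure.** A channel may reference a partner channel:

* `p_coloc` (TssH/ClpV-like mode, default mean 0.2 foci/cell, p = 0.8):
  each focus seeks a partner focus — selected field-wide and without
  replacement, as a disassembly factor concentrates at sheaths — and is
  placed within `coloc_radius_um` (0.1 µm) of it. Per-cell means are
  preserved; realized co-localization toward the partner is ≈ p.
* `p_partner_coloc` (TssL-like mode, p = 0.85): every partner focus receives
  one co-localized focus with probability p; an independent Poisson
  component (mean 0.9 − 0.85 × 0.343 ≈ 0.61, computed at configuration
  time) brings the total to 0.9 foci/cell. This reproduces the
  non-reciprocal structure in which most sheath foci sit on a membrane-complex
  focus while only a minority of membrane-complex foci are occupied.

**Optics and noise.** The expected image is
`offset + gain · (PSF ⊛ photon field)`. The PSF is a 3D Gaussian
(σ_xy = 0.11 µm, so FWHM ≈ 0.26 µm, consistent with the 0.272 µm resolution
figure; σ_z = 0.30 µm). Diffuse signal is rendered as a voxelized density
and blurred; each focus is added as an analytically pixel-integrated 3D
Gaussian (erf differences per axis), so ground-truth positions are exact at
sub-pixel scale and photons are conserved within the stack. EMCCD noise is
the standard Poisson–gain–Gaussian approximation: counts =
`offset + gain · Poisson(λ) + N(0, read_noise)`; the full EM-register
cascade (excess-noise factor) is not modelled, which is adequate at the
simulated signal levels. Defaults: 0.08 µm/px (so 0.272 µm = 3.4 px),
13 z planes at 0.2 µm, gain 30 e⁻/photon, read noise 6 e⁻, offset 100
counts; diffuse 50 photons/voxel (mask channel), focus 6000 photons.
The pixel size is generator-defined, not derived from any instrument.

**Time lapse.** Focus events arrive per cell as a Poisson process (warmed up
before t = 0 so movies start in steady state). Each event ramps up linearly
over `t_assemble_s` (30 s), holds for a drawn persistence time (exponential,
mean 60 s, or fixed), and ramps down over `t_disassemble_s` (45 s) — the
assembly/persistence/disassembly timescales reported for contractile T6SS
sheaths. The default event rate is set so the steady-state expected number
of visible foci per cell equals the snapshot mean (0.343/135 s ≈ 0.0025
s⁻¹cell⁻¹). The event log records true appearance/disappearance times.

## The analysis pipeline

**Segmentation** follows the classic reshaped-stack recipe: the (m, n, z)
stack is reshaped to an m × (n·z) plane; the normalized threshold is the
mean of the sub-Otsu pixels divided by the image maximum; the plane is
median-filtered (3×3), squared to emphasize gradients, rescaled to [0, 1],
edge-detected (Canny, high threshold = the normalized threshold, low = 0.4 ×
high, σ = 1 px), dilated by a radius-1 diamond, hole-filled from the border,
eroded by the same element, and cleaned with a 3×3 majority filter. The Otsu
threshold is computed exactly (discrete maximization of between-class
variance over observed values, ties toward the lower threshold) rather than
on a binned histogram, so it agrees with a brute-force oracle on arbitrary
small integer images.

Two deliberate departures from the literal recipe:

* *Labeling in 3D.* The binarized plane is restored to stack geometry and
  connected components are labelled in 3D (full connectivity), because a
  cell binarizes in several z slices and plane labeling would count it once
  per slice. Plane labeling remains available (`label_mode="plane"`).
* *Robust maximum.* The "image maximum" used for normalization and
  rescaling is the 99.5th percentile by default. On a focus-free
  cytoplasmic channel this equals the maximum (within noise); on a channel
  carrying bright puncta (dual-reporter mask channels) the literal maximum
  is ~4× the cell-body intensity, which collapses the Canny threshold and
  silently drops whole cells. `max_percentile=100` restores the literal
  recipe.

A minimum projected-footprint area (default 50 px ≈ 0.3 µm², far below the
>300 px footprint of any credible cell) removes speck artifacts; this is
the automated stand-in for the manual curation of masks that the original
workflow relied on. Segmentation is fully deterministic.

**Focus detection** is a standard single-molecule-style chain:
difference-of-Gaussians bandpass (σ = 1.0 / 2.5 px), robust threshold at
`median + snr_min × MAD` of the bandpassed image, non-maximum suppression at
3 px, and sub-pixel refinement by background-subtracted centre of mass in a
7×7 window (background = window-border median; a flat window falls back to
the integer peak, flagged). `snr_min` defaults to 600: the MAD of the
bandpassed image is set by the dark background, against which in-cell shot
noise and cell-edge responses reach ~200 MAD units while true foci exceed
~2000, so 600 sits between the two with a ~3× margin on either side. A
relative floor (10% of the peak bandpass response) covers noise-free input,
where the MAD collapses. Detection runs on the maximum-intensity z
projection by default and never uses cross-channel information, so
co-localization statistics are unbiased.

**Per-cell statistics.** Foci are assigned to the label under the rounded
centroid; a focus on background is rescued to a unique label within a 1-px
neighbourhood, else discarded and reported (assigned + discarded = detected,
always). Border-touching cells are excluded from all summaries because they
may be truncated by the field of view. "Single" cells are labels whose
radius-1 diamond dilation touches no other label and which do not touch the
border — the automated version of manual isolated-cell selection; note the
diamond does not reach across corners, so purely diagonal contact does not
disqualify. Summaries report the mean, the {0, 1, 2, 3+} histogram (raw
counts preserved), and the fraction of cells with at least one focus.

**Co-localization.** Object-based: reciprocal nearest-neighbour distances
between the two channels' centroids (2D, in µm), directional co-localized
fractions with strict `< 0.272 µm` comparison, Fig-style distance
histograms, and Venn counts from mutual-nearest-neighbour pairs under the
threshold (each focus in at most one pair). The 0.272 µm threshold is a
configuration constant, not recomputed from optics, since the wavelength/NA
arithmetic behind it is instrument-specific. Intensity-based: Pearson
correlation with Costes thresholding — orthogonal (total-least-squares)
regression of channel 2 on channel 1, candidate thresholds walked down from
the maximum in 1/256 of the dynamic range, the first pair at which the
below-threshold pixels are uncorrelated (r ≤ 0) taken as the thresholds, and
the coefficient reported over pixels above both. When no crossing exists
(e.g. perfectly correlated channels) thresholds fall to the minima; when too
few pixels lie above threshold (e.g. independent noise, where the crossing
happens immediately) the coefficient is computed over all pixels. Both
situations are flagged.

**Dynamics.** Drift registration maximizes circular normalized
cross-correlation against frame 0 after a 5×5 median prefilter (blinking
puncta otherwise dominate the correlation and can out-vote the true
alignment); a frame is flagged and left unshifted unless its correlation
peak is both above an absolute floor (0.1) and a ≥6σ outlier of the
correlation map (a pure-noise map peaks near √(2 ln N) σ ≈ 4σ). Linking is
greedy nearest-neighbour, closest pairs first, displacement ≤ 5 px, gaps
≤ 1 frame, deterministic tie-breaks — adequate at the sparse densities of
sheath reporters (≲1 focus/cell); temporally adjacent events at nearby
positions can chain into one track, a known limitation. Lifetimes are
(last − first + 1) × frame interval; turnover is the fraction of cells whose
has-a-focus state differs between consecutive frames (exactly 0 for an
eventless movie); the cycle period is the mean onset-to-onset interval over
cells with ≥ 2 onsets — simple cycle averaging, not spectral estimation.

## What passing tests do and do not show

The generator emulates the statistical structure of the study system —
focus-count distributions, co-localization geometry, kinetics, PSF blur and
EMCCD noise — but not everything about real data: no deconvolution
artifacts, no uneven illumination or autofluorescence gradients, no
photobleaching, no cell growth or lineage structure, no segmentation errors
from debris or overlapping 3D colonies. End-to-end recovery of the published
numbers therefore validates the pipeline's correctness and calibration under
a faithful forward model, not its robustness to every real-world artifact.

## Problem sizes and numerical choices

The pooled recovery runs use 50 default fields (~4,000 cells, 512×512×13
voxels each) for the population statistics, 20 isolated-mode fields for the
single-cell subset, and 30 dual-reporter fields per partner mode; together
they complete in roughly 6–8 minutes on one CPU, and every statistic is
asserted within three binomial/normal standard errors of its pooled sample.
All randomness descends from a single seed through `numpy` `SeedSequence`
spawning, so every run is bit-reproducible; rendering uses float32
throughout. Degenerate inputs have explicit behaviour: constant images raise
a degenerate-histogram error in Otsu; empty focus sets give flagged,
undefined (not zero) co-localized fractions; flat centroid windows fall back
flagged; featureless frames register as flagged zero offsets.

## Known limitations

Touching cells in microcolonies are segmented as one object (no watershed
splitting, matching the original counting workflow); per-cell statistics on
microcolonies therefore understate cell numbers. Greedy linking is not a
global assignment. Costes thresholding on images without genuine correlation
structure is intrinsically ill-posed and only reported with flags. 3D
co-localization (z-resolved NN matching) is not implemented; distances are
projected.
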