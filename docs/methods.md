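# Methods

This note documents the models, estimators and numerical choices behind
`synecto`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Synthetic scenes

A scene is a set of circular T-cell synaptic footprints (default 5 µm
radius) on a supported lipid bilayer, each depositing a number of
synaptic ectosomes (SE) drawn from a rounded normal (mean 36, sd 3 per
synapse). Vesicle diameters are normal (mean 84 nm, sd 5 nm). Every
vesicle carries a membrane reference label (CD81/WGA) modelled as a
uniformly labelled filled disk (default 60 molecules), plus receptor
microclusters modelled as compact Gaussian clusters (radius ~20 nm, 30
molecules) whose composition follows the vesicle's positivity class.

For a TCR-vs-partner pairing the class of each vesicle is drawn from
{TCR-only, partner-only, double-positive}; the double-positive fraction
is a scene parameter (defaults 0.545 for CD40L, 0.775 for ICOS, 0.75 for
BST2) and the remainder is split equally between the two single-positive
classes — only the double-positive fraction of each pairing is
constrained by observation, so the symmetric split is the least-informed
choice and is exposed as a parameter.

CD40L clusters are laterally offset from the vesicle centre by a draw
from N(150 nm, 15 nm), truncated so the cluster centre stays on the
vesicle; on sub-150 nm vesicles this places CD40L at the rim, segregated
from the central TCR cluster. ICOS and BST2 clusters sit at the centre,
co-clustered with TCR. All geometry is 2-D (the TIRF plane), in nm,
origin at the field corner.

## Photophysics forward model

A labelled molecule (labeling efficiency 0.8) produces
`1 + Poisson(μ − 1)` blink events (default μ = 1.5); each event stays on
for a geometric run of consecutive frames (mean 1.5). Every active frame
emits one localization at the true position plus stage drift at that
frame, plus the inter-channel warp for warped channels, plus isotropic
Gaussian error (default σ = 10 nm). Photon counts are log-normal with
mean 4000 (CV 0.3), so the ≥ 2000-photon inclusion filter and the
consecutive-frame merge rule are both exercised. Fiducial beads are
always on, in every channel, localized 4× better than single molecules.

The raw-frame mode renders active emitters as pixel-integrated 2-D
Gaussian PSFs (σ = 150 nm) on a uniform Poisson background, for fields
up to 256×256 pixels. It deliberately omits EM-gain and read-noise
physics, sCMOS pixel maps, 3-D/astigmatic PSFs and dark-state kinetics:
passing tests show the localization chain is correct for well-separated
emitters with Poisson statistics, not that it handles camera-specific
noise or overlapping PSFs.

## Localization processing

Peaks are strict local maxima above a threshold, deduplicated in 3×3
neighborhoods; sub-pixel positions come from least-squares fits of a
symmetric 2-D Gaussian in a 7×7 window (non-convergent fits are dropped
and counted, not imputed). Localization precision uses the first-order
Thompson estimate σ/√N. The merge rule links localizations in
*consecutive* frames within 1 camera pixel (default 107 nm) into one
photon-weighted localization; chains of arbitrary length are linked by
default, with an optional cap (`max_run=5`) for the stricter reading of
a five-frame limit. Merged precisions scale as 1/√k. Rendering uses
pixel-integrated unit-mass Gaussians at each localization's precision,
so image mass equals localization count up to border truncation.

## Drift and channel registration

Drift is estimated by rendering 500-frame subsets as 2-D histograms
(bin = camera pixel / 5, lightly smoothed), correlating each against the
first subset by upsampled phase cross-correlation (sub-pixel factor
100), and interpolating displacements piecewise-linearly between subset
centres with constant extrapolation. The trajectory is anchored at zero
on the reference segment, so corrected coordinates retain the reference
segment's (irrelevant, constant) drift offset. Subsets with too few
localizations are flagged and interpolated over. Fiducial tracks, when
present in the table, participate in the correlation like any other
localization and substantially stabilise the estimate.

Channel registration fits a least-squares polynomial (order 1 = affine
by default, order 2 available) mapping fiducial bead positions of the
moving (488 nm) channel onto the reference (640 nm) channel; bead
positions are cluster means of the always-on fiducial tracks. The 561 nm
channel is passed through unregistered by default. Numerical inversion
fits the inverse polynomial on a grid (exact for affine). Collinear
fiducials are rejected via a rank check on the design matrix.

## Vesicle segmentation and sizing

Vesicles and receptor microclusters are segmented with DBSCAN
(eps = 50 nm, min_pts = 5 by default; eps sits at the colocalization
search-radius scale and both are configurable).

The size metric is the FWHM of the radially averaged rendered intensity
profile about the cluster centroid (radii sampled at 1 nm over 48
angles; each localization contributes a unit-mass Gaussian at its
precision). Two numerical refinements remove known biases of the naive
FWHM: (i) the half level is taken from a two-pass plateau estimate (mean
of the raw profile inside half the first-pass half-max radius) rather
than the noisy profile maximum, and the profile is smoothed over r at
the rendering width when the cluster has ≥ 10 points; (ii) the observed
FWHM is inverted through the disk ⊛ Gaussian forward model
(`I(r) = ∫ s/σ² exp(−(r−s)²/2σ²) i0e(rs/σ²) ds`, Brent root-finding,
0.01 nm tolerance) at the effective blur √2 × median precision
(localization scatter plus rendering width in quadrature), because the
raw FWHM of a blurred disk under-reports the disk diameter by ~5–10 % at
σ = 10 nm. Degenerate clusters (coincident points, or width at the
rendering floor 2.355 σ) are flagged and report the rendering-limited
width. With these corrections the estimator's bias is within ±4 % for
true diameters 60–120 nm at 10 nm precision (the parameter-recovery
suite checks < 10 %).

Receptor localizations are assigned to the nearest vesicle centroid
within 100 nm (ties, at exact equality, go to the lower cluster id); a
channel is positive when ≥ 3 localizations are assigned — the threshold
rejects single spurious localizations and is a documented sensitivity
parameter. Class percentages are reported over positive vesicles and sum
to 100 exactly.

## Colocalization statistics

**CBC.** Radial step defaults to Rmax/5 (five ranks for the Spearman
correlation, average ranks on ties). The point's own channel count
excludes itself; exactly coincident points in the other channel (the
same emitter seen in both channels, distance < 1 nm) are likewise
excluded from the density, which makes the duplicated-channel control
exactly +1. A point with no own-channel neighbors within Rmax is
undefined and excluded (counted); a point with no other-channel signal
within Rmax contributes 0 (locally uncorrelated). The weighting
`exp(−d_NN/Rmax)` uses the nearest-neighbor distance; the
evaluation-radius alternative is available behind a flag
(`weight_by="rmax"`). Note a known small-sample property: at low
densities the shared 1/r² factor induces a mild positive bias (mean
≈ +0.09 for CSR at 250 points/µm²), which the null-calibration test
bounds at |mean| < 0.1.

**Cross-correlation.** Pair-distance histograms (10 nm bins to 1000 nm)
are normalized by the mean histogram of seeded CSR re-draws of the same
point counts inside the mask (≥ 10 draws required; the re-draws supply
the edge correction for arbitrary masks). Per-bin uncertainty combines
the Poisson error of observed counts with the CSR reference spread. The
reported peak is the most *significant* excess, argmax of
(C(r) − 1)/σ(r), because the raw maximum is dominated by the
lowest-count small-r bins.

**NND** is the exact Euclidean nearest-neighbor distance (k-d tree,
verified against the O(n²) scan), with per-cell medians when cell labels
are provided.

## Cytometry and geometry

MESF calibration fits log10(intensity − blank) → log10(MESF) by least
squares; conversions below blank raise, outside the bead range warn.
GMFIs are geometric means over strictly positive events (non-positive
events dropped with a logged count). Isotype-corrected GMFIs clamp at
zero — transfer cannot be negative — and the clamp is part of the
documented algebra. Molecule numbers divide by the antibody dye ratio.
Sphere area (πd²) is used for vesicles and beads throughout; the T-cell
surface area behind "fraction of cell surface" is an explicit, flagged
assumption (default 410 µm²), not a measurement.

Cytokine arrays: analyte value = mean of duplicate spots / mean of the
array's positive-control spots (cancelling global scale between arrays);
fold change is the ratio to the control condition; analytes missing a
duplicate are excluded with a warning.

## Proteome filtering and clustering

Fold change is LFQ(+ligand)/LFQ(−ligand) per experiment. Missing values
stay explicit: detected only in + means infinite enrichment (kept),
detected only in − means depletion (kept only in two-sided mode; the
default keeps enrichment only). The default threshold is the linear
fold change 3.35 (≈ 1.75 in log2; the two conventions differ in the
third digit and the linear value is used). With
`require_all_experiments` a protein must pass in every experiment.

MCL runs on the dense column-stochastic matrix of confidence weights
with unit self-loops: expansion (matrix square), inflation (entrywise
power 2.5, column renormalization), pruning below 1e-6, to a 1e-8
fixed-point tolerance within 200 iterations (non-convergence raises).
Clusters are read off the attractor rows of the limit matrix, merging
overlapping attractor supports; reported modules have ≥ 3 members.
Deterministic for a fixed input order (nodes are sorted).

## Problem sizes in the test and acceptance runs

The default suites use scenes of 1–5 cells (36 vesicles/cell), 500–5000
frames, 200 vesicles per diameter condition, 100 seeds for the
displacement-recovery scan, 10 seeds for CSR nulls, 2000 events per
cytometry population and 300-protein proteomes; positivity percentages
are pooled over three scenes per pairing (~500 vesicles) so their
sampling error is ~2 points. These sizes give sampling errors comfortably
inside the stated tolerances while keeping a full run to tens of seconds.

## Limitations

* The generator produces circular vesicles with uniform membrane label;
  real SE have size-dependent label density, partial antibody occupancy
  and clustering of the reference stain itself. Passing recovery tests
  therefore validate the estimators under the stated model, not antibody
  or labelling artefacts.
* The diameter deconvolution assumes the precision column honestly
  reflects localization scatter; miscalibrated precisions bias the
  correction.
* Drift estimation assumes structure-rich fields (vesicles and/or
  fiducials); featureless fields give noisy trajectories.
* The cross-correlation mask is rectangular (or any object exposing
  `area`/`sample`); pixel-mask geometries can be added through the same
  interface.
* No FCS binary parsing, compensation or gating; cytometry inputs are
  CSV event tables or precomputed GMFIs.
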