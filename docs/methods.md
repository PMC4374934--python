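# Methods

This note documents the models, conventions and numerical choices behind
`retinaquant`, and what the synthetic-data generators do and do not
emulate.

## Coordinate and angle conventions

All wholemount coordinates are retina-centred millimetres with the optic
disc at the origin; for a left-eye wholemount viewed from the vitreal
side, +y is superior (dorsal) and +x nasal, so the temporal pole lies on
−x. Angles use the *retina convention*: 0° at the temporal pole,
increasing counter-clockwise in that view (90° superior, 180° nasal,
270° inferior). The four radial relieving cuts that orient a wholemount
are carried as geometry metadata, with the deepest cut marking the
superior pole. Images use 0-based pixel indices with the origin at the
top-left; all mm↔pixel conversions go through one pair of inverse
functions (`geometry.mm_to_px` / `px_to_mm`, inverse-consistent to
1e-12).

## Synthetic wholemounts

Cell populations are inhomogeneous Poisson point processes on a disc of
radius 2.2 mm (a typical adult C57BL/6 wholemount; configurable). The
realised count is Poisson with mean `target_total`; positions are drawn
from the normalised intensity by rejection sampling against the uniform
disc measure, so a fixed seed gives bit-identical patterns.

Density profiles:

- `radial_linear` (default for traced/Brn3a⁺ RGCs and GCL nuclei):
  intensity decreasing linearly with eccentricity at a 2:1
  centre-to-edge ratio. Real retinas are only known qualitatively to be
  denser medially than peripherally; the 2:1 linear form is this
  package's concrete choice.
- `dorsotemporal` (default for melanopsin⁺ RGCs): the radial profile
  modulated by a cosine bump `(1 + b·cos(θ − θ₀))/(1 + b)` centred at
  45° (middle of the dorso-temporal quadrant) with a 2:1 peak:trough
  ratio (b = 1/3).
- `uniform`, used by oracle tests with closed-form expectations.

Default population targets are the control-group means this kind of
study reports: 38,479 traced RGCs, 37,904 Brn3a⁺ RGCs, 1,059
melanopsin⁺ RGCs, and 45,471 non-RGC GCL nuclei per retina.

**Lesions.** Sectorial damage is a list of pie-shaped wedges
(start, span, loss fraction) with apex at the optic disc; a cell inside
a wedge is removed independently with the wedge's loss probability, and
overlapping wedges compose as `1 − Π(1 − fᵢ)`. Diffuse loss then
removes each survivor with a second independent probability —
spatially uniform by default; an eccentricity-proportional
(mean-preserving) variant is available because the spatial structure of
diffuse loss is not established. Lesioning is a strict thinning:
survivors keep their exact coordinates, which the tests assert exactly.

**Fluorescence tiles.** Frames of 0.45 × 0.34 mm (a 20× field stand-in;
the true field size is instrument-specific) tile the requested region
side-by-side with no gap or overlap, at 0.001 mm/px. Each cell is
rendered as a Gaussian blob (σ = 1 px default — a point-like label
centroid rather than a resolved soma) of amplitude 1,000 counts on a
100-count background, with optional Poisson shot noise plus Gaussian
read noise (σ = 10 counts) — the default noise model. Ground-truth
positions travel with the tiles as a sidecar. What this does **not**
emulate: soma shape and size variation, uneven illumination and
vignetting, out-of-focus light, labelling-intensity heterogeneity, and
the hard-core spacing of real somata (points may fall arbitrarily
close). Detection scores on these images therefore measure the
detector's behaviour under Poisson crowding and shot noise, not its
performance on real micrographs.

**SC profiles.** Per-section labelled areas over Bregma −3.08 to −4.72
mm at 30 µm spacing are a smooth baseline (default: raised-cosine dome
peaking at 0.9 mm²) multiplied by patch attenuations
(bregma interval × loss fraction) and optional multiplicative lognormal
noise (mean-one, given CV). Sections can be flagged unusable to emulate
mounting artefacts.

**IOP series.** A linear rise from baseline (15 mmHg) to the designed
peak at 24 h, then exponential decay (τ = 36 h) back to baseline within
the week, sampled on a standard tonometry schedule. Noise (σ = 0.5
mmHg) is added everywhere except the peak sample and the series is
clipped at the designed peak, so the designed peak value and time are
exact by construction — the property the inclusion-filter tests rely
on.

## Cell detection

The detector is a conventional, fully specified blob-counting chain
standing in for the proprietary macros used historically:

1. band-pass enhancement `G(σ/2) − G(2σ)` of the montage (the narrow
   sigma is deliberately below the blob scale to preserve two-point
   resolution of close pairs; the wide sigma subtracts background),
2. threshold: Otsu on the enhanced image (default) or a fixed value,
3. candidate peaks: strict 3×3 local maxima above threshold,
4. an area filter on the thresholded component supporting each peak
   (defaults 3–500 px),
5. sub-pixel centroid: intensity-weighted mean of the
   thresholded-excess image over a ±1σ window (a tight window keeps
   centroids of adjacent cells from biasing toward each other),
6. merge of centroids closer than `min_separation_px` (default 0.5 px):
   larger integrated intensity wins, ties resolve by lexicographic
   pixel order.

Blank or saturated montages return an empty result with a logged
warning rather than raising. Detection is deterministic and
translation-equivariant; at the 4,000 cells/mm² density used in the
acceptance checks it achieves ≥ 95% recall and precision against the
generator's ground truth (matching one-to-one within 2σ of the blob
scale). The residual misses are dominated by Poisson close pairs that
no single-scale detector can split.

In-contour counting uses exact polygon membership with a **closed
boundary** (points exactly on the contour count as inside);
self-intersecting contours are rejected.

## Topography

**Isodensity grids** use square bins (default 0.1 mm — comparable to
published map granularity while keeping tens of cells per bin at
control densities) aligned to the contour's bounding box. Only
in-contour cells are binned, so the grid total equals the in-contour
count exactly; each density is count over the *contour-clipped* bin
area, and bins wholly outside the contour are NaN (undefined, not
zero). The colour scale is linear in 12 steps from purple (0) to red,
saturating at 4,800 cells/mm² (RGCs) or 9,200/mm² (GCL nuclei).

**Neighbour maps** count, for each cell, the other cells within 0.165
mm (closed ball, ties at the radius included; the open/closed choice is
this package's convention, as is excluding the focal cell itself).
Implementation uses a k-d tree but is exact; tests require bit-equality
with an O(n²) pairwise oracle. No edge correction is applied;
expected-value checks are restricted to interior cells.

**Wedge loss profiles** divide the disc into 24 equal sectors (15°, so
even a small pie-shaped sector spans at least one wedge) and compute
per-wedge loss `1 − n_exp/n_ctrl` (NaN where the control wedge is
empty). The *detected sector* is the maximal circular run of contiguous
wedges with loss above a threshold: 0.8 by default ("few to none"
surviving cells), or an adaptive half-of-maximum rule (floored at 0.2)
when `threshold=None`, which also recovers partial lesions; the
sector's loss estimate is the control-count-weighted mean loss over the
run. Over 60 simulations (38,000 cells, single 90° wedge,
f ∈ {0.5, 0.8, 1.0}) the recovery error is ≈ 0.002 in f and below one
wedge in span.

## SC volumetry

`SCInnervationModel.fit()` least-squares fits an order-5 polynomial to
the usable sections only (at least degree + 2 required), with the
abscissa recentred to the midpoint of the usable Bregma span for
conditioning; coefficients are reported in both the centred and raw
bases, making the volume invariant to uniform Bregma shifts. r² is
`1 − SS_res/SS_tot` on the raw response; constant data (SS_tot = 0) is
treated as a degenerate perfect fit (r² = 1). Fits with r² ≤ 0.78 — at
or below the quality regime reported for real serial-section data — are
flagged with a warning, not rejected.

The volume is the closed-form antiderivative of the fitted polynomial,
integrated piecewise between its real roots with negative lobes clipped
to zero (areas are physical; the clipping rule is this package's
choice). Integration defaults to the usable-section span rather than
the nominal atlas range, avoiding extrapolation; a reversed range
integrates over its absolute span with a warning. Percent innervation
is `100·V_treated/V_control` over a common span (plus its
deafferentation complement); a zero control volume is an explicit
error.

## Cohort statistics

- **Inclusion**: an animal enters the cohort only if its treated-eye
  IOP peak is *strictly greater* than 25 mmHg within the first 48 h;
  missing tonometry excludes the animal, and every exclusion is logged
  with its reason.
- **Summaries**: arithmetic mean and sample SD (n − 1); singleton
  groups report SD 0 with n = 1 visible.
- **Percentages** are computed from group means (not means of
  per-animal ratios) and rounded half-up to integers for reporting —
  the convention that reproduces the published headline percentages
  from the published group means.
- **Mann–Whitney U**: exact whenever n₁ + n₂ ≤ 16. The tie-free path
  computes the full rank-sum null distribution by dynamic programming;
  tied data are handled by enumerating all C(n₁+n₂, n₁) group
  assignments with midranks. The two-sided exact p doubles the smaller
  tail, capped at 1; all-tied data give p = 1 with a warning. Larger
  samples use the tie-corrected normal approximation. Sidedness
  defaults to two-sided (configurable); no multiple-testing correction
  is applied by default (α = 0.05 per comparison), with Holm available.
- **Kruskal–Wallis** (≥ 3 groups, guarded otherwise) uses the
  tie-corrected H with a χ² p-value on k − 1 df.
- **Correlation** reports squared Pearson r with slope/intercept;
  zero-variance input is an explicit error.

## Pipeline and reproducibility

One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence`; every artifact is recorded in a manifest
with its SHA-256 hash, and identical config + seed reproduces artifacts
byte-for-byte. Configurations are strict (unknown keys rejected) and
round-trip losslessly through YAML.

## Problem sizes

The test suite and acceptance script run at the sizes the analysis is
designed for: full-retina patterns of ~38,000 cells (60 lesion-recovery
simulations, 3 end-to-end 7-animal cohorts), 5,000-cell
neighbour-oracle checks, 55-section SC profiles, and a 2×2-frame
(0.9 × 0.68 mm, ~2,500-cell) detection field at 4,000 cells/mm² —
detection is scored on a representative patch rather than all 140
frames of a whole retina because recall and precision are
density-governed and a full montage adds no information to the check.

## Known limitations

- The detector is a declared stand-in: the historical macros'
  size/intensity criteria are not public, so defaults here are chosen
  for the synthetic rendering model, not claimed faithful to any
  specific instrument.
- The isodensity bin geometry (0.1 mm squares) is likewise a concrete
  choice where published maps state only the method family.
- Generator defaults (density contrast, noise levels, IOP curve shape,
  SC baseline) are field-plausible single choices, not fitted to any
  dataset; conclusions from passing tests transfer to real data only to
  the extent these assumptions hold.
- Percent-loss from group means and half-up integer rounding are
  reporting conventions; other conventions (per-animal ratios) give
  slightly different numbers.
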