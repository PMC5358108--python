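# Methods

`lamina` quantifies laminar (concentric-layer) organisation in single
2D fluorescence sections of re-aggregated retinal organoids.  The
analysis chain is: aggregate segmentation from DAPI → radial intensity
profile in concentric bands → normalised density and ECDF on a common
radial axis → area-between-curves lamination score → non-parametric
group comparison.  A seeded synthetic generator provides images with
known ground-truth organisation for testing and calibration.

## Segmentation

The aggregate footprint is found on the DAPI channel with a two-phase
Chan-Vese active contour (morphological ACWE, `scikit-image`), started
from a centred disk covering 25% of the frame.  The DAPI image is
first blurred with a Gaussian (`presmooth_sigma`, default 2 px) so
that individual nuclei merge into one region.  The contour evolves in
chunks of 20 iterations and stops when the level set is stationary,
up to a budget of 200 iterations.  The phase with the higher mean DAPI
intensity is taken as foreground, then: largest connected component →
hole filling → morphological opening (radius 2 px), re-asserting the
single-component/no-hole invariant afterwards.  A result smaller than
`min_area` (64 px) raises "no aggregate found", as does a constant
image.  These defaults were fixed by requiring IoU ≥ 0.90 against
ground truth across the synthetic noise grid (Gaussian read noise
σ ∈ {0, 5, 10} × shot noise on/off); they achieve ≈ 0.98 there and are
all overridable via `SegmentationParams`.

Manual masks (any two-valued PNG/TIFF) are accepted as an alternative
route — e.g. to exclude dead, non-fluorescent cells stuck to the
aggregate exterior; they are thresholded at half maximum, reduced to
the largest component and hole-filled.  There is no automatic debris
classifier.

## Radial profiling

Within the mask, the Euclidean distance transform `d` to the nearest
background pixel defines isocontours of depth; `d_max` is the deepest
point (the effective centre).  Two band constructions are available:

* **periphery** (default): pixel with outline distance `d` joins band
  `floor(d / w)`; the band's radial coordinate is `d_max` minus the
  midpoint of its distance interval, so the axis runs centre →
  periphery.  Bands follow the aggregate's actual outline, which makes
  the profile robust to non-circular shapes.
* **centroid**: circular crowns of width `w` around the mask centroid.

Band width defaults to `w = 5` px.  Every in-mask pixel belongs to
exactly one band (the band at the far end of the distance range may be
narrower than `w`; an exact partition is preferred over equal widths);
each band reports the arithmetic mean of every channel.  Empty bands
are dropped — profiles are later interpolated onto a common grid, so
gaps are benign.  For an unperturbed disk the two modes agree to
within a band; for elongated shapes with boundary-parallel structure
the periphery mode preserves a sharper ring, which is why it is the
default.

The radial axis is reported with 0 at the centre, so a centrally
enriched channel has its mass at small radii and its ECDF shifted
left of the diagonal.

## Normalisation, ECDF and the lamination score

Band radii are rescaled linearly to x ∈ [0, 100] radial units (ru) and
the samples are extended to the endpoints by constant continuation
(no gradient is invented beyond the outermost bands).  Each channel is
divided by its trapezoidal integral, making it a density of
fluorescence over radius (units 1/ru); the cumulative trapezoidal
integral is the channel's ECDF, pinned to F(0) = 0 and F(100) = 1.
A spatially uniform channel yields the diagonal F(x) = x/100, whose
area beneath is exactly 50 ru.

The lamination score is

    score = ∫₀¹⁰⁰ F_CFP dx − ∫₀¹⁰⁰ F_GFP dx   (ru; range −100 … 100)

positive when the CFP (Crx) signal is more central than the GFP
(Ptf1a) signal.  The sign is kept (no absolute value) so the direction
of lamination is preserved.  RFP (Atoh7) and any other channels are
profiled and reported (`area_beneath`, deviation from 50) but never
enter the score.  Images with a dark central core are scored exactly
like any other image — the core is not masked out.

Numerical notes: curves on different grids are linearly resampled onto
the union grid before subtraction; a single-band profile cannot be
rescaled and is rejected; an all-zero channel is rejected by name;
the ECDF's residual from 1 at x=100 (float round-off) is renormalised
away.

## Group statistics

Cohort profiles are linearly interpolated onto a fixed 101-point grid
(unit ru resolution) and averaged pointwise; the error band is the
standard error of the mean by default (sample SD optional).

Score comparisons use the two-tailed Mann-Whitney U test with half
credit for ties: exact (full enumeration of the null distribution)
when n₁ + n₂ ≤ 25 and the data are tie-free, otherwise the normal
approximation with tie and continuity correction.  Both paths can be
forced; at n₁ = n₂ = 15 they agree to < 0.01 in p for tie-free data.

## Synthetic data generator

The generator emulates single confocal sections of aggregates from a
three-reporter retinal line: CFP-positive cells central, GFP-positive
cells in a ring, RFP broadly distributed, DAPI positive throughout
the tissue.  Components:

* **Footprint** — a radially perturbed circle
  r(θ) = R·(1 + Σ_{k=2..5} a_k cos(kθ+φ_k)); the harmonic amplitudes
  are drawn from the seeded generator and normalised so their absolute
  sum equals `shape_perturbation`, keeping the boundary inside
  R·(1 ± shape_perturbation).
* **Cells** — four classes (CFP-only, GFP+RFP, RFP-only, CFP+RFP).
  With probability λ (`organization`) a cell is placed uniformly in
  its class's radial zone (CFP classes: normalised radius < `r_inner`;
  GFP class: `r_inner`–`r_outer`; RFP-only: anywhere), else uniformly
  anywhere in the mask.  The normalised radius of a pixel is
  1 − d/d_max, matching the profiling geometry.  Per-cell, per-channel
  amplitudes are log-normal with coefficient of variation
  `amplitude_cv`.
* **Rendering** — each cell stamps an isotropic Gaussian blob
  (σ = `cell_radius`/2) into its positive channels and DAPI; band
  means are all the pipeline measures, so sub-cellular morphology is
  deliberately not modelled.  DAPI additionally carries a uniform
  tissue term inside the mask (`dapi_tissue_level`), because real
  aggregate tissue is densely nucleated and DAPI-positive throughout —
  without it the synthetic DAPI would be unrealistically sparse and
  unsegmentable.  An optional non-fluorescent central core (pigment
  epithelium-like) zeroes the fluorescence channels — not DAPI —
  inside a disk of radius `core_radius_fraction`·R before noise.
  Optional debris blobs (dead-cell clumps) are rendered just outside
  the boundary into the DAPI channel only, where they can mislead
  segmentation; they carry no fluorophore signal.
* **Noise** — Poisson shot noise (gain `poisson_gain`, 0 disables)
  followed by additive Gaussian read noise, clipped at zero.

Defaults (chosen once to mimic published aggregate proportions at
reduced resolution, all overridable): 512×512 frame, R = 120 px,
`shape_perturbation` 0.08 (roughly circular, slightly irregular
aggregates), `r_inner` 0.55, `r_outer` 0.85, 60/60/40/60 cells,
`cell_radius` 6 px, amplitude 100 with CV 0.3, background 5, DAPI
tissue level 60, read noise σ = 2, Poisson gain 1, core fraction 0.12
(a small central pigment cluster), debris off.  No physical pixel size
is asserted; all geometry is in pixels.

All randomness derives from `SyntheticConfig.seed` via
`numpy.random.SeedSequence` (PCG64): sub-streams 0/1/2 for footprint,
placement and rendering, and cohort item i uses the i-th spawned child
of the root sequence, so cohorts are reproducible and items
independent.

### What the generator does and does not emulate

It reproduces the radial class zoning, channel semantics, rough
geometry and detector noise of the study system; it does not model
cell crowding, membrane-localised (ring-like) fluorophores, rosettes,
optical-section thickness, illumination gradients or autofluorescence.
Passing tests on synthetic cohorts therefore demonstrate that the
pipeline measures radial organisation correctly under known ground
truth — not that real images of any particular quality will segment
at the same IoU.

A consequence worth knowing: synthetic cohorts are far more
homogeneous than real ones (within-group score SD ≈ 1–2 ru).  Because
the radial profile is a per-unit-radius density, a non-fluorescent
central core removes a first-order fraction (≈ r_core/r_inner) of the
CFP mass and shifts the score by several ru; against the generator's
tight variance, a 15-vs-15 Mann-Whitney comparison detects this
reliably, whereas on real data the same contrast is swamped by
biological variability.  The ± core comparison on synthetic cohorts is
thus a sensitive detector of the core itself, not a null comparison.

## Problem sizes used in tests

Unit tests run on reduced geometry (256 px frame, R = 60, half the
cell count); the end-to-end statistical checks use the default
512 px geometry with 15 aggregates per group, and the
organisation-recovery check uses 20 seeds per λ ∈ {0, 0.5, 1} on
ground-truth masks.

## Known limitations

* Single 2D sections only; no z-stack handling or central-section
  selection.
* No background subtraction or flat-field correction.
* Scores are comparable only between runs using the same band mode
  and width; the score's absolute scale (ru on the 0–100 axis) is a
  convention of this implementation.
* The Chan-Vese defaults were calibrated on the synthetic generator;
  real micrographs may need `presmooth_sigma`, `init_shape` or the
  iteration budget adjusted, or a manual mask.
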