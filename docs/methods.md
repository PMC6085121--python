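# Methods

## Coordinate model

A cell is a 3D binary support Ω (multi-page TIFF, one page per z-plane)
with voxel sizes (µm per pixel laterally, µm per z-step); z indices are
multiplied by the anisotropy ratio before any Euclidean distance.  The
reference frame — origin O and a θ = 0 direction in the xy-plane — is
biological input (Golgi/ERC centroid, micro-pattern axis).
`geometry.default_frame` supplies the mask centroid and xy principal axis
as an explicitly labeled fallback when no biology is available.

Events are mapped to (r, θ, z) about O with two boundary distances per
event:

- **Angular boundary distance d_θ**: a ray is marched from O (projected on
  the event's plane) along the event's direction in 0.25-voxel steps with
  nearest-voxel membership tests; the crossing is placed midway between the
  last inside and first outside sample (the linear interpolant of a binary
  field).  This gives sub-voxel accuracy at ~0.1 voxel bias, verified
  against analytic disk and square geometry.
- **Axial boundary distance d_z**: the 3D distance from O to the topmost
  foreground voxel of the z-column at the event's lateral position.  A
  mask's surface generally has two sheets above/below a lateral point; the
  top sheet is the default (`axial_surface="top"`), appropriate for flat
  adherent cells imaged from the coverslip, with `"nearest"` available for
  rounder geometries.

Normalized coordinates are r_norm = r/d_θ ∈ [0, 1] and z_norm = the event's
height above its column's bottom divided by the column height.  r_norm may
exceed 1 by rasterization slack for events on ∂Ω; values in (1, 1.05] are
clipped, larger values raise (they indicate a frame/mask mismatch).  d_z is
floored at 1e-3 voxels: an event exactly at the origin of a single-plane
mask would otherwise have d_z = 0, and the floor only affects that
measure-zero configuration.  Events at r = 0 take θ = 0 by convention.
Boundary voxels are those 6-adjacent to background or to the grid edge; a
single-plane mask is therefore all boundary, which is the correct flat-cell
degenerate case.

## Density estimation

Three densities per cell: f(r) and f(z) by Gaussian KDE on [0, 1], f(θ) by
von Mises KDE on the circle, each with per-event weight w·d_θ (radial,
angular) or w·d_z (depth).  Boundary-distance weighting makes events
represent the cell volume behind them; together with the normalized
coordinates this is what makes densities comparable across cell shapes
(tested: the same normalized draws pushed into a disk and a crossbow give
nearly identical radial densities).

Numerical choices:

- **Edge correction**: Gaussian kernels are reflected at both ends of
  [0, 1], so the mass of peripheral events (the docking zone near
  r_norm = 1) is not underestimated.
- **Bandwidths**: Silverman's rule 0.9·min(σ_w, IQR_w/1.34)·N_eff^(−1/5)
  with weighted moments and effective sample size N_eff = (Σw)²/Σw²
  (reduces to the textbook rule at unit weights); zero-variance samples get
  a floor of 1e-3 of the support width with a warning.  The von Mises
  concentration follows Taylor's (2008) plug-in rule
  κ̂ = (3·N_eff·κ̂₀²·I₂(2κ̂₀) / (4√π·I₀(κ̂₀)²))^(2/5), with κ̂₀ obtained by
  inverting the Bessel ratio I₁/I₀ at the weighted mean resultant length
  (bisection to 1e-8).  The Bessel ratio is evaluated with exponentially
  scaled functions so the rule stays finite for tightly concentrated
  samples; κ is capped at 1e6.  Single-event sets get nominal smoothing
  (σ = 0.05, κ = 10).
- **Normalization**: the analytic normalization constants make the kernel
  sum a relative density only; every returned density is renormalized to
  unit integral (trapezoid rule on [0, 1], periodic Riemann sum on the
  circle), which is the contract transport distances need.
- **Grids**: K = 100 (linear) and K = 360 (circular) evaluation points;
  each density carries the K-bin weighted histogram it smooths.

Intensity weights are honored when the events file has a `w` column
(`--weights none` disables them).  Note that fluorescence intensity is a
proxy for molecule counts that photobleaching and focus drift can distort;
weighting is the user's modeling decision, not a package default.

## Trajectory layer

The gated distance between two tracks sums min(per-frame distance, ε) over
the union of their frame supports; frames covered by only one track
contribute the gate ε, penalizing length mismatch (the bare formula is
silent on unequal lengths).  Tracker consensus: with track sets from ≥ 2
trackers, the first set is the reference; reference tracks are matched
one-to-one to each other method greedily by ascending per-frame mean gated
distance (ε = 5 px), and a track is kept iff its match in at least one
other method is below 2 px per frame — i.e. the trajectory was found by at
least two methods in total.  The threshold is applied to the per-frame mean
rather than the raw sum so that it is invariant to track length; a summed
threshold of 2 px would reject essentially every multi-frame track with
sub-pixel localization jitter.

Dynamic features: confinement ratio (net displacement over path length,
in [0, 1]; a stationary track is defined as ratio 1 with a warning — a
point that never moves is maximally direct), total path length (µm), and
lifetime ((t_last − t_first)·dt seconds).  A track is localized by the
normalized cylindrical coordinates of its median point (index ⌊(n−1)/2⌋ of
the time-ordered track).  Direction classes compare the endpoints'
normalized radii; exact ties (purely tangential motion, |Δr_norm| < 1e-9)
fall to `toward_center` and are counted separately so the user can see how
many tracks carried no radial information.

Per-bin feature averages (20 linear / 36 circular bins by default) are
kernel-smoothed over the axis support — nonempty bin centers carry their
mean feature as weights; empty bins are skipped, never zero-filled, since a
bin with no tracks is missing data, not a zero feature — and the smoothed
profile is renormalized to unit mass so that profile shapes can be compared
with the same transport distances as spatial densities (the raw per-bin
average is not a probability density).

## Condition comparison

Densities are compared with EMD on linear axes (sum of |ΔCDF| over the
grid, in bin units) and CEMD on the angular axis (minimum over cumulation
start bins, equivalently min_k Σᵢ |D(i) − D(k−1)| with D the CDF
difference; rotation invariant).  All densities in a study share one grid
size, fixed study-wide, because EMD magnitudes scale with the bin count.

For each experiment, intra = mean distance to its own condition's other
replicates, inter = mean distance to all other conditions pooled, and
Δₑ = inter − intra.  The one-sided Wilcoxon signed-rank test (median Δ > 0)
drops zeros, uses the exact null up to n = 25 without ties and the normal
approximation with continuity correction otherwise, and warns below 5
nonzero differences.  Per-axis p values are reported without
multiple-testing correction — the three axes answer distinct scientific
questions and are printed side by side; users testing many features should
correct downstream.

The same-condition control randomly splits one condition into two
pseudo-conditions (larger half takes the extra experiment at odd counts)
and reruns the full procedure per split; exchangeable replicates give p
values centered near 0.5.  It is a calibration diagnostic, not a test: the
Δₑ of a split share the same distance matrix and are positively dependent,
so the p distribution is not exactly uniform, only centered.

## Organizing-center search

If events are emitted isotropically from a source, the angular density
seen from the source is flat, so the source is estimated as the origin
maximizing the entropy of the angular density.  The estimator recomputes,
for each candidate origin, the event angles and the plug-in concentration,
and takes the differential entropy −Σ_g f(θ_g) log f(θ_g) Δθ of the
resulting density on a 360-point grid.  Unlike the spatial densities, the
entropy criterion omits the d_θ boundary-distance weighting: an isotropic
source sees uniform angles whatever the cell outline, whereas d_θ weights
tilt the density toward the cell's far side and drag the entropy maximum
toward the centroid for off-center sources (a measured ~1.7-voxel bias at
an 8-voxel offset); user-supplied event weights w are honored.
The point-wise sum over event angles −Σᵢ f(θᵢ) log f(θᵢ) is available as an
alternative (`use_grid=False`) but is not the default: −x log x peaks at
x = 1/e, which exceeds the uniform level 1/2π, so that sum is maximized by
mildly concentrated densities and does not localize an isotropic source —
the plug-in entropy does, and recovers planted centers to within the
lattice resolution.

The exhaustive entropy map evaluates a lattice (step ≥ 1 voxel) restricted
to one z-plane (TIRF-like data; full-3D search is a straightforward
extension the map API admits).  The accelerated search is hierarchical
refinement: a coarse lattice at 1/8 of the mask bounding box, then a 5×5
window recentered on the best candidate with the stride halved until it
drops below a voxel.  It is deterministic, derivative-free and, on the
unimodal entropy surfaces isotropic sources produce, reaches ≥ 99% of the
exhaustive maximum at a fraction (typically < 1/100) of the evaluations.
Multiple organizing centers are out of scope, but the map output exposes
secondary maxima for inspection.  Tracking the center per frame and
reporting ‖O*(t) − O*(0)‖ (averaged across cells) follows the drift of the
organizing component over time; frames with < 2 events yield missing
values without breaking the series.

## Synthetic data

The generator rasterizes disk, square, ellipse and crossbow supports (the
crossbow is a stylized stand-in for the micro-pattern: a disk with three
lobes at 0, ±2π/3 — only its symmetry and non-circularity are relied on),
flat-extruded or dome-shaped (distance-transform superlevel sets shrinking
with height like a spherical cap).  Events are drawn directly in normalized
coordinates — uniform or beta radii and depths, uniform/von Mises/mixture
angles, unit or lognormal weights — and pushed into the mask by inverting
the normalization through the same ray-cast boundary distances the analysis
uses, with samples kept half a voxel inside the edge and a rejection loop
(capped at 1e5 draws) for rasterization stragglers.  Trajectories are
radially biased random walks with Gaussian step noise and known
outward/inward labels.  All randomness flows from explicit seeds;
generators return ground-truth records alongside the data.

What the generator does *not* emulate: detection noise and false positives,
anisotropic point-spread blur, photobleaching, moving or deforming cell
outlines, and spatially correlated event clusters.  Passing tests therefore
demonstrate that the estimators recover known generative structure through
the full coordinate/density/distance pipeline, not that detection artifacts
in real microscopy are harmless.

## Problem sizes and defaults

Synthetic studies use 8 replicates per condition with n = 300 events per
replicate (typical of per-cell event counts in trafficking movies), planted
angular effects of π/2 at concentration κ = 4, calibration runs of 100–200
studies, 100-split controls, center recovery at n = 500 events over 20
seeds, and drift tracking at 1 voxel/frame over 10 frames averaged over 3
cells.  The chosen sizes keep the full verification suite in the
few-minute range on a single core while leaving each statistical check
comfortably powered.

## Known limitations

- d_θ is ray-cast on the event's z-plane against that plane's outline;
  strongly overhanging 3D shapes where the outline is not star-shaped about
  O get the first crossing, which may undercut distant pockets of the same
  plane.
- The Wilcoxon test treats replicate Δₑ as exchangeable; they share one
  distance matrix and are mildly dependent, which the null-calibration
  check bounds empirically (≤ 10% rejection at the 5% level) but does not
  remove.
- CEMD is computed on the common grid; sub-bin mode shifts smaller than
  the angular grid step are invisible by construction.
- The entropy search assumes a single organizing center; with several
  sources the map shows multiple maxima but the argmax picks one.
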