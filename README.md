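# quantev

Quantitative comparison of the spatio-temporal distribution of
intracellular events — detected vesicles, segmented membrane compartments,
particle trajectories — across experimental conditions, independent of cell
shape and size.

Fluorescence microscopy of trafficking reporters (e.g. Rab6 on exocytic
carriers, Rab11 on recycling carriers) yields point events and tracks inside
cells whose outlines vary wildly, so raw coordinates from different cells
cannot be pooled or compared.  `quantev` normalizes each event's position by
the cell's own geometry, summarizes the result as one-dimensional densities,
and compares conditions with transport distances and a replicate-aware
non-parametric test.

## Model

Each event *i* inside the 3D cell support Ω is written in cylindrical
coordinates (rᵢ, θᵢ, zᵢ) about a biological reference point O (Golgi or ERC
centroid, or a micro-pattern axis), with θ measured from a reference
direction.  Two ray-cast boundary distances normalize the position:
d<sub>θᵢ</sub>, the distance from O to the cell edge ∂Ω along the event's
angular direction, and d<sub>zᵢ</sub>, the distance from O to the top
surface point above the event's lateral position.  Three weighted kernel
densities summarize an event set S = {(rᵢ, θᵢ, zᵢ, wᵢ)}:

- f(r) on the normalized radius rᵢ/d<sub>θᵢ</sub> ∈ [0, 1] — Gaussian
  kernels, reflected at the support boundaries;
- f(θ) on [0, 2π) — von Mises kernels
  H<sub>κ</sub>(θ) = e<sup>κ cos θ</sup>/(2π I₀(κ));
- f(z) on the normalized depth ∈ [0, 1] — Gaussian kernels.

Event *i* enters with weight wᵢ·d<sub>θᵢ</sub> (radial, angular) or
wᵢ·d<sub>zᵢ</sub> (depth), so peripheral events in wide sectors count for
the cell area they represent.  Bandwidths follow Silverman's rule of thumb
and Taylor's circular plug-in rule, adapted to weights through the effective
sample size (Σw)²/Σw².

Densities from different cells are compared with the 1D Earth Mover's
distance EMD(f₁, f₂) = Σᵢ |F₁(i) − F₂(i)| (cumulative sums on the grid) and
its circular version CEMD, which minimizes over the cumulation start bin.
For a study with replicate experiments under ≥ 2 conditions, each
experiment *e* gets a condition difference
Δₑ = inter(e) − intra(e) — its mean distance to the other conditions minus
its mean distance to its own replicates — and a one-sided Wilcoxon
signed-rank test asks whether the Δₑ are systematically positive.

Trajectories carry dynamic features (confinement ratio, total path length,
lifetime), are cross-validated across trackers with a gated frame-wise
distance, classified as moving toward the periphery or the center, and
averaged per spatial bin into smoothed feature profiles.  When events are
emitted isotropically from an organizing component, its location is
estimated as the origin maximizing the entropy of the angular density,
either on an exhaustive lattice (entropy map) or by hierarchical refinement.

## Worked example

Simulate a cell, estimate densities, and find the organizing center:

```bash
quantev simulate --shape disk --size 25 --n-events 200 --seed 3 --out demo
quantev density --mask demo/mask.tif --events demo/events.csv \
    --origin 28,28,0 --out demo
quantev uniformity --mask demo/mask.tif --events demo/events.csv --out demo
```

The last command prints

```
O* = (27.3, 27.3, 0), entropy 1.8379
```

i.e. the entropy-maximizing origin lands within a voxel of the generating
center (28, 28) of the simulated isotropic event cloud, and the entropy is
close to log 2π ≈ 1.8379, the value of a perfectly uniform angular
distribution.
`demo/density_*.csv` hold the three densities with their histograms;
`demo/center.json` records the search result and its candidate count.

A two-condition comparison takes a YAML study config mapping condition
labels to replicate entries (mask, events, origin, direction) and reports
per-axis p values:

```bash
quantev compare --study study.yaml --out report.json
# radius: p = 0.2188
# angle: p = 0.01562 *
# depth: p = 1
```

Here only the angular distribution differs between conditions (the
simulated effect was an angular mode shift); the radial law was identical,
and single-plane (TIRF-like) masks make the depth axis fully degenerate
(identical densities, p = 1 with a warning).  `quantev control --study study.yaml --condition ctrl`
runs the same-condition random-split control whose p values should center
near 0.5.

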