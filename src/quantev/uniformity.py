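"""Entropy-based search for the event-organizing center.

If intracellular events are emitted isotropically from some organizing
component (e.g. the endosomal recycling compartment), the angular density
seen from that component is flat — and the entropy of the angular density is
maximal there.  The center is therefore estimated as the candidate origin
O* inside the cell support that maximizes the entropy of the weighted von
Mises density f(. | O) of the event angles seen from O, by default the
plug-in differential entropy

    H(O) = - integral f(theta | O) * log f(theta | O) dtheta,

which is uniquely maximized by the flat density.  (The point-wise sum
- sum_i f(theta_i) log f(theta_i) over event angles is available as an
alternative estimator, but note that - x log x peaks at x = 1/e > 1/(2*pi),
so that sum is largest for mildly concentrated densities and does not
single out uniformity; the plug-in form is the criterion that does.)
The map over a lattice of candidates is
exhaustive; a hierarchical refinement ("bisection": halve the lattice stride
around the best candidate until sub-voxel) gives the same optimum on
unimodal surfaces at a fraction of the evaluations.  Applied per frame, the
drift of O* over time tracks the motion of the organizing component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import vonmises_concentration, vonmises_kde
from .geometry import CellSupport

__all__ = [
    "EntropyMap",
    "angular_entropy",
    "entropy_map",
    "find_uniform_center",
    "track_center_over_time",
]

_ENTROPY_GRID = 360
_LOG_FLOOR = 1e-12


@dataclass
class EntropyMap:
    """Angular-distribution entropy over a lattice of candidate origins."""

    candidates: np.ndarray  # (n, 2) xy lattice points inside the mask
    entropy: np.ndarray  # (n,)
    plane: int
    step: float
    n_evaluated: int

    @property
    def argmax(self) -> np.ndarray:
        return self.candidates[int(np.argmax(self.entropy))]

    @property
    def max_entropy(self) -> float:
        return float(self.entropy.max())

    def to_image(self, shape) -> np.ndarray:
        """Dense float image of the map (NaN outside the lattice)."""
        img = np.full(shape[:2], np.nan, float)
        ij = np.rint(self.candidates).astype(int)
        img[ij[:, 0], ij[:, 1]] = self.entropy
        return img


def _event_arrays(events) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(events, float)
    if pts.ndim != 2 or pts.shape[1] not in (3, 4):
        raise ValueError("events must be an (N, 3) or (N, 4) array")
    w = pts[:, 3] if pts.shape[1] == 4 else np.ones(len(pts))
    return pts[:, :3], w


def angular_entropy(
    events,
    origin,
    cell: CellSupport,
    use_grid: bool = True,
) -> float:
    """Entropy of the weighted angular density about a candidate origin.

    Recomputes the event angles for the candidate, estimates f(theta) with
    a von Mises kernel (concentration from the circular rule of thumb,
    event weights w_i) and returns the plug-in differential entropy
    - sum_g f(g) log f(g) dtheta over the evaluation grid (default), or,
    with ``use_grid=False``, the point-wise sum
    - sum_i f(theta_i) log f(theta_i) over the N event angles.

    Unlike the spatial densities, the entropy criterion deliberately omits
    the d_theta boundary-distance weighting: an isotropic source sees
    uniform angles regardless of the cell outline, whereas d_theta weights
    tilt the density toward the cell's far side and drag the entropy
    maximum toward the centroid for off-center sources (a measured ~1.7
    voxel bias at an 8-voxel offset in a disk).
    """
    xyz, w = _event_arrays(events)
    ox, oy, oz = float(origin[0]), float(origin[1]), float(origin[2]) if len(origin) > 2 else 0.0
    dx, dy = xyz[:, 0] - ox, xyz[:, 1] - oy
    r = np.hypot(dx, dy)
    if len(xyz) < 2:
        raise ValueError("need at least 2 events")
    if np.all(r < 1e-9):
        raise ValueError("all events coincide with the candidate origin")
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)  # entropy is rotation invariant
    eff_w = w
    if len(np.unique(np.round(theta, 12))) < 2:
        kappa = 1e6
    else:
        kappa = vonmises_concentration(theta, eff_w)
    grid = np.linspace(0.0, 2 * np.pi, _ENTROPY_GRID, endpoint=False)
    f = vonmises_kde(theta, eff_w, kappa, grid)
    step = 2 * np.pi / _ENTROPY_GRID
    f = f / (f.sum() * step)  # unit integral on the circle
    if use_grid:
        return float(-(f * np.log(np.maximum(f, _LOG_FLOOR))).sum() * step)
    # periodic linear interpolation of f at the event angles
    gi = theta / step
    lo = np.floor(gi).astype(int) % _ENTROPY_GRID
    hi = (lo + 1) % _ENTROPY_GRID
    frac = gi - np.floor(gi)
    fi = f[lo] * (1 - frac) + f[hi] * frac
    fi = np.maximum(fi, _LOG_FLOOR)
    return float(-(fi * np.log(fi)).sum())


def _lattice(cell: CellSupport, plane: int, step: float) -> np.ndarray:
    nx, ny = cell.mask.shape[:2]
    xs = np.arange(0, nx, step)
    ys = np.arange(0, ny, step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    ix = np.rint(pts[:, 0]).astype(int)
    iy = np.rint(pts[:, 1]).astype(int)
    inside = cell.mask[ix, iy, plane]
    return pts[inside]


def entropy_map(
    events,
    cell: CellSupport,
    step: float = 1.0,
    plane: int = None,
    use_grid: bool = True,
) -> EntropyMap:
    """Exhaustive entropy map over a lattice of candidate origins.

    Candidates are restricted to one z-plane (the plane of the first event
    by default, appropriate for TIRF-like data).
    """
    if step < 1.0:
        raise ValueError("lattice step must be at least 1 voxel")
    xyz, _ = _event_arrays(events)
    if plane is None:
        plane = min(max(int(round(xyz[0, 2])), 0), cell.mask.shape[2] - 1)
    cands = _lattice(cell, plane, step)
    if len(cands) == 0:
        raise ValueError("no lattice point falls inside the mask")
    ent = np.array(
        [
            angular_entropy(events, (cx, cy, plane), cell, use_grid=use_grid)
            for cx, cy in cands
        ]
    )
    return EntropyMap(
        candidates=cands, entropy=ent, plane=plane, step=step, n_evaluated=len(cands)
    )


def find_uniform_center(
    events,
    cell: CellSupport,
    method: str = "bisection",
    plane: int = None,
    step: float = 1.0,
    use_grid: bool = True,
) -> tuple[np.ndarray, float, int]:
    """Locate the origin of maximal angular entropy.

    ``method='map'`` evaluates the exhaustive lattice at ``step``;
    ``method='bisection'`` refines hierarchically: evaluate a coarse lattice
    (stride = 1/8 of the mask bounding box), recenter a 5x5 window on the
    best candidate, halve the stride, and repeat until the stride drops
    below 1 voxel.  Deterministic; returns (O*, entropy at O*, number of
    candidates evaluated).
    """
    xyz, _ = _event_arrays(events)
    if plane is None:
        plane = min(max(int(round(xyz[0, 2])), 0), cell.mask.shape[2] - 1)
    if method == "map":
        m = entropy_map(events, cell, step=step, plane=plane, use_grid=use_grid)
        best = m.argmax
        return np.array([best[0], best[1], plane], float), m.max_entropy, m.n_evaluated

    if method != "bisection":
        raise ValueError(f"unknown method {method!r}")
    idx = np.argwhere(cell.mask[:, :, plane])
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    stride = max(float(hi.max() - lo.min()) / 8.0, 1.0)
    cands = _lattice(cell, plane, stride)
    seen: dict[tuple[float, float], float] = {}

    def evaluate(pts: np.ndarray) -> None:
        for cx, cy in pts:
            key = (round(float(cx), 3), round(float(cy), 3))
            if key in seen:
                continue
            seen[key] = angular_entropy(
                events, (cx, cy, plane), cell, use_grid=use_grid
            )

    evaluate(cands)
    best = max(seen, key=seen.get)
    while stride >= 1.0:
        stride /= 2.0
        bx, by = best
        offs = np.arange(-2, 3) * stride
        gx, gy = np.meshgrid(bx + offs, by + offs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        nx, ny = cell.mask.shape[:2]
        ok = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= nx - 1)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= ny - 1)
        )
        pts = pts[ok]
        ix = np.rint(pts[:, 0]).astype(int)
        iy = np.rint(pts[:, 1]).astype(int)
        pts = pts[cell.mask[ix, iy, plane]]
        evaluate(pts)
        best = max(seen, key=seen.get)
    o_star = np.array([best[0], best[1], plane], float)
    return o_star, seen[best], len(seen)


def track_center_over_time(
    event_sets: list,
    cell: CellSupport,
    method: str = "bisection",
    plane: int = None,
) -> np.ndarray:
    """Drift of the uniform center: distance (µm) of O*(t) from O*(0).

    ``event_sets`` holds one event array per frame (first frame defines
    t = 0).  Frames with fewer than 2 events yield NaN and the series
    continues.  Voxel sizes of ``cell`` convert to physical units.
    """
    if len(event_sets) < 2:
        raise ValueError("need at least 2 frames")
    scale = np.array([cell.voxel_size[0], cell.voxel_size[1], cell.voxel_size[2]])
    centers = []
    for ev in event_sets:
        ev = np.asarray(ev, float)
        if ev.shape[0] < 2:
            centers.append(None)
            continue
        o, _, _ = find_uniform_center(ev, cell, method=method, plane=plane)
        centers.append(o)
    if centers[0] is None:
        raise ValueError("frame 0 has fewer than 2 events")
    out = np.full(len(centers), np.nan)
    for t, c in enumerate(centers):
        if c is not None:
            out[t] = float(np.linalg.norm((c - centers[0]) * scale))
    return out
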