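"""Trajectory features, tracker consensus, direction classes and
spatially resolved dynamic-feature densities.

A trajectory is a time-ordered sequence of 3D positions of one tracked
particle.  Because no single tracker is reliable on dense vesicle movies,
tracks from several trackers are cross-validated with a *gated distance* —
a frame-wise distance where each frame's discrepancy is capped at a gate
``epsilon`` — and only tracks confirmed by at least two methods are kept.

Per-track dynamic features (confinement ratio, total path length, lifetime)
are then localized at the track's median point in the shape-normalized
cylindrical frame, averaged per spatial bin, and kernel-smoothed into
densities comparable across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import (
    Density1D,
    gaussian_kde_reflected,
    silverman_bandwidth,
    vonmises_concentration,
    vonmises_kde,
)
from .geometry import CellSupport, ReferenceFrame, to_cylindrical

__all__ = [
    "Trajectory",
    "FeatureHistogram",
    "gated_distance",
    "consensus_filter",
    "confinement_ratio",
    "total_path_length",
    "lifetime",
    "classify_direction",
    "feature_histogram",
    "feature_density",
]

TOWARD_PERIPHERY = "toward_periphery"
TOWARD_CENTER = "toward_center"

DEFAULT_GATE = 5.0  # pixels
DEFAULT_MATCH_THRESHOLD = 2.0  # pixels per frame (mean gated distance)


@dataclass
class Trajectory:
    """One tracked particle: frame indices and continuous voxel positions."""

    id: str
    frames: np.ndarray  # (n,) int
    xyz: np.ndarray  # (n, 3) float
    dt: float = 1.0  # seconds per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        self.xyz = np.asarray(self.xyz, float).reshape(len(self.frames), 3)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.id}: frame indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def median_point(self) -> np.ndarray:
        """Position at the time-ordered middle frame, index floor((n-1)/2)."""
        return self.xyz[(len(self) - 1) // 2]


def gated_distance(a: Trajectory, b: Trajectory, epsilon: float = DEFAULT_GATE) -> float:
    """Sum over frames of min(per-frame distance, epsilon).

    Runs over the union of the two tracks' frame indices: where both exist
    the Euclidean distance (capped at epsilon) contributes; frames covered by
    exactly one track contribute the gate epsilon, penalizing length
    mismatches.  Symmetric, nonnegative, bounded by |union| * epsilon.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    union = np.union1d(a.frames, b.frames)
    in_a = np.isin(union, a.frames)
    in_b = np.isin(union, b.frames)
    both = in_a & in_b
    total = float(epsilon) * int((~both).sum())
    if both.any():
        pa = a.xyz[np.searchsorted(a.frames, union[both])]
        pb = b.xyz[np.searchsorted(b.frames, union[both])]
        d = np.linalg.norm(pa - pb, axis=1)
        total += float(np.minimum(d, epsilon).sum())
    return total


def mean_gated_distance(a: Trajectory, b: Trajectory, epsilon: float = DEFAULT_GATE) -> float:
    """Gated distance divided by the number of union frames."""
    n = len(np.union1d(a.frames, b.frames))
    return gated_distance(a, b, epsilon) / n


def _greedy_match(
    ref: list[Trajectory], other: list[Trajectory], epsilon: float
) -> dict[int, float]:
    """One-to-one greedy matching by ascending mean gated distance; returns
    {ref index: matched mean distance}."""
    pairs = []
    for i, ta in enumerate(ref):
        for j, tb in enumerate(other):
            pairs.append((mean_gated_distance(ta, tb, epsilon), i, j))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_i: dict[int, float] = {}
    used_j: set[int] = set()
    for d, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i[i] = d
        used_j.add(j)
    return used_i


def consensus_filter(
    tracks_by_method: dict[str, list[Trajectory]],
    epsilon: float = DEFAULT_GATE,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> list[Trajectory]:
    """Keep reference-method tracks confirmed by at least one other tracker.

    The first-listed method is the reference.  Against every other method,
    reference tracks are matched one-to-one greedily by ascending per-frame
    mean gated distance; a reference track is retained iff its match is
    closer than ``match_threshold`` in at least one other method, i.e. the
    trajectory was found by at least two methods in total.
    """
    if len(tracks_by_method) < 2:
        raise ValueError("consensus requires at least 2 track sets")
    methods = list(tracks_by_method)
    ref = tracks_by_method[methods[0]]
    support = np.zeros(len(ref), int)
    for m in methods[1:]:
        matches = _greedy_match(ref, tracks_by_method[m], epsilon)
        for i, d in matches.items():
            if d < match_threshold:
                support[i] += 1
    return [t for t, s in zip(ref, support) if s >= 1]


def total_path_length(traj: Trajectory, voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Summed step lengths in physical units (µm when voxel sizes are µm)."""
    if len(traj) < 2:
        raise ValueError("need at least 2 points")
    scaled = traj.xyz * np.asarray(voxel_size, float)
    return float(np.linalg.norm(np.diff(scaled, axis=0), axis=1).sum())


def confinement_ratio(traj: Trajectory, voxel_size=(1.0, 1.0, 1.0)) -> float:
    """Net displacement over total path length, in [0, 1].

    1 = perfectly direct motion, values near 0 = confined or looping motion.
    A stationary track (zero path length) returns 1 with a warning: a point
    that never moves is maximally direct by convention.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 points")
    scaled = traj.xyz * np.asarray(voxel_size, float)
    path = float(np.linalg.norm(np.diff(scaled, axis=0), axis=1).sum())
    if path == 0.0:
        warnings.warn(f"track {traj.id} is stationary: ratio set to 1", stacklevel=2)
        return 1.0
    disp = float(np.linalg.norm(scaled[-1] - scaled[0]))
    return min(disp / path, 1.0)


def lifetime(traj: Trajectory) -> float:
    """Track duration in seconds: (last frame - first frame) * dt."""
    if len(traj) < 2:
        raise ValueError("need at least 2 points")
    return float((traj.frames[-1] - traj.frames[0]) * traj.dt)


FEATURES = {
    "confinement_ratio": confinement_ratio,
    "total_path_length": total_path_length,
    "lifetime": lambda t, voxel_size=None: lifetime(t),
}


def classify_direction(
    traj: Trajectory, frame: ReferenceFrame, cell: CellSupport
) -> str:
    """Label a track by its net normalized-radius change between endpoints.

    ``toward_periphery`` if r_norm(last) > r_norm(first); ties (|change| <
    1e-9, e.g. purely tangential arcs) fall to ``toward_center`` and should
    be counted separately by callers via :func:`direction_proportions`.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 points")
    ends = np.array([traj.xyz[0], traj.xyz[-1]])
    es = to_cylindrical(ends, frame, cell)
    delta = es.r_norm[1] - es.r_norm[0]
    return TOWARD_PERIPHERY if delta > 1e-9 else TOWARD_CENTER


def direction_proportions(
    tracks: list[Trajectory], frame: ReferenceFrame, cell: CellSupport
) -> dict[str, float]:
    """Fractions of outward/inward tracks plus the count of exact ties."""
    labels = []
    ties = 0
    for t in tracks:
        ends = np.array([t.xyz[0], t.xyz[-1]])
        es = to_cylindrical(ends, frame, cell)
        delta = es.r_norm[1] - es.r_norm[0]
        if abs(delta) < 1e-9:
            ties += 1
            labels.append(TOWARD_CENTER)
        else:
            labels.append(TOWARD_PERIPHERY if delta > 0 else TOWARD_CENTER)
    n = len(labels)
    out = sum(1 for l in labels if l == TOWARD_PERIPHERY)
    return {
        TOWARD_PERIPHERY: out / n,
        TOWARD_CENTER: (n - out) / n,
        "ties": ties,
    }


@dataclass
class FeatureHistogram:
    """Per-bin average of a dynamic feature along one cylindrical axis.

    ``mean_feature`` is NaN in empty bins (explicit missing marker, never 0).
    """

    axis: str
    edges: np.ndarray
    mean_feature: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


def feature_histogram(
    tracks: list[Trajectory],
    feature: str,
    axis: str,
    frame: ReferenceFrame,
    cell: CellSupport,
    bins: int = None,
    voxel_size=None,
) -> FeatureHistogram:
    """Average a per-track dynamic feature in spatial bins.

    Each track is localized by the shape-normalized cylindrical coordinates
    of its median point (the frame with index floor((n-1)/2)); the feature
    values of tracks falling in each bin are averaged.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    if axis not in ("radius", "angle", "depth"):
        raise ValueError(f"unknown axis {axis!r}")
    bins = bins or (36 if axis == "angle" else 20)
    if bins < 2:
        raise ValueError("need at least 2 bins")
    vs = voxel_size if voxel_size is not None else cell.voxel_size
    pts = np.array([t.median_point() for t in tracks])
    es = to_cylindrical(pts, frame, cell)
    coord = {"radius": es.r_norm, "angle": es.theta, "depth": es.z_norm}[axis]
    hi = 2 * np.pi if axis == "angle" else 1.0
    edges = np.linspace(0.0, hi, bins + 1)
    func = FEATURES[feature]
    m = np.array([func(t, voxel_size=vs) for t in tracks])
    idx = np.clip(np.digitize(coord, edges) - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    sums = np.bincount(idx, weights=m, minlength=bins)
    if not counts.any():
        raise ValueError("all bins empty")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return FeatureHistogram(axis=axis, edges=edges, mean_feature=means, counts=counts)


def feature_density(hist: FeatureHistogram, k: int = None) -> Density1D:
    """Kernel-smooth per-bin feature averages into a unit-mass density.

    Nonempty bin centers carry their mean feature value as a weight; empty
    bins are skipped entirely (they carry no information, and zero-filling
    would fake minima).  Gaussian kernels with reflection on linear axes,
    von Mises on the circle; bandwidths from the nonempty bin-center
    locations.  The result is renormalized to integrate to 1 so transport
    distances between feature profiles are well defined.
    """
    sel = hist.nonempty
    if sel.sum() < 2:
        raise ValueError("need at least 2 nonempty bins")
    centers = hist.centers[sel]
    weights = hist.mean_feature[sel]
    if np.any(weights < 0):
        raise ValueError("feature averages must be nonnegative for smoothing")
    if hist.axis == "angle":
        k = k or 360
        grid = np.linspace(0.0, 2 * np.pi, k, endpoint=False)
        kappa = vonmises_concentration(centers)
        vals = vonmises_kde(centers, weights, kappa, grid)
        d = Density1D("circular", grid, vals)
    else:
        k = k or 100
        grid = np.linspace(0.0, 1.0, k)
        sigma = silverman_bandwidth(centers, support_width=1.0)
        vals = gaussian_kde_reflected(centers, weights, sigma, grid)
        d = Density1D("linear", grid, vals)
    return d.normalized()
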