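"""Synthetic cells, events and trajectories with known ground truth.

Micro-patterned cells constrain cell geometry to reproducible shapes (disk,
crossbow); this module rasterizes stylized versions of those shapes and
draws events directly in the shape-normalized coordinates the analysis
estimates, so every recovery test has an exact generating law.  Events are
sampled as (r_norm, theta, z_norm) and mapped back into the mask through the
same boundary distances the geometry module computes — the inverse of the
normalization — guaranteeing all samples land inside the support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    CellSupport,
    ReferenceFrame,
    boundary_distance_angular,
    _column_extent,
)

__all__ = [
    "SyntheticCellSpec",
    "EventModel",
    "make_cell_mask",
    "sample_events",
    "sample_trajectories",
    "simulate_condition_study",
]

_MAX_TRIES = 100_000


@dataclass
class SyntheticCellSpec:
    """Parameters of a rasterized synthetic cell support."""

    shape: str = "disk"  # disk | crossbow | ellipse | square
    size: int = 30  # lateral radius / half-width in voxels
    planes: int = 1
    profile: str = "flat"  # flat | dome
    margin: int = 3
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.size < 10:
            raise ValueError("size must be at least 10 voxels")
        if self.shape not in ("disk", "crossbow", "ellipse", "square"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.profile not in ("flat", "dome"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class EventModel:
    """Generating law for events in normalized cylindrical coordinates."""

    n: int = 300
    radial: tuple = ("uniform",)  # ("uniform",) | ("beta", a, b)
    angular: tuple = ("uniform",)  # ("uniform",) | ("vonmises", mu, kappa) | ("mixture", [(p, mu, kappa), ...])
    depth: tuple = ("uniform",)  # ("uniform",) | ("beta", a, b)
    weight_model: tuple = ("unit",)  # ("unit",) | ("lognormal", mu, sigma)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need n >= 1 events")


def _shape_2d(spec: SyntheticCellSpec) -> np.ndarray:
    a = spec.size
    m = spec.margin
    if spec.shape == "crossbow":
        side = 2 * (a + a // 2 + m) + 1
    else:
        side = 2 * (a + m) + 1
    c = side // 2
    xx, yy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    dx, dy = xx - c, yy - c
    if spec.shape == "disk":
        return dx**2 + dy**2 <= a**2
    if spec.shape == "square":
        return (np.abs(dx) <= a) & (np.abs(dy) <= a)
    if spec.shape == "ellipse":
        b = max(a // 2, 10)
        return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
    # crossbow: disk plus three lobes at 0 and +/- 2*pi/3 about the x-axis
    mask = dx**2 + dy**2 <= a**2
    lobe_r = a // 2
    for ang in (0.0, 2 * np.pi / 3, -2 * np.pi / 3):
        lx = c + a * np.cos(ang)
        ly = c + a * np.sin(ang)
        mask |= (xx - lx) ** 2 + (yy - ly) ** 2 <= lobe_r**2
    return mask


def make_cell_mask(spec: SyntheticCellSpec) -> CellSupport:
    """Rasterize the spec's shape into a 3D binary cell support.

    The ``dome`` profile shrinks the lateral outline with height like a
    spherical cap; ``flat`` extrudes it unchanged over all planes.
    """
    base = _shape_2d(spec)
    nz = max(spec.planes, 1)
    mask = np.zeros(base.shape + (nz,), bool)
    if spec.profile == "flat" or nz == 1:
        mask[:] = base[:, :, None]
    else:
        from scipy import ndimage

        # dome: planes shrink toward the shape's medial interior with
        # height, like a spherical cap; EDT superlevel sets stay connected
        edt = ndimage.distance_transform_edt(base)
        depth = edt.max()
        for zi in range(nz):
            frac = np.sqrt(max(1.0 - (zi / max(nz - 1, 1)) ** 2, 1e-4))
            mask[:, :, zi] = edt >= (1.0 - frac) * depth
        if not mask[:, :, -1].any():  # keep the top plane nonempty
            mask[:, :, -1] = mask[:, :, -2]
    cell = CellSupport(mask=mask, voxel_size=spec.voxel_size, name=f"synthetic-{spec.shape}")
    return cell


def center_frame(cell: CellSupport) -> ReferenceFrame:
    """Frame at the mask's center voxel, reference direction +x."""
    idx = np.argwhere(cell.mask)
    c = idx.mean(axis=0)
    origin = (float(round(c[0])), float(round(c[1])), float(round(c[2])))
    if not cell.contains(*origin)[0]:
        d2 = ((idx - c) ** 2).sum(axis=1)
        origin = tuple(float(v) for v in idx[int(np.argmin(d2))])
    return ReferenceFrame(origin=origin, direction=(1.0, 0.0))


def _draw(dist: tuple, n: int, rng: np.random.Generator, circular: bool) -> np.ndarray:
    kind = dist[0]
    if circular:
        if kind == "uniform":
            return rng.uniform(0.0, 2 * np.pi, n)
        if kind == "vonmises":
            _, mu, kappa = dist
            return np.mod(rng.vonmises(mu, kappa, n), 2 * np.pi)
        if kind == "mixture":
            comps = dist[1]
            probs = np.array([c[0] for c in comps], float)
            probs /= probs.sum()
            which = rng.choice(len(comps), size=n, p=probs)
            out = np.empty(n)
            for ci, (_, mu, kappa) in enumerate(comps):
                sel = which == ci
                out[sel] = rng.vonmises(mu, kappa, int(sel.sum()))
            return np.mod(out, 2 * np.pi)
    else:
        if kind == "uniform":
            return rng.uniform(0.0, 1.0, n)
        if kind == "beta":
            _, a, b = dist
            return rng.beta(a, b, n)
    raise ValueError(f"unknown distribution {dist!r}")


def sample_events(
    spec_or_cell,
    model: EventModel,
    frame: ReferenceFrame = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw events from the model and map them into the mask.

    (r_norm, theta, z_norm) are drawn from the model's laws, then inverted
    through the ray-cast boundary distance (r = r_norm * d_theta(theta)) and
    the z-column extent, so the normalized coordinates of the returned
    events follow the generating law exactly (up to rasterization).  Returns
    the event table (columns x, y, z, w) and a ground-truth record.
    """
    cell = spec_or_cell if isinstance(spec_or_cell, CellSupport) else make_cell_mask(spec_or_cell)
    frame = frame or center_frame(cell)
    rng = np.random.default_rng(model.seed)
    n = model.n
    theta = _draw(model.angular, n, rng, circular=True)
    r_norm = _draw(model.radial, n, rng, circular=False)
    z_norm = _draw(model.depth, n, rng, circular=False)
    if model.weight_model[0] == "unit":
        w = np.ones(n)
    elif model.weight_model[0] == "lognormal":
        _, mu, sigma = model.weight_model
        w = rng.lognormal(mu, sigma, n)
    else:
        raise ValueError(f"unknown weight model {model.weight_model!r}")

    oz = int(round(frame.origin[2]))
    d_theta = boundary_distance_angular(cell, frame, theta, oz)
    # keep samples strictly interior: the normalization clips at the edge
    r = r_norm * np.maximum(d_theta - 0.5, 0.5 * d_theta)
    ang = theta + frame.angle
    x = frame.origin[0] + r * np.cos(ang)
    y = frame.origin[1] + r * np.sin(ang)
    z_bot, z_top = _column_extent(cell, x, y)
    z = z_bot + z_norm * (z_top - z_bot)

    inside = cell.contains(x, y, z)
    tries = 0
    while not inside.all():
        bad = np.nonzero(~inside)[0]
        tries += bad.size
        if tries > _MAX_TRIES:
            raise RuntimeError("rejection sampling failed: mask/model mismatch")
        theta_b = _draw(model.angular, bad.size, rng, circular=True)
        rn_b = _draw(model.radial, bad.size, rng, circular=False)
        d_b = boundary_distance_angular(cell, frame, theta_b, oz)
        r_b = rn_b * np.maximum(d_b - 0.5, 0.5 * d_b)
        ang_b = theta_b + frame.angle
        x[bad] = frame.origin[0] + r_b * np.cos(ang_b)
        y[bad] = frame.origin[1] + r_b * np.sin(ang_b)
        zb, zt = _column_extent(cell, x[bad], y[bad])
        z[bad] = zb + z_norm[bad] * (zt - zb)
        theta[bad], r_norm[bad] = theta_b, rn_b
        inside = cell.contains(x, y, z)

    events = pd.DataFrame({"x": x, "y": y, "z": z, "w": w})
    truth = {
        "model": {
            "n": n,
            "radial": list(model.radial),
            "angular": _jsonable(model.angular),
            "depth": list(model.depth),
            "weight_model": list(model.weight_model),
            "seed": model.seed,
        },
        "frame": {"origin": list(frame.origin), "direction": list(frame.direction)},
        "cell": cell.name,
    }
    return events, truth


def _jsonable(dist: tuple) -> list:
    return json.loads(json.dumps(dist, default=list))


def sample_trajectories(
    spec_or_cell,
    n: int = 100,
    outward_fraction: float = 1.0,
    step_length: float = 1.0,
    angular_noise: float = 0.0,
    r0_frac: float = 0.5,
    max_lifetime: int = 50,
    dt: float = 1.0,
    seed: int = 0,
    frame: ReferenceFrame = None,
) -> tuple[pd.DataFrame, dict]:
    """Biased radial random walks inside the mask with known direction labels.

    Each track starts at radius ``r0_frac`` of the local boundary distance
    (uniform angle) and drifts radially outward with probability
    ``outward_fraction``, else inward, taking steps of ``step_length`` voxels
    with isotropic Gaussian noise of s.d. ``angular_noise`` per step, until
    it meets the boundary, reaches the center, or exhausts ``max_lifetime``
    frames.  Returns a track table (track_id, t, x, y, z) and the labels.
    """
    cell = spec_or_cell if isinstance(spec_or_cell, CellSupport) else make_cell_mask(spec_or_cell)
    frame = frame or center_frame(cell)
    rng = np.random.default_rng(seed)
    ox, oy, oz = frame.origin
    rows = []
    labels = {}
    for ti in range(n):
        outward = bool(rng.random() < outward_fraction)
        theta = rng.uniform(0, 2 * np.pi)
        d = boundary_distance_angular(cell, frame, theta, int(round(oz)))
        r = r0_frac * d
        ang = theta + frame.angle
        x, y = ox + r * np.cos(ang), oy + r * np.sin(ang)
        sign = 1.0 if outward else -1.0
        tid = f"track_{ti:04d}"
        labels[tid] = "toward_periphery" if outward else "toward_center"
        for t in range(max_lifetime):
            if not cell.contains(x, y, oz)[0]:
                break
            rows.append((tid, t, x, y, float(oz)))
            ux, uy = x - ox, y - oy
            rr = np.hypot(ux, uy)
            if rr < 1e-9:
                break
            ux, uy = ux / rr, uy / rr
            nx_, ny_ = rng.normal(0, angular_noise, 2) if angular_noise > 0 else (0.0, 0.0)
            x2 = x + sign * step_length * ux + nx_
            y2 = y + sign * step_length * uy + ny_
            if not cell.contains(x2, y2, oz)[0]:
                break
            x, y = x2, y2
            if not outward and np.hypot(x - ox, y - oy) < step_length:
                rows.append((tid, t + 1, x, y, float(oz)))
                break
    tracks = pd.DataFrame(rows, columns=["track_id", "t", "x", "y", "z"])
    # drop tracks with < 2 points (started at the boundary)
    ok = tracks.groupby("track_id")["t"].transform("size") >= 2
    tracks = tracks[ok].reset_index(drop=True)
    truth = {
        "labels": labels,
        "outward_fraction": outward_fraction,
        "step_length": step_length,
        "angular_noise": angular_noise,
        "seed": seed,
        "dt": dt,
    }
    return tracks, truth


def simulate_condition_study(
    cell: CellSupport,
    condition_models: dict,
    replicates: int,
    seed: int,
    axes=("angle",),
    n_events: int = 300,
    frame: ReferenceFrame = None,
):
    """Replicate study with known generating laws, ready for comparison.

    ``condition_models`` maps condition label -> EventModel template (its
    seed is ignored); each of the ``replicates`` experiments per condition
    gets an independent seed derived from ``seed``.  Returns a
    :class:`~quantev.comparison.ConditionStudy` whose experiments carry the
    requested per-axis densities estimated by the full pipeline.
    """
    from dataclasses import replace

    from .comparison import ConditionStudy, Experiment
    from .density import weighted_density
    from .geometry import to_cylindrical

    frame = frame or center_frame(cell)
    rng = np.random.default_rng(seed)
    experiments = []
    for label, model in condition_models.items():
        for i in range(replicates):
            sub = int(rng.integers(0, 2**31 - 1))
            ev, _ = sample_events(cell, replace(model, n=n_events, seed=sub), frame)
            es = to_cylindrical(ev.to_numpy(), frame, cell)
            dens = {ax: weighted_density(es, ax) for ax in axes}
            experiments.append(Experiment(f"{label}_{i}", label, dens))
    return ConditionStudy(experiments=experiments)
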