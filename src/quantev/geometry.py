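"""Cylindrical, shape-normalized coordinates of events inside a cell support.

Events detected inside a cell (vesicles, segmented membrane regions, track
points) are expressed in cylindrical coordinates (r, theta, z) about a
user-supplied reference point O (e.g. the Golgi or ERC centroid) with theta
measured from a reference direction in the xy-plane.  Each event also carries
two boundary distances:

* ``d_theta`` — distance from O (projected on the event's z-plane) to the
  cell edge along the event's angular direction, obtained by ray marching;
* ``d_z``    — 3D distance from O to the top surface voxel of the z-column
  at the event's lateral position.

Dividing r by ``d_theta`` and the in-column height by the column height
yields coordinates in [0, 1] that are comparable across cells of different
shape and size; the raw distances additionally enter the density estimates
as multiplicative weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CellSupport",
    "ReferenceFrame",
    "CylindricalEventSet",
    "to_cylindrical",
    "boundary_distance_angular",
    "boundary_distance_axial",
    "default_frame",
]

RAY_STEP = 0.25  # voxels; sub-voxel ray-march resolution

# 6-adjacency structuring element for boundary extraction
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class CoordinateError(ValueError):
    """An event coordinate is incompatible with the cell support."""


class FrameError(ValueError):
    """The reference frame is invalid for the cell support."""


class BoundaryError(ValueError):
    """A boundary distance query fell outside the cell support."""


@dataclass
class CellSupport:
    """3D binary cell support with voxel sizes.

    Parameters
    ----------
    mask : ndarray of bool, shape (nx, ny, nz)
        Foreground voxels form the cell interior.
    voxel_size : tuple of float
        Physical size (µm) of a voxel along x, y, z. x and y must match.
    name : str
        Identifier used in reports.
    """

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = "cell"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim == 2:
            self.mask = self.mask[:, :, None]
        if self.mask.ndim != 3:
            raise ValueError("mask must be 2D or 3D")
        if not self.mask.any():
            raise ValueError("mask contains no foreground voxel")
        if abs(self.voxel_size[0] - self.voxel_size[1]) > 1e-9:
            raise ValueError("x and y voxel sizes must be equal")
        for zi in range(self.mask.shape[2]):
            plane = self.mask[:, :, zi]
            if not plane.any():
                continue
            closed = ndimage.binary_closing(plane, iterations=1)
            _, n = ndimage.label(closed)
            if n > 1:
                raise ValueError(
                    f"z-plane {zi} of mask {self.name!r} is fragmented "
                    f"({n} components after closing)"
                )

    @property
    def z_scale(self) -> float:
        """Ratio of z step to xy pixel size; z indices × z_scale are
        commensurable with xy voxel units."""
        return self.voxel_size[2] / self.voxel_size[0]

    @property
    def boundary(self) -> np.ndarray:
        """Foreground voxels 6-adjacent to background or to the grid edge."""
        eroded = ndimage.binary_erosion(
            self.mask, structure=_STRUCT6, border_value=0
        )
        return self.mask & ~eroded

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Nearest-voxel membership test for continuous coordinates."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        z = np.atleast_1d(np.asarray(z, float))
        ix = np.rint(x).astype(int)
        iy = np.rint(y).astype(int)
        iz = np.rint(z).astype(int)
        nx, ny, nz = self.mask.shape
        inside = (
            (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
        )
        out = np.zeros(x.shape, bool)
        out[inside] = self.mask[ix[inside], iy[inside], iz[inside]]
        return out


@dataclass
class ReferenceFrame:
    """Origin O (continuous voxel coordinates) and the xy direction of
    theta = 0."""

    origin: tuple[float, float, float]
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        n = float(np.linalg.norm(d))
        if n < 1e-12:
            raise FrameError("reference direction has zero length")
        if abs(n - 1.0) > 1e-9:
            d = d / n
        self.direction = (float(d[0]), float(d[1]))
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def angle(self) -> float:
        """Absolute angle (rad) of the reference direction in the xy-plane."""
        return float(np.arctan2(self.direction[1], self.direction[0]))

    def validate(self, cell: CellSupport) -> None:
        ox, oy, oz = self.origin
        if not cell.contains(ox, oy, oz)[0]:
            raise FrameError(f"frame origin {self.origin} lies outside the mask")


@dataclass
class CylindricalEventSet:
    """Events of one cell in cylindrical coordinates with boundary distances.

    All arrays share the event index.  ``r_norm`` is clipped to [0, 1] after
    construction; values above 1.05 before clipping indicate a mask/frame
    mismatch and raise at construction time.
    """

    r: np.ndarray
    theta: np.ndarray
    z: np.ndarray
    w: np.ndarray
    d_theta: np.ndarray
    d_z: np.ndarray
    r_norm: np.ndarray = field(default=None)  # type: ignore[assignment]
    z_norm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("r", "theta", "z", "w", "d_theta", "d_z"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        n = len(self.r)
        if n < 1:
            raise ValueError("event set is empty")
        if np.any(self.w < 0) or self.w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        if np.any(self.d_theta <= 0) or np.any(self.d_z <= 0):
            raise ValueError("boundary distances must be strictly positive")

    def __len__(self) -> int:
        return len(self.r)


def default_frame(cell: CellSupport) -> ReferenceFrame:
    """Fallback frame: mask centroid and xy principal axis.

    The reference point is biological input (Golgi/ERC centroid, pattern
    axis); use this only when none is available.
    """
    idx = np.argwhere(cell.mask).astype(float)
    c = idx.mean(axis=0)
    xy = idx[:, :2] - c[:2]
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    d = evecs[:, np.argmax(evals)]
    origin = (float(c[0]), float(c[1]), float(c[2]))
    if not cell.contains(*origin)[0]:
        # centroid can fall outside non-convex masks; snap to nearest voxel
        d2 = ((idx - c) ** 2).sum(axis=1)
        origin = tuple(idx[int(np.argmin(d2))])
    return ReferenceFrame(origin=origin, direction=(float(d[0]), float(d[1])))


def _ray_crossings(
    cell: CellSupport, ox: float, oy: float, plane: int, angles: np.ndarray
) -> np.ndarray:
    """Vectorized ray march from (ox, oy) on ``plane`` along absolute xy
    ``angles``; returns the distance (voxels) to the first background
    crossing, with the crossing position taken midway between the last
    inside and first outside sample (linear interpolation on a binary mask).
    """
    angles = np.atleast_1d(np.asarray(angles, float))
    mask2d = cell.mask[:, :, plane]
    nx, ny = mask2d.shape
    max_t = float(np.hypot(nx, ny)) + 1.0
    ts = np.arange(RAY_STEP, max_t + RAY_STEP, RAY_STEP)
    cos, sin = np.cos(angles), np.sin(angles)
    # march in chunks so short rays stop early
    n = len(angles)
    dist = np.full(n, np.nan)
    active = np.arange(n)
    last_inside = np.zeros(n)
    chunk = 64
    for start in range(0, len(ts), chunk):
        if active.size == 0:
            break
        t = ts[start : start + chunk]
        x = ox + np.outer(cos[active], t)
        y = oy + np.outer(sin[active], t)
        ix = np.rint(x).astype(int)
        iy = np.rint(y).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        inside = np.zeros_like(ok)
        inside[ok] = mask2d[ix[ok], iy[ok]]
        crossed = ~inside
        has_cross = crossed.any(axis=1)
        first = np.argmax(crossed, axis=1)
        done = active[has_cross]
        t_out = t[first[has_cross]]
        dist[done] = t_out - RAY_STEP / 2.0
        # rays still fully inside this chunk continue
        keep = ~has_cross
        last_inside[active[keep]] = t[-1]
        active = active[keep]
    if active.size:  # pragma: no cover - max_t exceeds any mask diagonal
        dist[active] = last_inside[active]
    return np.maximum(dist, RAY_STEP / 2.0)


def boundary_distance_angular(
    cell: CellSupport,
    frame: ReferenceFrame,
    theta: float | np.ndarray,
    z: int | float = None,
) -> float | np.ndarray:
    """Distance from the origin (projected on plane z) to the cell edge
    along direction(s) ``theta`` (measured from the frame direction)."""
    ox, oy, oz = frame.origin
    plane = int(round(oz if z is None else z))
    plane = min(max(plane, 0), cell.mask.shape[2] - 1)
    if not cell.mask[:, :, plane].any():
        raise BoundaryError(f"plane {plane} contains no foreground")
    if not cell.contains(ox, oy, plane)[0]:
        raise BoundaryError(
            f"origin projection ({ox:.1f}, {oy:.1f}) outside plane-{plane} foreground"
        )
    theta_arr = np.atleast_1d(np.asarray(theta, float))
    d = _ray_crossings(cell, ox, oy, plane, theta_arr + frame.angle)
    return float(d[0]) if np.isscalar(theta) or np.ndim(theta) == 0 else d


def _column_extent(
    cell: CellSupport, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(z_bottom, z_top) plane indices of the foreground z-column at each
    lateral position; -1 where the column is empty."""
    nx, ny, nz = cell.mask.shape
    ix = np.clip(np.rint(x).astype(int), 0, nx - 1)
    iy = np.clip(np.rint(y).astype(int), 0, ny - 1)
    cols = cell.mask[ix, iy, :]  # (n, nz)
    any_fg = cols.any(axis=1)
    z_top = np.where(any_fg, nz - 1 - np.argmax(cols[:, ::-1], axis=1), -1)
    z_bot = np.where(any_fg, np.argmax(cols, axis=1), -1)
    return z_bot, z_top


def boundary_distance_axial(
    cell: CellSupport,
    frame: ReferenceFrame,
    r: float | np.ndarray,
    theta: float | np.ndarray,
    surface: str = "top",
) -> float | np.ndarray:
    """3D distance from the origin O to the surface voxel of the z-column
    at lateral position (r, theta).

    ``surface='top'`` (default, flat adherent cells) takes the topmost
    foreground voxel of the column; ``'nearest'`` takes whichever of the
    column's two ends is closer to O.
    """
    scalar = np.ndim(r) == 0 and np.ndim(theta) == 0
    r_arr = np.atleast_1d(np.asarray(r, float))
    t_arr = np.atleast_1d(np.asarray(theta, float))
    ox, oy, oz = frame.origin
    ang = t_arr + frame.angle
    x = ox + r_arr * np.cos(ang)
    y = oy + r_arr * np.sin(ang)
    z_bot, z_top = _column_extent(cell, x, y)
    if np.any(z_top < 0):
        bad = np.nonzero(z_top < 0)[0][:5]
        raise BoundaryError(
            f"lateral positions outside the mask xy-projection at indices {bad.tolist()}"
        )
    s = cell.z_scale
    d_top = np.sqrt(r_arr**2 + ((z_top - oz) * s) ** 2)
    if surface == "nearest":
        d_bot = np.sqrt(r_arr**2 + ((z_bot - oz) * s) ** 2)
        d = np.minimum(d_top, d_bot)
    elif surface == "top":
        d = d_top
    else:
        raise ValueError(f"unknown axial surface {surface!r}")
    d = np.maximum(d, 1e-3)  # strict positivity for on-origin flat events
    return float(d[0]) if scalar else d


def to_cylindrical(
    points,
    frame: ReferenceFrame,
    cell: CellSupport,
    axial_surface: str = "top",
) -> CylindricalEventSet:
    """Convert event points to the shape-normalized cylindrical event set.

    Parameters
    ----------
    points : array-like, shape (N, 3) or (N, 4)
        Columns x, y, z (continuous voxel/plane coordinates) and optionally a
        nonnegative weight (defaults to 1).
    frame : ReferenceFrame
    cell : CellSupport
    axial_surface : {'top', 'nearest'}
        Which surface point defines d_z (see :func:`boundary_distance_axial`).

    Raises
    ------
    CoordinateError
        If any point lies outside the mask (offending indices listed).
    FrameError
        If the frame origin lies outside the mask.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] not in (3, 4):
        raise ValueError("points must be an (N, 3) or (N, 4) array")
    frame.validate(cell)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    w = pts[:, 3] if pts.shape[1] == 4 else np.ones(len(pts))
    inside = cell.contains(x, y, z)
    if not inside.all():
        bad = np.nonzero(~inside)[0]
        raise CoordinateError(
            f"{bad.size} event(s) outside the mask, indices {bad[:10].tolist()}"
        )

    ox, oy, oz = frame.origin
    dx, dy = x - ox, y - oy
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx) - frame.angle, 2 * np.pi)
    theta[r < 1e-12] = 0.0  # undefined angle at the origin: convention

    # d_theta per event, grouped by z-plane for the vectorized ray march
    d_theta = np.empty(len(pts))
    planes = np.clip(np.rint(z).astype(int), 0, cell.mask.shape[2] - 1)
    for p in np.unique(planes):
        sel = planes == p
        d_theta[sel] = boundary_distance_angular(cell, frame, theta[sel], p)

    d_z = boundary_distance_axial(cell, frame, r, theta, surface=axial_surface)

    r_norm = r / d_theta
    if np.any(r_norm > 1.05):
        worst = float(r_norm.max())
        warnings.warn(
            f"r/d_theta up to {worst:.3f} exceeds 1.05; clipping "
            "(check mask/frame consistency)",
            stacklevel=2,
        )
    r_norm = np.clip(r_norm, 0.0, 1.0)

    ang = theta + frame.angle
    z_bot, z_top = _column_extent(cell, ox + r * np.cos(ang), oy + r * np.sin(ang))
    height = np.maximum((z_top - z_bot).astype(float), 1e-12)
    z_norm = np.clip((z - z_bot) / height, 0.0, 1.0)

    es = CylindricalEventSet(
        r=r, theta=theta, z=z, w=w, d_theta=d_theta, d_z=d_z
    )
    es.r_norm = r_norm
    es.z_norm = z_norm
    return es
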