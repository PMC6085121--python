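"""File formats, study configuration and the end-to-end study runner.

Masks are multi-page TIFFs (one page per z-plane, nonzero = foreground);
events and tracks are plain CSV; TrackMate-style XML track files are read
(spots + edges, track order reconstructed from the edge topology); study
configuration is YAML or JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from lxml import etree

from .comparison import AXES, ConditionStudy, Experiment, run_condition_test
from .density import Density1D, weighted_density, estimate_bandwidths
from .dynamics import Trajectory
from .geometry import CellSupport, ReferenceFrame, to_cylindrical

log = logging.getLogger("quantev")

__all__ = [
    "read_mask",
    "write_mask",
    "read_events",
    "read_tracks",
    "write_density",
    "read_density",
    "StudyConfig",
    "run_study",
    "write_report",
]


def read_mask(path, voxel_size=(1.0, 1.0, 1.0), name: str = None) -> CellSupport:
    """Load a multi-page TIFF mask; nonzero voxels form the foreground."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D or 3D TIFF, got ndim={arr.ndim}")
    mask = np.moveaxis(arr != 0, 0, -1)  # pages are z-planes -> (x, y, z)
    if not mask.any():
        raise ValueError(f"{path}: mask is empty")
    return CellSupport(mask=mask, voxel_size=tuple(voxel_size), name=name or Path(path).stem)


def write_mask(cell: CellSupport, path) -> None:
    pages = np.moveaxis(cell.mask.astype(np.uint8), -1, 0)
    tifffile.imwrite(str(path), pages)


def read_events(path) -> pd.DataFrame:
    """Events CSV with header x,y,z[,w]; a missing weight column means unit
    weights (logged once)."""
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "w" not in df.columns:
        log.info("%s: no weight column, defaulting to unit weights", path)
        df["w"] = 1.0
    return df[["x", "y", "z", "w"]].astype(float)


def _read_tracks_csv(path, dt: float) -> list[Trajectory]:
    df = pd.read_csv(path)
    need = {"track_id", "t", "x", "y", "z"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: track CSV needs columns {sorted(need)}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t")
        tracks.append(
            Trajectory(
                id=str(tid),
                frames=g["t"].to_numpy(int),
                xyz=g[["x", "y", "z"]].to_numpy(float),
                dt=dt,
            )
        )
    return tracks


def _read_tracks_xml(path, dt: float) -> list[Trajectory]:
    """TrackMate-style XML: spots carry positions/frames, edges define the
    track topology; each track is ordered by frame."""
    tree = etree.parse(str(path))
    spots = {}
    for spot in tree.iter("Spot"):
        sid = spot.get("ID")
        try:
            spots[sid] = (
                int(float(spot.get("FRAME"))),
                float(spot.get("POSITION_X")),
                float(spot.get("POSITION_Y")),
                float(spot.get("POSITION_Z", "0")),
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: malformed Spot element ID={sid}") from err
    tracks = []
    for track in tree.iter("Track"):
        tid = track.get("TRACK_ID", track.get("name", str(len(tracks))))
        ids: set[str] = set()
        for edge in track.iter("Edge"):
            ids.add(edge.get("SPOT_SOURCE_ID"))
            ids.add(edge.get("SPOT_TARGET_ID"))
        pts = sorted((spots[i] for i in ids if i in spots), key=lambda p: p[0])
        if len(pts) < 2:
            continue
        arr = np.asarray(pts, float)
        tracks.append(
            Trajectory(id=str(tid), frames=arr[:, 0].astype(int), xyz=arr[:, 1:4], dt=dt)
        )
    return tracks


def read_tracks(path, dt: float = 1.0) -> list[Trajectory]:
    """Read trajectories from CSV (track_id,t,x,y,z) or TrackMate-style XML."""
    p = Path(path)
    if p.suffix.lower() == ".xml":
        return _read_tracks_xml(p, dt)
    return _read_tracks_csv(p, dt)


def write_density(d: Density1D, path) -> None:
    """CSV with columns axis-free grid, histogram, density (9 significant
    digits for reproducible diffs); support recorded in a comment-free extra
    column to keep the file strictly tabular."""
    hist = d.histogram if d.histogram is not None else np.full(len(d.grid), np.nan)
    df = pd.DataFrame(
        {"grid": d.grid, "histogram": hist, "density": d.values,
         "support": [d.support] * len(d.grid)}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_density(path) -> Density1D:
    df = pd.read_csv(path)
    hist = df["histogram"].to_numpy(float) if "histogram" in df else None
    if hist is not None and np.all(np.isnan(hist)):
        hist = None
    return Density1D(
        support=str(df["support"].iloc[0]),
        grid=df["grid"].to_numpy(float),
        values=df["density"].to_numpy(float),
        histogram=hist,
    )


class StudyConfig:
    """Conditions mapped to replicate experiments plus shared parameters.

    YAML/JSON layout::

        voxel_size: [0.064, 0.064, 0.3]
        parameters: {k_linear: 100, k_circular: 360, seed: 0}
        conditions:
          control:
            - {mask: cell1.tif, events: cell1_events.csv,
               origin: [40, 40, 0], direction: [1, 0]}
    """

    def __init__(self, conditions: dict, parameters: dict = None,
                 voxel_size=(1.0, 1.0, 1.0), base_dir: Path = None):
        if len(conditions) < 1:
            raise ValueError("config names no conditions")
        labels = list(conditions)
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        self.conditions = conditions
        self.parameters = dict(parameters or {})
        self.voxel_size = tuple(voxel_size)
        self.base_dir = Path(base_dir) if base_dir else Path(".")
        for label, entries in conditions.items():
            for ent in entries:
                for key in ("mask", "events"):
                    p = self.base_dir / ent[key]
                    if not p.exists():
                        raise FileNotFoundError(f"{label}: missing file {p}")

    @classmethod
    def load(cls, path) -> "StudyConfig":
        p = Path(path)
        text = p.read_text()
        data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
        return cls(
            conditions=data["conditions"],
            parameters=data.get("parameters"),
            voxel_size=data.get("voxel_size", (1.0, 1.0, 1.0)),
            base_dir=p.parent,
        )


def run_study(config: StudyConfig) -> dict:
    """Run densities, distances, condition differences and tests end to end.

    Returns a report dict with per-experiment bandwidths, per-axis distance
    matrices, condition differences and p-values.  Per-experiment failures
    are collected (id + stage) without aborting the remaining experiments;
    any failure is reported and blocks the comparison stage only if fewer
    than two conditions survive.
    """
    k_lin = int(config.parameters.get("k_linear", 100))
    k_circ = int(config.parameters.get("k_circular", 360))
    experiments = []
    failures = []
    bandwidths = {}
    for label, entries in config.conditions.items():
        for ent in entries:
            exp_id = ent.get("id") or Path(ent["events"]).stem
            stage = "read"
            try:
                cell = read_mask(config.base_dir / ent["mask"], config.voxel_size)
                events = read_events(config.base_dir / ent["events"])
                frame = ReferenceFrame(
                    origin=tuple(ent["origin"]), direction=tuple(ent["direction"])
                )
                stage = "coordinates"
                es = to_cylindrical(events.to_numpy(), frame, cell)
                stage = "density"
                dens = {
                    "radius": weighted_density(es, "radius", k=k_lin),
                    "angle": weighted_density(es, "angle", k=k_circ),
                    "depth": weighted_density(es, "depth", k=k_lin),
                }
                bw = estimate_bandwidths(es)
                bandwidths[exp_id] = {
                    "sigma_r": bw.sigma_r, "sigma_z": bw.sigma_z,
                    "kappa": bw.kappa, "n_events": len(es),
                }
                experiments.append(Experiment(exp_id, label, dens))
                log.info("experiment %s (%s): %d events", exp_id, label, len(es))
            except Exception as err:  # noqa: BLE001 - per-experiment isolation
                failures.append({"id": exp_id, "stage": stage, "error": str(err)})
                log.error("experiment %s failed at %s: %s", exp_id, stage, err)
    report = {"failures": failures, "bandwidths": bandwidths}
    study = ConditionStudy(experiments=experiments)
    if len(study.conditions) >= 2:
        p_values = run_condition_test(study)
        report["p_values"] = p_values
        report["condition_difference"] = {
            ax: {e.id: float(d) for e, d in zip(experiments, study.condition_difference_[ax])}
            for ax in study.condition_difference_
        }
        report["distance_matrix"] = {
            ax: study.distance_matrix[ax].tolist() for ax in study.distance_matrix
        }
        report["experiment_ids"] = [e.id for e in experiments]
        report["conditions"] = {e.id: e.condition for e in experiments}
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
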