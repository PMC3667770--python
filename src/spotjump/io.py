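"""File formats, configuration round-tripping, and deterministic fixtures.

Conventions: image stacks are multi-frame grayscale 16-bit TIFF; tracks and
ground truth travel as CSV with a ``#``-prefixed key=value header; units in
files are always micrometers and seconds. All randomness flows from one
recorded master seed, and every CSV embeds the schema version.
"""

from __future__ import annotations

import dataclasses
import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect_track import Detection, Track
from .simulate import (
    GroundTruthTrajectory,
    ImagingModel,
    MotionChange,
    PopulationMix,
    SimulationConfig,
    render_stack,
    simulate_trajectories,
)

__all__ = [
    "FormatError",
    "ValidationError",
    "read_stack",
    "write_stack",
    "write_tracks",
    "read_tracks",
    "write_ground_truth",
    "read_ground_truth",
    "save_config",
    "load_config",
    "make_fixtures",
]

TRACK_SCHEMA = "spotjump-tracks v1"
GT_SCHEMA = "spotjump-ground-truth v1"


class FormatError(ValueError):
    pass


class ValidationError(ValueError):
    pass


def write_stack(stack: np.ndarray, path) -> None:
    """Write a (frames, h, w) stack as 16-bit unsigned multi-frame TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise FormatError("stack must be (frames, rows, cols)")
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a multi-frame grayscale TIFF as a (frames, h, w) uint16 array."""
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # truncated/corrupt files: clean error, no partial stack
        raise FormatError(f"cannot read TIFF stack from {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected grayscale stack, got shape {data.shape}")
    return data


def _write_csv_with_header(df: pd.DataFrame, path, header: dict, schema: str) -> None:
    lines = [f"# {schema}"]
    for k, v in header.items():
        lines.append(f"# {k}={v}")
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.6f")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def _read_header(path) -> dict:
    header = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                header[k.strip()] = v.strip()
    return header


def write_tracks(tracks: list[Track], path, dt_s: float, pixel_size_nm: float = float("nan"), source: str = "spotjump") -> None:
    """Write linked tracks as CSV (track_id, frame, x_um, y_um, intensity)."""
    rows = [
        (tr.id, d.frame, d.x_um, d.y_um, d.intensity)
        for tr in tracks
        for d in tr.detections
    ]
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "intensity"])
    _write_csv_with_header(df, path, {"dt_s": dt_s, "pixel_size_nm": pixel_size_nm, "source": source}, TRACK_SCHEMA)


def read_tracks(path) -> tuple[list[Track], dict]:
    """Read a track CSV; validates uniqueness and frame continuity.

    Returns ``(tracks, header)`` where header carries dt_s etc. as strings
    parsed to float where possible. An empty file with a header is an empty
    track list, not an error.
    """
    header = _read_header(path)
    df = pd.read_csv(path, comment="#")
    for col in ("track_id", "frame", "x_um", "y_um"):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r} in {path}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        offenders = df.loc[dup, ["track_id", "frame"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (track_id, frame) rows: {offenders[:10]}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if len(frames) > 1 and np.any(np.diff(frames) != 1):
            raise ValidationError(f"track {tid} has a frame gap (frames {frames.tolist()})")
        dets = [
            Detection(
                frame=int(r.frame),
                x_um=float(r.x_um),
                y_um=float(r.y_um),
                intensity=float(getattr(r, "intensity", float("nan"))),
            )
            for r in grp.itertuples()
        ]
        tracks.append(Track(id=int(tid), detections=dets))
    for k in ("dt_s", "pixel_size_nm"):
        if k in header:
            try:
                header[k] = float(header[k])
            except ValueError:
                pass
    return tracks, header


def write_ground_truth(trajectories: list[GroundTruthTrajectory], path, dt_s: float) -> None:
    """Ground truth CSV: traj_id, frame, x_um, y_um, population, is_change_frame."""
    rows = []
    for t in trajectories:
        changes = set(t.change_frames)
        for f, x, y, lab in zip(t.frames, t.x, t.y, t.population_label):
            rows.append((t.id, int(f), x, y, int(lab), int(f) in changes))
    df = pd.DataFrame(rows, columns=["traj_id", "frame", "x_um", "y_um", "population", "is_change_frame"])
    _write_csv_with_header(df, path, {"dt_s": dt_s}, GT_SCHEMA)


def read_ground_truth(path) -> tuple[list[GroundTruthTrajectory], dict]:
    header = _read_header(path)
    df = pd.read_csv(path, comment="#")
    trajs = []
    for tid, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("frame")
        changes = tuple(int(f) for f in grp.loc[grp["is_change_frame"].astype(bool), "frame"])
        trajs.append(
            GroundTruthTrajectory(
                id=int(tid),
                frames=grp["frame"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy(),
                population_label=grp["population"].to_numpy(),
                change_frames=changes,
            )
        )
    if "dt_s" in header:
        header["dt_s"] = float(header["dt_s"])
    return trajs, header


# --- configuration -----------------------------------------------------------

_NESTED = {"mix": PopulationMix, "imaging": ImagingModel, "motion_change": MotionChange}


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_dict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _NESTED and isinstance(v, dict):
            kwargs[k] = _from_dict(_NESTED[k], v)
        elif k == "components":
            kwargs[k] = tuple(tuple(c) for c in v)
        elif k == "frame_shape":
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def save_config(config: SimulationConfig, path) -> None:
    """Serialize a simulation config to YAML (field names mirror the dataclass)."""
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=True))


def load_config(path) -> SimulationConfig:
    """Load a YAML config; unknown keys are rejected. load(save(cfg)) == cfg."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError("config must be a mapping")
    return _from_dict(SimulationConfig, data)


# --- fixtures ----------------------------------------------------------------

def make_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write small deterministic datasets for examples and smoke tests.

    Produces: a 10-track single-population track set, a 20-track
    two-population set, one 20-frame 32×32 movie with 5 particles, and one
    immobile-particle precision stack — each with ground-truth or config
    sidecars. The same seed always produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    imaging = ImagingModel(frame_shape=(64, 64), amplitude=85.0)
    ss = np.random.SeedSequence(seed)
    s_stack, s_prec = ss.spawn(2)  # render-noise streams; trajectories use config seeds

    def gt_tracks(trajs):
        return [
            Track(id=t.id, detections=[
                Detection(frame=int(f), x_um=float(x), y_um=float(y), intensity=1.0)
                for f, x, y in zip(t.frames, t.x, t.y)
            ])
            for t in trajs
        ]

    cfg1 = SimulationConfig(
        mix=PopulationMix.single(0.1), imaging=imaging, n_particles=10, n_frames=30,
        initial_min_spacing_um=1.0, rng_seed=seed,
    )
    trajs1 = simulate_trajectories(cfg1)
    paths["single_tracks"] = out / "single_population_tracks.csv"
    write_tracks(gt_tracks(trajs1), paths["single_tracks"], dt_s=imaging.dt_s,
                 pixel_size_nm=imaging.pixel_size_nm, source="simulated ground truth")
    paths["single_gt"] = out / "single_population_gt.csv"
    write_ground_truth(trajs1, paths["single_gt"], dt_s=imaging.dt_s)

    cfg2 = SimulationConfig(
        mix=PopulationMix.two_populations(0.1, 0.02), imaging=imaging, n_particles=20,
        n_frames=30, initial_min_spacing_um=1.0, rng_seed=seed + 1,
    )
    trajs2 = simulate_trajectories(cfg2)
    paths["two_pop_tracks"] = out / "two_population_tracks.csv"
    write_tracks(gt_tracks(trajs2), paths["two_pop_tracks"], dt_s=imaging.dt_s,
                 pixel_size_nm=imaging.pixel_size_nm, source="simulated ground truth")
    paths["two_pop_gt"] = out / "two_population_gt.csv"
    write_ground_truth(trajs2, paths["two_pop_gt"], dt_s=imaging.dt_s)

    small = ImagingModel(frame_shape=(32, 32), amplitude=85.0)
    cfg3 = SimulationConfig(
        mix=PopulationMix.single(0.05), imaging=small, n_particles=5, n_frames=20,
        initial_min_spacing_um=1.0, rng_seed=seed,
    )
    trajs3 = simulate_trajectories(cfg3)
    stack3 = render_stack(trajs3, small, rng=np.random.default_rng(s_stack), n_frames=20)
    paths["movie"] = out / "movie_5_particles.tif"
    write_stack(stack3, paths["movie"])
    paths["movie_gt"] = out / "movie_5_particles_gt.csv"
    write_ground_truth(trajs3, paths["movie_gt"], dt_s=small.dt_s)
    paths["movie_config"] = out / "movie_5_particles_config.yaml"
    save_config(cfg3, paths["movie_config"])

    cfg4 = SimulationConfig(
        mix=PopulationMix.single(0.0), imaging=small, n_particles=4, n_frames=20,
        initial_min_spacing_um=1.0, rng_seed=seed + 2,
    )
    trajs4 = simulate_trajectories(cfg4)
    stack4 = render_stack(trajs4, small, rng=np.random.default_rng(s_prec), n_frames=20)
    paths["precision_stack"] = out / "immobile_precision.tif"
    write_stack(stack4, paths["precision_stack"])
    paths["precision_gt"] = out / "immobile_precision_gt.csv"
    write_ground_truth(trajs4, paths["precision_gt"], dt_s=small.dt_s)
    return paths
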