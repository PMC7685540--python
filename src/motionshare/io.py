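"""File formats: angle-series CSV, pose CSV, fixtures, frames, result JSON.

Angle CSVs carry provenance as ``#``-prefixed header lines; numeric columns
are written with 17 significant digits so write -> read round-trips are exact
to double precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ImageSequence, MotionSequence, SceneGeometry

SEQUENCE_COLUMNS = [
    "time_s",
    "phase",
    "gross_deg",
    "l2l3_deg",
    "l3l4_deg",
    "l4l5_deg",
    "l5s1_deg",
]

_FLOAT_FMT = "%.17g"


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sequence_csv(seq: MotionSequence, path) -> None:
    """Write a motion sequence (angles in degrees, flexion positive)."""
    path = Path(path)
    if seq.level_angles is not None and seq.level_angles.shape[1] != 4:
        raise ValueError("sequence CSV format expects exactly 4 levels")
    data = {
        "time_s": seq.frame_times,
        "phase": seq.phase_labels
        if seq.phase_labels is not None
        else np.full(seq.n_frames, "", dtype=object),
        "gross_deg": seq.gross_angle,
    }
    levels = (
        seq.level_angles
        if seq.level_angles is not None
        else np.full((seq.n_frames, 4), np.nan)
    )
    for i, col in enumerate(SEQUENCE_COLUMNS[3:]):
        data[col] = levels[:, i]
    df = pd.DataFrame(data, columns=SEQUENCE_COLUMNS)
    meta = {k: v for k, v in seq.meta.items() if not isinstance(v, np.ndarray)}
    header = "# motionshare MotionSequence v1; angles deg, flexion positive\n"
    header += f"# meta: {json.dumps(_jsonable(meta), sort_keys=True)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_sequence_csv(path) -> MotionSequence:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# meta:"):
                meta = json.loads(line[len("# meta:") :])
    df = pd.read_csv(path, comment="#")
    missing = set(SEQUENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sequence CSV missing columns: {sorted(missing)}")
    levels = df[SEQUENCE_COLUMNS[3:]].to_numpy(dtype=float)
    phase = None
    if df["phase"].notna().all() and (df["phase"].astype(str) != "").all():
        phase = df["phase"].astype(str).to_numpy(dtype=object)
    return MotionSequence(
        frame_times=df["time_s"].to_numpy(dtype=float),
        gross_angle=df["gross_deg"].to_numpy(dtype=float),
        level_angles=None if np.isnan(levels).all() else levels,
        phase_labels=phase,
        meta=meta,
    )


def write_pose_csv(series, path) -> None:
    """Tracked poses as long-format CSV (frame, vertebra, tx, ty, rot, score, flag)."""
    rows = []
    names = series.vertebra_names or [f"V{v}" for v in range(series.n_vertebrae)]
    for f in range(series.n_frames):
        for v in range(series.n_vertebrae):
            tx, ty, rot = series.poses[f, v]
            rows.append(
                {
                    "frame": f,
                    "vertebra": names[v],
                    "tx_px": tx,
                    "ty_px": ty,
                    "rot_deg": rot,
                    "score": series.scores[f, v],
                    "flag": bool(series.flags[f, v]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_fixture_json(fixture: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(fixture), indent=1, sort_keys=True))


def read_fixture_json(path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


def write_image_sequence(imgs: ImageSequence, outdir) -> None:
    """Numbered PNG frames plus ground-truth pose and geometry JSON sidecars."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i in range(imgs.n_frames):
        frame8 = np.clip(imgs.frames[i] * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(outdir / f"frame_{i:04d}.png", frame8)
    (outdir / "poses.json").write_text(
        json.dumps({"poses": imgs.poses.tolist()}, sort_keys=True)
    )
    (outdir / "geometry.json").write_text(
        json.dumps(_jsonable(dataclasses.asdict(imgs.geometry)), indent=1, sort_keys=True)
    )


def read_image_sequence(indir) -> ImageSequence:
    import imageio.v3 as iio

    indir = Path(indir)
    files = sorted(indir.glob("frame_*.png"))
    if not files:
        raise FileNotFoundError(f"no frame_*.png files in {indir}")
    frames = np.stack([iio.imread(f).astype(np.float32) / 255.0 for f in files])
    poses = np.asarray(json.loads((indir / "poses.json").read_text())["poses"])
    geo_raw = json.loads((indir / "geometry.json").read_text())
    geo_raw["image_shape"] = tuple(geo_raw["image_shape"])
    geo_raw["centroids"] = tuple(tuple(c) for c in geo_raw["centroids"])
    geo_raw["quads"] = tuple(tuple(tuple(p) for p in q) for q in geo_raw["quads"])
    geo_raw["background_range"] = tuple(geo_raw["background_range"])
    return ImageSequence(frames=frames, poses=poses, geometry=SceneGeometry(**geo_raw))


def write_result_json(result: dict, path, provenance: dict | None = None) -> None:
    payload = dict(_jsonable(result))
    if provenance:
        payload["provenance"] = _jsonable(provenance)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_readings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "rater", "biomarker", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"readings CSV must have columns {sorted(required)}")
    return df
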