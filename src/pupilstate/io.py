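"""Readers and writers for the pipeline's on-disk formats.

Spatial maps go to NIfTI (values scattered into the mask) and flat CSV
(voxel_index, value); pupil traces, landmark series and labels to CSV;
reports and ground truth to JSON (+ NPZ for arrays).  The voxel <-> flat
index mapping scans the mask with x fastest, then y, then z, 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from pupilstate.corrmaps import SpatialMap
from pupilstate.pupil import LandmarkSeries, PupilTrace
from pupilstate.synthetic import BrainGeometry, Trial

__all__ = [
    "save_map_nifti", "load_map_nifti",
    "save_map_csv", "load_map_csv",
    "save_trace_csv", "load_trace_csv",
    "save_landmarks_csv", "load_landmarks_csv",
    "save_trial_bundle", "load_trial_bundle",
    "save_labels_csv", "load_labels_csv",
    "save_json", "load_json",
]


def save_map_nifti(smap: SpatialMap, path: str | Path) -> Path:
    geom = smap.geometry
    if geom is None:
        raise ValueError("map has no geometry; cannot write NIfTI")
    vol = geom.embed(smap.values).astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_map_nifti(path: str | Path, geometry: BrainGeometry,
                   kind: str = "correlation") -> SpatialMap:
    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    return SpatialMap(values=geometry.extract(vol), geometry=geometry, kind=kind)


def save_map_csv(smap: SpatialMap, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "voxel_index": np.arange(smap.values.shape[0]),
        "value": smap.values,
    }).to_csv(path, index=False)
    return path


def load_map_csv(path: str | Path, geometry: BrainGeometry | None = None,
                 kind: str = "correlation") -> SpatialMap:
    df = _read_csv(path, required={"voxel_index", "value"})
    values = np.empty(len(df))
    values[df["voxel_index"].to_numpy(dtype=int)] = df["value"].to_numpy(dtype=float)
    return SpatialMap(values=values, geometry=geometry, kind=kind)


def save_trace_csv(trace: PupilTrace, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(len(trace)) * trace.dt
    pd.DataFrame({"time_s": t, "diameter": trace.values}).to_csv(path, index=False)
    return path


def load_trace_csv(path: str | Path, normalized: bool = False) -> PupilTrace:
    df = _read_csv(path, required={"time_s", "diameter"})
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer dt")
    return PupilTrace(values=df["diameter"].to_numpy(dtype=float),
                      dt=float(t[1] - t[0]), normalized=normalized)


def save_landmarks_csv(series: LandmarkSeries, path: str | Path) -> Path:
    pts = series.points
    cols = {"frame": np.arange(pts.shape[0])}
    for i in range(4):
        cols[f"x{i + 1}"] = pts[:, i, 0]
        cols[f"y{i + 1}"] = pts[:, i, 1]
    path = Path(path)
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# fps={series.fps} eye_size={series.eye_size}\n")
        df.to_csv(fh, index=False)
    return path


def load_landmarks_csv(path: str | Path) -> LandmarkSeries:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(fh)
    required = {"frame"} | {f"{c}{i}" for c in "xy" for i in range(1, 5)}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pts = np.empty((len(df), 4, 2))
    for i in range(4):
        pts[:, i, 0] = df[f"x{i + 1}"]
        pts[:, i, 1] = df[f"y{i + 1}"]
    return LandmarkSeries(points=pts, fps=float(meta["fps"]),
                          eye_size=float(meta["eye_size"]))


def save_trial_bundle(trial: Trial, path: str | Path) -> Path:
    """One NPZ holding the voxel matrix, pupil trace and metadata."""
    path = Path(path)
    np.savez_compressed(
        path,
        fmri=trial.fmri,
        pupil=trial.pupil,
        tr=trial.tr,
        subject_id=trial.subject_id,
        meta=json.dumps(trial.meta),
        mask=trial.geometry.mask if trial.geometry is not None else np.zeros(0),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_trial_bundle(path: str | Path) -> Trial:
    from pupilstate.synthetic import generate_geometry

    with np.load(path, allow_pickle=False) as z:
        mask = z["mask"]
        geom = None
        if mask.size:
            geom = generate_geometry(mask.shape, "full")
            coords = np.argwhere(mask)
            order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
            geom = BrainGeometry(shape=tuple(mask.shape), mask=mask,
                                 coords=coords[order])
        return Trial(
            subject_id=str(z["subject_id"]),
            fmri=z["fmri"],
            pupil=z["pupil"],
            tr=float(z["tr"]),
            geometry=geom,
            meta=json.loads(str(z["meta"])),
        )


def save_labels_csv(trial_ids, labels, stability, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "trial_id": list(trial_ids),
        "label": np.asarray(labels, dtype=int),
        "stability": np.asarray(stability, dtype=float),
    }).to_csv(path, index=False)
    return path


def load_labels_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, required={"trial_id", "label", "stability"})


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed CSV ({err})") from err
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: missing values at row(s) {list(bad[:5])}")
    return df
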