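"""File formats: volumes, fiducial lists, pose streams, transforms, configs.

Conventions
-----------
* Volumes: NIfTI-1 (``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``)
  via SimpleITK.  ITK's in-memory convention is LPS, so RAS-coded NIfTI
  headers are converted on read and restored on write -- the package is LPS
  throughout.
* Fiducials: 3D Slicer FCSV (treated as RAS regardless of header hints,
  per Slicer's convention: x and y are negated on read/write), Slicer
  markups JSON (the declared ``coordinateSystem`` field is honored), and
  plain CSV ``label,x,y,z`` (already LPS).
* Poses: CSV ``time_s,tool_id,tx,ty,tz,qx,qy,qz,qw,valid`` with scalar-last
  unit quaternions; quaternions off unit norm by more than 1e-6 are
  rejected rather than silently normalized.
* Transforms: a text file of 4 rows x 4 floats with a header line
  ``# source=<frame> target=<frame> kind=<rigid|affine>``.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .calibration import PoseReading, PoseStream
from .pointreg import FiducialSet
from .transforms import (
    AffineTransform,
    RigidTransform,
    Transform,
    from_quaternion,
)
from .volume import LabelMask, VolumeImage

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_fiducials",
    "write_fiducials",
    "read_pose_csv",
    "write_pose_csv",
    "read_transform",
    "write_transform",
    "load_config",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


class FormatError(ValueError):
    """Unsupported or corrupt file."""


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(f"unsupported volume format: {path}")


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_volume(path, frame: str = "world") -> VolumeImage:
    path = Path(path)
    _check_volume_path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read volume {path}: corrupt or truncated") from exc
    return VolumeImage.from_sitk(img, frame=frame)


def write_volume(v: VolumeImage, path) -> None:
    path = Path(path)
    _check_volume_path(path)
    # MetaImage .mhd needs its companion .raw next to the final name, so a
    # temp-rename dance breaks it; only .mhd is written in place.
    if path.name.lower().endswith(".mhd"):
        path.parent.mkdir(parents=True, exist_ok=True)
        sitk.WriteImage(v.to_sitk(), str(path))
        return

    def _w(tmp: Path):
        tmp2 = tmp.with_name("v" + path.name)
        sitk.WriteImage(v.to_sitk(), str(tmp2))
        os.replace(tmp2, tmp)

    _atomic_write(path, _w)


def read_mask(path, frame: str = "world") -> LabelMask:
    v = read_volume(path, frame=frame)
    return LabelMask(
        voxels=v.voxels > 0.5,
        spacing=v.spacing,
        origin=v.origin,
        direction=v.direction,
        frame=frame,
    )


def write_mask(mask: LabelMask, path) -> None:
    write_volume(
        VolumeImage(
            voxels=mask.voxels.astype(float),
            spacing=mask.spacing,
            origin=mask.origin,
            direction=mask.direction,
            frame=mask.frame,
        ),
        path,
    )


# ---------------------------------------------------------------------------
# fiducials


def read_fiducials(path, frame: str = "world") -> FiducialSet:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".fcsv":
        return _read_fcsv(path, frame)
    if suffix == ".json" or path.name.lower().endswith(".mrk.json"):
        return _read_markups_json(path, frame)
    if suffix == ".csv":
        return _read_points_csv(path, frame)
    raise FormatError(f"unsupported fiducial format: {path}")


def write_fiducials(fs: FiducialSet, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".fcsv":
        writer = _write_fcsv
    elif suffix == ".json":
        writer = _write_markups_json
    elif suffix == ".csv":
        writer = _write_points_csv
    else:
        raise FormatError(f"unsupported fiducial format: {path}")
    _atomic_write(path, lambda tmp: writer(fs, tmp))


def _read_fcsv(path: Path, frame: str) -> FiducialSet:
    labels, coords = [], []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}") from exc
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) < 12:
            raise FormatError(f"malformed FCSV row in {path}: {line!r}")
        x, y, z = (float(parts[1]), float(parts[2]), float(parts[3]))
        labels.append(parts[11] or parts[0])
        coords.append([-x, -y, z])  # RAS -> LPS
    if not labels:
        raise FormatError(f"no fiducial rows in {path}")
    return FiducialSet.from_arrays(labels, np.array(coords), frame=frame)


def _write_fcsv(fs: FiducialSet, path: Path) -> None:
    rows = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = RAS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, p in enumerate(fs.points):
        x, y, z = p.coordinates
        rows.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{-x:.6f},{-y:.6f},{z:.6f},"
            f"0,0,0,1,1,1,0,{p.label},,"
        )
    path.write_text("\n".join(rows) + "\n")


def _read_markups_json(path: Path, frame: str) -> FiducialSet:
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse markups JSON {path}") from exc
    try:
        markup = data["markups"][0]
        system = markup.get("coordinateSystem", "LPS").upper()
        labels, coords = [], []
        for cp in markup["controlPoints"]:
            labels.append(cp["label"])
            pos = np.array(cp["position"], dtype=float)
            if system == "RAS":
                pos = pos * np.array([-1.0, -1.0, 1.0])
            coords.append(pos)
    except (KeyError, IndexError, TypeError) as exc:
        raise FormatError(f"markups JSON {path} lacks expected structure") from exc
    return FiducialSet.from_arrays(labels, np.array(coords), frame=frame)


def _write_markups_json(fs: FiducialSet, path: Path) -> None:
    markup = {
        "type": "Fiducial",
        "coordinateSystem": "LPS",
        "controlPoints": [
            {"label": p.label, "position": [float(c) for c in p.coordinates]}
            for p in fs.points
        ],
    }
    path.write_text(json.dumps({"markups": [markup]}, indent=2))


def _read_points_csv(path: Path, frame: str) -> FiducialSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path}") from exc
    cols = {c.lower(): c for c in df.columns}
    needed = ("label", "x", "y", "z")
    if not all(c in cols for c in needed):
        raise FormatError(f"CSV {path} must have columns label,x,y,z")
    return FiducialSet.from_arrays(
        df[cols["label"]].astype(str).tolist(),
        df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float),
        frame=frame,
    )


def _write_points_csv(fs: FiducialSet, path: Path) -> None:
    df = pd.DataFrame(
        {
            "label": fs.labels,
            "x": fs.coordinates[:, 0],
            "y": fs.coordinates[:, 1],
            "z": fs.coordinates[:, 2],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pose streams

_POSE_COLUMNS = ["time_s", "tool_id", "tx", "ty", "tz", "qx", "qy", "qz", "qw", "valid"]


def read_pose_csv(path, tracker_frame: str = "world") -> PoseStream:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse pose CSV {path}") from exc
    if list(df.columns) != _POSE_COLUMNS:
        raise FormatError(
            f"pose CSV {path} must have columns {','.join(_POSE_COLUMNS)}"
        )
    readings = []
    for row in df.itertuples(index=False):
        pose = from_quaternion(
            (row.qx, row.qy, row.qz, row.qw),
            (row.tx, row.ty, row.tz),
            source=str(row.tool_id),
            target=tracker_frame,
        )
        readings.append(
            PoseReading(
                time_s=float(row.time_s),
                tool_id=str(row.tool_id),
                pose=pose,
                valid=bool(row.valid),
            )
        )
    return PoseStream(readings=readings)


def write_pose_csv(stream: PoseStream, path) -> None:
    rows = []
    for r in stream.readings:
        q = r.pose.quaternion
        t = r.pose.translation
        rows.append(
            {
                "time_s": r.time_s,
                "tool_id": r.tool_id,
                "tx": t[0],
                "ty": t[1],
                "tz": t[2],
                "qx": q[0],
                "qy": q[1],
                "qz": q[2],
                "qw": q[3],
                "valid": int(r.valid),
            }
        )
    df = pd.DataFrame(rows, columns=_POSE_COLUMNS)
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, index=False))


# ---------------------------------------------------------------------------
# transforms


def read_transform(path) -> Transform:
    path = Path(path)
    try:
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    except OSError as exc:
        raise FormatError(f"cannot read transform file {path}") from exc
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"transform file {path} lacks the header line")
    header = dict(
        tok.split("=", 1) for tok in lines[0].lstrip("#").split() if "=" in tok
    )
    if "source" not in header or "target" not in header:
        raise FormatError(f"transform header in {path} must declare source and target")
    rows = [ln.split() for ln in lines[1:5]]
    if len(rows) != 4 or any(len(r) != 4 for r in rows):
        raise FormatError(f"transform file {path} must have 4 rows of 4 floats")
    m = np.array(rows, dtype=float)
    kind = header.get("kind", "rigid")
    cls = RigidTransform if kind == "rigid" else AffineTransform
    return cls(m, source=header["source"], target=header["target"])


def write_transform(t: Transform, path) -> None:
    kind = "rigid" if isinstance(t, RigidTransform) else "affine"

    def _w(tmp: Path):
        with open(tmp, "w") as fh:
            fh.write(f"# source={t.source} target={t.target} kind={kind}\n")
            for row in t.matrix:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")

    _atomic_write(Path(path), _w)


# ---------------------------------------------------------------------------
# config


def load_config(path) -> dict:
    """Load a YAML or JSON experiment configuration as a plain dict."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read config {path}") from exc
    if path.suffix.lower() == ".json":
        try:
            return json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON config {path}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"invalid YAML config {path}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping")
    return data
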