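"""File formats, the packaged reference table, and report writing.

Pose tables are flat CSV/JSON files of planned and placed implant poses
(millimetres, right-handed frame, period decimal separator).  Point
clouds come from STL/PLY meshes (vertices de-duplicated, connectivity
discarded — registration here is point based) or plain XYZ text.
Reports mirror the conventional accuracy-table layout: one row per
implant at one decimal, a "Mean (SD)" footer with the angular column at
two decimals, and "NA" for implants whose accuracy could not be
measured.

All readers validate and reject rather than coerce; every error names
the offending row and column.  Rounding happens only at report-writing
time — internal pipelines carry full precision.
"""

from __future__ import annotations

import csv
import importlib.resources
import io as _io
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import DeviationRecord, ImplantPose
from .registration import PointCloud

__all__ = [
    "PoseTableError",
    "CloudFormatError",
    "read_pose_table",
    "write_pose_table",
    "pair_poses",
    "read_cloud",
    "write_cloud_xyz",
    "load_table1",
    "table1_records",
    "write_report",
    "format_summary",
]

_POSE_COLUMNS = [
    "patient_id",
    "implant_id",
    "location_fdi",
    "role",
    "shoulder_x",
    "shoulder_y",
    "shoulder_z",
    "apex_x",
    "apex_y",
    "apex_z",
    "length_mm",
    "diameter_mm",
]
_OPTIONAL_COLUMNS = {"length_mm", "diameter_mm"}


class PoseTableError(ValueError):
    """Malformed pose table; the message names row and column."""


class CloudFormatError(ValueError):
    """Malformed point-cloud file."""


def _parse_float(text: str, row: int, col: str, optional: bool = False) -> Optional[float]:
    s = text.strip()
    if s == "" or s.upper() in ("NA", "NAN"):
        if optional:
            return None
        raise PoseTableError(f"row {row}: missing value in column '{col}'")
    if "," in s:
        raise PoseTableError(
            f"row {row}, column '{col}': comma found in {s!r} — this reader "
            "requires a period decimal separator (comma-decimal CSV rejected)"
        )
    try:
        v = float(s)
    except ValueError:
        raise PoseTableError(f"row {row}, column '{col}': non-numeric value {s!r}") from None
    if not math.isfinite(v):
        raise PoseTableError(f"row {row}, column '{col}': non-finite value {s!r}")
    return v


def _pose_from_mapping(m: dict, row: int) -> ImplantPose:
    for col in _POSE_COLUMNS:
        if col not in m and col not in _OPTIONAL_COLUMNS:
            raise PoseTableError(f"row {row}: missing column '{col}'")
    coords = {
        c: _parse_float(str(m[c]), row, c)
        for c in _POSE_COLUMNS[4:10]
    }
    length = _parse_float(str(m.get("length_mm", "")), row, "length_mm", optional=True)
    diam = _parse_float(str(m.get("diameter_mm", "")), row, "diameter_mm", optional=True)
    role = str(m["role"]).strip()
    if role not in ("planned", "placed"):
        raise PoseTableError(f"row {row}, column 'role': must be planned/placed, got {role!r}")
    try:
        return ImplantPose(
            patient_id=str(m["patient_id"]).strip(),
            implant_id=str(m["implant_id"]).strip(),
            location=str(m["location_fdi"]).strip(),
            role=role,
            shoulder=np.array([coords["shoulder_x"], coords["shoulder_y"], coords["shoulder_z"]]),
            apex=np.array([coords["apex_x"], coords["apex_y"], coords["apex_z"]]),
            length_mm=length,
            diameter_mm=diam,
        )
    except ValueError as e:
        raise PoseTableError(f"row {row}: {e}") from e


def read_pose_table(path: Union[str, Path], format: Optional[str] = None) -> list[ImplantPose]:
    """Read a validated pose table (CSV with header, or JSON list).

    Keys ``(patient_id, location_fdi, role)`` must be unique.  The CSV
    dialect is comma-separated, period-decimal, UTF-8.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    poses: list[ImplantPose] = []
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise PoseTableError(f"{path}: empty file (header row required)")
            missing = [c for c in _POSE_COLUMNS if c not in reader.fieldnames and c not in _OPTIONAL_COLUMNS]
            if missing:
                raise PoseTableError(f"{path}: missing column '{missing[0]}'")
            for i, row in enumerate(reader, start=2):  # header is line 1
                poses.append(_pose_from_mapping(row, i))
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise PoseTableError(f"{path}: JSON pose table must be a list of objects")
        for i, row in enumerate(data, start=1):
            poses.append(_pose_from_mapping(row, i))
    else:
        raise PoseTableError(f"unknown pose-table format {fmt!r}")
    seen = set()
    for i, p in enumerate(poses):
        key = (p.patient_id, p.location, p.role)
        if key in seen:
            raise PoseTableError(f"duplicate pose key {key} (patient_id, location_fdi, role)")
        seen.add(key)
    return poses


def write_pose_table(poses: Sequence[ImplantPose], path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write poses as CSV (default) or JSON, full precision."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = []
    for p in poses:
        rows.append(
            {
                "patient_id": p.patient_id,
                "implant_id": p.implant_id,
                "location_fdi": p.location,
                "role": p.role,
                "shoulder_x": repr(float(p.shoulder[0])),
                "shoulder_y": repr(float(p.shoulder[1])),
                "shoulder_z": repr(float(p.shoulder[2])),
                "apex_x": repr(float(p.apex[0])),
                "apex_y": repr(float(p.apex[1])),
                "apex_z": repr(float(p.apex[2])),
                "length_mm": "" if p.length_mm is None else repr(float(p.length_mm)),
                "diameter_mm": "" if p.diameter_mm is None else repr(float(p.diameter_mm)),
            }
        )
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=_POSE_COLUMNS)
            w.writeheader()
            w.writerows(rows)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise PoseTableError(f"unknown pose-table format {fmt!r}")


def pair_poses(
    planned: Sequence[ImplantPose], placed: Sequence[ImplantPose]
) -> list[tuple[ImplantPose, ImplantPose]]:
    """Match planned and placed poses on (patient_id, location_fdi).

    Raises with the unpaired keys spelled out when the two sets do not
    cover exactly the same implants.
    """
    pl = {(p.patient_id, p.location): p for p in planned}
    pc = {(p.patient_id, p.location): p for p in placed}
    only_planned = sorted(set(pl) - set(pc))
    only_placed = sorted(set(pc) - set(pl))
    if only_planned or only_placed:
        raise PoseTableError(
            f"unpaired implants — planned only: {only_planned or 'none'}, "
            f"placed only: {only_placed or 'none'}"
        )
    return [(pl[k], pc[k]) for k in sorted(pl)]


def read_cloud(path: Union[str, Path], format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from STL (binary or ASCII), PLY, or XYZ text.

    Mesh vertices are de-duplicated into a point set; triangle
    connectivity is discarded.
    """
    path = Path(path)
    ext = (format or path.suffix.lstrip(".")).lower()
    if ext in ("stl", "stl_binary", "stl_ascii", "ply"):
        import trimesh

        if path.stat().st_size == 0:
            raise CloudFormatError(f"{path}: empty file")
        try:
            mesh = trimesh.load(str(path), file_type="ply" if ext == "ply" else "stl", process=True)
        except Exception as e:
            raise CloudFormatError(f"{path}: cannot parse mesh ({e})") from e
        verts = np.asarray(mesh.vertices, dtype=float)
        if verts.size == 0:
            raise CloudFormatError(f"{path}: mesh contains no vertices")
        verts = np.unique(np.round(verts, 9), axis=0)
        return PointCloud(verts)
    if ext == "xyz":
        try:
            pts = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as e:
            raise CloudFormatError(f"{path}: cannot parse XYZ text ({e})") from e
        if pts.size == 0:
            raise CloudFormatError(f"{path}: empty file")
        if pts.shape[1] != 3:
            raise CloudFormatError(f"{path}: expected 3 columns, got {pts.shape[1]}")
        return PointCloud(pts)
    raise CloudFormatError(f"unsupported cloud format {ext!r}")


def write_cloud_xyz(cloud: PointCloud, path: Union[str, Path]) -> None:
    np.savetxt(path, cloud.points, fmt="%.9f")


def load_table1() -> pd.DataFrame:
    """The packaged per-implant deviation table of the reference cohort.

    24 implants in 11 patients; one implant (patient 6, site 23) carries
    NA throughout because its template did not fit and its accuracy was
    not measured.
    """
    with importlib.resources.files("implacc.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(
            fh,
            dtype={"patient_no": int, "template_fit": str, "location_fdi": str},
            na_values=["NA"],
        )
    return df


def table1_records() -> list[DeviationRecord]:
    """The packaged table as deviation records (signs unknown: depth
    stored as its printed magnitude)."""
    recs = []
    for _, row in load_table1().iterrows():
        missing = pd.isna(row["angular_deg"])
        recs.append(
            DeviationRecord(
                patient_id=str(row["patient_no"]),
                location=str(row["location_fdi"]),
                angular_deg=None if missing else float(row["angular_deg"]),
                global_mm=None if missing else float(row["global_mm"]),
                lateral_mm=None if missing else float(row["lateral_mm"]),
                depth_mm=None if missing else float(row["depth_mm"]),
                depth_signed_mm=None if missing else float(row["depth_mm"]),
                implant_length_mm=None
                if pd.isna(row["implant_length_mm"])
                else float(row["implant_length_mm"]),
            )
        )
    return recs


def _fmt(v: Optional[float], decimals: int) -> str:
    return "NA" if v is None else f"{v:.{decimals}f}"


def format_summary(records: Sequence[DeviationRecord], divisor: str = "population") -> str:
    """Human-readable 'Mean (SD)' summary block, report rounding applied
    (angular two decimals, distances one)."""
    from .agreement import summarise_cohort

    rows = summarise_cohort(records, divisor=divisor)
    out = []
    for r in rows:
        dec = 2 if r.metric == "angular_deg" else 1
        unit = "deg" if r.metric == "angular_deg" else "mm"
        name = r.metric.replace("_deg", "").replace("_mm", "")
        out.append(f"{name:8s} n={r.n:<3d} mean (SD) = {r.mean:.{dec}f} ({r.sd:.{dec}f}) {unit}")
    return "\n".join(out)


def write_report(
    records: Sequence[DeviationRecord],
    output_path: Union[str, Path],
    style: str = "per_implant_csv",
    divisor: str = "population",
) -> None:
    """Write a deviation report.

    ``per_implant_csv``: one row per implant (1-decimal cells, "NA" for
    unmeasured implants) plus a "Mean (SD)" footer with the angular cell
    at 2 decimals.  ``summary_csv``: the four summary rows with n, mean,
    sd, min, max.
    """
    from .agreement import summarise_cohort

    if not records:
        raise ValueError("no records to report")
    output_path = Path(output_path)
    if style == "per_implant_csv":
        buf = _io.StringIO()
        w = csv.writer(buf)
        w.writerow(
            [
                "patient_id",
                "location_fdi",
                "implant_length_mm",
                "angular_deg",
                "global_mm",
                "lateral_mm",
                "depth_mm",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.location,
                    "NA" if r.implant_length_mm is None else f"{r.implant_length_mm:g}",
                    _fmt(r.angular_deg, 1),
                    _fmt(r.global_mm, 1),
                    _fmt(r.lateral_mm, 1),
                    _fmt(r.depth_mm, 1),
                ]
            )
        summ = {s.metric: s for s in summarise_cohort(records, divisor=divisor)}
        a = summ["angular_deg"]
        w.writerow(
            [
                "Mean (SD)",
                "",
                "",
                f"{a.mean:.2f} ({a.sd:.2f})",
                f"{summ['global_mm'].mean:.1f} ({summ['global_mm'].sd:.1f})",
                f"{summ['lateral_mm'].mean:.1f} ({summ['lateral_mm'].sd:.1f})",
                f"{summ['depth_mm'].mean:.1f} ({summ['depth_mm'].sd:.1f})",
            ]
        )
        output_path.write_text(buf.getvalue(), encoding="utf-8")
    elif style == "summary_csv":
        rows = summarise_cohort(records, divisor=divisor)
        buf = _io.StringIO()
        w = csv.writer(buf)
        w.writerow(["metric", "n", "mean", "sd", "min", "max"])
        for r in rows:
            dec = 2 if r.metric == "angular_deg" else 1
            w.writerow(
                [r.metric, r.n, f"{r.mean:.{dec}f}", f"{r.sd:.{dec}f}", f"{r.min:.{dec}f}", f"{r.max:.{dec}f}"]
            )
        output_path.write_text(buf.getvalue(), encoding="utf-8")
    else:
        raise ValueError(f"unknown report style {style!r}")
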