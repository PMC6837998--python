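"""Readers and writers for landmark tables, meshes and report files.

Landmark CSV schema: ``subject_id,structure,side,sex,point_index,x,y,z`` with
0-based point indices and coordinates in mm. JSON mirrors the same fields.
PLY/OBJ meshes are read with trimesh (unprocessed, so file vertex order is
the landmark order); faces are ignored for statistics but retained for
visualization export.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import CorrespondenceError, LandmarkConfiguration

__all__ = [
    "ParseError",
    "read_landmarks",
    "write_landmarks",
    "read_mesh_landmarks",
    "write_mesh",
    "write_scalar_field_csv",
    "write_scalar_field_ply",
    "pair_by_subject",
]

_CSV_COLUMNS = ["subject_id", "structure", "side", "sex", "point_index", "x", "y", "z"]


class ParseError(ValueError):
    """Malformed landmark file."""


def _validate_group(subject_id, side, idx: np.ndarray, path) -> None:
    expected = np.arange(idx.size)
    if not np.array_equal(np.sort(idx), expected):
        missing = sorted(set(expected) - set(idx))
        raise ParseError(
            f"{path}: subject {subject_id} side {side} has invalid point indices "
            f"(missing or duplicated: {missing[:10]})"
        )


def _check_consistent_K(configs: Sequence[LandmarkConfiguration], path) -> None:
    by_structure = {}
    for c in configs:
        by_structure.setdefault(c.structure, set()).add(c.n_landmarks)
    bad = {s: ks for s, ks in by_structure.items() if len(ks) > 1}
    if bad:
        raise CorrespondenceError(
            f"{path}: inconsistent landmark counts per structure: {bad}"
        )


def read_landmarks(path, fmt: Optional[str] = None) -> list:
    """Read a landmark dataset from CSV/JSON (or a PLY/OBJ mesh).

    Returns a list of :class:`LandmarkConfiguration`, validated for complete
    0..K-1 point indices and a consistent K per structure.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("ply", "obj"):
        return [read_mesh_landmarks(path)]
    if fmt == "json":
        payload = json.loads(path.read_text())
        configs = []
        for rec in payload["configurations"]:
            pts = np.asarray(rec["points"], dtype=float)
            configs.append(
                LandmarkConfiguration(
                    subject_id=str(rec["subject_id"]),
                    structure=str(rec.get("structure", payload.get("structure", ""))),
                    points=pts,
                    side=rec.get("side", "none"),
                    sex=rec.get("sex", "unknown"),
                )
            )
        _check_consistent_K(configs, path)
        return configs
    if fmt != "csv":
        raise ValueError(f"unsupported landmark format: {fmt}")

    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    if df[["x", "y", "z"]].isna().any().any():
        bad = int(df[["x", "y", "z"]].isna().any(axis=1).idxmax()) + 2  # header line
        raise ParseError(f"{path}: non-numeric coordinate near line {bad}")

    configs = []
    for (sid, structure, side), grp in df.groupby(
        ["subject_id", "structure", "side"], sort=True
    ):
        idx = grp["point_index"].to_numpy(dtype=int)
        _validate_group(sid, side, idx, path)
        order = np.argsort(idx)
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)[order]
        sexes = grp["sex"].unique()
        configs.append(
            LandmarkConfiguration(
                subject_id=str(sid),
                structure=str(structure),
                points=pts,
                side=str(side),
                sex=str(sexes[0]),
            )
        )
    _check_consistent_K(configs, path)
    return configs


def write_landmarks(configs: Sequence[LandmarkConfiguration], path,
                    fmt: Optional[str] = None) -> None:
    """Write configurations to CSV or JSON; round trips are lossless."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        payload = {
            "configurations": [
                {
                    "subject_id": c.subject_id,
                    "structure": c.structure,
                    "side": c.side,
                    "sex": c.sex,
                    "points": c.points.tolist(),
                }
                for c in configs
            ]
        }
        path.write_text(json.dumps(payload))
        return
    if fmt != "csv":
        raise ValueError(f"unsupported landmark format: {fmt}")
    rows = []
    for c in configs:
        for i, (x, y, z) in enumerate(c.points):
            rows.append((c.subject_id, c.structure, c.side, c.sex, i, x, y, z))
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_mesh_landmarks(path, subject_id: Optional[str] = None,
                        structure: str = "", side: str = "none",
                        sex: str = "unknown") -> LandmarkConfiguration:
    """Read a PLY/OBJ mesh; vertices in file order become the landmarks."""
    import trimesh

    path = Path(path)
    mesh = trimesh.load(path, process=False)
    vertices = np.asarray(mesh.vertices, dtype=float)
    return LandmarkConfiguration(
        subject_id=subject_id or path.stem,
        structure=structure or path.stem,
        points=vertices,
        side=side,
        sex=sex,
    )


def write_mesh(points: np.ndarray, path, faces: Optional[np.ndarray] = None) -> None:
    """Export landmarks as a PLY/OBJ mesh (point cloud when no faces)."""
    import trimesh

    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if faces is None:
        trimesh.PointCloud(pts).export(str(path))
    else:
        trimesh.Trimesh(vertices=pts, faces=faces, process=False).export(str(path))


def write_scalar_field_csv(values: np.ndarray, path) -> None:
    """Per-vertex scalar field as ``point_index,value_mm`` CSV."""
    df = pd.DataFrame(
        {"point_index": np.arange(len(values)), "value_mm": np.asarray(values, float)}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_scalar_field_ply(points: np.ndarray, values: np.ndarray, path,
                           faces: Optional[np.ndarray] = None) -> None:
    """Heat-map export: scalar field mapped to vertex colors on the shape."""
    import trimesh
    from matplotlib import cm

    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    vals = np.asarray(values, dtype=float)
    vmax = vals.max() if vals.max() > 0 else 1.0
    colors = (cm.viridis(vals / vmax) * 255).astype(np.uint8)
    if faces is None:
        cloud = trimesh.PointCloud(pts, colors=colors)
        cloud.export(str(path))
    else:
        mesh = trimesh.Trimesh(vertices=pts, faces=faces, process=False)
        mesh.visual.vertex_colors = colors
        mesh.export(str(path))


def pair_by_subject(configs: Sequence[LandmarkConfiguration]) -> list:
    """Group configurations into (left, right) pairs per subject."""
    by_subject = {}
    for c in configs:
        by_subject.setdefault(c.subject_id, {})[c.side] = c
    pairs = []
    for sid in sorted(by_subject):
        sides = by_subject[sid]
        if "left" not in sides or "right" not in sides:
            raise CorrespondenceError(f"subject {sid} lacks a left/right pair")
        pairs.append((sides["left"], sides["right"]))
    return pairs
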