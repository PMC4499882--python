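"""File formats and run plumbing.

Bead tracks travel as CSV with columns ``bead_id, t, x, y, z`` (hours and
micrometres; one row per bead per timepoint; header required). Images and
masks are single-channel TIFF. Field data for visualisation is written as
legacy ASCII VTK. Reports and ground-truth sidecars are JSON with sorted
keys so identical runs produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .kinematics import BeadTrack
from .mesh import GelDomainMesh

BEAD_TRACK_COLUMNS = ("bead_id", "t", "x", "y", "z")


def read_bead_tracks(path: str | Path) -> list[BeadTrack]:
    """Read and validate a bead-track CSV into per-bead trajectories.

    Raises with the offending column name / row number on missing columns,
    non-numeric cells or duplicated (bead_id, t) pairs. Rows are sorted by
    time within each bead.
    """
    df = pd.read_csv(path, dtype={"bead_id": str},
                 float_precision="round_trip")
    for col in BEAD_TRACK_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"bead track file {path}: missing column {col!r}")
    for col in ("t", "x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if len(bad):
            raise ValueError(
                f"bead track file {path}: non-numeric {col!r} at row {bad[0] + 2}")
        if vals.isna().any():
            row = int(np.nonzero(vals.isna().to_numpy())[0][0])
            raise ValueError(
                f"bead track file {path}: missing {col!r} at row {row + 2}")
        df[col] = vals
    if df.duplicated(subset=["bead_id", "t"]).any():
        dup = df[df.duplicated(subset=["bead_id", "t"])].iloc[0]
        raise ValueError(
            f"bead track file {path}: duplicate (bead_id, t) = "
            f"({dup.bead_id!r}, {dup.t})")
    tracks = []
    for bead_id, grp in df.sort_values("t").groupby("bead_id", sort=True):
        tracks.append(BeadTrack(
            bead_id=str(bead_id),
            times=grp["t"].to_numpy(),
            positions=grp[["x", "y", "z"]].to_numpy()))
    return tracks


def write_bead_tracks(table: pd.DataFrame, path: str | Path) -> None:
    """Write a bead-track table; floats use shortest round-trip repr so a
    write/read cycle is lossless."""
    missing = [c for c in BEAD_TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"bead track table missing columns {missing}")
    table.to_csv(path, index=False, columns=list(BEAD_TRACK_COLUMNS))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Single-channel TIFF, grayscale, no timestamps (reproducible bytes)."""
    tifffile.imwrite(path, np.asarray(image), photometric="minisblack")


def write_mask_stack(stack: np.ndarray, path: str | Path) -> None:
    write_image(np.asarray(stack).astype(np.uint8), path)


def read_mask_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# Legacy ASCII VTK writers (visualisation only)
# --------------------------------------------------------------------------

def write_vtk_points(
    path: str | Path,
    points: np.ndarray,
    vectors: dict[str, np.ndarray] | None = None,
    scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Point cloud with optional per-point vector/scalar data."""
    pts = np.atleast_2d(np.asarray(points, float))
    lines = ["# vtk DataFile Version 3.0", "geltrax point data", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(pts)} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in pts]
    data_lines = [f"POINT_DATA {len(pts)}"]
    for name, arr in (vectors or {}).items():
        data_lines.append(f"VECTORS {name} double")
        data_lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
    for name, arr in (scalars or {}).items():
        data_lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        data_lines += [f"{v:.9g}" for v in arr]
    Path(path).write_text("\n".join(lines + data_lines) + "\n")


def write_vtk_mesh(
    path: str | Path,
    mesh: GelDomainMesh,
    point_vectors: dict[str, np.ndarray] | None = None,
) -> None:
    """Unstructured tetrahedral grid (corner nodes only, VTK_TETRA)."""
    corners = mesh.tets[:, :4]
    lines = ["# vtk DataFile Version 3.0", "geltrax gel mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {len(corners)} {len(corners) * 5}")
    lines += ["4 " + " ".join(str(i) for i in tet) for tet in corners]
    lines.append(f"CELL_TYPES {len(corners)}")
    lines += ["10"] * len(corners)
    if point_vectors:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_vectors.items():
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def hash_files(paths: Iterable[str | Path]) -> dict[str, str]:
    """Relative-path -> sha256 map used in run manifests."""
    return {str(Path(p).name): sha256_file(p) for p in sorted(map(str, paths))}
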