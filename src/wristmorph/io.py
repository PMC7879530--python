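"""File I/O: surface meshes, landmark files, transforms, run configuration.

Meshes travel as PLY (binary little-endian, float64 vertices so coordinates
round-trip losslessly) or STL; landmarks as JSON ``{name: [x, y, z]}`` or
long-format CSV (case_id, state, landmark, x, y, z).  Units are always mm.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import MeshError, SchemaError
from .metrics import LANDMARK_NAMES, TRIAD_NAMES

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "RunConfig",
]


def _export_ply_f64(mesh: trimesh.Trimesh, path: Path) -> None:
    # trimesh's PLY export stores float32 vertices; write double precision so
    # mm coordinates survive a round trip bit-exactly
    v = np.asarray(mesh.vertices, dtype="<f8")
    f = np.asarray(mesh.faces, dtype="<i4")
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {len(v)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(f)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(v.tobytes())
        for tri in f:
            fh.write(struct.pack("<B3i", 3, *tri))


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh as PLY (float64 binary) or STL, by file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        _export_ply_f64(mesh, path)
    elif suffix == ".stl":
        mesh.export(path)
    else:
        raise MeshError(f"unsupported mesh format {suffix!r} (use .ply or .stl)")


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a PLY or STL surface; cleans duplicate faces and enforces a
    consistent winding."""
    path = Path(path)
    if not path.exists():
        raise MeshError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(path, file_type=path.suffix.lstrip(".").lower(), process=False)
    except Exception as exc:  # malformed / truncated file
        raise MeshError(f"failed to parse mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshError(f"{path} contains no triangulated surface")
    mesh.update_faces(mesh.nondegenerate_faces())
    trimesh.repair.fix_normals(mesh)
    return mesh


def _validate_names(landmarks: dict, required: tuple = TRIAD_NAMES) -> None:
    missing = [n for n in required if n not in landmarks]
    if missing:
        pretty = ", ".join(f"{n} ({LANDMARK_NAMES.get(n, n)})" for n in missing)
        raise SchemaError(f"missing required landmark(s): {pretty}")


def write_landmarks(landmarks: dict, path: str | Path) -> None:
    """JSON ``{name: [x, y, z]}`` in mm."""
    payload = {k: np.asarray(v, dtype=float).tolist() for k, v in landmarks.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_landmarks(path: str | Path, required: tuple = TRIAD_NAMES) -> dict:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed landmark JSON {path}: {exc}") from exc
    landmarks = {}
    for name, xyz in data.items():
        arr = np.asarray(xyz, dtype=float)
        if arr.shape != (3,):
            raise SchemaError(f"landmark {name!r} in {path} is not a 3-vector")
        landmarks[name] = arr
    _validate_names(landmarks, required)
    return landmarks


def write_landmarks_csv(
    landmarks: dict, path: str | Path, case_id: str = "case", state: str = "plan"
) -> None:
    """Long-format CSV: case_id, state, landmark, x, y, z (mm)."""
    rows = [
        {"case_id": case_id, "state": state, "landmark": k,
         "x": float(v[0]), "y": float(v[1]), "z": float(v[2])}
        for k, v in sorted(landmarks.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_landmarks_csv(
    path: str | Path,
    case_id: str | None = None,
    state: str | None = None,
    required: tuple = TRIAD_NAMES,
) -> dict:
    df = pd.read_csv(path)
    needed = {"case_id", "state", "landmark", "x", "y", "z"}
    if not needed.issubset(df.columns):
        raise SchemaError(
            f"landmark CSV {path} missing columns: {sorted(needed - set(df.columns))}"
        )
    if case_id is not None:
        df = df[df["case_id"] == case_id]
    if state is not None:
        df = df[df["state"] == state]
    landmarks = {
        row.landmark: np.array([row.x, row.y, row.z], dtype=float)
        for row in df.itertuples()
    }
    _validate_names(landmarks, required)
    return landmarks


class RunConfig(BaseModel):
    """Validated configuration for the end-to-end pipeline run."""

    input_dir: str
    output_dir: str
    # frame
    shaft_band: tuple[float, float] = (0.35, 0.95)
    proximal_cutoff: float = 20.0  # mm of frame-y above which shaft counts as intact
    # registration
    icp_tol: float = 1e-6
    icp_max_iter: int = 200
    icp_trim_fraction: float = 0.1
    # statistics
    icc_form: str = "twoway_agreement_2_1"
    correction: str = "holm"
    # bookkeeping
    seed: int = 0
    verbosity: int = Field(default=1, ge=0, le=2)

    @field_validator("shaft_band")
    @classmethod
    def _band_ordered(cls, v):
        lo, hi = v
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("shaft_band must satisfy 0 <= lo < hi <= 1")
        return v

    @field_validator("icp_trim_fraction")
    @classmethod
    def _trim_range(cls, v):
        if not 0.0 <= v < 1.0:
            raise ValueError("icp_trim_fraction must be in [0, 1)")
        return v

    @field_validator("icc_form")
    @classmethod
    def _known_form(cls, v):
        from .stats import ICC_FORMS

        if v not in ICC_FORMS:
            raise ValueError(f"icc_form must be one of {ICC_FORMS}")
        return v

    @field_validator("correction")
    @classmethod
    def _known_correction(cls, v):
        if v not in ("holm", "bonferroni"):
            raise ValueError("correction must be 'holm' or 'bonferroni'")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        try:
            return cls(**data)
        except Exception as exc:
            raise SchemaError(f"invalid run config {path}: {exc}") from exc
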