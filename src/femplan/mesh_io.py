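"""Mesh reading, validation and contour export.

Meshes are represented as :class:`trimesh.Trimesh` throughout the package;
this module owns the validated entry and exit points.  All coordinates are
millimetres — no unit inference is attempted, because every clinical
threshold downstream (1.5 mm overhang, 2 mm underhang, 10 mm distal cut,
1.8 mm cartilage offset) is absolute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "MeshFormatError",
    "MeshValidationError",
    "WatertightReport",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "validate_watertight",
    "export_contours_json",
    "load_contours_json",
]

_SUPPORTED = {".stl", ".ply", ".obj"}
#: vertices closer than this are welded on load (mm)
MERGE_TOL = 1e-6


class MeshFormatError(RuntimeError):
    """File could not be parsed as a supported mesh format."""


class MeshValidationError(RuntimeError):
    """Mesh parsed but failed structural validation."""


@dataclass
class WatertightReport:
    watertight: bool
    boundary_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    nonmanifold_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    n_components: int = 1

    def __bool__(self) -> bool:  # truthiness == verdict
        return self.watertight


def validate_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Weld duplicate vertices, drop degenerate faces, range-check indices."""
    if len(mesh.faces) == 0:
        raise MeshValidationError("mesh has no faces")
    if mesh.faces.max() >= len(mesh.vertices) or mesh.faces.min() < 0:
        raise MeshValidationError("face indices out of range")
    mesh = mesh.copy()
    mesh.merge_vertices(digits_vertex=int(-np.log10(MERGE_TOL)))
    areas = trimesh.triangles.area(mesh.triangles)
    if (areas <= 0).any():
        mesh.update_faces(areas > 0)
    mesh.remove_unreferenced_vertices()
    if len(mesh.faces) == 0:
        raise MeshValidationError("all faces degenerate after welding")
    return mesh


def read_mesh(path: str | Path, expected_units: str = "mm") -> trimesh.Trimesh:
    """Read an STL/PLY/OBJ surface and return a validated mesh.

    ``expected_units`` is documentation of caller intent only — the file is
    taken to be in that unit (always millimetres in this package).
    """
    path = Path(path)
    if expected_units != "mm":
        raise ValueError("only millimetre meshes are supported")
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    if path.suffix.lower() not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh extension {path.suffix!r}")
    try:
        loaded = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # parser errors vary by format
        raise MeshFormatError(f"could not parse {path}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle geometry")
    return validate_mesh(loaded)


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh; format chosen by extension (binary STL by default)."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh extension {path.suffix!r}")
    mesh.export(str(path))


def validate_watertight(mesh: trimesh.Trimesh) -> WatertightReport:
    """Check that every edge is shared by exactly two faces.

    Diagnostics (boundary and non-manifold edge lists, connected-component
    count) are returned, never raised, so callers can report them.
    """
    edges = np.sort(mesh.edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    nonmanifold = uniq[counts > 2]
    n_comp = len(mesh.split(only_watertight=False)) if len(mesh.faces) else 0
    return WatertightReport(
        watertight=len(boundary) == 0 and len(nonmanifold) == 0,
        boundary_edges=boundary,
        nonmanifold_edges=nonmanifold,
        n_components=max(n_comp, 1),
    )


def export_contours_json(contours: list[np.ndarray], path: str | Path) -> None:
    """Write polylines as a JSON list of lists of [x, y, z] (mm)."""
    data = [np.asarray(c, dtype=float).tolist() for c in contours]
    Path(path).write_text(json.dumps(data))


def load_contours_json(path: str | Path) -> list[np.ndarray]:
    data = json.loads(Path(path).read_text())
    return [np.asarray(c, dtype=float) for c in data]
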