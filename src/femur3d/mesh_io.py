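"""Reading, validating, cleaning and writing femur surface meshes.

STL files carry no units; this package fixes **millimetres** by contract,
matching the scale of CT-derived bone exports.  Reading merges duplicate
vertices (STL stores vertices per facet) at a tolerance of 1e-6 mm, far
below any CT voxel size.

The one cleaning step the measurement pipeline relies on is
:func:`remove_internal_shells`: segmented CT bone often contains a second,
inner cortical/medullary shell, and only the outer cortical surface is
anatomy.  Shells are ranked by surface area (robust to differing mesh
resolution between shells) and only the largest is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import EmptyMeshError, MeshFormatError

MERGE_TOL = 1e-6  # mm; duplicate-vertex merge distance


@dataclass
class TriangleMesh:
    """A triangular surface mesh in millimetres.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    provenance : source filename, or ``"synthetic"`` for generated meshes.
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, provenance: str = "unknown"):
        return cls(
            vertices=np.asarray(tm.vertices, dtype=float),
            faces=np.asarray(tm.faces, dtype=np.int64),
            provenance=provenance,
        )

    def check(self) -> None:
        """Raise if basic structural invariants are violated."""
        if self.n_vertices == 0 or self.n_faces == 0:
            raise EmptyMeshError("mesh has no vertices or faces")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError("non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshFormatError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshFormatError("face with repeated vertex")


@dataclass
class ValidationReport:
    """Structural summary of a mesh; serializable to JSON."""

    watertight: bool
    n_components: int
    n_vertices: int
    n_faces: int
    n_degenerate_faces: int
    bbox_min: tuple
    bbox_max: tuple
    extent_mm: tuple
    surface_area_mm2: float
    issues: list = field(default_factory=list)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.__dict__, indent=indent, default=list)


def _merge_duplicates(tm: trimesh.Trimesh) -> trimesh.Trimesh:
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    # drop faces degenerated by the merge
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    return tm


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a :class:`TriangleMesh`.

    Duplicate vertices within 1e-6 mm are merged; triangle winding is kept
    as stored.
    """
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # trimesh raises assorted types on bad bytes
        raise MeshFormatError(f"unreadable STL file {path!s}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise EmptyMeshError(f"STL file {path!s} contains no triangles")
    tm = _merge_duplicates(tm)
    mesh = TriangleMesh.from_trimesh(tm, provenance=str(path))
    mesh.check()
    return mesh


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write a mesh to ``path`` as binary (default) or ASCII STL.

    Binary output is byte-stable for a fixed input mesh.
    """
    mesh.check()
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    tm = mesh.to_trimesh()
    if dialect == "binary":
        data = trimesh.exchange.stl.export_stl(tm)
        with open(path, "wb") as fh:
            fh.write(data)
    else:
        data = trimesh.exchange.stl.export_stl_ascii(tm)
        with open(path, "w") as fh:
            fh.write(data)


def connected_components(mesh: TriangleMesh) -> list[TriangleMesh]:
    """Split into connected shells, ordered by descending surface area."""
    tm = mesh.to_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) == 0:
        return []
    parts = sorted(parts, key=lambda p: -float(p.area))
    return [TriangleMesh.from_trimesh(p, provenance=mesh.provenance) for p in parts]


def remove_internal_shells(mesh: TriangleMesh) -> TriangleMesh:
    """Keep only the connected shell with the largest surface area.

    Segmented long bones frequently carry an inner (endosteal) shell in
    addition to the outer cortical surface; only the outer one is measured.
    Idempotent; single-component input is returned unchanged.
    """
    mesh.check()
    parts = connected_components(mesh)
    if len(parts) <= 1:
        return mesh
    return parts[0]


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Report watertightness, component count, extent and degeneracies.

    Never mutates its input.
    """
    mesh.check()
    tm = mesh.to_trimesh()
    n_degenerate = int(len(mesh.faces) - tm.nondegenerate_faces().sum())
    n_components = len(tm.split(only_watertight=False))
    bmin = tm.bounds[0]
    bmax = tm.bounds[1]
    issues = []
    if not tm.is_watertight:
        issues.append("not watertight")
    if n_components != 1:
        issues.append(f"{n_components} connected components")
    if n_degenerate:
        issues.append(f"{n_degenerate} degenerate faces")
    return ValidationReport(
        watertight=bool(tm.is_watertight),
        n_components=n_components,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        n_degenerate_faces=n_degenerate,
        bbox_min=tuple(float(x) for x in bmin),
        bbox_max=tuple(float(x) for x in bmax),
        extent_mm=tuple(float(x) for x in (bmax - bmin)),
        surface_area_mm2=float(tm.area),
        issues=issues,
    )
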