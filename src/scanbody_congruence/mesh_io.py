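"""Triangle mesh container and STL/PLY/OBJ input-output.

All mesh coordinates are millimetres.  Deviation quantities elsewhere in the
package are micrometres; the conversion happens at the deviation layer, never
here.

STL stores a triangle soup with no vertex sharing, so :func:`read_mesh`
re-merges coincident vertices (tolerance ``MERGE_TOL`` mm) to rebuild the
connectivity needed for consistent outward normals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import trimesh

from .errors import EmptyMeshError, MeshInputError, ParameterError

log = logging.getLogger(__name__)

#: vertices closer than this (mm) are considered the same point
MERGE_TOL = 1e-9
#: faces with area (mm^2) at or below this are dropped as degenerate
DEGENERATE_AREA_TOL = 1e-12

_FORMATS = ("stl", "stl_ascii", "ply", "obj")


@dataclass
class TriangleMesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    name : free-text label carried through the pipeline
    metadata : provenance (simulation parameters, applied transforms, ...)
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ParameterError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ParameterError("faces must be an (m, 3) array")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ParameterError("face indices out of range")
        self._cache: dict = {}

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        if "triangles" not in self._cache:
            self._cache["triangles"] = self.vertices[self.faces]
        return self._cache["triangles"]

    @property
    def face_normals(self) -> np.ndarray:
        """Unit normals following the winding order (outward for valid solids)."""
        if "face_normals" not in self._cache:
            t = self.triangles
            n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._cache["face_normals"] = n / norm
        return self._cache["face_normals"]

    @property
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            t = self.triangles
            c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            self._cache["face_areas"] = 0.5 * np.linalg.norm(c, axis=1)
        return self._cache["face_areas"]

    @property
    def face_centroids(self) -> np.ndarray:
        if "face_centroids" not in self._cache:
            self._cache["face_centroids"] = self.triangles.mean(axis=1)
        return self._cache["face_centroids"]

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of adjacent face normals, unit length."""
        if "vertex_normals" not in self._cache:
            vn = np.zeros_like(self.vertices)
            weighted = self.face_normals * self.face_areas[:, None]
            for k in range(3):
                np.add.at(vn, self.faces[:, k], weighted)
            norm = np.linalg.norm(vn, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._cache["vertex_normals"] = vn / norm
        return self._cache["vertex_normals"]

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) axis-aligned min/max corner."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- manipulation -------------------------------------------------------

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.name, dict(self.metadata)
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Return a copy with vertices mapped through ``R v + t``."""
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return TriangleMesh(v, self.faces.copy(), self.name, dict(self.metadata))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_arrays(
        cls,
        vertices: np.ndarray,
        faces: np.ndarray,
        name: str = "",
        merge_tol: float = MERGE_TOL,
    ) -> "TriangleMesh":
        """Build a validated mesh: merge near-duplicate vertices, drop
        degenerate faces.  Raises :class:`EmptyMeshError` if nothing survives."""
        vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        vertices, faces = _merge_vertices(vertices, faces, merge_tol)
        faces = _drop_degenerate(vertices, faces)
        if len(faces) == 0:
            raise EmptyMeshError(f"mesh {name!r} has no valid faces after cleaning")
        used = np.unique(faces)
        remap = np.full(len(vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return cls(vertices[used], remap[faces], name=name)


def _merge_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    if len(vertices) == 0:
        return vertices, faces
    keys = np.round(vertices / max(tol, 1e-12)).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def _drop_degenerate(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    if len(faces) == 0:
        return faces
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    t = vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
    )
    keep = distinct & (areas > DEGENERATE_AREA_TOL)
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropped %d degenerate face(s)", dropped)
        warnings.warn(f"dropped {dropped} degenerate face(s)", stacklevel=3)
    return faces[keep]


# ---------------------------------------------------------------------------
# file I/O (delegated to trimesh; STL binary + ASCII, PLY ascii, OBJ geometry)
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        fmt = format_hint.lower()
        if fmt not in _FORMATS:
            raise MeshInputError(f"unsupported format {format_hint!r}")
        return fmt
    ext = path.suffix.lower().lstrip(".")
    if ext not in ("stl", "ply", "obj"):
        raise MeshInputError(f"cannot infer mesh format from {path.name!r}")
    return ext


def read_mesh(path: str | Path, format_hint: str | None = None) -> TriangleMesh:
    """Read an STL (binary or ASCII), PLY, or OBJ file into a validated mesh.

    Duplicate vertices within ``MERGE_TOL`` mm are merged and degenerate
    faces dropped.  Raises :class:`MeshInputError` for unreadable files and
    :class:`EmptyMeshError` when no faces survive cleaning.
    """
    path = Path(path)
    if not path.exists():
        raise MeshInputError(f"no such file: {path}")
    fmt = _infer_format(path, format_hint)
    try:
        raw = trimesh.load(
            str(path), file_type=fmt.replace("stl_ascii", "stl"), process=False,
            force="mesh",
        )
    except EmptyMeshError:
        raise
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise MeshInputError(f"could not read {path}: {exc}") from exc
    if not hasattr(raw, "faces") or len(getattr(raw, "faces", [])) == 0:
        raise EmptyMeshError(f"{path} contains no triangles")
    return TriangleMesh.from_arrays(raw.vertices, raw.faces, name=path.stem)


def write_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    format: Literal["stl", "stl_ascii", "ply", "obj"] | None = None,
) -> None:
    """Write ``mesh`` to ``path``.

    ``format`` defaults to the file extension; plain ``"stl"`` is binary,
    ``"stl_ascii"`` the text variant.  PLY is written ascii so all outputs
    stay text-based.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write a mesh with no faces")
    tm = mesh.to_trimesh()
    kwargs: dict = {}
    if fmt == "ply":
        kwargs["encoding"] = "ascii"
    try:
        tm.export(str(path), file_type=fmt, **kwargs)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


@dataclass
class TrimRegion:
    """Axis-aligned box or axis-aligned cylinder used to crop a scan to a
    uniform extent.  The predicate is evaluated on face centroids; faces are
    kept whole (no re-triangulation).

    ``kind="box"`` uses ``lower``/``upper`` corners (mm).  ``kind="cylinder"``
    keeps points within ``radius`` of the axis through ``origin`` along
    ``axis`` with axial coordinate in ``[z_min, z_max]``.
    """

    kind: Literal["box", "cylinder"] = "box"
    mode: Literal["keep_inside", "keep_outside"] = "keep_inside"
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    origin: np.ndarray | None = None
    axis: np.ndarray | None = None
    radius: float = 0.0
    z_min: float = -np.inf
    z_max: float = np.inf

    def __post_init__(self) -> None:
        if self.kind == "box":
            if self.lower is None or self.upper is None:
                raise ParameterError("box region needs lower and upper corners")
            self.lower = np.asarray(self.lower, dtype=float)
            self.upper = np.asarray(self.upper, dtype=float)
            if not np.all(self.upper > self.lower):
                raise ParameterError("box region must have positive volume")
        elif self.kind == "cylinder":
            if self.origin is None or self.axis is None:
                raise ParameterError("cylinder region needs origin and axis")
            self.origin = np.asarray(self.origin, dtype=float)
            axis = np.asarray(self.axis, dtype=float)
            norm = np.linalg.norm(axis)
            if norm == 0 or self.radius <= 0:
                raise ParameterError("cylinder region must have positive volume")
            self.axis = axis / norm
        else:
            raise ParameterError(f"unknown region kind {self.kind!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        if self.kind == "box":
            inside = np.all((points >= self.lower) & (points <= self.upper), axis=1)
        else:
            rel = points - self.origin
            z = rel @ self.axis
            radial = np.linalg.norm(rel - np.outer(z, self.axis), axis=1)
            inside = (radial <= self.radius) & (z >= self.z_min) & (z <= self.z_max)
        if self.mode == "keep_outside":
            return ~inside
        return inside


def trim_mesh(mesh: TriangleMesh, region: TrimRegion) -> TriangleMesh:
    """Keep the faces whose centroid satisfies the region predicate."""
    keep = region.contains(mesh.face_centroids)
    if not keep.any():
        raise EmptyMeshError("trim region removed every face")
    used = np.unique(mesh.faces[keep])
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(
        mesh.vertices[used], remap[mesh.faces[keep]], mesh.name, dict(mesh.metadata)
    )
    return out
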