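"""Closed triangulated surfaces: I/O, validation, volumetry, plane operations.

All coordinates are millimetres; all volumes are millilitres.  The mm³→mL
conversion (÷1000) happens in exactly one place (:data:`MM3_PER_ML`).

File formats (STL binary/ascii, PLY, OBJ) are read and written through
``trimesh``; the in-memory container is a light :class:`SurfaceMesh` wrapper
around vertex/face arrays so the rest of the package is independent of the
I/O backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

MM3_PER_ML = 1000.0
#: vertices closer than this (mm) are merged on load; STL duplicates
#: vertices per facet, so merging is what makes the edge-manifold check work
MERGE_TOL = 1e-9


class MeshValidationError(ValueError):
    """Raised when a surface fails structural validation."""


class OpenMeshError(MeshValidationError):
    """Raised when a volume operation is attempted on a non-watertight mesh."""


@dataclass
class SurfaceMesh:
    """A triangulated surface in mm coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    name : identifier carried through reports
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "mesh"
    watertight: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshValidationError(
                f"{self.name}: face references vertex index outside "
                f"[0, {len(self.vertices)})"
            )

    # -- derived geometry ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (mm²): one third of each incident face.

        Used as quadrature weights for every area-weighted surface mean, which
        keeps those means mesh-resolution invariant.
        """
        areas = np.zeros(self.n_vertices)
        np.add.at(areas, self.faces.ravel(), np.repeat(self.face_areas() / 3.0, 3))
        return areas

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(), self.name, self.watertight
        )


@dataclass(frozen=True)
class Plane:
    """An oriented plane: unit ``normal`` and a ``point`` on the plane (mm)."""

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0.0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(
            self, "point", np.asarray(self.point, dtype=np.float64).reshape(3)
        )

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of ``points`` (positive on the normal side)."""
        return (np.atleast_2d(points) - self.point) @ self.normal

    def flipped(self) -> "Plane":
        return Plane(-self.normal, self.point)


# ---------------------------------------------------------------------------
# I/O and validation


def _validate(tm: trimesh.Trimesh, name: str) -> SurfaceMesh:
    if len(tm.faces) == 0:
        raise MeshValidationError(f"{name}: mesh has no faces")
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
    areas = tm.area_faces
    if np.any(areas <= 0.0):
        tm.update_faces(areas > 0.0)
        tm.remove_unreferenced_vertices()
    mesh = SurfaceMesh(tm.vertices.view(np.ndarray), tm.faces.view(np.ndarray), name)
    mesh.watertight = bool(tm.is_watertight)
    if mesh.watertight:
        # orientation repair: segmentation exports vary in winding
        if tm.volume < 0.0:
            mesh.faces = mesh.faces[:, ::-1].copy()
    else:
        warnings.warn(
            f"{name}: mesh is not watertight; volume operations will refuse it",
            stacklevel=3,
        )
    return mesh


def read_mesh(path: str | Path, format_hint: str | None = None) -> SurfaceMesh:
    """Read an STL/PLY/OBJ surface, merge duplicate vertices, validate.

    Non-watertight input yields a warning and a mesh whose volume operations
    raise :class:`OpenMeshError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load_mesh(str(path), file_type=format_hint, process=False)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read mesh {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise IOError(f"no mesh geometry in {path}")
        tm = trimesh.util.concatenate(geoms)
    return _validate(tm, name=path.stem)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write to STL/PLY/OBJ; the format follows the file extension."""
    mesh.to_trimesh().export(str(path))


def from_trimesh(tm: trimesh.Trimesh, name: str = "mesh") -> SurfaceMesh:
    """Wrap (and validate) an existing :class:`trimesh.Trimesh`."""
    return _validate(tm.copy(), name)


# ---------------------------------------------------------------------------
# Volumetry


def _require_closed(mesh: SurfaceMesh) -> None:
    if not mesh.watertight:
        raise OpenMeshError(
            f"{mesh.name}: volume requires a closed (watertight) mesh"
        )


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume in mL via the divergence theorem (signed tetrahedra)."""
    _require_closed(mesh)
    t = mesh.triangles()
    signed = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    return abs(signed) / MM3_PER_ML


def clip_volumes_by_plane(mesh: SurfaceMesh, plane: Plane) -> tuple[float, float]:
    """Volumes (mL) of the mesh parts on the normal / anti-normal side.

    Each triangle is clipped against the plane and its sub-polygons contribute
    signed tetrahedra referenced to a point *on* the plane, so the planar caps
    of both halves contribute exactly zero and the two parts sum to
    :func:`mesh_volume` to machine precision, for any plane and closed mesh.
    """
    _require_closed(mesh)
    tri = mesh.triangles() - plane.point  # reference point on the plane
    d = tri @ plane.normal  # (m, 3) signed vertex distances

    total = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    pos_mask = (d >= 0.0).all(axis=1)
    neg_mask = (d <= 0.0).all(axis=1)
    vol_pos = total[pos_mask].sum()
    vol_neg = total[neg_mask & ~pos_mask].sum()

    cross_idx = np.nonzero(~(pos_mask | neg_mask))[0]
    for i in cross_idx:
        vol_pos += _clipped_tet_volume(tri[i], d[i])
        vol_neg += _clipped_tet_volume(tri[i], -d[i])

    # orientation of the input decides the global sign; normalise like
    # mesh_volume does (validation already fixed winding for read meshes)
    sign = 1.0 if (vol_pos + vol_neg) >= 0.0 else -1.0
    vol_pos *= sign
    vol_neg *= sign
    return vol_pos / MM3_PER_ML, vol_neg / MM3_PER_ML


def _clipped_tet_volume(tri: np.ndarray, d: np.ndarray) -> float:
    """Signed tet volume (origin-referenced) of the part of one triangle
    with nonnegative plane distance ``d``; origin lies on the plane."""
    # Sutherland–Hodgman clip of a single triangle against d >= 0
    poly: list[np.ndarray] = []
    for j in range(3):
        a, b = tri[j], tri[(j + 1) % 3]
        da, db = d[j], d[(j + 1) % 3]
        if da >= 0.0:
            poly.append(a)
        if (da > 0.0) != (db > 0.0) and da != db:
            t = da / (da - db)
            if 0.0 < t < 1.0:
                poly.append(a + t * (b - a))
    if len(poly) < 3:
        return 0.0
    p0 = poly[0]
    vol = 0.0
    for j in range(1, len(poly) - 1):
        vol += np.dot(p0, np.cross(poly[j], poly[j + 1])) / 6.0
    return vol


# ---------------------------------------------------------------------------
# Plane fitting


def fit_plane(points: np.ndarray, orientation_hint: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through ``points``.

    The normal is the principal direction of smallest variance of the centered
    points (SVD).  With ``orientation_hint`` the normal sign is chosen so the
    hint point lies on the positive side.

    Raises
    ------
    ValueError
        For fewer than 3 points or a collinear/degenerate configuration.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("fit_plane needs at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    # collinear points: second singular value vanishes relative to the first
    if s[0] == 0.0 or s[1] <= 1e-12 * s[0]:
        raise ValueError("fit_plane: points are collinear or coincident")
    normal = vt[2]
    if orientation_hint is not None:
        if np.dot(np.asarray(orientation_hint, dtype=np.float64) - centroid, normal) < 0:
            normal = -normal
    return Plane(normal, centroid)
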