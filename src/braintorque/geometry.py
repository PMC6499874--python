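"""Triangle-mesh primitives shared by the torque pipeline.

All coordinates are millimetres in an RAS-like frame: +x toward the
subject's right, +y anterior, +z superior.  The left hemisphere therefore
occupies predominantly x < 0 and the inter-hemispheric midline is near the
plane x = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "Box3",
    "Plane3",
    "vertex_normals",
    "bounding_box",
    "extract_pole",
    "rigid_transform",
    "mirror_x",
]

_SIDES = ("left", "right", "whole")


@dataclass(frozen=True)
class TriMesh:
    """A triangulated surface of one cerebral hemisphere (or a whole brain).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm (RAS-like frame).
    faces : (m, 3) int array
        Vertex-index triples; winding is counter-clockwise seen from
        outside the surface.
    side : {"left", "right", "whole"}
        Anatomical label.  ``left`` surfaces are expected at x < 0.

    The surface is intended to be closed (a FreeSurfer-style outer
    hemispheric hull); non-watertight input is accepted with a warning so
    that partial synthetic fixtures remain usable.
    """

    vertices: np.ndarray
    faces: np.ndarray
    side: str = "whole"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3) triangles, got {f.shape}")
        if v.shape[0] < 4:
            raise ValueError("mesh needs at least 4 vertices")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range")
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def check_closed(self) -> bool:
        """Warn (do not raise) if the surface is not watertight."""
        tm = _trimesh.Trimesh(self.vertices, self.faces, process=False)
        if not tm.is_watertight:
            warnings.warn(
                f"{self.side} surface is not watertight "
                f"({len(self.vertices)} vertices)", stacklevel=2
            )
        return bool(tm.is_watertight)

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        return replace(self, vertices=np.asarray(vertices, dtype=float))


@dataclass(frozen=True)
class Box3:
    """Axis-aligned bounding box; extents define the brain's linear dimensions.

    length = antero-posterior (y) extent, height = dorso-ventral (z) extent,
    width = latero-medial (x) extent, all in mm.
    """

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("corners must be 3-vectors")
        if np.any(hi < lo):
            raise ValueError("max corner must be >= min corner componentwise")
        object.__setattr__(self, "min_corner", lo)
        object.__setattr__(self, "max_corner", hi)

    @property
    def extents(self) -> np.ndarray:
        return self.max_corner - self.min_corner

    @property
    def width(self) -> float:
        return float(self.extents[0])

    @property
    def length(self) -> float:
        return float(self.extents[1])

    @property
    def height(self) -> float:
        return float(self.extents[2])


@dataclass(frozen=True)
class Plane3:
    """A plane given by a point and a unit normal (x-component >= 0)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if abs(nn - 1.0) > 1e-9:
            n = n / nn
        n = _canonical_normal(n)
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.point @ self.normal

    def angle_to_x(self, degrees: bool = True) -> float:
        """Unsigned angle between the plane normal and the x-axis."""
        a = float(np.arccos(np.clip(abs(self.normal[0]), -1.0, 1.0)))
        return float(np.degrees(a)) if degrees else a


def _canonical_normal(n: np.ndarray) -> np.ndarray:
    """Resolve the +-n ambiguity: first nonzero of (x, y, z) made positive."""
    for c in n:
        if c != 0.0:
            return n if c > 0 else -n
    raise ValueError("zero normal")


def _face_geometry(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-face (unit normal, area) from the winding order."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    normals = np.zeros_like(cross)
    ok = area2 > 0
    normals[ok] = cross[ok] / area2[ok, None]
    return normals, 0.5 * area2


def _signed_volume(mesh: TriMesh) -> float:
    tri = mesh.vertices[mesh.faces] - mesh.centroid
    return float(np.einsum("ij,ij->i", tri[:, 0],
                           np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Outward unit normal at each vertex.

    Area-weighted average of the incident face normals, with the global
    winding flipped first if the signed volume indicates the faces point
    inward, so that normals point away from the surface interior.

    Raises
    ------
    ValueError
        If a vertex belongs to no face (no normal is defined there).
    """
    normals, areas = _face_geometry(mesh)
    if _signed_volume(mesh) < 0:
        normals = -normals
    acc = np.zeros_like(mesh.vertices)
    weighted = normals * areas[:, None]
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], weighted)
    norms = np.linalg.norm(acc, axis=1)
    incident = np.zeros(mesh.n_vertices, dtype=bool)
    incident[mesh.faces.ravel()] = True
    if not incident.all():
        raise ValueError(
            f"{int((~incident).sum())} isolated vertices have no normal"
        )
    if np.any(norms == 0):
        raise ValueError("degenerate vertex star: zero accumulated normal")
    return acc / norms[:, None]


def bounding_box(mesh: TriMesh, scale: float = 1.0) -> Box3:
    """Smallest axis-aligned box enclosing the mesh, in native-space mm.

    ``scale`` is the subject's uniform normalized-to-native scale factor
    (1.0 when the mesh is already in native space).  Corners are scaled so
    extents come out in native mm.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh has no bounding box")
    lo = mesh.vertices.min(axis=0) * scale
    hi = mesh.vertices.max(axis=0) * scale
    return Box3(lo, hi)


def extract_pole(mesh: TriMesh, direction: str) -> np.ndarray:
    """The frontal ("anterior") or occipital ("posterior") pole vertex.

    The pole is the raw vertex with extreme y-coordinate (max for anterior,
    min for posterior); coordinate ties resolve to the lowest vertex index,
    which keeps the choice deterministic.
    """
    y = mesh.vertices[:, 1]
    if direction == "anterior":
        idx = int(np.argmax(y))
    elif direction == "posterior":
        idx = int(np.argmin(y))
    else:
        raise ValueError(f"direction must be 'anterior' or 'posterior', got {direction!r}")
    return mesh.vertices[idx].copy()


def rigid_transform(mesh: TriMesh, rotation: np.ndarray,
                    translation: np.ndarray) -> TriMesh:
    """Apply v -> R v + t to every vertex; faces are untouched."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or t.shape != (3,):
        raise ValueError("rotation must be 3x3 and translation a 3-vector")
    if (np.abs(R @ R.T - np.eye(3)).max() > 1e-8
            or abs(np.linalg.det(R) - 1.0) > 1e-8):
        raise ValueError("rotation must be orthonormal with determinant +1")
    return mesh.with_vertices(mesh.vertices @ R.T + t)


def mirror_x(mesh: TriMesh) -> TriMesh:
    """Reflect the mesh through x = 0.

    Face winding is reversed so the surface stays outward-oriented, and the
    left/right side label swaps.  Used by the anti-symmetry checks: every
    signed torque metric must negate under this operation.
    """
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    f = mesh.faces[:, ::-1].copy()
    side = {"left": "right", "right": "left"}.get(mesh.side, mesh.side)
    return TriMesh(v, f, side=side)
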