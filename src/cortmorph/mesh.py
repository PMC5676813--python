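"""Triangle-mesh container and integrity checks.

All geometry in this package lives on oriented triangulated surfaces in
millimeter coordinates.  Cortical reconstructions are closed genus-0
surfaces; synthetic sheet fixtures are bounded, so a mesh carries a
``boundary_allowed`` flag that relaxes the closedness requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class MeshValidationError(ValueError):
    """Raised when a mesh violates its structural invariants."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_mesh` — report-only, never raises."""

    n_vertices: int
    n_edges: int
    n_faces: int
    euler_characteristic: int
    is_edge_manifold: bool
    is_closed: bool
    is_consistently_oriented: bool
    boundary_edges: list = field(default_factory=list)
    nonmanifold_edges: list = field(default_factory=list)
    misoriented_edges: list = field(default_factory=list)
    degenerate_faces: list = field(default_factory=list)
    duplicate_faces: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            self.is_edge_manifold
            and self.is_consistently_oriented
            and not self.degenerate_faces
            and not self.duplicate_faces
        )


@dataclass
class TriangleMesh:
    """Oriented triangle mesh in millimeter coordinates.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array of vertex indices (0-based)
    hemisphere_tag : optional ``"left"`` or ``"right"``
    boundary_allowed : if False the mesh must be closed (every edge shared
        by exactly two faces) to pass validation.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere_tag: Optional[str] = None
    boundary_allowed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (F, 3) array")
        if self.hemisphere_tag not in (None, "left", "right"):
            raise MeshValidationError(
                f"hemisphere_tag must be left/right/None, got {self.hemisphere_tag!r}"
            )

    # -- basic combinatorics -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def directed_edges(self) -> np.ndarray:
        """(3F, 2) array of half-edges in face winding order."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def undirected_edges(self) -> np.ndarray:
        """(E, 2) sorted unique edges."""
        e = np.sort(self.directed_edges(), axis=1)
        return np.unique(e, axis=0)

    # -- metric quantities ---------------------------------------------------

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit face normals (right-hand winding) and face areas in mm^2."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        areas = 0.5 * norm
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cross / norm[:, None]
        normals[norm == 0] = 0.0
        return normals, areas

    def face_areas(self) -> np.ndarray:
        return self.face_normals_areas()[1]

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        normals, areas = self.face_normals_areas()
        weighted = normals * areas[:, None]
        out = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], weighted)
        n = np.linalg.norm(out, axis=1)
        n[n == 0] = 1.0
        return out / n[:, None]

    def mean_edge_length(self) -> float:
        e = self.undirected_edges()
        return float(
            np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean()
        )

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Adjacency list (1-ring) per vertex."""
        e = self.undirected_edges()
        order = np.argsort(e[:, 0], kind="stable")
        nbr: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for a, b in e[order]:
            nbr[a].append(b)
            nbr[b].append(a)
        return [np.array(sorted(x), dtype=np.int64) for x in nbr]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.hemisphere_tag, self.boundary_allowed
        )


MIN_FACE_AREA = 1e-12  # mm^2; anything below is a degenerate sliver


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Structural audit of a mesh: manifoldness, closedness, orientation,
    degenerate and duplicate faces, Euler characteristic chi = V - E + F.

    Report-only; use :func:`require_valid` to raise on failure.
    """
    f = mesh.faces
    if len(f) and (f.min() < 0 or f.max() >= mesh.n_vertices):
        bad = np.where((f < 0) | (f >= mesh.n_vertices))[0]
        raise MeshValidationError(
            f"face indices out of range [0, {mesh.n_vertices}) in faces {bad.tolist()[:10]}"
        )

    repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    degenerate = list(np.where(repeated)[0])
    areas = mesh.face_areas()
    degenerate += list(np.where((~repeated) & (areas <= MIN_FACE_AREA))[0])

    sorted_faces = np.sort(f, axis=1)
    _, first, counts = np.unique(sorted_faces, axis=0, return_index=True, return_counts=True)
    duplicates = []
    for idx, c in zip(first, counts):
        if c > 1:
            duplicates.append(int(idx))

    de = mesh.directed_edges()
    ue = np.sort(de, axis=1)
    uniq, inv, counts = np.unique(ue, axis=0, return_inverse=True, return_counts=True)
    boundary = [tuple(map(int, uniq[i])) for i in np.where(counts == 1)[0]]
    nonmanifold = [tuple(map(int, uniq[i])) for i in np.where(counts > 2)[0]]

    # orientation: a shared edge must be traversed in opposite directions
    misoriented = []
    shared = np.where(counts == 2)[0]
    if len(shared):
        # for each undirected edge, the two directed copies; same direction twice => flip
        order = np.argsort(inv, kind="stable")
        inv_sorted = inv[order]
        de_sorted = de[order]
        starts = np.searchsorted(inv_sorted, shared)
        for s, ei in zip(starts, shared):
            a, b = de_sorted[s], de_sorted[s + 1]
            if a[0] == b[0] and a[1] == b[1]:
                misoriented.append(tuple(map(int, np.sort(a))))

    V, E, F = mesh.n_vertices, len(uniq), mesh.n_faces
    return ValidationReport(
        n_vertices=V,
        n_edges=E,
        n_faces=F,
        euler_characteristic=V - E + F,
        is_edge_manifold=not nonmanifold,
        is_closed=not boundary,
        is_consistently_oriented=not misoriented,
        boundary_edges=boundary,
        nonmanifold_edges=nonmanifold,
        misoriented_edges=misoriented,
        degenerate_faces=[int(i) for i in degenerate],
        duplicate_faces=duplicates,
    )


def require_valid(mesh: TriangleMesh) -> ValidationReport:
    """Validate and raise :class:`MeshValidationError` on any violation."""
    report = validate_mesh(mesh)
    problems = []
    if report.nonmanifold_edges:
        problems.append(f"non-manifold edges: {report.nonmanifold_edges[:10]}")
    if report.misoriented_edges:
        problems.append(f"inconsistent winding at edges: {report.misoriented_edges[:10]}")
    if report.degenerate_faces:
        problems.append(f"degenerate faces: {report.degenerate_faces[:10]}")
    if report.duplicate_faces:
        problems.append(f"duplicate faces: {report.duplicate_faces[:10]}")
    if not mesh.boundary_allowed and report.boundary_edges:
        problems.append(
            f"mesh has {len(report.boundary_edges)} boundary edges but boundary_allowed is False"
        )
    if problems:
        raise MeshValidationError("; ".join(problems))
    return report
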