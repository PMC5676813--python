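"""Per-vertex principal and intrinsic (Gaussian) curvature.

Intrinsic curvature K = k1*k2 is the product of the two principal
curvatures and is a property of the surface itself, independent of how it
bends in space: a folded but undeformed sheet has K = 0 everywhere, while
differential expansion of a cortical sheet produces pointwise positive or
negative K at the millimeter scale.  A region's IC distribution is heavily
massed near zero, so it is summarized by its skewness: the *less* skewed
the distribution, the *greater* the degree of intrinsic deformation.

The estimator fits a local quadric height function over a k-ring vertex
neighborhood in the tangent frame and takes the eigenvalues of the exact
graph-surface shape operator at the vertex.  This yields both principal
curvatures separately (needed by the resolution filter, which thresholds
their osculating radii individually); the classical angle-deficit estimate
of K is provided only as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .mesh import TriangleMesh

__all__ = [
    "PrincipalCurvatureField",
    "ICField",
    "ICSummary",
    "principal_curvatures",
    "intrinsic_curvature",
    "filter_ic",
    "ic_skew",
    "angle_deficit_curvature",
]

MIN_REGION_VERTICES = 10  # below this an IC summary is flagged unusable


@dataclass
class PrincipalCurvatureField:
    """Per-vertex maximum (k1) and minimum (k2) normal curvature, mm^-1."""

    k1: np.ndarray
    k2: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.k1) == len(self.k2) == len(self.valid)):
            raise ValueError("k1, k2, valid must have equal length")
        bad = self.valid & (self.k1 < self.k2 - 1e-12)
        if bad.any():
            raise ValueError("k1 < k2 on valid vertices")


@dataclass
class ICField:
    """Per-vertex intrinsic curvature K (mm^-2) with a validity mask.

    ``k1``/``k2`` are carried along so the resolution filter can threshold
    the individual osculating radii.  ``abs_applied`` records whether the
    values have already been folded to |K|.
    """

    ic: np.ndarray
    valid: np.ndarray
    abs_applied: bool = False
    filtered: bool = False
    k1: Optional[np.ndarray] = None
    k2: Optional[np.ndarray] = None
    fraction_removed: float = 0.0


@dataclass
class ICSummary:
    """Skewness of a region's |IC| distribution."""

    skew: float
    n_valid: int
    usable: bool


def _ring_neighborhoods(mesh: TriangleMesh, ring: int) -> list[np.ndarray]:
    """Vertex indices within graph distance ``ring`` (excluding the vertex)."""
    adj = mesh.vertex_neighbors()
    if ring == 1:
        return adj
    out = []
    for v in range(mesh.n_vertices):
        seen = {v}
        frontier = set(adj[v].tolist())
        seen |= frontier
        for _ in range(ring - 1):
            nxt = set()
            for u in frontier:
                nxt.update(adj[u].tolist())
            frontier = nxt - seen
            seen |= frontier
        seen.discard(v)
        out.append(np.fromiter(seen, dtype=np.int64))
    return out


def principal_curvatures(
    mesh: TriangleMesh, ring: int = 2, min_neighbors: int = 5
) -> PrincipalCurvatureField:
    """Estimate k1 >= k2 at every vertex by a local quadric height fit.

    For each vertex the ``ring``-neighborhood is expressed in a tangent
    frame built from the area-weighted vertex normal, a full quadric
    ``z = a x^2 + b xy + c y^2 + d x + e y`` is fit by least squares, and
    the principal curvatures are the eigenvalues of the exact shape
    operator of the graph surface at the origin.  Sign convention:
    convex-outward regions of a closed, outward-wound mesh have positive
    curvature.  Vertices with fewer than ``min_neighbors`` usable
    neighbors or a rank-deficient fit are marked invalid.
    """
    V = mesh.n_vertices
    normals = mesh.vertex_normals()
    hoods = _ring_neighborhoods(mesh, ring)
    verts = mesh.vertices

    k1 = np.zeros(V)
    k2 = np.zeros(V)
    valid = np.zeros(V, dtype=bool)

    for v in range(V):
        nbrs = hoods[v]
        if len(nbrs) < min_neighbors:
            continue
        n = normals[v]
        # tangent basis orthogonal to n
        a0 = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, a0)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)

        d = verts[nbrs] - verts[v]
        x = d @ e1
        y = d @ e2
        z = d @ n
        A = np.column_stack([x * x, x * y, y * y, x, y])
        coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
        if rank < 5:
            continue
        a, b, c, dd, ee = coef
        grad = np.array([dd, ee])
        H = np.array([[2 * a, b], [b, 2 * c]])
        G = np.eye(2) + np.outer(grad, grad)  # first fundamental form
        II = H / np.sqrt(1.0 + grad @ grad)  # second fundamental form
        try:
            ev = sla.eigh(II, G, eigvals_only=True)
        except sla.LinAlgError:
            continue
        # n is the outward normal; graph height decreases outward on a
        # convex region, so flip to make convex-outward positive
        ev = -ev
        k1[v], k2[v] = max(ev), min(ev)
        valid[v] = True

    return PrincipalCurvatureField(k1=k1, k2=k2, valid=valid)


def intrinsic_curvature(pc: PrincipalCurvatureField) -> ICField:
    """K = k1 * k2 per vertex (signed; validity inherited)."""
    return ICField(
        ic=pc.k1 * pc.k2,
        valid=pc.valid.copy(),
        abs_applied=False,
        filtered=False,
        k1=pc.k1.copy(),
        k2=pc.k2.copy(),
    )


def filter_ic(ic: ICField, mesh: TriangleMesh, max_radius_factor: float = 1.0) -> ICField:
    """Remove curvature values inconsistent with the mesh resolution.

    A vertex is sharper than the tessellation can represent — and is
    marked invalid — when its smallest osculating radius falls below
    ``max_radius_factor`` times the mean edge length.  The radius is the
    minimum over the fitted principal curvatures and a per-edge normal
    curvature probe (the circumscribed-circle estimate
    ``2 (n . (p_v - p_j)) / |p_v - p_j|^2``, exact on spheres); the probe
    catches creases and spikes that the smoothing of a ring-neighborhood
    quadric fit would average away.  With factor 0 nothing is removed.
    """
    if ic.filtered:
        raise ValueError("ICField is already filtered")
    if ic.k1 is None or ic.k2 is None:
        raise ValueError("ICField lacks principal curvatures; cannot filter")
    threshold = max_radius_factor * mesh.mean_edge_length()
    kappa_edge = _max_edge_normal_curvature(mesh)
    with np.errstate(divide="ignore"):
        r1 = np.where(np.abs(ic.k1) > 0, 1.0 / np.abs(ic.k1), np.inf)
        r2 = np.where(np.abs(ic.k2) > 0, 1.0 / np.abs(ic.k2), np.inf)
        r3 = np.where(kappa_edge > 0, 1.0 / kappa_edge, np.inf)
    too_sharp = np.minimum(np.minimum(r1, r2), r3) < threshold
    n_before = int(ic.valid.sum())
    new_valid = ic.valid & ~too_sharp
    if n_before > 0 and not new_valid.any():
        raise ValueError(
            "resolution filter removed every vertex; "
            "use a smaller max_radius_factor or a finer mesh"
        )
    removed = 0.0 if n_before == 0 else 1.0 - new_valid.sum() / n_before
    return ICField(
        ic=ic.ic.copy(),
        valid=new_valid,
        abs_applied=ic.abs_applied,
        filtered=True,
        k1=ic.k1.copy(),
        k2=ic.k2.copy(),
        fraction_removed=float(removed),
    )


def _max_edge_normal_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Per vertex, the largest |normal curvature| probed along incident
    edges via the circumscribed-circle estimate (exact on a sphere)."""
    normals = mesh.vertex_normals()
    e = mesh.undirected_edges()
    d = mesh.vertices[e[:, 1]] - mesh.vertices[e[:, 0]]
    L2 = np.einsum("ij,ij->i", d, d)
    k_ab = np.abs(2.0 * np.einsum("ij,ij->i", normals[e[:, 0]], -d) / L2)
    k_ba = np.abs(2.0 * np.einsum("ij,ij->i", normals[e[:, 1]], d) / L2)
    out = np.zeros(mesh.n_vertices)
    np.maximum.at(out, e[:, 0], k_ab)
    np.maximum.at(out, e[:, 1], k_ba)
    return out


def moment_skewness(values: np.ndarray) -> float:
    """Population moment coefficient of skewness g1 = m3 / m2^(3/2)."""
    return float(stats.skew(values, bias=True))


def ic_skew(
    ic: ICField,
    region_vertices: Optional[Sequence[int]] = None,
    min_valid: int = MIN_REGION_VERTICES,
) -> ICSummary:
    """Skewness of the absolute IC distribution over a region.

    Absolute values are taken before summarizing (if not already applied).
    g1 is dimensionless and scale-free, so the summary is invariant to
    multiplying all curvatures by a positive constant.
    """
    mask = ic.valid.copy()
    if region_vertices is not None:
        region_mask = np.zeros(len(ic.ic), dtype=bool)
        region_mask[np.asarray(region_vertices, dtype=np.int64)] = True
        mask &= region_mask
    vals = ic.ic[mask]
    if not ic.abs_applied:
        vals = np.abs(vals)
    n = len(vals)
    if n < min_valid:
        return ICSummary(skew=np.nan, n_valid=n, usable=False)
    if np.var(vals) == 0:
        raise ValueError("degenerate IC distribution: zero variance")
    return ICSummary(skew=moment_skewness(vals), n_valid=n, usable=True)


def angle_deficit_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Gaussian curvature by angle deficit: (2*pi - sum of incident
    angles) / one-third incident triangle area.  Independent cross-check
    for the quadric estimator; exact in the Gauss-Bonnet aggregate."""
    verts, faces = mesh.vertices, mesh.faces
    deficits = np.full(mesh.n_vertices, 2 * np.pi)
    areas = np.zeros(mesh.n_vertices)
    tri = verts[faces]
    face_area = mesh.face_areas()
    for corner in range(3):
        p = tri[:, corner]
        q = tri[:, (corner + 1) % 3]
        r = tri[:, (corner + 2) % 3]
        u = q - p
        w = r - p
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.subtract.at(deficits, faces[:, corner], ang)
        np.add.at(areas, faces[:, corner], face_area / 3.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = deficits / areas
    K[areas == 0] = 0.0
    return K
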