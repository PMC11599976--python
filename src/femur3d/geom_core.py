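"""Geometric primitives underlying the femoral measurement pipeline.

The pipeline is assembled from a small number of operations:

* least-squares **sphere fitting** (algebraic initialisation followed by a
  geometric, orthogonal-distance refinement) for the femoral head and the
  condyles;
* a **seeded, region-grown sphere fit** that starts from a single user
  click on the femoral head and alternates fitting with inlier
  re-selection, so that head vertices are kept and acetabular or neck
  vertices are excluded;
* **sectioning** of a triangle mesh by a plane or by a sphere, producing
  closed polyline loops whose arc-length-weighted centroids feed the
  anatomical and head–neck axes;
* **total-least-squares line fitting** and **projected angles** between
  axes in a named anatomical plane.

All coordinates are millimetres, all angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares
from scipy.sparse.csgraph import connected_components as _cc

from .errors import DegenerateGeometryError, FitFailureError, SeedError
from .mesh_io import TriangleMesh

# ---------------------------------------------------------------------------
# primitives


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raises on (near-)zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("cannot normalize near-zero vector")
    return v / n


@dataclass
class Sphere:
    """A fitted sphere with fit diagnostics."""

    center: np.ndarray
    radius: float
    rms_residual: float = 0.0
    support_count: int = 0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise DegenerateGeometryError("sphere radius must be positive")

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned orthogonal distance of points to the sphere surface."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.abs(np.linalg.norm(pts - self.center, axis=1) - self.radius)

    def to_dict(self) -> dict:
        return {
            "center": [float(x) for x in self.center],
            "radius": float(self.radius),
            "rms_residual": float(self.rms_residual),
            "support_count": int(self.support_count),
        }


@dataclass
class Axis3D:
    """An oriented line: a point on the line and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.direction = unit(np.asarray(self.direction, dtype=float).reshape(3))

    def to_dict(self) -> dict:
        return {
            "point": [float(x) for x in self.point],
            "direction": [float(x) for x in self.direction],
        }


@dataclass
class SectionLoop:
    """A closed polyline produced by cutting a mesh with a plane or sphere.

    ``points`` is closed (first point repeated last).  The centroid is
    arc-length weighted, so it does not depend on mesh resolution.
    """

    points: np.ndarray
    cut: dict  # descriptor of the cutting surface

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 4:
            raise DegenerateGeometryError("section loop needs >= 3 distinct points")
        if not np.allclose(self.points[0], self.points[-1], atol=1e-9):
            raise DegenerateGeometryError("section loop must be closed")

    @property
    def perimeter(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        seg = np.diff(self.points, axis=0)
        lengths = np.linalg.norm(seg, axis=1)
        mids = 0.5 * (self.points[:-1] + self.points[1:])
        total = lengths.sum()
        if total < 1e-12:
            raise DegenerateGeometryError("zero-perimeter loop")
        return (mids * lengths[:, None]).sum(axis=0) / total


def fit_circle_center(points: np.ndarray) -> np.ndarray:
    """Center of a least-squares circle through near-coplanar 3D points.

    The best-fit plane comes from PCA; the circle is fitted algebraically
    in-plane and the center mapped back to 3D.  For a section loop through
    a noisy surface this is a much lower-variance location estimate than
    the polyline centroid, because boundary zigzag enters only through the
    residuals instead of through arc-length weights.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegenerateGeometryError("circle fit needs >= 3 points")
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u, v = vt[0], vt[1]
    x = centered @ u
    y = centered @ v
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones(len(x))])
    b = x**2 + y**2
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("degenerate circle fit")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return mean + sol[0] * u + sol[1] * v


# ---------------------------------------------------------------------------
# sphere fitting


def _algebraic_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear least-squares sphere (Coope's method)."""
    pts = np.asarray(points, dtype=float)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are coplanar or otherwise degenerate")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit produced r^2 <= 0")
    return center, float(np.sqrt(r2))


def fit_sphere(points: np.ndarray) -> Sphere:
    """Best-fit sphere minimizing summed squared orthogonal distances.

    Algebraic (linear) initialisation followed by geometric Gauss-Newton
    refinement over the center, with the radius profiled out as the mean
    center-to-point distance.  Deterministic for a fixed input.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 points")
    c0, _ = _algebraic_sphere(pts)

    def residuals(c):
        d = np.linalg.norm(pts - c, axis=1)
        return d - d.mean()

    sol = least_squares(residuals, c0, method="lm", xtol=1e-12, ftol=1e-12)
    center = sol.x
    d = np.linalg.norm(pts - center, axis=1)
    radius = float(d.mean())
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    return Sphere(center=center, radius=radius, rms_residual=rms,
                  support_count=len(pts))


def _vertex_adjacency(mesh: TriangleMesh) -> sparse.csr_matrix:
    f = mesh.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    n = mesh.n_vertices
    data = np.ones(len(i), dtype=np.int8)
    adj = sparse.coo_matrix((data, (i, j)), shape=(n, n)).tocsr()
    return adj + adj.T


def fit_sphere_seeded(
    mesh: TriangleMesh,
    seed: np.ndarray,
    inclusion_tol: float = 0.025,
    max_iter: int = 50,
) -> tuple[Sphere, np.ndarray]:
    """Region-grown sphere fit from a single seed click on the femoral head.

    Starting from a small vertex cap around the seed, the fit alternates
    (sphere fit) with (re-selection of vertices whose orthogonal distance to
    the current sphere is within a tolerance band, restricted to the
    connected surface patch containing the seed).  The band is
    ``max(inclusion_tol * radius, 3 * sigma)`` where ``sigma`` is a robust
    scale of the current support residuals, capped at 15 % of the radius —
    this keeps the selection stable on noisy surfaces while still shedding
    neck and acetabular vertices, whose residuals grow quickly.

    Returns the final sphere and the indices of its supporting vertices.

    Raises
    ------
    SeedError
        if the seed is more than 5 mm from the mesh surface.
    FitFailureError
        if the support collapses below 50 vertices.
    """
    mesh.check()
    seed = np.asarray(seed, dtype=float).reshape(3)
    verts = mesh.vertices
    d_seed = np.linalg.norm(verts - seed, axis=1)
    if d_seed.min() > 5.0:
        raise SeedError(
            f"seed is {d_seed.min():.1f} mm from the mesh surface (limit 5 mm)"
        )
    seed_vertex = int(np.argmin(d_seed))

    # local radius estimate: grow a ball around the seed until a sphere fit
    # is well-posed, then take its radius
    diag = float(np.linalg.norm(verts.max(axis=0) - verts.min(axis=0)))
    r_local = max(0.02 * diag, 1.0)
    r_est = None
    for _ in range(12):
        cap = np.flatnonzero(d_seed <= r_local)
        if len(cap) >= 40:
            try:
                s0 = fit_sphere(verts[cap])
            except DegenerateGeometryError:
                s0 = None
            if s0 is not None and s0.rms_residual < 0.15 * s0.radius:
                r_est = s0.radius
                break
        r_local *= 1.5
    if r_est is None:
        raise FitFailureError("could not form an initial head-radius estimate")

    # restrict the working set to a generous neighbourhood of the seed
    universe = np.flatnonzero(d_seed <= 4.0 * r_est)
    adj = _vertex_adjacency(mesh)[universe][:, universe]
    local_pos = verts[universe]
    local_seed = int(np.searchsorted(universe, seed_vertex))
    d_seed_local = d_seed[universe]

    support = np.flatnonzero(d_seed_local <= 0.4 * r_est)
    if len(support) < 40:
        support = np.argsort(d_seed_local)[:40]
    prev: set = set()
    sphere = None
    for _ in range(max_iter):
        sphere = fit_sphere(local_pos[support])
        resid = np.abs(
            np.linalg.norm(local_pos - sphere.center, axis=1) - sphere.radius
        )
        sup_res = resid[support]
        sigma = 1.4826 * float(np.median(sup_res))
        tol = max(inclusion_tol * sphere.radius,
                  min(3.0 * sigma, 0.15 * sphere.radius))
        sel = resid <= tol
        sel[local_seed] = True
        sel_idx = np.flatnonzero(sel)
        sub = adj[sel_idx][:, sel_idx]
        ncomp, labels = _cc(sub, directed=False)
        seed_pos = int(np.searchsorted(sel_idx, local_seed))
        support_new = sel_idx[labels == labels[seed_pos]]
        if len(support_new) < 50:
            raise FitFailureError(
                f"head-fit support collapsed to {len(support_new)} vertices"
            )
        cur = set(support_new.tolist())
        if cur == prev:
            support = support_new
            break
        prev = cur
        support = support_new

    sphere = fit_sphere(local_pos[support])
    return sphere, universe[support]


# ---------------------------------------------------------------------------
# sectioning


def _iso_loops(mesh: TriangleMesh, field: np.ndarray, cut: dict) -> list[SectionLoop]:
    """Zero-level loops of a per-vertex scalar field, by edge interpolation.

    Each crossing point lies on a unique mesh edge, so segments from
    adjacent faces share exact endpoint keys and chain into closed loops
    without any coordinate rounding.
    """
    f = np.asarray(field, dtype=float).copy()
    # nudge exact zeros so every crossing is transversal
    zero = f == 0.0
    if zero.any():
        scale = max(float(np.abs(f).max()), 1.0)
        f[zero] = 1e-12 * scale

    faces = mesh.faces
    sgn = f[faces] > 0.0
    crossing = ~(sgn.all(axis=1) | (~sgn).all(axis=1))
    if not crossing.any():
        return []

    verts = mesh.vertices
    edge_pairs = [(0, 1), (1, 2), (2, 0)]
    seg_edges = []  # per crossing face: the two crossed edge keys
    for face in faces[crossing]:
        keys = []
        for a, b in edge_pairs:
            i, j = int(face[a]), int(face[b])
            if (f[i] > 0) != (f[j] > 0):
                keys.append((i, j) if i < j else (j, i))
        if len(keys) == 2:
            seg_edges.append((keys[0], keys[1]))

    # adjacency between edge keys
    nbrs: dict = {}
    for a, b in seg_edges:
        nbrs.setdefault(a, []).append(b)
        nbrs.setdefault(b, []).append(a)

    def edge_point(key):
        i, j = key
        t = f[i] / (f[i] - f[j])
        return verts[i] + t * (verts[j] - verts[i])

    visited = set()
    loops = []
    for start in nbrs:
        if start in visited or len(nbrs[start]) != 2:
            continue
        chain = [start]
        visited.add(start)
        cur = start
        prev = None
        closed = False
        while True:
            nxt = None
            for cand in nbrs[cur]:
                if cand != prev:
                    nxt = cand
                    break
            if nxt is None:
                break
            if nxt == start:
                closed = True
                break
            if nxt in visited or len(nbrs[nxt]) != 2:
                break
            visited.add(nxt)
            chain.append(nxt)
            prev, cur = cur, nxt
        if closed and len(chain) >= 3:
            pts = np.array([edge_point(k) for k in chain])
            pts = np.vstack([pts, pts[:1]])
            try:
                loops.append(SectionLoop(points=pts, cut=cut))
            except DegenerateGeometryError:
                pass
    loops.sort(key=lambda lp: -lp.perimeter)
    return loops


def section_by_plane(
    mesh: TriangleMesh, point: np.ndarray, normal: np.ndarray
) -> list[SectionLoop]:
    """Closed intersection loops of the mesh with a plane.

    Loops are ordered by descending perimeter; an empty list (no
    intersection) is not an error.
    """
    point = np.asarray(point, dtype=float).reshape(3)
    n = unit(normal)
    field = (mesh.vertices - point) @ n
    cut = {"type": "plane", "point": point.tolist(), "normal": n.tolist()}
    return _iso_loops(mesh, field, cut)


def section_by_sphere(
    mesh: TriangleMesh, center: np.ndarray, radius: float
) -> list[SectionLoop]:
    """Closed curves where the mesh crosses a sphere of given center/radius.

    This realises the 'curvilinear section parallel to the femoral head':
    cutting the proximal femur with a sphere concentric with the fitted
    head isolates the neck cross-section at a controlled distance.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    if radius <= 0:
        raise DegenerateGeometryError("cut radius must be positive")
    field = np.linalg.norm(mesh.vertices - center, axis=1) - radius
    cut = {"type": "sphere", "center": center.tolist(), "radius": float(radius)}
    return _iso_loops(mesh, field, cut)


# ---------------------------------------------------------------------------
# lines and angles


def fit_line(points: np.ndarray) -> Axis3D:
    """Total-least-squares line: first principal direction through the
    centroid.  The direction sign points from the first toward the last
    input point."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise DegenerateGeometryError("line fit needs >= 2 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.linalg.norm(centered) < 1e-12:
        raise DegenerateGeometryError("all points identical")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction @ (pts[-1] - pts[0]) < 0:
        direction = -direction
    return Axis3D(point=centroid, direction=direction)


def project_to_plane(direction: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Component of ``direction`` in the plane with unit normal ``normal``."""
    n = unit(normal)
    d = np.asarray(direction, dtype=float)
    proj = d - (d @ n) * n
    if np.linalg.norm(proj) < 1e-6:
        raise DegenerateGeometryError("direction is normal to the plane")
    return proj


def projected_angle(a: Axis3D, b: Axis3D, plane_normal: np.ndarray) -> float:
    """Unsigned angle in degrees, in [0, 180], between the projections of
    two axis directions into the plane with the given normal."""
    pa = unit(project_to_plane(a.direction, plane_normal))
    pb = unit(project_to_plane(b.direction, plane_normal))
    return float(np.degrees(np.arccos(np.clip(pa @ pb, -1.0, 1.0))))


def signed_projected_angle(
    from_dir: np.ndarray, to_dir: np.ndarray, plane_normal: np.ndarray
) -> float:
    """Signed angle (degrees, in (-180, 180]) from ``from_dir`` to
    ``to_dir`` measured in the plane, positive counter-clockwise around
    ``plane_normal``."""
    n = unit(plane_normal)
    pa = unit(project_to_plane(from_dir, n))
    pb = unit(project_to_plane(to_dir, n))
    s = float(np.cross(pa, pb) @ n)
    c = float(pa @ pb)
    return float(np.degrees(np.arctan2(s, c)))
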