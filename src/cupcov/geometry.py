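"""Low-level geometric primitives with exact contracts.

Everything downstream (pelvic frames, cup placement, coverage classification)
is built on the objects in this module: oriented planes, rigid transforms,
watertight triangle meshes, and batched point-membership / ray / surface
distance queries.  All coordinates are millimetres throughout the package.

The solid-membership test is ray parity: a query point is inside a watertight
mesh iff a ray from it crosses the surface an odd number of times.  Rays are
cast along a fixed direction and re-cast along a random direction whenever a
hit grazes a triangle edge/vertex or a near-parallel facet, which makes the
parity rule robust without an exact-arithmetic predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree


class DegenerateGeometryError(ValueError):
    """Raised when input geometry is degenerate (collinear, zero-length...)."""


class NotWatertightError(ValueError):
    """Raised when a solid query is attempted on a mesh with open edges."""

    def __init__(self, n_open_edges: int):
        self.n_open_edges = int(n_open_edges)
        super().__init__(
            f"mesh is not watertight: {self.n_open_edges} edges are not "
            "shared by exactly two faces"
        )


def as_point(p) -> np.ndarray:
    """Validate and return a finite 3-vector (mm)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point has non-finite coordinates: {a}")
    return a


def unit(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{name} has (near-)zero length")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Oriented plane a*x + b*y + c*z + d = 0 with unit normal (a, b, c).

    ``d`` is in mm; the normal is normalized at construction, but
    :func:`point_plane_distance` also accepts raw unnormalized coefficients.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        n = float(np.sqrt(self.a**2 + self.b**2 + self.c**2))
        if n < 1e-12:
            raise DegenerateGeometryError("plane normal has zero length")
        object.__setattr__(self, "a", self.a / n)
        object.__setattr__(self, "b", self.b / n)
        object.__setattr__(self, "c", self.c / n)
        object.__setattr__(self, "d", self.d / n)

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        n = unit(normal, "plane normal")
        p = as_point(point)
        return cls(n[0], n[1], n[2], -float(n @ p))

    def signed_distance(self, points) -> np.ndarray | float:
        """Signed distance(s) of point(s); positive on the normal side."""
        p = np.asarray(points, dtype=float)
        return p @ self.normal + self.d

    def flipped(self) -> "Plane":
        return Plane(-self.a, -self.b, -self.c, -self.d)

    def oriented_toward(self, point) -> "Plane":
        """Return a copy whose positive side contains ``point``."""
        if float(self.signed_distance(as_point(point))) < 0.0:
            return self.flipped()
        return self


def plane_from_points(p, q, r, orient_toward=None) -> Plane:
    """Plane through three non-collinear points.

    If ``orient_toward`` is given, the returned plane's positive side
    contains that point.  Raises :class:`DegenerateGeometryError` when the
    triangle spanned by the points has area below 1e-9 mm².
    """
    p, q, r = as_point(p), as_point(q), as_point(r)
    n = np.cross(q - p, r - p)
    if 0.5 * np.linalg.norm(n) <= 1e-9:
        raise DegenerateGeometryError(
            "the three points are (near-)collinear; cannot define a plane"
        )
    n = n / np.linalg.norm(n)
    plane = Plane(n[0], n[1], n[2], -float(n @ p))
    if orient_toward is not None:
        plane = plane.oriented_toward(orient_toward)
    return plane


def point_plane_distance(plane, point) -> float:
    """Perpendicular distance |a p1 + b p2 + c p3 + d| / sqrt(a²+b²+c²).

    ``plane`` may be a :class:`Plane` or any length-4 coefficient sequence;
    raw coefficients need not be normalized (the sqrt denominator handles
    arbitrary scaling).
    """
    if isinstance(plane, Plane):
        a, b, c, d = plane.a, plane.b, plane.c, plane.d
    else:
        a, b, c, d = (float(x) for x in plane)
    norm = np.sqrt(a * a + b * b + c * c)
    if norm < 1e-12:
        raise DegenerateGeometryError("plane coefficients have zero normal")
    p = as_point(point)
    return float(abs(a * p[0] + b * p[1] + c * p[2] + d) / norm)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        max_angle_deg: float = 180.0,
        max_translation_mm: float = 100.0,
    ) -> "RigidTransform":
        """Uniform random axis, random angle/translation up to the bounds."""
        axis = unit(rng.normal(size=3))
        angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
        K = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
        return cls(R, t)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def apply_plane(self, plane: Plane) -> Plane:
        n = self.rotation @ plane.normal
        # a point on the old plane, transformed
        p0 = self.apply(-plane.d * plane.normal)
        return Plane(n[0], n[1], n[2], -float(n @ p0))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply_mesh(self, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.apply(mesh.vertices), faces=mesh.faces.copy(), process=False
        )


# ---------------------------------------------------------------------------
# mesh utilities
# ---------------------------------------------------------------------------


def open_edge_count(mesh: trimesh.Trimesh) -> int:
    edges = mesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def require_watertight(mesh: trimesh.Trimesh) -> None:
    if not mesh.is_watertight:
        raise NotWatertightError(open_edge_count(mesh))


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area (mm²): sum of triangle areas."""
    return float(mesh.area_faces.sum())


def load_stl(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), file_type="stl", force="mesh")
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path}: not a readable triangle mesh")
    return mesh

def save_stl(mesh: trimesh.Trimesh, path, ascii: bool = False) -> None:
    mesh.export(str(path), file_type="stl_ascii" if ascii else "stl")


def _orthonormal_basis(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third row is ``direction`` (unit)."""
    w = unit(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(helper, w))
    v = np.cross(w, u)
    return np.vstack([u, v, w])


class MeshQueries:
    """Batched solid-membership, first-entry ray and surface-distance queries.

    Parameters
    ----------
    mesh:
        Watertight triangle mesh (raises :class:`NotWatertightError` if not).
    seed:
        Seed for the re-cast directions used on degenerate ray hits; queries
        are deterministic given the seed.
    """

    _EDGE_TOL = 1e-9  # mm² scale for edge-function degeneracy
    _T_TOL = 1e-9  # mm; hits closer than this to the origin are degenerate
    _MAX_RECAST = 8

    def __init__(self, mesh: trimesh.Trimesh, seed: int = 0):
        require_watertight(mesh)
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        self._seed = int(seed)
        self._tree: cKDTree | None = None
        self._tri_centroids: np.ndarray | None = None
        self._tri_radius: np.ndarray | None = None

    # -- ray casting ------------------------------------------------------

    def _cast(self, origins: np.ndarray, direction: np.ndarray, rng, depth=0,
              recast: bool = True):
        """Return (crossing_count, min_positive_t) per origin.

        Degenerate hits (edge grazing, near-parallel facets, origin on the
        surface) are resolved by re-casting those origins along a fresh
        random direction.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        n_q = len(origins)
        counts = np.zeros(n_q, dtype=np.int64)
        t_min = np.full(n_q, np.inf)
        degenerate = np.zeros(n_q, dtype=bool)

        B = _orthonormal_basis(direction)
        tv = self.triangles @ B.T  # (n_tri, 3, 3); ray direction is +z
        ov = origins @ B.T

        txy = tv[:, :, :2]
        lo = txy.min(axis=1)  # (n_tri, 2)
        hi = txy.max(axis=1)

        # 2-D uniform grid over the triangle bounding box
        gmin = lo.min(axis=0)
        gmax = hi.max(axis=0)
        span = np.maximum(gmax - gmin, 1e-9)
        n_cell = int(np.clip(np.sqrt(len(tv) / 8.0), 1, 128))
        cell = span / n_cell

        ti_lo = np.clip(((lo - gmin) / cell).astype(int), 0, n_cell - 1)
        ti_hi = np.clip(((hi - gmin) / cell).astype(int), 0, n_cell - 1)
        nx = ti_hi[:, 0] - ti_lo[:, 0] + 1
        ny = ti_hi[:, 1] - ti_lo[:, 1] + 1
        reps = nx * ny
        tri_ids = np.repeat(np.arange(len(tv)), reps)
        # enumerate covered cells per triangle (vectorized ragged arange)
        total = int(reps.sum())
        starts = np.cumsum(reps) - reps
        offs = np.arange(total) - np.repeat(starts, reps)
        wx = np.repeat(nx, reps)
        cxs = np.repeat(ti_lo[:, 0], reps) + offs % wx
        cys = np.repeat(ti_lo[:, 1], reps) + offs // wx
        tri_cell = cxs * n_cell + cys
        order = np.argsort(tri_cell, kind="stable")
        tri_cell = tri_cell[order]
        tri_ids = tri_ids[order]
        cell_starts = np.searchsorted(tri_cell, np.arange(n_cell * n_cell))
        cell_ends = np.searchsorted(tri_cell, np.arange(n_cell * n_cell), side="right")

        q_ix = np.floor((ov[:, 0] - gmin[0]) / cell[0]).astype(int)
        q_iy = np.floor((ov[:, 1] - gmin[1]) / cell[1]).astype(int)
        in_grid = (q_ix >= 0) & (q_ix < n_cell) & (q_iy >= 0) & (q_iy < n_cell)
        q_cell = np.where(in_grid, q_ix * n_cell + q_iy, -1)

        for c in np.unique(q_cell):
            if c < 0:
                continue
            tris = tri_ids[cell_starts[c] : cell_ends[c]]
            if len(tris) == 0:
                continue
            qs = np.flatnonzero(q_cell == c)
            P = ov[qs]  # (m, 3)
            A = tv[tris, 0]
            Bv = tv[tris, 1]
            C = tv[tris, 2]
            # 2-D edge functions, broadcast (m, k)
            px = P[:, 0, None]
            py = P[:, 1, None]
            e0 = (C[:, 0] - Bv[:, 0]) * (py - Bv[:, 1]) - (C[:, 1] - Bv[:, 1]) * (px - Bv[:, 0])
            e1 = (A[:, 0] - C[:, 0]) * (py - C[:, 1]) - (A[:, 1] - C[:, 1]) * (px - C[:, 0])
            e2 = (Bv[:, 0] - A[:, 0]) * (py - A[:, 1]) - (Bv[:, 1] - A[:, 1]) * (px - A[:, 0])
            denom = (
                (Bv[:, 0] - A[:, 0]) * (C[:, 1] - A[:, 1])
                - (Bv[:, 1] - A[:, 1]) * (C[:, 0] - A[:, 0])
            )  # (k,)
            near_parallel = np.abs(denom) < self._EDGE_TOL
            sgn = np.sign(denom)[None, :]
            inside = (e0 * sgn > self._EDGE_TOL) & (e1 * sgn > self._EDGE_TOL) & (
                e2 * sgn > self._EDGE_TOL
            )
            onedge = (
                (np.abs(e0) <= self._EDGE_TOL)
                | (np.abs(e1) <= self._EDGE_TOL)
                | (np.abs(e2) <= self._EDGE_TOL)
            )
            # a near-parallel facet under the point, or an edge graze where the
            # point is otherwise within the facet footprint, poisons the parity
            bbox_hit = (
                (px >= lo[tris, 0][None, :] - 1e-9)
                & (px <= hi[tris, 0][None, :] + 1e-9)
                & (py >= lo[tris, 1][None, :] - 1e-9)
                & (py <= hi[tris, 1][None, :] + 1e-9)
            )
            poison = (onedge & bbox_hit) | (near_parallel[None, :] & bbox_hit)
            degenerate[qs] |= poison.any(axis=1)

            with np.errstate(divide="ignore", invalid="ignore"):
                lam0 = e0 / denom[None, :]
                lam1 = e1 / denom[None, :]
                lam2 = e2 / denom[None, :]
                z_hit = lam0 * A[:, 2] + lam1 * Bv[:, 2] + lam2 * C[:, 2]
            t = z_hit - P[:, 2, None]
            hit = inside & ~near_parallel[None, :]
            degenerate[qs] |= (hit & (np.abs(t) <= self._T_TOL)).any(axis=1)
            pos = hit & (t > self._T_TOL)
            counts[qs] += pos.sum(axis=1)
            t_pos = np.where(pos, t, np.inf)
            t_min[qs] = np.minimum(t_min[qs], t_pos.min(axis=1))

        if degenerate.any():
            if not recast:
                # a grazed hit cannot give a trustworthy entry distance along
                # the requested direction; report "no usable hit" instead
                t_min[degenerate] = np.inf
            elif depth >= self._MAX_RECAST:
                # keep the possibly-biased parity rather than failing outright
                pass
            else:
                new_dir = unit(rng.normal(size=3))
                sub_counts, _ = self._cast(origins[degenerate], new_dir, rng, depth + 1)
                counts[degenerate] = sub_counts
        return counts, t_min

    def contains(self, points) -> np.ndarray:
        """Ray-parity membership: True where the point is strictly inside."""
        rng = np.random.default_rng(self._seed)
        counts, _ = self._cast(points, np.array([0.0, 0.0, 1.0]), rng)
        out = counts % 2 == 1
        return out if np.ndim(points) > 1 else bool(out[0])

    def first_entry(self, origins, direction, max_range_mm: float = np.inf) -> np.ndarray:
        """Distance along ``direction`` to the first surface crossing per ray.

        Returns +inf for rays that do not reach the surface within
        ``max_range_mm`` (and for rays whose hit grazes an edge/vertex).
        Origins are assumed outside the solid, so the first crossing is the
        entry into bone.
        """
        rng = np.random.default_rng(self._seed + 1)
        _, t = self._cast(origins, np.asarray(direction, dtype=float), rng,
                          recast=False)
        t = np.where(t > max_range_mm, np.inf, t)
        return t

    # -- surface distance -------------------------------------------------

    def _ensure_tree(self):
        if self._tree is None:
            self._tri_centroids = self.triangles.mean(axis=1)
            self._tri_radius = np.linalg.norm(
                self.triangles - self._tri_centroids[:, None, :], axis=2
            ).max(axis=1)
            self._tree = cKDTree(self._tri_centroids)

    def surface_distance(self, points, cutoff: float | None = None) -> np.ndarray:
        """Unsigned distance (mm) from each point to the mesh surface.

        With ``cutoff`` given, values above the cutoff may be upper bounds
        (enough to decide "farther than cutoff"); values at or below the
        cutoff are exact.  This keeps the candidate search bounded when only
        a near-surface decision is needed.
        """
        self._ensure_tree()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(8, len(self.triangles))
        d_cent, idx = self._tree.query(pts, k=k)
        d_cent = np.atleast_2d(d_cent)
        idx = np.atleast_2d(idx)
        flat_tris = self.triangles[idx.ravel()]
        flat_pts = np.repeat(pts, k, axis=0)
        closest = trimesh.triangles.closest_point(flat_tris, flat_pts)
        d = np.linalg.norm(closest - flat_pts, axis=1).reshape(len(pts), k)
        d_ub = d.min(axis=1)

        # a triangle not among the k nearest centroids can still be closer;
        # widen to every triangle whose centroid could beat the upper bound
        r_max = float(self._tri_radius.max())
        d_lb = d_cent[:, 0] - r_max
        if cutoff is None:
            refine = d_ub - np.maximum(d_lb, 0.0) > 1e-12
            radius = d_ub + r_max + 1e-9
        else:
            refine = (d_ub > cutoff) & (d_lb <= cutoff)
            radius = np.full(len(pts), cutoff + r_max + 1e-9)
        if refine.any():
            rpts = pts[refine]
            balls = self._tree.query_ball_point(rpts, radius[refine])
            lens = np.fromiter((len(b) for b in balls), dtype=int, count=len(rpts))
            if lens.sum():
                cand = np.concatenate(
                    [np.asarray(b, dtype=int) for b in balls if len(b)]
                )
                rep_pts = np.repeat(rpts, lens, axis=0)
                closest = trimesh.triangles.closest_point(self.triangles[cand], rep_pts)
                dd = np.linalg.norm(closest - rep_pts, axis=1)
                cuts = np.cumsum(lens) - lens
                nonzero = lens > 0
                mins = np.minimum.reduceat(dd, cuts[nonzero])
                sub = d_ub[refine]
                sub[nonzero] = np.minimum(sub[nonzero], mins)
                d_ub[refine] = sub
        return d_ub

    def in_solid(self, points, eps: float = 0.1) -> np.ndarray:
        """Inside the solid OR within ``eps`` mm of its surface."""
        if eps < 0:
            raise ValueError("eps must be >= 0")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = self.contains(pts)
        if eps > 0:
            near = self.surface_distance(pts, cutoff=eps) <= eps
            inside = inside | near
        return inside


def point_in_solid(mesh, point, eps: float = 0.1) -> bool:
    """Membership flag for a single point (see :class:`MeshQueries`).

    ``mesh`` may be a trimesh.Trimesh or a prebuilt :class:`MeshQueries`
    (preferred when querying repeatedly).
    """
    q = mesh if isinstance(mesh, MeshQueries) else MeshQueries(mesh)
    return bool(q.in_solid(np.asarray(point, dtype=float)[None, :], eps)[0])
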