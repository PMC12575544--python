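"""Catheter-vessel contact: proximity detection and Signorini-Coulomb response.

Detection follows a local-minimum proximity scheme: every catheter point whose
distance to a lumen triangle falls below an alarm threshold becomes a
*candidate* pair; crossing a second, smaller threshold (the contact distance,
defaulting to the catheter radius) makes it *active*.  Per point, pairs that
are dominated by an adjacent triangle (one sharing a vertex) with a strictly
smaller distance are collapsed, so a point near an edge or vertex yields one
pair, not one per incident triangle.

Resolution enforces Signorini's unilateral law (non-negative gap beyond the
contact distance, non-negative normal force, complementarity) together with
Coulomb friction (|f_t| <= mu * f_n, stick below the bound, slip at it;
mu = 0.62 by default, the measured catheter-on-silicone value).  The solver is
a velocity-level projected Gauss-Seidel over the contact impulses with a
box (4-direction polyhedral) friction cone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class ContactError(ValueError):
    pass


@dataclass(frozen=True)
class ContactParams:
    """Two-threshold detection plus friction coefficient."""

    alarm_distance: float = 2.0       # mm
    contact_distance: float = 0.66    # mm (catheter radius)
    friction_coefficient: float = 0.62

    def __post_init__(self):
        if not self.alarm_distance > self.contact_distance > 0:
            raise ContactError("need alarm_distance > contact_distance > 0")
        if self.friction_coefficient < 0:
            raise ContactError("friction coefficient must be >= 0")


@dataclass
class ContactPair:
    """One catheter point vs lumen triangle proximity."""

    point_id: int
    triangle_id: int
    closest_point: np.ndarray  # (3,) mm, on the triangle
    normal: np.ndarray         # (3,) unit, pointing from the wall into the lumen
    gap: float                 # signed distance along the normal, mm
    status: str                # "candidate" | "active"


@dataclass
class ContactForce:
    """Resolved contact reaction on the catheter point."""

    pair: ContactPair
    normal_force: float        # N, >= 0
    tangential_force: np.ndarray  # (2,) N in the tangent basis
    tangent_basis: np.ndarray  # (2, 3) orthonormal tangent directions

    def force_vector(self) -> np.ndarray:
        return (self.normal_force * self.pair.normal
                + self.tangential_force @ self.tangent_basis)


# ---------------------------------------------------------------------------
# Point-triangle geometry (vectorized Ericson closest-point algorithm)
# ---------------------------------------------------------------------------

def _closest_core(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                  c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on triangles (a, b, c) from points p; all inputs already
    broadcast to a common leading shape (..., 3)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(np.abs(denom) > 0, vb / denom, 0.0)
        w_face = np.where(np.abs(denom) > 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        t_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    # Voronoi-region cascade (Ericson): start from the face interior and layer
    # the outer regions, applying higher-priority regions last so they win.
    q = a + v_face[..., None] * ab + w_face[..., None] * ac       # face interior
    q = np.where(((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0))[..., None],
                 b + np.clip(t_bc, 0, 1)[..., None] * (c - b), q)  # edge BC
    q = np.where(((vb <= 0) & (d2 >= 0) & (d6 <= 0))[..., None],
                 a + np.clip(w_ac, 0, 1)[..., None] * ac, q)      # edge AC
    q = np.where(((d6 >= 0) & (d5 <= d6))[..., None],
                 np.broadcast_to(c, q.shape), q)                  # vertex C
    q = np.where(((vc <= 0) & (d1 >= 0) & (d3 <= 0))[..., None],
                 a + np.clip(v_ab, 0, 1)[..., None] * ab, q)      # edge AB
    q = np.where(((d3 >= 0) & (d4 <= d3))[..., None],
                 np.broadcast_to(b, q.shape), q)                  # vertex B
    q = np.where(((d1 <= 0) & (d2 <= 0))[..., None],
                 np.broadcast_to(a, q.shape), q)                  # vertex A
    dist = np.linalg.norm(p - q, axis=-1)
    return dist, q


def closest_points_on_triangles(points: np.ndarray,
                                triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs closest points: ``points`` (n, 3) vs ``triangles`` (m, 3, 3);
    returns the (n, m) distance matrix and (n, m, 3) closest points."""
    p = np.asarray(points, dtype=float)[:, None, :]
    tri = np.asarray(triangles, dtype=float)
    return _closest_core(p, tri[None, :, 0], tri[None, :, 1], tri[None, :, 2])


def closest_point_pairs(points: np.ndarray,
                        triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise closest points: ``points`` (k, 3) paired with
    ``triangles`` (k, 3, 3); returns (k,) distances and (k, 3) closest points."""
    p = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    return _closest_core(p, tri[:, 0], tri[:, 1], tri[:, 2])


@dataclass(frozen=True)
class CollisionSurface:
    """Triangulated lumen surface with inward normals and adjacency."""

    vertices: np.ndarray       # (nv, 3)
    faces: np.ndarray          # (nf, 3) int
    inward_normals: np.ndarray = field(init=False)
    _adjacent: tuple = field(init=False, repr=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        tri = v[f]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        areas = np.linalg.norm(n, axis=1)
        if np.any(areas < 1e-12):
            bad = int(np.argmin(areas))
            raise ContactError(f"degenerate (zero-area) triangle {bad}")
        object.__setattr__(self, "inward_normals", n / areas[:, None])
        # faces adjacent to each face (sharing >= 1 vertex), incl. itself
        vert_to_faces: list[list[int]] = [[] for _ in range(v.shape[0])]
        for fi, face in enumerate(f):
            for vid in face:
                vert_to_faces[vid].append(fi)
        adj = tuple(
            np.unique(np.concatenate([vert_to_faces[vid] for vid in face]))
            for face in f)
        object.__setattr__(self, "_adjacent", adj)

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def adjacent_faces(self, face_id: int) -> np.ndarray:
        return self._adjacent[face_id]

    def with_vertices(self, vertices: np.ndarray) -> "CollisionSurface":
        """Same topology with moved vertices (adjacency reused, normals redone)."""
        new = object.__new__(CollisionSurface)
        v = np.asarray(vertices, dtype=float)
        object.__setattr__(new, "vertices", v)
        object.__setattr__(new, "faces", self.faces)
        tri = v[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        areas = np.linalg.norm(n, axis=1)
        if np.any(areas < 1e-12):
            raise ContactError("deformation collapsed a collision triangle")
        object.__setattr__(new, "inward_normals", n / areas[:, None])
        object.__setattr__(new, "_adjacent", self._adjacent)
        return new

    @classmethod
    def from_trimesh(cls, mesh, inward: bool = True) -> "CollisionSurface":
        """Wrap a trimesh surface; flips faces so normals point into the lumen
        (trimesh watertight normals point outward)."""
        faces = mesh.faces[:, ::-1] if inward else mesh.faces
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(faces))


def detect_proximities(points: np.ndarray, surface: CollisionSurface,
                       params: ContactParams,
                       use_broad_phase: bool = True) -> list[ContactPair]:
    """All locally-minimal (point, triangle) pairs within the alarm distance.

    Per point, a pair survives only if no adjacent triangle is strictly closer
    (ties broken toward the lower triangle index), collapsing the duplicate
    hits a point near a shared edge or vertex would otherwise produce.  The
    signed gap is positive on the lumen side of the wall and negative once the
    point has penetrated it.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tris = surface.triangles
    if use_broad_phase:
        # AABB prefilter: exact distances only where the alarm-inflated
        # triangle bounding box contains the point (a superset of hits, since
        # distance < alarm implies membership in the inflated box).
        lo = tris.min(axis=1) - params.alarm_distance
        hi = tris.max(axis=1) + params.alarm_distance
        inside = np.all((pts[:, None, :] >= lo[None]) & (pts[:, None, :] <= hi[None]),
                        axis=2)
        ip, it = np.nonzero(inside)
    else:
        ip, it = np.divmod(np.arange(pts.shape[0] * tris.shape[0]), tris.shape[0])
    if ip.size == 0:
        return []
    dist, closest = closest_point_pairs(pts[ip], tris[it])
    keep = dist < params.alarm_distance
    ip, it, dist, closest = ip[keep], it[keep], dist[keep], closest[keep]
    if ip.size == 0:
        return []

    pairs: list[ContactPair] = []
    order = np.lexsort((it, ip))
    bounds = np.searchsorted(ip[order], np.arange(pts.shape[0] + 1))
    for pid in range(pts.shape[0]):
        sel = order[bounds[pid]:bounds[pid + 1]]
        if sel.size == 0:
            continue
        dist_by_tri = dict(zip(it[sel].tolist(), dist[sel].tolist()))
        for k in sel:
            tid, d = int(it[k]), float(dist[k])
            dominated = False
            for other in surface.adjacent_faces(tid):
                if other == tid or other not in dist_by_tri:
                    continue
                od = dist_by_tri[other]
                if od < d - 1e-12 or (abs(od - d) <= 1e-12 and other < tid):
                    dominated = True
                    break
            if dominated:
                continue
            cp = closest[k]
            n_tri = surface.inward_normals[tid]
            u = pts[pid] - cp
            if d > 1e-9:
                sign = 1.0 if float(u @ n_tri) >= 0 else -1.0
                normal = sign * u / d
                gap = sign * d
            else:
                normal = n_tri
                gap = 0.0
            status = "active" if gap < params.contact_distance else "candidate"
            pairs.append(ContactPair(point_id=pid, triangle_id=tid,
                                     closest_point=cp, normal=normal,
                                     gap=float(gap), status=status))
    return pairs


def tangent_basis(normal: np.ndarray) -> np.ndarray:
    """Orthonormal (2, 3) basis of the plane orthogonal to ``normal``."""
    n = np.asarray(normal, dtype=float)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, ref)
    t1 /= np.linalg.norm(t1)
    return np.vstack([t1, np.cross(n, t1)])


# ---------------------------------------------------------------------------
# Projected Gauss-Seidel resolution
# ---------------------------------------------------------------------------

@dataclass
class ContactSolveResult:
    forces: list[ContactForce]
    v_next: np.ndarray           # corrected velocities (all coupled DOFs)
    iterations: int
    residual: float              # largest impulse update of the last sweep / dt, N
    residual_history: np.ndarray
    converged: bool


def resolve_contacts(pairs: Sequence[ContactPair],
                     jac_rows: np.ndarray,
                     solve: callable,
                     v_free: np.ndarray,
                     params: ContactParams,
                     dt: float,
                     max_iterations: int = 200,
                     tolerance: float = 1e-6) -> ContactSolveResult:
    """Velocity-level Signorini-Coulomb solve by projected Gauss-Seidel.

    ``jac_rows`` is (3 * n_pairs, n_dofs): for each pair, stacked rows for the
    normal and two tangent directions mapping system velocities to relative
    contact velocities.  ``solve(rhs)`` applies the inverse of the implicit
    system matrix (the same one the free-motion solve used).  ``v_free`` is the
    unconstrained velocity solution.  The normal impulse is projected to be
    non-negative and to remove any penetration beyond the contact distance
    within the step (Signorini with a positional stabilization bias); the
    tangential impulses are projected onto the box |lambda_t_i| <= mu*lambda_n
    (a 4-direction polyhedral Coulomb cone).

    On non-convergence the best iterate is returned with ``converged=False``
    and the residual history for diagnosis; the step is not aborted.
    """
    n_pairs = len(pairs)
    if n_pairs == 0:
        return ContactSolveResult([], v_free.copy(), 0, 0.0, np.zeros(0), True)
    j = np.asarray(jac_rows, dtype=float)
    # Delassus operator columns: A^-1 J^T (one linear solve per contact row)
    cols = solve(j.T)                       # (n_dofs, 3*n_pairs)
    w = j @ cols                            # (3*np, 3*np)
    diag = np.maximum(np.diag(w), 1e-12)
    mu = params.friction_coefficient

    # Stabilization: require outgoing normal velocity sufficient to restore
    # gap >= contact_distance by the end of the step (clamped at 0 approach).
    bias = np.array([(params.contact_distance - p.gap) / dt for p in pairs])

    lam = np.zeros(3 * n_pairs)
    v = v_free.copy()
    history = []
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        # merit: largest projected impulse update this sweep, in force units
        max_dlam = 0.0
        for k in range(n_pairs):
            ni, t1i, t2i = 3 * k, 3 * k + 1, 3 * k + 2
            # normal
            vn = float(j[ni] @ v)
            new = max(0.0, lam[ni] - (vn - bias[k]) / diag[ni])
            if new != lam[ni]:
                v += cols[:, ni] * (new - lam[ni])
                max_dlam = max(max_dlam, abs(new - lam[ni]))
                lam[ni] = new
            # tangential box, aligned to the contact's tangent basis
            bound = mu * lam[ni]
            for ti in (t1i, t2i):
                vt = float(j[ti] @ v)
                new = float(np.clip(lam[ti] - vt / diag[ti], -bound, bound))
                if new != lam[ti]:
                    v += cols[:, ti] * (new - lam[ti])
                    max_dlam = max(max_dlam, abs(new - lam[ti]))
                    lam[ti] = new
        res = max_dlam / dt
        history.append(res)
        if res <= tolerance:
            converged = True
            break

    forces = []
    for k, p in enumerate(pairs):
        basis = tangent_basis(p.normal)
        forces.append(ContactForce(pair=p, normal_force=float(lam[3 * k] / dt),
                                   tangential_force=lam[3 * k + 1:3 * k + 3] / dt,
                                   tangent_basis=basis))
    return ContactSolveResult(forces=forces, v_next=v, iterations=it,
                              residual=history[-1] if history else 0.0,
                              residual_history=np.asarray(history),
                              converged=converged)


def contact_jacobian_points(pairs: Sequence[ContactPair], n_dofs: int,
                            dofs_per_node: int = 6) -> np.ndarray:
    """Jacobian rows for point contacts on beam nodes (translations only).

    Rows come in triples (normal, tangent1, tangent2) per pair; relative
    velocity is taken positive along the inward normal (separation).
    """
    j = np.zeros((3 * len(pairs), n_dofs))
    for k, p in enumerate(pairs):
        base = dofs_per_node * p.point_id
        basis = tangent_basis(p.normal)
        j[3 * k, base:base + 3] = p.normal
        j[3 * k + 1, base:base + 3] = basis[0]
        j[3 * k + 2, base:base + 3] = basis[1]
    return j
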