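"""Tetrahedral finite-element vessel model.

The vessel wall is a linear (P1) tetrahedral mesh with one of two material
treatments:

* ``elastic`` -- small-strain isotropic elasticity evaluated in a per-element
  rotated frame (corotational: the element rotation is extracted from the
  deformation gradient by polar decomposition), so visible rigid rotations of
  the wall do not generate spurious strain.  A ``pure_linear`` switch disables
  the rotation extraction for strict-linearity checks.
* hyperelastic (``neo_hookean`` / ``mooney_rivlin`` / ``ogden``) -- the
  invariant- or stretch-based strain-energy densities with near-
  incompressibility imposed weakly by a volumetric penalty kappa*(J-1)^2
  (strict incompressibility is numerically singular in displacement-only FEM).
  Each energy carries a -c*ln(J) consistency term chosen so the stress
  vanishes in the reference configuration.

Static deformation under a constant force field is solved by Newton iteration
on the residual (one iteration suffices in pure-linear mode); dynamic stepping
reuses a single per-step linearized tangent, mirroring interactive-simulation
practice (and its known accuracy cost for hyperelastic walls).

Units: mm, N, MPa, tonne, s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .materials import ConstitutiveModel, MaterialError
from . import mesh_io


class MeshValidationError(ValueError):
    pass


class SolveError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TetModel:
    """Tetrahedral mesh + material + boundary conditions."""

    vertices: np.ndarray          # (nv, 3) mm, rest configuration
    tets: np.ndarray              # (nt, 4) int, positively oriented
    surface_faces: np.ndarray     # (nf, 3) boundary triangles, outward of solid
    material: ConstitutiveModel
    poisson_ratio: float = 0.45   # elastic kind only
    bulk_penalty: float = 0.0     # kappa (MPa), hyperelastic kinds
    fixed_vertex_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    density: float = 1.1e-9       # tonne/mm^3 (silicone-like)
    corotational: bool = True     # elastic kind: extract per-element rotation
    # precomputed
    dm_inv: np.ndarray = field(init=False, repr=False)
    volumes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.tets, dtype=int)
        dm = np.stack([v[t[:, 1]] - v[t[:, 0]],
                       v[t[:, 2]] - v[t[:, 0]],
                       v[t[:, 3]] - v[t[:, 0]]], axis=2)  # columns are edges
        vol = np.linalg.det(dm) / 6.0
        if np.any(vol <= 0):
            bad = int(np.argmin(vol))
            raise MeshValidationError(
                f"tetrahedron {bad} has non-positive volume {vol[bad]:.3e}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "tets", t)
        object.__setattr__(self, "surface_faces", np.asarray(self.surface_faces, dtype=int))
        object.__setattr__(self, "fixed_vertex_ids",
                           np.asarray(self.fixed_vertex_ids, dtype=int))
        object.__setattr__(self, "dm_inv", np.linalg.inv(dm))
        object.__setattr__(self, "volumes", vol)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_vertices

    def lumped_masses(self) -> np.ndarray:
        m = np.zeros(self.n_vertices)
        np.add.at(m, self.tets.ravel(),
                  np.repeat(self.density * self.volumes / 4.0, 4))
        return m

    def with_fixed(self, fixed_vertex_ids) -> "TetModel":
        return replace(self, fixed_vertex_ids=np.asarray(fixed_vertex_ids, dtype=int))


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Boundary triangles of a tet mesh, oriented outward of the solid."""
    # local faces with outward orientation for a positively oriented tet
    local = [(0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3)]
    faces = np.concatenate([tets[:, f] for f in local], axis=0)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def default_bulk_penalty(material: ConstitutiveModel) -> float:
    """Volumetric penalty kappa = 100 x the material's shear-modulus scale."""
    return 100.0 * material.small_strain_shear_modulus()


def build_tet_model(material: ConstitutiveModel,
                    vertices: Optional[np.ndarray] = None,
                    tets: Optional[np.ndarray] = None,
                    surface_mesh=None,
                    fixed_vertex_ids: Sequence[int] = (),
                    poisson_ratio: float = 0.45,
                    bulk_penalty: Optional[float] = None,
                    density: float = 1.1e-9,
                    corotational: bool = True,
                    target_edge: Optional[float] = None) -> TetModel:
    """Validate and assemble a tet model from a volume mesh or a watertight
    surface.

    Volume input: tets with negative signed volume are re-oriented (node swap);
    a genuinely degenerate element raises.  Surface input (a trimesh): the
    interior is point-sampled on a grid and Delaunay-tetrahedralized, keeping
    only tets whose centroid lies inside the surface -- adequate for chunky
    solids, not for thin shells (the phantom generator builds those directly).
    """
    if vertices is None or tets is None:
        if surface_mesh is None:
            raise MeshValidationError("need (vertices, tets) or a surface mesh")
        if not surface_mesh.is_watertight:
            raise MeshValidationError("surface mesh is not watertight; cannot fill volume")
        vertices, tets = _delaunay_fill(surface_mesh, target_edge)
    vertices = np.asarray(vertices, dtype=float)
    tets = np.asarray(tets, dtype=int).copy()
    dm = np.stack([vertices[tets[:, 1]] - vertices[tets[:, 0]],
                   vertices[tets[:, 2]] - vertices[tets[:, 0]],
                   vertices[tets[:, 3]] - vertices[tets[:, 0]]], axis=2)
    vol = np.linalg.det(dm) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    if bulk_penalty is None:
        bulk_penalty = (default_bulk_penalty(material)
                        if material.kind != "elastic" else 0.0)
    return TetModel(vertices=vertices, tets=tets,
                    surface_faces=boundary_faces(tets), material=material,
                    poisson_ratio=poisson_ratio, bulk_penalty=bulk_penalty,
                    fixed_vertex_ids=np.asarray(fixed_vertex_ids, dtype=int),
                    density=density, corotational=corotational)


def points_inside_surface(vertices: np.ndarray, faces: np.ndarray,
                          points: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Containment test by generalized winding number (van Oosterom-Strackee
    solid angles); robust for watertight meshes, no spatial index needed."""
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty(pts.shape[0], dtype=bool)
    tri = v[f]
    for start in range(0, pts.shape[0], chunk):
        p = pts[start:start + chunk][:, None, :]
        a = tri[None, :, 0] - p
        b = tri[None, :, 1] - p
        c = tri[None, :, 2] - p
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        det = np.einsum("pti,pti->pt", a, np.cross(b, c))
        denom = (la * lb * lc + np.einsum("pti,pti->pt", a, b) * lc
                 + np.einsum("pti,pti->pt", b, c) * la
                 + np.einsum("pti,pti->pt", c, a) * lb)
        omega = 2.0 * np.arctan2(det, denom)
        out[start:start + chunk] = np.abs(omega.sum(axis=1)) > 2.0 * np.pi
    return out


def _delaunay_fill(surface_mesh, target_edge: Optional[float]):
    from scipy.spatial import Delaunay
    pts = np.asarray(surface_mesh.vertices, dtype=float)
    faces = np.asarray(surface_mesh.faces, dtype=int)
    if target_edge:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        axes = [np.arange(lo[k], hi[k] + target_edge, target_edge) for k in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        inside = points_inside_surface(pts, faces, grid)
        pts = np.vstack([pts, grid[inside]])
    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    keep = points_inside_surface(np.asarray(surface_mesh.vertices, dtype=float),
                                 faces, cent)
    return pts, tri.simplices[keep]


def load_tet_model(path: str | Path, material: ConstitutiveModel,
                   **kwargs) -> TetModel:
    """Read a volume mesh (MSH or legacy VTK by extension) into a TetModel."""
    path = Path(path)
    if path.suffix.lower() == ".msh":
        verts, tets, _ = mesh_io.read_msh(path)
    elif path.suffix.lower() == ".vtk":
        verts, tets, _ = mesh_io.read_vtk(path)
    else:
        raise MeshValidationError(f"unsupported volume mesh format {path.suffix}")
    if tets.size == 0:
        raise MeshValidationError(f"{path}: no tetrahedra found")
    return build_tet_model(material, vertices=verts, tets=tets, **kwargs)


# ---------------------------------------------------------------------------
# Constitutive evaluation (first Piola-Kirchhoff stress and tangent)
# ---------------------------------------------------------------------------

def _lame(e_mod: float, nu: float) -> tuple[float, float]:
    mu = e_mod / (2.0 * (1.0 + nu))
    lam = e_mod * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu, lam


def elastic_moduli_equivalent(material: ConstitutiveModel,
                              bulk_penalty: float) -> tuple[float, float]:
    """(E, nu) of the linear material matching a hyperelastic model's
    small-strain limit: mu from the model, lambda = 2*kappa."""
    mu = material.small_strain_shear_modulus()
    lam = 2.0 * bulk_penalty
    e_mod = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return e_mod, nu


def strain_energy_density(material: ConstitutiveModel, bulk_penalty: float,
                          f_grad: np.ndarray) -> float:
    """W(F) for the hyperelastic kinds (with ln-J consistency + penalty)."""
    j_det = float(np.linalg.det(f_grad))
    if j_det <= 0:
        raise SolveError("element inverted (J <= 0)")
    c_mat = f_grad.T @ f_grad
    i1 = float(np.trace(c_mat))
    pen = bulk_penalty * (j_det - 1.0) ** 2
    kind, p = material.kind, material.params
    if kind == "neo_hookean":
        return p["mu"] * (i1 - 3.0 - 2.0 * np.log(j_det)) + pen
    if kind == "mooney_rivlin":
        i2 = 0.5 * (i1**2 - float(np.trace(c_mat @ c_mat)))
        c_log = 2.0 * p["c10"] + 4.0 * p["c01"]
        return (p["c10"] * (i1 - 3.0) + p["c01"] * (i2 - 3.0)
                - c_log * np.log(j_det) + pen)
    if kind == "ogden":
        mu, alpha = material.ogden_terms()
        lam2 = np.linalg.eigvalsh(c_mat)
        lam_p = np.sqrt(np.maximum(lam2, 1e-30))
        c_log = float(np.sum(2.0 * mu / alpha))
        w = float(np.sum(2.0 * mu / alpha**2
                         * (np.sum(lam_p[None, :] ** alpha[:, None], axis=1) - 3.0)))
        return w - c_log * np.log(j_det) + pen
    raise MaterialError(f"no strain energy for kind {kind!r}")


def piola_stress(material: ConstitutiveModel, bulk_penalty: float,
                 f_grad: np.ndarray) -> np.ndarray:
    """First Piola-Kirchhoff stress P(F) for the hyperelastic kinds."""
    j_det = float(np.linalg.det(f_grad))
    if j_det <= 0:
        raise SolveError("element inverted (J <= 0)")
    f_inv_t = np.linalg.inv(f_grad).T
    pen = 2.0 * bulk_penalty * (j_det - 1.0) * j_det * f_inv_t
    kind, p = material.kind, material.params
    if kind == "neo_hookean":
        mu = p["mu"]
        return 2.0 * mu * f_grad - 2.0 * mu * f_inv_t + pen
    if kind == "mooney_rivlin":
        c_mat = f_grad.T @ f_grad
        i1 = float(np.trace(c_mat))
        c_log = 2.0 * p["c10"] + 4.0 * p["c01"]
        return (2.0 * p["c10"] * f_grad
                + 2.0 * p["c01"] * (i1 * f_grad - f_grad @ c_mat)
                - c_log * f_inv_t + pen)
    if kind == "ogden":
        mu, alpha = material.ogden_terms()
        c_mat = f_grad.T @ f_grad
        lam2, n_ref = np.linalg.eigh(c_mat)
        lam_p = np.sqrt(np.maximum(lam2, 1e-30))
        c_log = float(np.sum(2.0 * mu / alpha))
        p_out = pen
        for a in range(3):
            dw = float(np.sum(2.0 * mu / alpha * lam_p[a] ** (alpha - 1.0)))
            dw -= c_log / lam_p[a]
            n_cur = f_grad @ n_ref[:, a] / lam_p[a]
            p_out = p_out + dw * np.outer(n_cur, n_ref[:, a])
        return p_out
    raise MaterialError(f"no stress law for kind {kind!r}")


def piola_tangent(material: ConstitutiveModel, bulk_penalty: float,
                  f_grad: np.ndarray) -> np.ndarray:
    """dP/dF as a 9x9 matrix (row-major F flattening).

    Analytic for neo-Hookean and Mooney-Rivlin; central finite differences of
    the analytic stress for Ogden (symmetrized).
    """
    kind = material.kind
    if kind == "ogden":
        h = 1e-6
        a9 = np.empty((9, 9))
        for k in range(9):
            df = np.zeros(9)
            df[k] = h
            fp = f_grad + df.reshape(3, 3)
            fm = f_grad - df.reshape(3, 3)
            a9[:, k] = ((piola_stress(material, bulk_penalty, fp)
                         - piola_stress(material, bulk_penalty, fm)) / (2 * h)).ravel()
        return 0.5 * (a9 + a9.T)

    j_det = float(np.linalg.det(f_grad))
    f_inv = np.linalg.inv(f_grad)
    f_inv_t = f_inv.T
    p = material.params
    eye9 = np.eye(9)
    # building blocks, all as 9x9 acting on vec(dF) row-major
    #   d(F^-T)[dF]_ij = -(F^-T)_il dF_kl (F^-T)_kj
    finvt_kron = -np.einsum("il,kj->ijkl", f_inv_t, f_inv_t).reshape(9, 9)
    fit_flat = f_inv_t.ravel()
    if kind == "neo_hookean":
        mu = p["mu"]
        a9 = 2.0 * mu * eye9 - 2.0 * mu * finvt_kron
    elif kind == "mooney_rivlin":
        c_mat = f_grad.T @ f_grad
        i1 = float(np.trace(c_mat))
        c01 = p["c01"]
        # d(I1 F) = 2(F:dF) F + I1 dF
        t1 = 2.0 * np.outer(f_grad.ravel(), f_grad.ravel()) + i1 * eye9
        # d(F C) = dF C + F dF^T F + F F^T dF
        dfc = np.einsum("jl,ik->ijkl", c_mat, np.eye(3)).reshape(9, 9)
        # (F dF^T F)_ij derivative wrt dF_kl is F_il F_kj
        fdftf = np.einsum("il,kj->ijkl", f_grad, f_grad).reshape(9, 9)
        b_mat = f_grad @ f_grad.T
        ffdf = np.einsum("ik,jl->ijkl", b_mat, np.eye(3)).reshape(9, 9)
        c_log = 2.0 * p["c10"] + 4.0 * c01
        a9 = (2.0 * p["c10"] * eye9 + 2.0 * c01 * (t1 - dfc - fdftf - ffdf)
              - c_log * finvt_kron)
    else:
        raise MaterialError(f"no analytic tangent for kind {kind!r}")
    # volumetric penalty: P_pen = g(J) F^-T, g = 2*kappa*(J-1)*J
    g = 2.0 * bulk_penalty * (j_det - 1.0) * j_det
    gp = 2.0 * bulk_penalty * (2.0 * j_det - 1.0)
    a9 += gp * j_det * np.outer(fit_flat, fit_flat) + g * finvt_kron
    return a9


# ---------------------------------------------------------------------------
# Element quantities and assembly
# ---------------------------------------------------------------------------

def _element_cache(model: TetModel) -> dict:
    """Per-model precomputed element data (DOF indices, B-matrices, etc.)."""
    cache = getattr(model, "_ecache", None)
    if cache is not None:
        return cache
    nt = model.n_tets
    conn = model.tets
    idx = (3 * conn[:, :, None] + np.arange(3)).reshape(nt, 12)
    cache = {
        "idx": idx,
        "rows": np.repeat(idx, 12, axis=1).ravel(),
        "cols": np.tile(idx, (1, 12)).ravel(),
    }
    # shape-function gradients: grad N_i = dm_inv row (i-1); node 0 = -sum
    grads = np.empty((nt, 4, 3))
    grads[:, 1:] = model.dm_inv
    grads[:, 0] = -model.dm_inv.sum(axis=1)
    cache["grads"] = grads
    if model.material.kind == "elastic":
        e_mod, nu = model.material.params["e"], model.poisson_ratio
        mu, lam = _lame(e_mod, nu)
        c_mat = np.zeros((6, 6))
        c_mat[:3, :3] = lam
        c_mat[np.diag_indices(3)] = lam + 2.0 * mu
        c_mat[3:, 3:] = mu * np.eye(3)
        b_mat = np.zeros((nt, 6, 12))
        gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
        for i in range(4):
            b_mat[:, 0, 3 * i] = gx[:, i]
            b_mat[:, 1, 3 * i + 1] = gy[:, i]
            b_mat[:, 2, 3 * i + 2] = gz[:, i]
            b_mat[:, 3, 3 * i] = gy[:, i]
            b_mat[:, 3, 3 * i + 1] = gx[:, i]
            b_mat[:, 4, 3 * i + 1] = gz[:, i]
            b_mat[:, 4, 3 * i + 2] = gy[:, i]
            b_mat[:, 5, 3 * i] = gz[:, i]
            b_mat[:, 5, 3 * i + 2] = gx[:, i]
        cache["k_lin"] = model.volumes[:, None, None] * np.einsum(
            "nji,jk,nkl->nil", b_mat, c_mat, b_mat)
    else:
        # dF/du as (nt, 9, 12), row-major F flattening
        d_mat = np.zeros((nt, 9, 12))
        for n_node in range(4):
            for ell in range(3):
                for j in range(3):
                    d_mat[:, 3 * ell + j, 3 * n_node + ell] = grads[:, n_node, j]
        cache["d_mat"] = d_mat
    object.__setattr__(model, "_ecache", cache)
    return cache


def _polar_rotations(f_grads: np.ndarray) -> np.ndarray:
    """Batched rotation factors of the polar decomposition (reflection-safe)."""
    u, _, vt = np.linalg.svd(f_grads)
    det = np.linalg.det(u @ vt)
    u = u.copy()
    u[det < 0, :, -1] *= -1.0
    return u @ vt


def _batched_piola(material: ConstitutiveModel, kappa: float,
                   f: np.ndarray) -> np.ndarray:
    """First Piola-Kirchhoff stress for a batch of deformation gradients."""
    j_det = np.linalg.det(f)
    if np.any(j_det <= 0):
        bad = int(np.argmin(j_det))
        raise SolveError(f"element {bad} inverted (J = {j_det[bad]:.3e})")
    f_inv_t = np.linalg.inv(f).transpose(0, 2, 1)
    pen = (2.0 * kappa * (j_det - 1.0) * j_det)[:, None, None] * f_inv_t
    kind, p = material.kind, material.params
    if kind == "neo_hookean":
        mu = p["mu"]
        return 2.0 * mu * f - 2.0 * mu * f_inv_t + pen
    if kind == "mooney_rivlin":
        c_mat = f.transpose(0, 2, 1) @ f
        i1 = np.trace(c_mat, axis1=1, axis2=2)
        c_log = 2.0 * p["c10"] + 4.0 * p["c01"]
        return (2.0 * p["c10"] * f
                + 2.0 * p["c01"] * (i1[:, None, None] * f - f @ c_mat)
                - c_log * f_inv_t + pen)
    if kind == "ogden":
        mu, alpha = material.ogden_terms()
        c_mat = f.transpose(0, 2, 1) @ f
        lam2, n_ref = np.linalg.eigh(c_mat)
        lam_p = np.sqrt(np.maximum(lam2, 1e-30))        # (nt, 3)
        c_log = float(np.sum(2.0 * mu / alpha))
        # dW/dlambda_a per principal direction
        dw = np.zeros_like(lam_p)
        for m, a in zip(mu, alpha):
            dw += 2.0 * m / a * lam_p ** (a - 1.0)
        dw -= c_log / lam_p
        n_cur = (f @ n_ref) / lam_p[:, None, :]          # columns: n_a
        return pen + np.einsum("na,nia,nja->nij", dw, n_cur, n_ref)
    raise MaterialError(f"no stress law for kind {kind!r}")


def _batched_tangent(material: ConstitutiveModel, kappa: float,
                     f: np.ndarray) -> np.ndarray:
    """dP/dF as (nt, 9, 9); analytic for NH/MR, central FD on P for Ogden."""
    nt = f.shape[0]
    kind, p = material.kind, material.params
    if kind == "ogden":
        h = 1e-6
        a9 = np.empty((nt, 9, 9))
        for k in range(9):
            df = np.zeros(9)
            df[k] = h
            df = df.reshape(3, 3)
            a9[:, :, k] = ((_batched_piola(material, kappa, f + df)
                            - _batched_piola(material, kappa, f - df))
                           / (2.0 * h)).reshape(nt, 9)
        return 0.5 * (a9 + a9.transpose(0, 2, 1))
    j_det = np.linalg.det(f)
    f_inv_t = np.linalg.inv(f).transpose(0, 2, 1)
    eye9 = np.eye(9)
    finvt_kron = -np.einsum("nil,nkj->nijkl", f_inv_t, f_inv_t).reshape(nt, 9, 9)
    fit_flat = f_inv_t.reshape(nt, 9)
    if kind == "neo_hookean":
        mu = p["mu"]
        a9 = 2.0 * mu * eye9[None] - 2.0 * mu * finvt_kron
    elif kind == "mooney_rivlin":
        c_mat = f.transpose(0, 2, 1) @ f
        i1 = np.trace(c_mat, axis1=1, axis2=2)
        c01 = p["c01"]
        f_flat = f.reshape(nt, 9)
        t1 = (2.0 * np.einsum("ni,nj->nij", f_flat, f_flat)
              + i1[:, None, None] * eye9[None])
        eye3 = np.eye(3)
        dfc = np.einsum("njl,ik->nijkl", c_mat, eye3).reshape(nt, 9, 9)
        fdftf = np.einsum("nil,nkj->nijkl", f, f).reshape(nt, 9, 9)
        b_mat = f @ f.transpose(0, 2, 1)
        ffdf = np.einsum("nik,jl->nijkl", b_mat, eye3).reshape(nt, 9, 9)
        c_log = 2.0 * p["c10"] + 4.0 * c01
        a9 = (2.0 * p["c10"] * eye9[None] + 2.0 * c01 * (t1 - dfc - fdftf - ffdf)
              - c_log * finvt_kron)
    else:
        raise MaterialError(f"no analytic tangent for kind {kind!r}")
    g = 2.0 * kappa * (j_det - 1.0) * j_det
    gp = 2.0 * kappa * (2.0 * j_det - 1.0)
    a9 += ((gp * j_det)[:, None, None] * np.einsum("ni,nj->nij", fit_flat, fit_flat)
           + g[:, None, None] * finvt_kron)
    return a9


def internal_forces(model: TetModel, displacement: np.ndarray,
                    with_tangent: bool = True
                    ) -> tuple[np.ndarray, Optional[sparse.csr_matrix]]:
    """Global internal force vector (3nv,) and tangent stiffness (sparse).

    Elastic kind: corotational (or pure linear) per-element stiffness.
    Hyperelastic kinds: exact P(F) forces with the consistent dP/dF tangent.
    Fully vectorized over elements.
    """
    u = np.asarray(displacement, dtype=float).reshape(model.n_vertices, 3)
    x_cur = model.vertices + u
    cache = _element_cache(model)
    conn = model.tets
    nt = model.n_tets
    xc = x_cur[conn]                                    # (nt, 4, 3)
    ds = (xc[:, 1:] - xc[:, :1]).transpose(0, 2, 1)     # columns are edges
    f_grads = ds @ model.dm_inv
    k_elem = None
    if model.material.kind != "elastic":
        p_stress = _batched_piola(model.material, model.bulk_penalty, f_grads)
        g_mat = model.volumes[:, None, None] * (
            p_stress @ model.dm_inv.transpose(0, 2, 1))  # (nt, 3, 3)
        f_elem = np.empty((nt, 12))
        f_elem[:, 3:] = g_mat.transpose(0, 2, 1).reshape(nt, 9)
        f_elem[:, :3] = -g_mat.sum(axis=2)
        if with_tangent:
            a9 = _batched_tangent(model.material, model.bulk_penalty, f_grads)
            d_mat = cache["d_mat"]
            k_elem = model.volumes[:, None, None] * np.einsum(
                "nji,njk,nkl->nil", d_mat, a9, d_mat)
    else:
        k_lin = cache["k_lin"]
        if model.corotational:
            r_mat = _polar_rotations(f_grads)
        else:
            r_mat = np.broadcast_to(np.eye(3), (nt, 3, 3))
        # local displacement: R^T x_cur - x_rest per node
        d_loc = (np.einsum("nji,nkj->nki", r_mat, xc)
                 - model.vertices[conn]).reshape(nt, 12)
        f_loc = np.einsum("nij,nj->ni", k_lin, d_loc).reshape(nt, 4, 3)
        f_elem = np.einsum("nij,nkj->nki", r_mat, f_loc).reshape(nt, 12)
        if with_tangent:
            r_blk = np.zeros((nt, 12, 12))
            for blk in range(4):
                r_blk[:, 3 * blk:3 * blk + 3, 3 * blk:3 * blk + 3] = r_mat
            k_elem = r_blk @ k_lin @ r_blk.transpose(0, 2, 1)
    f_out = np.zeros(model.n_dofs)
    np.add.at(f_out, cache["idx"].ravel(), f_elem.ravel())
    k_out = None
    if with_tangent:
        k_out = sparse.csr_matrix(
            (k_elem.ravel(), (cache["rows"], cache["cols"])),
            shape=(model.n_dofs, model.n_dofs))
    return f_out, k_out


def total_strain_energy(model: TetModel, displacement: np.ndarray) -> float:
    """Stored energy of a hyperelastic model at the given displacement."""
    u = np.asarray(displacement, dtype=float).reshape(model.n_vertices, 3)
    x_cur = model.vertices + u
    total = 0.0
    for e in range(model.n_tets):
        conn = model.tets[e]
        ds = (x_cur[conn[1:]] - x_cur[conn[0]]).T
        f_grad = ds @ model.dm_inv[e]
        total += model.volumes[e] * strain_energy_density(
            model.material, model.bulk_penalty, f_grad)
    return total


def tangent_stiffness(model: TetModel, displacement: np.ndarray) -> sparse.csr_matrix:
    """Global tangent at the given displacement (see :func:`internal_forces`)."""
    _, k_mat = internal_forces(model, displacement, with_tangent=True)
    return k_mat


# ---------------------------------------------------------------------------
# Static solve and deformation reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantForceField:
    """Constant nodal forces applied to a set of target vertices."""

    vertex_ids: np.ndarray    # (k,)
    forces: np.ndarray        # (k, 3) N per vertex, or (3,) shared

    def as_vector(self, model: TetModel) -> np.ndarray:
        ids = np.asarray(self.vertex_ids, dtype=int)
        if np.any(ids < 0) or np.any(ids >= model.n_vertices):
            raise MeshValidationError("force-field target vertex out of range")
        f = np.zeros((model.n_vertices, 3))
        forces = np.asarray(self.forces, dtype=float)
        f[ids] = forces if forces.ndim == 2 else np.tile(forces, (ids.size, 1))
        return f.ravel()

    def total_magnitude(self) -> float:
        forces = np.atleast_2d(np.asarray(self.forces, dtype=float))
        if forces.shape[0] == 1:
            forces = np.tile(forces, (np.asarray(self.vertex_ids).size, 1))
        return float(np.linalg.norm(forces.sum(axis=0)))


@dataclass(frozen=True)
class DeformationReport:
    """Static-solve outcome: per-vertex displacement and landmark summary."""

    displacements: np.ndarray          # (nv, 3) mm
    applied_force_magnitude: float     # N
    landmark_ids: np.ndarray
    landmark_displacements: np.ndarray  # (k,) mm, Euclidean per landmark
    residual_norm: float
    iterations: int

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=1).max())


def static_solve(model: TetModel, field_: ConstantForceField,
                 landmark_ids: Sequence[int] = (),
                 max_iter: int = 150, tol: float = 1e-6, xtol: float = 1e-11,
                 n_load_steps: Optional[int] = None) -> DeformationReport:
    """Newton solve of static equilibrium under a constant force field.

    Requires a non-empty fixed set.  Converges when ||f_int - f_ext|| on the
    free DOFs drops below ``tol`` times the external-force norm.  Hyperelastic
    models ramp the load over a few increments for robustness.
    """
    if model.fixed_vertex_ids.size == 0:
        raise MeshValidationError("static solve requires a non-empty fixed vertex set")
    f_ext_full = field_.as_vector(model)
    fixed_dofs = (3 * model.fixed_vertex_ids[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(model.n_dofs), fixed_dofs)
    scale = np.linalg.norm(f_ext_full[free])
    u = np.zeros(model.n_dofs)
    if scale == 0:
        return _report(model, u, field_, landmark_ids, 0.0, 0)
    if n_load_steps is None:
        linear = model.material.kind == "elastic" and not model.corotational
        n_load_steps = 1 if linear else 4
    total_iters = 0
    resid_norm = np.inf
    for step in range(1, n_load_steps + 1):
        f_target = f_ext_full * (step / n_load_steps)
        f_int, k_mat = internal_forces(model, u, with_tangent=True)
        resid = f_target - f_int
        resid_norm = float(np.linalg.norm(resid[free]))
        for _ in range(max_iter):
            if resid_norm <= tol * scale * (step / n_load_steps):
                break
            kff = k_mat[free][:, free].tocsc()
            du = spsolve(kff, resid[free])
            if not np.all(np.isfinite(du)):
                raise SolveError("Newton increment is non-finite")
            if np.max(np.abs(du)) <= xtol:
                break  # increment at the rounding floor; residual won't improve
            # backtracking line search on the free-DOF residual norm
            alpha = 1.0
            for _ in range(10):
                u_try = u.copy()
                u_try[free] += alpha * du
                try:
                    f_int_t, k_t = internal_forces(model, u_try, with_tangent=True)
                except SolveError:
                    alpha *= 0.5
                    continue
                r_try = float(np.linalg.norm((f_target - f_int_t)[free]))
                if r_try < resid_norm or alpha < 1e-3:
                    u = u_try
                    f_int, k_mat = f_int_t, k_t
                    resid = f_target - f_int
                    resid_norm = r_try
                    break
                alpha *= 0.5
            else:
                raise SolveError(f"line search failed at residual {resid_norm:.3e} "
                                 f"(load step {step}/{n_load_steps})")
            total_iters += 1
        else:
            raise SolveError(f"static solve stagnated at residual {resid_norm:.3e} "
                             f"(load step {step}/{n_load_steps})")
    return _report(model, u, field_, landmark_ids, resid_norm, total_iters)


def _report(model, u, field_, landmark_ids, resid, iters) -> DeformationReport:
    disp = u.reshape(model.n_vertices, 3)
    lm = np.asarray(landmark_ids, dtype=int)
    lm_disp = np.linalg.norm(disp[lm], axis=1) if lm.size else np.zeros(0)
    return DeformationReport(displacements=disp,
                             applied_force_magnitude=field_.total_magnitude(),
                             landmark_ids=lm, landmark_displacements=lm_disp,
                             residual_norm=resid, iterations=iters)


def measure_displacement(model: TetModel, report: DeformationReport,
                         landmark_ids: Sequence[int]) -> tuple[np.ndarray, float]:
    """Euclidean displacement (mm) at each landmark and the max over the mesh."""
    lm = np.asarray(landmark_ids, dtype=int)
    if np.any(lm < 0) or np.any(lm >= model.n_vertices):
        raise MeshValidationError("landmark id out of range")
    per = np.linalg.norm(report.displacements[lm], axis=1)
    return per, report.max_displacement()


def export_deformed_vtk(path: str | Path, model: TetModel,
                        report: DeformationReport) -> None:
    mesh_io.write_vtk(path, model.vertices + report.displacements,
                      tets=model.tets,
                      point_data={"displacement": report.displacements})


# ---------------------------------------------------------------------------
# Dynamic stepping (single linearization per step, for coupled scenes)
# ---------------------------------------------------------------------------

def implicit_system(model: TetModel, u: np.ndarray, v: np.ndarray, dt: float,
                    external: Optional[np.ndarray] = None,
                    rayleigh_alpha: float = 0.1, rayleigh_beta: float = 0.01
                    ) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Backward-Euler velocity system A v+ = b for the vessel block.

    A = M + dt C + dt^2 K with K linearized once at the current displacement
    (this per-step linearization is exactly the approximation that degrades
    hyperelastic walls in interactive use; static_solve does full Newton).
    """
    f_int, k_mat = internal_forces(model, u, with_tangent=True)
    m_diag = np.repeat(model.lumped_masses(), 3)
    f_ext = np.zeros(model.n_dofs) if external is None else np.asarray(external, float)
    a_mat = (sparse.diags(m_diag * (1.0 + dt * rayleigh_alpha))
             + (dt * rayleigh_beta + dt**2) * k_mat)
    b_vec = m_diag * v + dt * (f_ext - f_int)
    return a_mat.tocsr(), b_vec
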