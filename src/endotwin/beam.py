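"""Catheter model: a chain of two-node, six-DOF corotational beam elements.

The catheter (80 cm long, 4 F = 1.32 mm diameter by default) is discretized
into two-node Timoshenko beam elements whose nodes carry a position and an
orientation quaternion.  Motion is decomposed into a rigid per-element frame
plus small local deformations (corotational formulation), so the stiff, long
instrument can undergo arbitrary rigid motion while the element-level material
law stays linear.  Dynamics follow Newton's second law,

    M(x) xdd = F(t) - f(x, xd) + W(x, xd),

with M a lumped inertia matrix, f the corotational internal forces (plus
Rayleigh damping), F external loads and W the boundary conditions (the
insertion driver and contact impulses).  Time integration is implicit
(backward) Euler with one linearization per step.

Units: mm, N, MPa (= N/mm^2), tonne (so that 1 N = 1 tonne*mm/s^2), seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

GRAVITY_MM_S2 = 9810.0


class BeamConfigError(ValueError):
    pass


class StepError(RuntimeError):
    """Implicit step failed (solver breakdown or non-finite state)."""


# ---------------------------------------------------------------------------
# Configuration and assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamConfig:
    """Geometric and material description of the catheter.

    Defaults reproduce the reference instrument configuration: 800 mm length,
    1.32 mm outer diameter, an effective (tuned, not physical) Young's modulus
    of 600 GPa, density 1.55 g/cm^3 and 50 nodes.
    """

    total_length: float = 800.0          # mm
    outer_diameter: float = 1.32         # mm
    young_modulus: float = 6.0e5         # MPa (600 GPa)
    density: float = 1.55e-9             # tonne/mm^3 (1.55 g/cm^3)
    n_nodes: int = 50
    poisson_ratio: float = 0.3
    inner_diameter: float = 0.0          # > 0 for a hollow tube section
    rest_centerline: Optional[np.ndarray] = None  # (n_nodes, 3); straight +x if None
    rayleigh_alpha: float = 0.1          # mass-proportional damping, 1/s
    rayleigh_beta: float = 0.01          # stiffness-proportional damping, s
    gravity: bool = False

    def __post_init__(self):
        if self.n_nodes < 2:
            raise BeamConfigError("n_nodes must be >= 2")
        if min(self.total_length, self.outer_diameter, self.young_modulus,
               self.density) <= 0:
            raise BeamConfigError("lengths, modulus and density must be positive")
        if not 0 <= self.inner_diameter < self.outer_diameter:
            raise BeamConfigError("inner_diameter must lie in [0, outer_diameter)")
        if self.rest_centerline is not None:
            c = np.asarray(self.rest_centerline, dtype=float)
            if c.shape != (self.n_nodes, 3):
                raise BeamConfigError("rest_centerline must be (n_nodes, 3)")
            arclen = float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())
            if abs(arclen - self.total_length) > 1e-3 * self.total_length:
                raise BeamConfigError(
                    f"rest_centerline arclength {arclen:.3f} mm differs from "
                    f"total_length {self.total_length} mm by more than 0.1%")
            object.__setattr__(self, "rest_centerline", c)


@dataclass(frozen=True)
class BeamAssembly:
    """Discretized catheter: rest geometry, section properties, lumped inertia."""

    config: BeamConfig
    rest_positions: np.ndarray     # (n, 3)
    rest_frames: np.ndarray        # (n, 3, 3) node material frames at rest
    element_frames0: np.ndarray    # (ne, 3, 3) element frames at rest
    rest_lengths: np.ndarray       # (ne,)
    area: float                    # mm^2
    inertia: float                 # second moment I (mm^4), bending
    polar_inertia: float           # J (mm^4), torsion
    node_mass: np.ndarray          # (n,) tonne
    node_rot_inertia: np.ndarray   # (n,) tonne*mm^2 (isotropic lumped)

    @property
    def n_nodes(self) -> int:
        return self.rest_positions.shape[0]

    @property
    def n_elements(self) -> int:
        return self.n_nodes - 1

    @property
    def n_dofs(self) -> int:
        return 6 * self.n_nodes

    def total_mass(self) -> float:
        return float(self.node_mass.sum())


@dataclass(frozen=True)
class CatheterState:
    """Positions, orientation quaternions (scalar-last), 6-DOF velocities."""

    positions: np.ndarray      # (n, 3) mm
    quaternions: np.ndarray    # (n, 4) xyzw, unit
    velocities: np.ndarray     # (n, 6) [vx vy vz wx wy wz], mm/s and rad/s
    time: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        q = np.asarray(self.quaternions, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        n = p.shape[0]
        if p.shape != (n, 3) or q.shape != (n, 4) or v.shape != (n, 6):
            raise ValueError("inconsistent state array shapes")
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must be unit-norm within 1e-9")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "quaternions", q)
        object.__setattr__(self, "velocities", v)

    def rotations(self) -> np.ndarray:
        return Rotation.from_quat(self.quaternions).as_matrix()


def parallel_transport_frames(centerline: np.ndarray) -> np.ndarray:
    """Material frames along a polyline: x-axis = tangent, twist-free transport."""
    pts = np.asarray(centerline, dtype=float)
    tangents = np.diff(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n = pts.shape[0]
    frames = np.empty((n, 3, 3))
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0]) if abs(t0[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(ref, t0)
    e2 /= np.linalg.norm(e2)
    frames[0] = np.column_stack([t0, e2, np.cross(t0, e2)])
    node_tangents = np.empty((n, 3))
    node_tangents[0] = tangents[0]
    node_tangents[-1] = tangents[-1]
    for i in range(1, n - 1):
        t = tangents[i - 1] + tangents[i]
        node_tangents[i] = t / np.linalg.norm(t)
    for i in range(1, n):
        frames[i] = _align_x(frames[i - 1], node_tangents[i])
    return frames


def _align_x(frame: np.ndarray, new_x: np.ndarray) -> np.ndarray:
    """Minimal rotation of ``frame`` taking its x-axis onto ``new_x`` (unit)."""
    t1 = frame[:, 0]
    c = float(np.clip(np.dot(t1, new_x), -1.0, 1.0))
    v = np.cross(t1, new_x)
    s = np.linalg.norm(v)
    if s < 1e-14:
        if c > 0:
            return frame
        # Antipodal: rotate pi about any axis orthogonal to t1.
        axis = frame[:, 1]
        return Rotation.from_rotvec(np.pi * axis).as_matrix() @ frame
    axis = v / s
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * axis).as_matrix() @ frame


def build_catheter(config: BeamConfig) -> BeamAssembly:
    """Discretize the catheter into uniform two-node beam elements.

    Section properties come from the circular (solid or hollow) cross-section;
    total mass equals density * area * total_length exactly under the lumping.
    """
    n = config.n_nodes
    if config.rest_centerline is None:
        s = np.linspace(0.0, config.total_length, n)
        centerline = np.column_stack([s, np.zeros(n), np.zeros(n)])
    else:
        centerline = config.rest_centerline
    rest_lengths = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    if np.any(rest_lengths <= 0):
        raise BeamConfigError("rest_centerline contains coincident nodes")

    ro = config.outer_diameter / 2.0
    ri = config.inner_diameter / 2.0
    area = np.pi * (ro**2 - ri**2)
    inertia = np.pi * (ro**4 - ri**4) / 4.0  # about a diameter; = pi d^4/64 when solid
    polar = 2.0 * inertia

    frames = parallel_transport_frames(centerline)
    elem_frames = np.empty((n - 1, 3, 3))
    for e in range(n - 1):
        t = centerline[e + 1] - centerline[e]
        elem_frames[e] = _align_x(frames[e], t / np.linalg.norm(t))

    node_mass = np.zeros(n)
    node_rot = np.zeros(n)
    for e, le in enumerate(rest_lengths):
        half = config.density * area * le / 2.0
        node_mass[e] += half
        node_mass[e + 1] += half
        # Lumped isotropic rotary inertia: torsional term plus a consistent-ish
        # bending term A*L^2/12 to keep rotational DOFs well-conditioned.
        rot = config.density * le / 2.0 * (polar + area * le**2 / 12.0)
        node_rot[e] += rot
        node_rot[e + 1] += rot

    return BeamAssembly(config=config, rest_positions=centerline,
                        rest_frames=frames, element_frames0=elem_frames,
                        rest_lengths=rest_lengths, area=float(area),
                        inertia=float(inertia), polar_inertia=float(polar),
                        node_mass=node_mass, node_rot_inertia=node_rot)


def initial_state(assembly: BeamAssembly) -> CatheterState:
    """Rest state: nodes on the rest centerline, zero velocity."""
    q = Rotation.from_matrix(assembly.rest_frames).as_quat()
    return CatheterState(positions=assembly.rest_positions.copy(),
                         quaternions=q,
                         velocities=np.zeros((assembly.n_nodes, 6)),
                         time=0.0)


# ---------------------------------------------------------------------------
# Element matrices (local frame)
# ---------------------------------------------------------------------------

def element_matrices(assembly: BeamAssembly, element_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Local 12x12 (stiffness, lumped mass) for one element.

    DOF order per node: [ux uy uz, tx ty tz] with the local x-axis along the
    element.  The stiffness is the shear-deformable (Timoshenko) beam matrix;
    it is symmetric PSD with exactly the six rigid-body zero modes, and its
    axial diagonal entry is E*A/L.  The mass matrix is diagonal (lumped) and
    positive definite.
    """
    cfg = assembly.config
    le = float(assembly.rest_lengths[element_index])
    e_mod = cfg.young_modulus
    g_mod = e_mod / (2.0 * (1.0 + cfg.poisson_ratio))
    a, iy, jp = assembly.area, assembly.inertia, assembly.polar_inertia
    kappa = 6.0 * (1.0 + cfg.poisson_ratio) / (7.0 + 6.0 * cfg.poisson_ratio)
    phi = 12.0 * e_mod * iy / (kappa * g_mod * a * le**2)

    k = np.zeros((12, 12))
    ax = e_mod * a / le
    k[0, 0] = k[6, 6] = ax
    k[0, 6] = -ax
    tr = g_mod * jp / le
    k[3, 3] = k[9, 9] = tr
    k[3, 9] = -tr
    c = e_mod * iy / (le**3 * (1.0 + phi))
    k1, k2 = 12.0 * c, 6.0 * c * le
    k3, k4 = (4.0 + phi) * c * le**2, (2.0 - phi) * c * le**2
    # bending in the x-y plane (deflection uy, rotation tz)
    k[1, 1] = k[7, 7] = k1
    k[1, 7] = -k1
    k[1, 5] = k[1, 11] = k2
    k[5, 7] = k[7, 11] = -k2
    k[5, 5] = k[11, 11] = k3
    k[5, 11] = k4
    # bending in the x-z plane (deflection uz, rotation ty; opposite signs)
    k[2, 2] = k[8, 8] = k1
    k[2, 8] = -k1
    k[2, 4] = k[2, 10] = -k2
    k[4, 8] = k[8, 10] = k2
    k[4, 4] = k[10, 10] = k3
    k[4, 10] = k4
    k = np.triu(k) + np.triu(k, 1).T

    half_m = cfg.density * a * le / 2.0
    half_i = cfg.density * le / 2.0 * (jp + a * le**2 / 12.0)
    m = np.diag([half_m] * 3 + [half_i] * 3 + [half_m] * 3 + [half_i] * 3)
    return k, m


# ---------------------------------------------------------------------------
# Corotational internal forces
# ---------------------------------------------------------------------------

def _element_kinematics(assembly: BeamAssembly, positions: np.ndarray,
                        rotations: np.ndarray, e: int):
    """Current element frame and the local 12-DOF deformation vector."""
    a, b = e, e + 1
    dx = positions[b] - positions[a]
    ln = float(np.linalg.norm(dx))
    if ln < 1e-12:
        raise StepError(f"element {e} collapsed to zero length")
    e1 = dx / ln
    t0 = assembly.element_frames0[e]
    sa = rotations[a] @ assembly.rest_frames[a].T
    sb = rotations[b] @ assembly.rest_frames[b].T
    # mid relative rotation: sa * exp(0.5 * log(sa^T sb))
    rel = Rotation.from_matrix(sa.T @ sb).as_rotvec()
    sm = sa @ Rotation.from_rotvec(0.5 * rel).as_matrix()
    t_frame = _align_x(sm @ t0, e1)
    theta_a = Rotation.from_matrix(t_frame.T @ sa @ t0).as_rotvec()
    theta_b = Rotation.from_matrix(t_frame.T @ sb @ t0).as_rotvec()
    d_local = np.zeros(12)
    d_local[3:6] = theta_a
    d_local[6] = ln - assembly.rest_lengths[e]
    d_local[9:12] = theta_b
    return t_frame, d_local


def internal_forces(assembly: BeamAssembly, positions: np.ndarray,
                    rotations: np.ndarray,
                    with_tangent: bool = True) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Corotational internal force vector (6n,) and approximate tangent (6n, 6n).

    Per element the local force is K_local @ d_local; it is mapped to the world
    by the block-diagonal element frame, and the tangent is the congruent
    rotation of K_local (symmetric PSD, which keeps the implicit solver SPD).
    """
    n = assembly.n_nodes
    f = np.zeros(6 * n)
    k_glob = np.zeros((6 * n, 6 * n)) if with_tangent else None
    for e in range(assembly.n_elements):
        k_local, _ = element_matrices(assembly, e)
        t_frame, d_local = _element_kinematics(assembly, positions, rotations, e)
        f_local = k_local @ d_local
        lam = np.zeros((12, 12))
        for blk in range(4):
            lam[3 * blk:3 * blk + 3, 3 * blk:3 * blk + 3] = t_frame
        f_world = lam @ f_local
        idx = np.r_[6 * e:6 * e + 6, 6 * (e + 1):6 * (e + 1) + 6]
        f[idx] += f_world
        if with_tangent:
            ke = lam @ k_local @ lam.T
            k_glob[np.ix_(idx, idx)] += ke
    return f, k_glob


def elastic_energy(assembly: BeamAssembly, positions: np.ndarray,
                   rotations: np.ndarray) -> float:
    """Total stored elastic energy, 0.5 * d_local' K_local d_local per element."""
    total = 0.0
    for e in range(assembly.n_elements):
        k_local, _ = element_matrices(assembly, e)
        _, d_local = _element_kinematics(assembly, positions, rotations, e)
        total += 0.5 * float(d_local @ k_local @ d_local)
    return total


def kinetic_energy(assembly: BeamAssembly, state: CatheterState) -> float:
    v = state.velocities
    lin = 0.5 * float(np.sum(assembly.node_mass * np.sum(v[:, :3]**2, axis=1)))
    rot = 0.5 * float(np.sum(assembly.node_rot_inertia * np.sum(v[:, 3:]**2, axis=1)))
    return lin + rot


# ---------------------------------------------------------------------------
# Constraints and drivers
# ---------------------------------------------------------------------------

def drive_insertion(t: float, speed: float, axis: np.ndarray) -> np.ndarray:
    """Prescribed base displacement at time t for a constant-speed insertion."""
    if speed < 0:
        raise ValueError("insertion speed must be >= 0")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    return speed * t * ax


@dataclass(frozen=True)
class InsertionDriver:
    """Clamps the base node and advances it at constant speed along an axis.

    Realizes the boundary-condition term of the equation of motion: the base
    node's position is constrained to start + speed*t*axis and its orientation
    to the rest orientation (a moving clamp).
    """

    speed: float = 0.0                # mm/s
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    node: int = 0
    start_position: Optional[np.ndarray] = None  # defaults to rest position
    start_rotation: Optional[np.ndarray] = None  # defaults to rest frame

    def prescribed_velocity(self, assembly: BeamAssembly, state: CatheterState,
                            dt: float) -> tuple[np.ndarray, np.ndarray]:
        """(dof indices, velocity values) realizing the clamp over [t, t+dt]."""
        start_p = (self.start_position if self.start_position is not None
                   else assembly.rest_positions[self.node])
        start_r = (self.start_rotation if self.start_rotation is not None
                   else assembly.rest_frames[self.node])
        ax = np.asarray(self.axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        target = start_p + self.speed * (state.time + dt) * ax
        v_lin = (target - state.positions[self.node]) / dt
        r_cur = Rotation.from_quat(state.quaternions[self.node]).as_matrix()
        v_ang = Rotation.from_matrix(start_r @ r_cur.T).as_rotvec() / dt
        base = 6 * self.node
        idx = np.arange(base, base + 6)
        return idx, np.concatenate([v_lin, v_ang])


def apply_prescribed(a_mat: np.ndarray, b_vec: np.ndarray,
                     idx: np.ndarray, values: np.ndarray) -> None:
    """Symmetric elimination of prescribed velocity DOFs (in place)."""
    b_vec -= a_mat[:, idx] @ values
    a_mat[idx, :] = 0.0
    a_mat[:, idx] = 0.0
    a_mat[idx, idx] = 1.0
    b_vec[idx] = values


# ---------------------------------------------------------------------------
# Implicit time stepping
# ---------------------------------------------------------------------------

def mass_matrix_diagonal(assembly: BeamAssembly) -> np.ndarray:
    diag = np.empty(assembly.n_dofs)
    for i in range(assembly.n_nodes):
        diag[6 * i:6 * i + 3] = assembly.node_mass[i]
        diag[6 * i + 3:6 * i + 6] = assembly.node_rot_inertia[i]
    return diag


def implicit_system(assembly: BeamAssembly, state: CatheterState, dt: float,
                    external_forces: Optional[np.ndarray] = None,
                    include_stiffness: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Backward-Euler velocity system (A, b) with A v_next = b.

    A = M + dt*C + dt^2*K and b = M v + dt*(F_ext - f_int), with Rayleigh
    damping C = alpha*M + beta*K and one linearization of the internal force.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = assembly.config
    m_diag = mass_matrix_diagonal(assembly)
    if include_stiffness:
        f_int, k_mat = internal_forces(assembly, state.positions, state.rotations())
    else:
        f_int = np.zeros(assembly.n_dofs)
        k_mat = np.zeros((assembly.n_dofs, assembly.n_dofs))
    f_ext = np.zeros(assembly.n_dofs)
    if external_forces is not None:
        f_ext += np.asarray(external_forces, dtype=float).reshape(-1)
    if cfg.gravity:
        for i in range(assembly.n_nodes):
            f_ext[6 * i + 2] -= assembly.node_mass[i] * GRAVITY_MM_S2
    a_mat = (dt**2) * k_mat + (1.0 + dt * cfg.rayleigh_alpha) * np.diag(m_diag) \
        + dt * cfg.rayleigh_beta * k_mat
    v = state.velocities.reshape(-1)
    b_vec = m_diag * v + dt * (f_ext - f_int)
    return a_mat, b_vec


def advance_state(assembly: BeamAssembly, state: CatheterState, dt: float,
                  v_next: np.ndarray) -> CatheterState:
    """Integrate positions/orientations with the solved velocities."""
    if not np.all(np.isfinite(v_next)):
        raise StepError("non-finite velocities after implicit solve")
    v = v_next.reshape(assembly.n_nodes, 6)
    pos = state.positions + dt * v[:, :3]
    dq = Rotation.from_rotvec(dt * v[:, 3:])
    q_new = (dq * Rotation.from_quat(state.quaternions)).as_quat()
    q_new /= np.linalg.norm(q_new, axis=1, keepdims=True)
    if not np.all(np.isfinite(pos)):
        raise StepError("non-finite positions after implicit step")
    return CatheterState(positions=pos, quaternions=q_new, velocities=v,
                         time=state.time + dt)


def step_dynamics(assembly: BeamAssembly, state: CatheterState, dt: float,
                  external_forces: Optional[np.ndarray] = None,
                  constraints: Optional[Sequence] = None,
                  include_stiffness: bool = True,
                  contact_hook: Optional[Callable] = None) -> CatheterState:
    """Advance the catheter one implicit Euler step.

    ``constraints`` is a sequence of drivers exposing
    ``prescribed_velocity(assembly, state, dt) -> (dof_idx, values)``.
    ``contact_hook(a_mat, b_vec, v_free) -> v_next`` lets the contact solver
    correct the unconstrained solution (used by the scene runner).
    """
    a_mat, b_vec = implicit_system(assembly, state, dt, external_forces,
                                   include_stiffness=include_stiffness)
    for driver in constraints or ():
        idx, vals = driver.prescribed_velocity(assembly, state, dt)
        apply_prescribed(a_mat, b_vec, idx, vals)
    try:
        v_free = np.linalg.solve(a_mat, b_vec)
    except np.linalg.LinAlgError as exc:
        raise StepError(f"implicit solve failed: {exc}") from exc
    v_next = contact_hook(a_mat, b_vec, v_free) if contact_hook else v_free
    return advance_state(assembly, state, dt, v_next)


# ---------------------------------------------------------------------------
# Static solve (quasi-static equilibrium)
# ---------------------------------------------------------------------------

def static_solve(assembly: BeamAssembly, loads: np.ndarray,
                 fixed_nodes: Sequence[int] = (0,),
                 max_iter: int = 60, tol: float = 1e-8, xtol: float = 1e-10,
                 state: Optional[CatheterState] = None) -> CatheterState:
    """Newton iteration for the static equilibrium under nodal loads.

    ``loads`` is (n_nodes, 6) [forces, torques]; ``fixed_nodes`` are clamped
    (position and orientation).  Converges when the free-DOF force residual
    drops below ``tol`` relative to the load magnitude, or when the Newton
    increment falls below ``xtol`` mm (the force residual then sits at the
    rounding floor of the rotation extraction).
    """
    st = state if state is not None else initial_state(assembly)
    pos = st.positions.copy()
    rot = st.rotations().copy()
    f_ext = np.asarray(loads, dtype=float).reshape(-1)
    fixed = np.concatenate([np.arange(6 * i, 6 * i + 6) for i in fixed_nodes])
    free = np.setdiff1d(np.arange(assembly.n_dofs), fixed)
    scale = max(np.linalg.norm(f_ext), 1e-12)
    history = []
    for _ in range(max_iter):
        f_int, k_mat = internal_forces(assembly, pos, rot)
        resid = f_ext - f_int
        history.append(float(np.linalg.norm(resid[free])))
        if history[-1] <= tol * scale:
            break
        kff = k_mat[np.ix_(free, free)]
        # tiny regularization guards rigid modes if the clamp under-constrains
        kff[np.diag_indices_from(kff)] += 1e-12 * np.trace(kff) / kff.shape[0]
        du = np.linalg.solve(kff, resid[free])
        full = np.zeros(assembly.n_dofs)
        full[free] = du
        inc = full.reshape(assembly.n_nodes, 6)
        pos = pos + inc[:, :3]
        rot = np.einsum("nij,njk->nik",
                        Rotation.from_rotvec(inc[:, 3:]).as_matrix(), rot)
        if np.max(np.abs(du)) <= xtol:
            break
    else:
        raise StepError("static beam solve did not converge; residual history "
                        f"{['%.3e' % h for h in history[-5:]]}")
    q = Rotation.from_matrix(rot).as_quat()
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return CatheterState(positions=pos, quaternions=q,
                         velocities=np.zeros((assembly.n_nodes, 6)), time=st.time)
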