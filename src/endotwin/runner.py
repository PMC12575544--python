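"""Scene assembly and the two validation protocols.

A scene couples the catheter beam model, a vessel (rigid collision geometry or
a deformable tetrahedral wall), the contact parameters, and a constant-speed
insertion driver.  Each frame solves one implicit step: the beam (and, when
deformable, the vessel) velocity systems are assembled and factored, contacts
are detected at the current configuration, and a projected Gauss-Seidel on the
combined Delassus operator applies Signorini-Coulomb impulses that couple the
two blocks exactly (monolithic mode).  A staggered mode -- contacts resolved
against the catheter only, reactions fed to the vessel as external forces on
the next frame -- exists for debugging.

Protocols:

* :func:`run_insertion` -- constant-speed insertion (13 or 23 mm/s in the
  reference experiments) with tip-path, proximal-shape and contact-force logs
  emulating a 1 kHz load-cell channel downsampled to the output rate.
* :func:`run_static_deformation` -- static solves at a sequence of force
  magnitudes applied to landmark vertices (the "catheter presses on the iliac
  wall" scenario), reporting landmark displacements per force level.

All solvers are deterministic; the scene seed only feeds synthetic-data noise.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu

from . import beam, contact, fem, phantom
from .materials import ConstitutiveModel


class SceneError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scene configuration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "catheter": {
        "length_mm": 800.0,
        "diameter_mm": 1.32,
        "young_modulus_mpa": 6.0e5,
        "density_g_cm3": 1.55,
        "n_nodes": 50,
        "poisson_ratio": 0.3,
        "rayleigh_alpha": 0.1,
        "rayleigh_beta": 0.01,
        "precurve": None,  # {"tip_angle_deg": .., "tip_length_mm": ..}
    },
    "vessel": {
        "preset": "iliac_curve",
        "length_mm": 150.0,
        "lumen_radius_mm": 4.5,
        "wall_thickness_mm": 2.0,
        "n_rings": 30,
        "n_around": 16,
        "rigid": True,
        "material": {"kind": "elastic", "e": 0.46},
        "poisson_ratio": 0.45,
    },
    "contact": {
        "alarm_distance_mm": 2.0,
        "contact_distance_mm": 0.66,
        "mu": 0.62,
    },
    "driver": {
        "speed_mm_s": 13.0,
        "axis": [1.0, 0.0, 0.0],
    },
    "simulation": {
        "dt_s": 0.001,
        "duration_s": 2.0,
        "output_rate_hz": 100.0,
        "seed": 0,
        "coupling": "monolithic",
    },
}


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise SceneError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_strict(defaults[key], val, path + key + ".")
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class Scene:
    """Resolved scene: configuration dict plus built simulation objects."""

    config: dict
    assembly: beam.BeamAssembly
    catheter_state: beam.CatheterState
    contact_params: contact.ContactParams
    driver: beam.InsertionDriver
    vessel_spec: phantom.VesselSpec
    collision: contact.CollisionSurface
    vessel_model: Optional[fem.TetModel]  # None when rigid
    dt: float
    duration: float
    output_rate: float
    seed: int
    coupling: str = "monolithic"

    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def manifest(self) -> dict:
        import scipy
        from . import __version__
        return {"config": self.config, "config_hash": self.config_hash(),
                "endotwin_version": __version__,
                "numpy_version": np.__version__,
                "scipy_version": scipy.__version__}


def build_scene(config: Optional[dict] = None) -> Scene:
    """Resolve a (possibly partial) configuration dict into a ready scene.

    Unknown keys raise; every default is recorded in the resolved config so the
    run manifest carries full parameter provenance.  The catheter is positioned
    with its tip at the lumen entrance, pointing along the insertion axis.
    """
    cfg = _merge_strict(_DEFAULT_CONFIG, config or {})
    cat = cfg["catheter"]
    sim = cfg["simulation"]
    if sim["output_rate_hz"] > 1.0 / sim["dt_s"] + 1e-12:
        raise SceneError("output rate cannot exceed 1/dt")
    beam_cfg = beam.BeamConfig(
        total_length=cat["length_mm"], outer_diameter=cat["diameter_mm"],
        young_modulus=cat["young_modulus_mpa"],
        density=cat["density_g_cm3"] * 1e-9,   # g/cm^3 -> tonne/mm^3
        n_nodes=cat["n_nodes"], poisson_ratio=cat["poisson_ratio"],
        rayleigh_alpha=cat["rayleigh_alpha"], rayleigh_beta=cat["rayleigh_beta"])
    if cat["precurve"]:
        beam_cfg = phantom.make_precurved_catheter(
            cat["precurve"]["tip_angle_deg"], cat["precurve"]["tip_length_mm"],
            beam_cfg)
    assembly = beam.build_catheter(beam_cfg)

    ves = cfg["vessel"]
    spec = phantom.VesselSpec(preset=ves["preset"], length=ves["length_mm"],
                              lumen_radius=ves["lumen_radius_mm"],
                              wall_thickness=ves["wall_thickness_mm"],
                              n_rings=ves["n_rings"], n_around=ves["n_around"])
    material = ConstitutiveModel(ves["material"]["kind"],
                                 {k: v for k, v in ves["material"].items() if k != "kind"})
    vessel_model = None
    if not ves["rigid"]:
        _, vessel_model = phantom.make_tube_vessel(spec, material=material)
    collision = phantom.make_collision_surface(spec)

    con = cfg["contact"]
    params = contact.ContactParams(alarm_distance=con["alarm_distance_mm"],
                                   contact_distance=con["contact_distance_mm"],
                                   friction_coefficient=con["mu"])

    # place catheter behind the lumen entrance, tip at the entrance
    centerline = phantom.preset_centerline(spec)
    entry_tangent = centerline[1] - centerline[0]
    entry_tangent /= np.linalg.norm(entry_tangent)
    axis = np.asarray(cfg["driver"]["axis"], dtype=float)
    axis /= np.linalg.norm(axis)
    state0 = beam.initial_state(assembly)
    offset = centerline[0] - state0.positions[-1]
    state0 = beam.CatheterState(positions=state0.positions + offset,
                                quaternions=state0.quaternions,
                                velocities=state0.velocities, time=0.0)
    driver = beam.InsertionDriver(speed=cfg["driver"]["speed_mm_s"], axis=axis,
                                  node=0, start_position=state0.positions[0],
                                  start_rotation=assembly.rest_frames[0])
    return Scene(config=cfg, assembly=assembly, catheter_state=state0,
                 contact_params=params, driver=driver, vessel_spec=spec,
                 collision=collision, vessel_model=vessel_model,
                 dt=float(sim["dt_s"]), duration=float(sim["duration_s"]),
                 output_rate=float(sim["output_rate_hz"]),
                 seed=int(sim["seed"]), coupling=sim["coupling"])


def load_scene(path: str | Path) -> Scene:
    """Load a YAML or JSON scene configuration file (strict keys)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SceneError(f"{path}: expected a mapping at top level")
    return build_scene(data)


def dump_scene_config(scene: Scene, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scene.config, sort_keys=True))


# ---------------------------------------------------------------------------
# Insertion protocol
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Insertion outcome: trajectory, contact-force channel, diagnostics."""

    times: np.ndarray                  # (ns,) s, at the output rate
    tip_path: np.ndarray               # (ns, 3) mm
    node_paths: np.ndarray             # (ns, n_nodes, 3) mm
    catheter_force: np.ndarray         # (ns, 3) N, total contact force on catheter
    vessel_force: np.ndarray           # (ns, 3) N, total contact force on vessel
    contact_log: list                  # per-sample list of (node, tri, gap, fn, |ft|)
    solver_iterations: np.ndarray      # (ns,)
    solver_residuals: np.ndarray       # (ns,)
    final_state: beam.CatheterState
    final_vessel_displacement: Optional[np.ndarray]
    warnings: list = field(default_factory=list)

    def tip_polyline(self):
        from .metrics import Polyline3D
        return Polyline3D(self.tip_path, timestamps=self.times)

    def write_csv_logs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ns, nn = self.node_paths.shape[:2]
        with open(out / "trajectory.csv", "w") as fh:
            fh.write("time,node,x,y,z\n")
            for i in range(ns):
                for j in range(nn):
                    x, y, z = self.node_paths[i, j]
                    fh.write(f"{self.times[i]:.6f},{j},{x:.9g},{y:.9g},{z:.9g}\n")
        with open(out / "tip_path.csv", "w") as fh:
            fh.write("t,x,y,z\n")
            for i in range(ns):
                x, y, z = self.tip_path[i]
                fh.write(f"{self.times[i]:.6f},{x:.9g},{y:.9g},{z:.9g}\n")
        with open(out / "total_force.csv", "w") as fh:
            fh.write("time,Fx,Fy,Fz\n")
            for i in range(ns):
                fx, fy, fz = self.catheter_force[i]
                fh.write(f"{self.times[i]:.6f},{fx:.9g},{fy:.9g},{fz:.9g}\n")
        with open(out / "contacts.csv", "w") as fh:
            fh.write("time,node,triangle,gap_mm,fn_N,ft_N\n")
            for t, entries in zip(self.times, self.contact_log):
                for node, tri, gap, fn, ft in entries:
                    fh.write(f"{t:.6f},{node},{tri},{gap:.6g},{fn:.6g},{ft:.6g}\n")


def _barycentric(point: np.ndarray, tri: np.ndarray) -> np.ndarray:
    v0, v1 = tri[1] - tri[0], tri[2] - tri[0]
    v2 = point - tri[0]
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    den = d00 * d11 - d01 * d01
    w1 = (d11 * d20 - d01 * d21) / den
    w2 = (d00 * d21 - d01 * d20) / den
    return np.array([1.0 - w1 - w2, w1, w2])


def run_insertion(scene: Scene, log_contacts: bool = True) -> RunResult:
    """Step the coupled catheter-vessel system through the insertion.

    Deterministic for a fixed scene; solver failures raise
    :class:`endotwin.beam.StepError` carrying the failing step's diagnostics,
    and a catheter node escaping the lumen is recorded as a warning with the
    step index.
    """
    asm = scene.assembly
    st = scene.catheter_state
    dt = scene.dt
    n_steps = int(round(scene.duration / dt))
    every = max(1, int(round(1.0 / (scene.output_rate * dt))))
    n_beam = asm.n_dofs

    model = scene.vessel_model
    deformable = model is not None
    if deformable:
        u_f = np.zeros(model.n_dofs)
        v_f = np.zeros(model.n_dofs)
        fixed_dofs = (3 * model.fixed_vertex_ids[:, None] + np.arange(3)).ravel()
        staggered_reaction = np.zeros(model.n_dofs)
    surface = scene.collision

    times, tips, nodes_log, f_cat, f_ves = [], [], [], [], []
    contacts_log, iters_log, resid_log, warnings = [], [], [], []

    for step in range(n_steps):
        a_b, b_b = beam.implicit_system(asm, st, dt)
        idx, vals = scene.driver.prescribed_velocity(asm, st, dt)
        beam.apply_prescribed(a_b, b_b, idx, vals)
        cho = cho_factor(a_b)
        v_beam_free = cho_solve(cho, b_b)

        if deformable:
            if scene.coupling == "staggered":
                ext = staggered_reaction
            else:
                ext = None
            a_f, b_f = fem.implicit_system(model, u_f, v_f, dt, external=ext)
            # symmetric elimination of clamped vertices via projection
            from scipy import sparse as sp
            mask = np.ones(model.n_dofs)
            mask[fixed_dofs] = 0.0
            s_proj = sp.diags(mask)
            a_f = (s_proj @ a_f @ s_proj + sp.diags(1.0 - mask)).tocsc()
            b_f = mask * b_f
            lu_f = splu(a_f)
            v_fem_free = lu_f.solve(b_f)
            surface = scene.collision.with_vertices(
                (model.vertices + u_f.reshape(-1, 3)))
        else:
            v_fem_free = np.zeros(0)

        pairs = contact.detect_proximities(st.positions, surface,
                                           scene.contact_params)
        n_total = n_beam + (model.n_dofs if deformable else 0)
        v_free = np.concatenate([v_beam_free, v_fem_free])

        if pairs:
            jac = np.zeros((3 * len(pairs), n_total))
            jac[:, :n_beam] = contact.contact_jacobian_points(pairs, n_beam)
            couple_fem = deformable and scene.coupling == "monolithic"
            if couple_fem:
                for k, p in enumerate(pairs):
                    tri_ids = surface.faces[p.triangle_id]
                    bary = _barycentric(p.closest_point,
                                        surface.vertices[tri_ids])
                    basis = contact.tangent_basis(p.normal)
                    for w, vid in zip(bary, tri_ids):
                        col = n_beam + 3 * vid
                        jac[3 * k, col:col + 3] -= w * p.normal
                        jac[3 * k + 1, col:col + 3] -= w * basis[0]
                        jac[3 * k + 2, col:col + 3] -= w * basis[1]
                # prescribed/fixed DOFs cannot move: zero their columns
                jac[:, n_beam + fixed_dofs] = 0.0
            jac[:, idx] = 0.0  # driver-clamped beam DOFs

            def block_solve(rhs):
                rhs = np.atleast_2d(rhs.T).T
                top = cho_solve(cho, rhs[:n_beam])
                if deformable:
                    bot = np.column_stack([lu_f.solve(rhs[n_beam:, k])
                                           for k in range(rhs.shape[1])])
                    return np.vstack([top, bot])
                return top

            res = contact.resolve_contacts(pairs, jac, block_solve, v_free,
                                           scene.contact_params, dt)
            v_next = res.v_next
            iters_log.append(res.iterations)
            resid_log.append(res.residual)
            if not res.converged:
                warnings.append(f"step {step}: contact solver residual "
                                f"{res.residual:.2e} after {res.iterations} sweeps")
            total = np.zeros(3)
            entries = []
            for cf in res.forces:
                total += cf.force_vector()
                entries.append((cf.pair.point_id, cf.pair.triangle_id,
                                cf.pair.gap, cf.normal_force,
                                float(np.linalg.norm(cf.tangential_force))))
            if deformable and scene.coupling == "staggered":
                staggered_reaction = np.zeros(model.n_dofs)
                for cf in res.forces:
                    tri_ids = surface.faces[cf.pair.triangle_id]
                    bary = _barycentric(cf.pair.closest_point,
                                        surface.vertices[tri_ids])
                    fv = -cf.force_vector()
                    for w, vid in zip(bary, tri_ids):
                        staggered_reaction[3 * vid:3 * vid + 3] += w * fv
        else:
            v_next = v_free
            iters_log.append(0)
            resid_log.append(0.0)
            total = np.zeros(3)
            entries = []

        st = beam.advance_state(asm, st, dt, v_next[:n_beam])
        if deformable:
            v_f = v_next[n_beam:]
            v_f[fixed_dofs] = 0.0
            u_f = u_f + dt * v_f

        # escape check: any node past the entrance should stay near the lumen
        inserted = st.positions[:, 0] > surface.vertices[:, 0].min() - 1e-9
        if pairs:
            worst = min(p.gap for p in pairs)
            if worst < -(scene.contact_params.contact_distance):
                warnings.append(f"step {step}: penetration {worst:.3f} mm "
                                "(catheter may be escaping the lumen)")

        if (step + 1) % every == 0:
            times.append(st.time)
            tips.append(st.positions[-1].copy())
            nodes_log.append(st.positions.copy())
            f_cat.append(total.copy())
            f_ves.append(-total.copy())
            contacts_log.append(entries if log_contacts else [])

    return RunResult(times=np.asarray(times), tip_path=np.asarray(tips),
                     node_paths=np.asarray(nodes_log),
                     catheter_force=np.asarray(f_cat),
                     vessel_force=np.asarray(f_ves),
                     contact_log=contacts_log,
                     solver_iterations=np.asarray(iters_log),
                     solver_residuals=np.asarray(resid_log),
                     final_state=st,
                     final_vessel_displacement=(u_f.reshape(-1, 3).copy()
                                                if deformable else None),
                     warnings=warnings)


# ---------------------------------------------------------------------------
# Static deformation protocol
# ---------------------------------------------------------------------------

def run_static_deformation(scene_or_model, force_magnitudes: Sequence[float],
                           direction: np.ndarray,
                           landmark_ids: Sequence[int],
                           pure_linear: bool = False) -> list[fem.DeformationReport]:
    """One static solve per force level, measuring landmark displacements.

    Each magnitude is distributed evenly over the landmark vertices along
    ``direction`` (the catheter pressing the inner iliac wall), as a constant
    force field.  Accepts a Scene with a deformable vessel or a TetModel.
    """
    if isinstance(scene_or_model, Scene):
        model = scene_or_model.vessel_model
        if model is None:
            raise SceneError("static deformation needs a deformable vessel")
    else:
        model = scene_or_model
    if pure_linear and model.material.kind == "elastic":
        from dataclasses import replace
        model = replace(model, corotational=False)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    lm = np.asarray(landmark_ids, dtype=int)
    if lm.size == 0:
        raise SceneError("need at least one landmark vertex")
    reports = []
    for mag in force_magnitudes:
        field_ = fem.ConstantForceField(lm, mag / lm.size * direction)
        reports.append(fem.static_solve(model, field_, landmark_ids=lm))
    return reports
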