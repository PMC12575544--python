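"""Synthetic fixture generation: parametric vessel lumens, pre-curved catheter
rest shapes, and noisy tensile curves.

No imaging data ships with the package; instead this module builds stand-ins
that match the quantified properties of the physical phantom: a swept-tube
lumen at the aorto-iliac calibre (iliac lumen about 8-10 mm in diameter), a
wall of the tensile sample's 2 mm thickness, a surface budget near 477
vertices / 1000 faces, six fiducial bead coordinates outside the lumen, and
uniaxial tensile curves drawn from a chosen ground-truth constitutive model
with seeded Gaussian noise.  Everything is deterministic for a fixed spec and
seed.

The aorto-iliac preset is a single curved aorta-to-left-iliac swept tube with
a varying radius (and optional aneurysm bulge) rather than a Y junction: the
insertion path from the left iliac to the distal aorta is one continuous
lumen, which is the only part the simulated protocols touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import trimesh

from .beam import BeamConfig, parallel_transport_frames
from .fem import TetModel, boundary_faces, build_tet_model, default_bulk_penalty
from .materials import ConstitutiveModel, StressStrainCurve, uniaxial_stress


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselSpec:
    """Parametric lumen description.

    ``preset`` is one of ``straight_tube``, ``iliac_curve``, ``aortoiliac``;
    alternatively give an explicit centerline.  The default radius (4.5 mm)
    puts the lumen diameter at 9 mm, and wall thickness 2 mm matches the
    phantom wall sample.  ``n_rings``/``n_around`` default to the reference
    surface budget (about 477 vertices / 1000 faces).
    """

    preset: str = "straight_tube"
    centerline: Optional[np.ndarray] = None
    length: float = 150.0               # mm, used by presets
    lumen_radius: float = 4.5           # mm (constant part of the profile)
    wall_thickness: float = 2.0         # mm
    n_rings: int = 30
    n_around: int = 16
    aneurysm_center: Optional[float] = None   # fractional arclength in (0, 1)
    aneurysm_amplitude: float = 0.0           # mm added to the radius
    aneurysm_width: float = 0.15              # fractional arclength std
    catheter_radius: float = 0.66             # mm, for the clearance invariant

    def __post_init__(self):
        if self.lumen_radius <= self.catheter_radius:
            raise PhantomError("lumen radius must exceed the catheter radius")
        if self.wall_thickness <= 0:
            raise PhantomError("wall thickness must be positive")
        if self.n_rings < 2 or self.n_around < 3:
            raise PhantomError("budget below a minimal closed tube")


@dataclass(frozen=True)
class TensileSpec:
    """Synthetic uniaxial tensile protocol.

    The stretch range default [1, 6.5] covers rupture near 550% strain with
    margin; noise sigma defaults to 0.04 MPa, the best-fit residual scale of
    the reference material characterization.
    """

    model: ConstitutiveModel = field(
        default_factory=lambda: ConstitutiveModel("ogden", {"mu": [0.20], "alpha": [1.4]}))
    stretch_max: float = 6.5
    n_samples: int = 200
    noise_sigma: float = 0.04   # MPa
    seed: int = 0

    def __post_init__(self):
        if self.stretch_max <= 1:
            raise PhantomError("stretch_max must exceed 1")
        if self.noise_sigma < 0:
            raise PhantomError("noise sigma must be >= 0")


# ---------------------------------------------------------------------------
# Centerline presets
# ---------------------------------------------------------------------------

def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, points[:, k]) for k in range(3)])


def preset_centerline(spec: VesselSpec) -> np.ndarray:
    """Centerline polyline for a named preset, resampled at the ring stations."""
    if spec.centerline is not None:
        return _resample_polyline(np.asarray(spec.centerline, dtype=float), spec.n_rings)
    if spec.preset == "straight_tube":
        s = np.linspace(0.0, spec.length, spec.n_rings)
        return np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
    if spec.preset == "iliac_curve":
        # planar arc sweeping 60 degrees over the requested length
        phi_max = np.pi / 3.0
        radius = spec.length / phi_max
        phi = np.linspace(0.0, phi_max, 4 * spec.n_rings)
        pts = np.column_stack([radius * np.sin(phi),
                               radius * (1.0 - np.cos(phi)),
                               np.zeros_like(phi)])
        return _resample_polyline(pts, spec.n_rings)
    if spec.preset == "aortoiliac":
        # left iliac rising into the distal abdominal aorta: an S-ish planar
        # path, iliac segment first (entrance at s=0)
        t = np.linspace(0.0, 1.0, 6 * spec.n_rings)
        x = spec.length * t
        y = 0.25 * spec.length * (1.0 - np.cos(np.pi * t)) / 2.0
        pts = np.column_stack([x, y, np.zeros_like(x)])
        return _resample_polyline(pts, spec.n_rings)
    raise PhantomError(f"unknown vessel preset {spec.preset!r}")


def radius_profile(spec: VesselSpec, n: Optional[int] = None) -> np.ndarray:
    """Lumen radius at each ring station, with the optional aneurysm bulge."""
    n = n or spec.n_rings
    s = np.linspace(0.0, 1.0, n)
    r = np.full(n, spec.lumen_radius)
    if spec.preset == "aortoiliac":
        # taper from iliac calibre up to a wider distal aorta over the last third
        r = r + np.clip((s - 0.66) / 0.34, 0.0, 1.0) * 0.6 * spec.lumen_radius
    if spec.aneurysm_center is not None and spec.aneurysm_amplitude > 0:
        r = r + spec.aneurysm_amplitude * np.exp(
            -0.5 * ((s - spec.aneurysm_center) / spec.aneurysm_width) ** 2)
    return r


# ---------------------------------------------------------------------------
# Swept tube surface + extruded wall tets
# ---------------------------------------------------------------------------

def _sweep_rings(centerline: np.ndarray, radii: np.ndarray, n_around: int,
                 offset: float = 0.0) -> np.ndarray:
    frames = parallel_transport_frames(centerline)
    ang = 2.0 * np.pi * np.arange(n_around) / n_around
    circ = np.column_stack([np.cos(ang), np.sin(ang)])
    rings = np.empty((centerline.shape[0], n_around, 3))
    for i, (c, fr, r) in enumerate(zip(centerline, frames, radii)):
        rings[i] = c + (r + offset) * (circ @ np.vstack([fr[:, 1], fr[:, 2]]))
    return rings


def _side_faces(n_rings: int, n_around: int) -> np.ndarray:
    """Quad-split triangles over the swept side surface (outward orientation)."""
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_around):
            a = i * n_around + j
            b = i * n_around + (j + 1) % n_around
            c = (i + 1) * n_around + j
            d = (i + 1) * n_around + (j + 1) % n_around
            faces.append([a, b, d])
            faces.append([a, d, c])
    return np.asarray(faces, dtype=int)


def make_lumen_surface(spec: VesselSpec) -> trimesh.Trimesh:
    """Watertight swept lumen surface: ring vertices plus two cap apexes."""
    centerline = preset_centerline(spec)
    radii = radius_profile(spec)
    rings = _sweep_rings(centerline, radii, spec.n_around)
    n_ring_verts = spec.n_rings * spec.n_around
    verts = np.vstack([rings.reshape(-1, 3), centerline[0], centerline[-1]])
    faces = list(_side_faces(spec.n_rings, spec.n_around))
    apex0, apex1 = n_ring_verts, n_ring_verts + 1
    na = spec.n_around
    for j in range(na):
        faces.append([apex0, (j + 1) % na, j])                      # start cap
        faces.append([apex1, (spec.n_rings - 1) * na + j,
                      (spec.n_rings - 1) * na + (j + 1) % na])      # end cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if not mesh.is_watertight:
        raise PhantomError("generated lumen surface is not watertight")
    if not mesh.is_winding_consistent:
        raise PhantomError("inconsistent winding in generated lumen surface")
    return mesh


def _prism_tets(bottom: Sequence[int], top: Sequence[int]) -> list[list[int]]:
    """Split the prism (bottom triangle, matching top triangle) into 3 tets
    with globally consistent diagonals (smallest-index rule), so adjacent
    prisms share conforming faces."""
    v = list(bottom) + list(top)
    # rotations that keep the prism intact, bringing each vertex to slot 0
    perms = [(0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
             (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0)]
    best = min(perms, key=lambda p: v[p[0]])
    w = [v[i] for i in best]
    if min(w[1], w[5]) < min(w[2], w[4]):
        tets = [[w[0], w[1], w[2], w[5]], [w[0], w[1], w[5], w[4]],
                [w[0], w[4], w[5], w[3]]]
    else:
        tets = [[w[0], w[1], w[2], w[4]], [w[0], w[4], w[2], w[5]],
                [w[0], w[4], w[5], w[3]]]
    return tets


def make_tube_vessel(spec: VesselSpec,
                     material: Optional[ConstitutiveModel] = None,
                     fix_end_rings: bool = True) -> tuple[trimesh.Trimesh, TetModel]:
    """Swept lumen surface plus a tetrahedral wall model.

    The wall is the radial extrusion of the lumen side surface by
    ``wall_thickness``, each surface quad becoming a prism split into three
    conforming tets.  Inlet/outlet vertex rings are clamped by default
    (emulating the phantom's mounting).  Deterministic for a fixed spec.
    """
    if material is None:
        material = ConstitutiveModel("elastic", {"e": 0.46})
    surface = make_lumen_surface(spec)
    centerline = preset_centerline(spec)
    radii = radius_profile(spec)
    inner = _sweep_rings(centerline, radii, spec.n_around).reshape(-1, 3)
    outer = _sweep_rings(centerline, radii, spec.n_around,
                         offset=spec.wall_thickness).reshape(-1, 3)
    n_inner = inner.shape[0]
    verts = np.vstack([inner, outer])
    tets = []
    for tri in _side_faces(spec.n_rings, spec.n_around):
        tets.extend(_prism_tets(tri, [t + n_inner for t in tri]))
    fixed: list[int] = []
    if fix_end_rings:
        na = spec.n_around
        first = list(range(na)) + [n_inner + k for k in range(na)]
        last_start = (spec.n_rings - 1) * na
        last = ([last_start + k for k in range(na)]
                + [n_inner + last_start + k for k in range(na)])
        fixed = first + last
    model = build_tet_model(material, vertices=verts,
                            tets=np.asarray(tets, dtype=int),
                            fixed_vertex_ids=fixed,
                            bulk_penalty=(None if material.kind != "elastic" else 0.0))
    return surface, model


def make_aortoiliac_phantom(spec: Optional[VesselSpec] = None,
                            material: Optional[ConstitutiveModel] = None
                            ) -> tuple[trimesh.Trimesh, TetModel, np.ndarray, np.ndarray]:
    """Aorto-iliac phantom stand-in: lumen surface, wall TetModel, landmark
    vertex ids on the inner iliac wall, and six fiducial bead coordinates.

    Landmarks sit on the inner-curvature side of the iliac segment (the wall a
    catheter pushed against the inside of the bend would indent); beads sit on
    the corners of the phantom's bounding box, rigidly attached to the mesh
    frame.
    """
    if spec is None:
        spec = VesselSpec(preset="aortoiliac")
    if spec.preset not in ("aortoiliac", "iliac_curve"):
        raise PhantomError("phantom preset must be aortoiliac or iliac_curve")
    surface, model = make_tube_vessel(spec, material=material)
    # landmarks: inner-wall ring vertices near 40-60% arclength, on the side
    # toward the bend center (+y side of the local frame)
    na = spec.n_around
    lm = []
    for ring in range(int(0.4 * spec.n_rings), int(0.6 * spec.n_rings)):
        ring_ids = np.arange(ring * na, (ring + 1) * na)
        ring_pts = model.vertices[ring_ids]
        center = ring_pts.mean(axis=0)
        side = ring_pts[:, 1] - center[1]
        lm.append(int(ring_ids[np.argmax(side)]))
    landmarks = np.asarray(lm, dtype=int)
    lo, hi = surface.bounds
    lo = lo - 10.0
    hi = hi + 10.0
    beads = np.array([[lo[0], lo[1], lo[2]], [hi[0], lo[1], lo[2]],
                      [lo[0], hi[1], lo[2]], [hi[0], hi[1], lo[2]],
                      [lo[0], lo[1], hi[2]], [hi[0], hi[1], hi[2]]])
    return surface, model, landmarks, beads


def make_collision_surface(spec: VesselSpec, vertices: Optional[np.ndarray] = None):
    """Lumen *side* surface as a CollisionSurface with inward normals.

    End caps are excluded (the catheter enters through them); pass the current
    wall vertices of a deformed TetModel to track deformation.
    """
    from .contact import CollisionSurface
    if vertices is None:
        centerline = preset_centerline(spec)
        radii = radius_profile(spec)
        vertices = _sweep_rings(centerline, radii, spec.n_around).reshape(-1, 3)
    else:
        vertices = np.asarray(vertices, dtype=float)[:spec.n_rings * spec.n_around]
    faces = _side_faces(spec.n_rings, spec.n_around)[:, ::-1]  # flip: inward
    return CollisionSurface(vertices, faces)


# ---------------------------------------------------------------------------
# Pre-curved catheter
# ---------------------------------------------------------------------------

def make_precurved_catheter(tip_angle_deg: float, tip_length: float,
                            base_config: Optional[BeamConfig] = None) -> BeamConfig:
    """Catheter rest shape: straight shaft plus a circular-arc tip.

    The tip turns through ``tip_angle_deg`` over ``tip_length`` of arclength
    (arc radius = tip_length / angle); total arclength is preserved exactly.
    """
    cfg = base_config or BeamConfig()
    if not 0.0 <= tip_angle_deg <= 180.0:
        raise PhantomError("tip angle must lie in [0, 180] degrees")
    if tip_length >= cfg.total_length:
        raise PhantomError("tip length must be smaller than the catheter length")
    n = cfg.n_nodes
    s = np.linspace(0.0, cfg.total_length, n)
    angle = np.deg2rad(tip_angle_deg)
    shaft_len = cfg.total_length - tip_length
    pts = np.empty((n, 3))
    if angle < 1e-12:
        pts[:, 0] = s
        pts[:, 1:] = 0.0
    else:
        arc_r = tip_length / angle
        for i, si in enumerate(s):
            if si <= shaft_len:
                pts[i] = [si, 0.0, 0.0]
            else:
                phi = (si - shaft_len) / arc_r
                pts[i] = [shaft_len + arc_r * np.sin(phi),
                          arc_r * (1.0 - np.cos(phi)), 0.0]
    # chordal sampling shortens the arc slightly; rescale to preserve arclength
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    pts *= cfg.total_length / seg.sum()
    pts -= pts[0]
    from dataclasses import replace
    return replace(cfg, rest_centerline=pts)


# ---------------------------------------------------------------------------
# Synthetic tensile data
# ---------------------------------------------------------------------------

def synth_tensile_data(spec: TensileSpec) -> StressStrainCurve:
    """Uniaxial tensile curve from the ground-truth model plus seeded noise."""
    lam = np.linspace(1.0, spec.stretch_max, spec.n_samples)
    sigma = np.asarray(uniaxial_stress(spec.model, lam), dtype=float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = sigma + rng.normal(0.0, spec.noise_sigma, size=lam.shape)
    return StressStrainCurve(lam, sigma, provenance="synthetic")


# ---------------------------------------------------------------------------
# Structured box bar (oracle fixture for FEM checks)
# ---------------------------------------------------------------------------

def structured_bar(length: float = 20.0, width: float = 4.0,
                   nx: int = 6, ny: int = 2, nz: int = 2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bar meshed by Kuhn (6-tet) cube subdivision (conforming)."""
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, width, ny + 1)
    zs = np.linspace(0.0, width, nz + 1)
    shape = (nx + 1, ny + 1, nz + 1)
    verts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    def vid(i, j, k):
        return (i * shape[1] + j) * shape[2] + k
    kuhn = [(0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
            (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = [vid(i + a, j + b, k + c)
                          for a in (0, 1) for b in (0, 1) for c in (0, 1)]
                # corner order: bit pattern (a, b, c) -> index a*4 + b*2 + c
                for t in kuhn:
                    tets.append([corner[m] for m in t])
    return verts, np.asarray(tets, dtype=int)
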