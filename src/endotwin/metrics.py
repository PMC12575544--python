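"""Validation metrics for comparing simulated and reference catheter paths.

Contains the geometric machinery used to compare a simulated insertion with a
tracked one: rigid bead-based registration between the imaging frame and the
simulation frame (Kabsch), pointwise Euclidean tip error, discrete Frechet
distance between proximal-segment polylines, and least-squares Bezier
smoothing of noisy proximal points.  Lengths are millimetres throughout.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import comb


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise MetricError("rotation must be 3x3, translation length 3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise MetricError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise MetricError("rotation must have det +1 (no reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass(frozen=True)
class Polyline3D:
    """Ordered 3-D points, optionally time-stamped."""

    points: np.ndarray  # (n, 3)
    timestamps: Optional[np.ndarray] = None  # (n,), seconds

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise MetricError("polyline needs an (n>=2, 3) point array")
        if not np.all(np.isfinite(p)):
            raise MetricError("polyline contains non-finite coordinates")
        object.__setattr__(self, "points", p)
        if self.timestamps is not None:
            t = np.asarray(self.timestamps, dtype=float)
            if t.shape != (p.shape[0],) or np.any(np.diff(t) < 0):
                raise MetricError("timestamps must be per-point and non-decreasing")
            object.__setattr__(self, "timestamps", t)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Polyline3D":
        """Read a path CSV with header ``t,x,y,z``."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            rows = [(float(r["t"]), float(r["x"]), float(r["y"]), float(r["z"]))
                    for r in reader]
        arr = np.array(rows)
        return cls(arr[:, 1:4], timestamps=arr[:, 0])

    def arclength(self) -> np.ndarray:
        """Cumulative arclength at each point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def project_2d(self, drop_axis: int = 2) -> "Polyline3D":
        """AP-plane style projection: zero one coordinate (default z)."""
        p = self.points.copy()
        p[:, drop_axis] = 0.0
        return Polyline3D(p, timestamps=self.timestamps)


def load_beads_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a fiducial-bead CSV with header ``label,x,y,z``."""
    labels, pts = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for r in reader:
            labels.append(r["label"])
            pts.append([float(r["x"]), float(r["y"]), float(r["z"])])
    return labels, np.asarray(pts)


# ---------------------------------------------------------------------------
# Rigid registration (Kabsch)
# ---------------------------------------------------------------------------

def rigid_register(source: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping ``source`` beads onto ``target``.

    Correspondence is by index; needs >= 3 non-collinear pairs.  Returns the
    transform and the post-fit RMSD (mm).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise MetricError("bead sets must have matching shapes")
    if src.ndim != 2 or src.shape[1] != 3 or src.shape[0] < 3:
        raise MetricError("need >= 3 corresponding 3-D beads")
    sc = src - src.mean(axis=0)
    tc = tgt - tgt.mean(axis=0)
    h = sc.T @ tc
    u, s, vt = np.linalg.svd(h)
    # Collinear beads leave rotation about the line undetermined.
    if s[1] <= 1e-9 * max(s[0], 1e-30):
        raise MetricError("degenerate (collinear) bead configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tgt.mean(axis=0) - rot @ src.mean(axis=0)
    xf = RigidTransform(rot, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((xf.apply(src) - tgt) ** 2, axis=1))))
    return xf, rmsd


# ---------------------------------------------------------------------------
# Tip error
# ---------------------------------------------------------------------------

def _resample_by_arclength(path: Polyline3D, fractions: np.ndarray) -> np.ndarray:
    s = path.arclength()
    total = s[-1]
    if total <= 0:
        return np.repeat(path.points[:1], fractions.size, axis=0)
    target = fractions * total
    out = np.empty((fractions.size, 3))
    for k in range(3):
        out[:, k] = np.interp(target, s, path.points[:, k])
    return out


def tip_error(sim_path: Polyline3D, ref_path: Polyline3D,
              pairing: str = "auto") -> tuple[float, np.ndarray]:
    """Mean and per-sample Euclidean distance between two tip paths (mm).

    ``pairing``: ``by_time`` interpolates the reference at the simulated
    timestamps over the overlapping time range; ``by_arclength`` re-parametrizes
    both paths by normalized arclength; ``auto`` picks by_time when both carry
    timestamps.
    """
    if pairing == "auto":
        pairing = ("by_time" if sim_path.timestamps is not None
                   and ref_path.timestamps is not None else "by_arclength")
    if pairing == "by_time":
        if sim_path.timestamps is None or ref_path.timestamps is None:
            raise MetricError("by_time pairing requires timestamps on both paths")
        t0 = max(sim_path.timestamps[0], ref_path.timestamps[0])
        t1 = min(sim_path.timestamps[-1], ref_path.timestamps[-1])
        if t1 <= t0:
            raise MetricError("time ranges do not overlap")
        mask = (sim_path.timestamps >= t0) & (sim_path.timestamps <= t1)
        ts = sim_path.timestamps[mask]
        a = sim_path.points[mask]
        b = np.column_stack([np.interp(ts, ref_path.timestamps, ref_path.points[:, k])
                             for k in range(3)])
    elif pairing == "by_arclength":
        n = max(sim_path.points.shape[0], ref_path.points.shape[0])
        frac = np.linspace(0.0, 1.0, n)
        a = _resample_by_arclength(sim_path, frac)
        b = _resample_by_arclength(ref_path, frac)
    else:
        raise MetricError(f"unknown pairing {pairing!r}")
    dists = np.linalg.norm(a - b, axis=1)
    return float(dists.mean()), dists


# ---------------------------------------------------------------------------
# Discrete Frechet distance
# ---------------------------------------------------------------------------

def discrete_frechet(a: Polyline3D | np.ndarray, b: Polyline3D | np.ndarray) -> float:
    """Discrete Frechet distance between two sampled curves (mm).

    Minimal leash length over monotone couplings, computed by the standard
    O(n m) dynamic program; symmetric in its arguments.
    """
    pa = a.points if isinstance(a, Polyline3D) else np.asarray(a, dtype=float)
    pb = b.points if isinstance(b, Polyline3D) else np.asarray(b, dtype=float)
    if pa.size == 0 or pb.size == 0:
        raise MetricError("polylines must be non-empty")
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])


# ---------------------------------------------------------------------------
# Bezier smoothing
# ---------------------------------------------------------------------------

def _bernstein_matrix(ts: np.ndarray, degree: int) -> np.ndarray:
    i = np.arange(degree + 1)
    return (comb(degree, i)[None, :] * ts[:, None] ** i[None, :]
            * (1.0 - ts[:, None]) ** (degree - i)[None, :])


def _solve_clamped_controls(pts: np.ndarray, ts: np.ndarray,
                            degree: int) -> np.ndarray:
    basis = _bernstein_matrix(ts, degree)
    # Clamp endpoints: move their contribution to the RHS and solve for the
    # interior control points only.
    rhs = pts - np.outer(basis[:, 0], pts[0]) - np.outer(basis[:, -1], pts[-1])
    interior, *_ = np.linalg.lstsq(basis[:, 1:-1], rhs, rcond=None)
    return np.vstack([pts[0], interior, pts[-1]])


def fit_bezier(points: Polyline3D | np.ndarray, degree: int = 3,
               n_samples: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares Bezier fit of a noisy polyline, clamped at the endpoints.

    The curve interpolates the first and last input points.  Sample parameters
    start at chord-length values and are optimized jointly with the curve by
    variable projection (the interior control points are the exact linear
    least-squares solution at each parameter iterate), so points sampled
    exactly from a Bezier curve recover its control points.  Returns
    ``(control_points, resampled_curve)`` with the curve evaluated at
    ``n_samples`` uniform parameters.
    """
    from scipy.optimize import least_squares
    pts = points.points if isinstance(points, Polyline3D) else np.asarray(points, dtype=float)
    n = pts.shape[0]
    if degree < 2:
        raise MetricError("degree must be >= 2")
    if n <= degree:
        raise MetricError(f"need more points ({n}) than the degree ({degree})")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    ts0 = s / s[-1] if s[-1] > 0 else np.linspace(0, 1, n)

    def residuals(interior_ts):
        ts = np.concatenate([[0.0], interior_ts, [1.0]])
        control = _solve_clamped_controls(pts, ts, degree)
        return (_bernstein_matrix(ts, degree) @ control - pts).ravel()

    sol = least_squares(residuals, ts0[1:-1], bounds=(0.0, 1.0),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ts = np.concatenate([[0.0], sol.x, [1.0]])
    control = _solve_clamped_controls(pts, ts, degree)
    tt = np.linspace(0.0, 1.0, n_samples)
    curve = _bernstein_matrix(tt, degree) @ control
    return control, curve


def metric_report(sim_path: Polyline3D, ref_path: Polyline3D,
                  registration_rmsd: float | None = None,
                  pairing: str = "auto",
                  path: str | Path | None = None) -> dict:
    """Bundle the comparison metrics into one JSON-serializable record."""
    mean_err, series = tip_error(sim_path, ref_path, pairing=pairing)
    report = {
        "mean_euclidean_tip_error_mm": mean_err,
        "per_sample_tip_error_mm": [float(v) for v in series],
        "frechet_distance_mm": discrete_frechet(sim_path, ref_path),
        "registration_rmsd_mm": (None if registration_rmsd is None
                                 else float(registration_rmsd)),
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
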