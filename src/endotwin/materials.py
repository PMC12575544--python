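"""Constitutive models for the vessel-wall material and their tensile-test fitting.

Four material laws are supported, all calibrated from uniaxial tension data on
the silicone phantom wall:

* ``elastic``        -- Hooke's law, sigma = E * eps with engineering strain
  eps = lambda - 1.
* ``neo_hookean``    -- one-coefficient incompressible hyperelastic law,
  W = C10 (I1 - 3); uniaxial stress sigma = 2 (lambda^2 - 1/lambda) mu with
  mu identified with C10.
* ``mooney_rivlin``  -- two-coefficient law, W = C10 (I1 - 3) + C01 (I2 - 3);
  uniaxial stress sigma = 2 (lambda^2 - 1/lambda)(C10 + C01/lambda).
* ``ogden``          -- principal-stretch law,
  W = sum_i 2 mu_i / alpha_i^2 (lambda1^alpha_i + lambda2^alpha_i
  + lambda3^alpha_i - 3); the uniaxial stress used for fitting is the
  single-term sigma = mu1 (lambda^alpha1 - lambda^(-alpha1/2)).

Note the Ogden uniaxial fitting formula is kept exactly as used for
coefficient identification and is *not* the lambda dW/dlambda of the Ogden
strain-energy density above (they differ by a 2/alpha factor); coefficients
fitted with one formula are only meaningful with that formula, so the two are
deliberately not reconciled.  See docs/methods.md.

Stresses are in MPa, stretches dimensionless.  The uniaxial path assumes
incompressibility: lambda2 = lambda3 = lambda1^(-1/2), hence I3 = 1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

HYPERELASTIC_KINDS = ("neo_hookean", "mooney_rivlin", "ogden")
KINDS = ("elastic",) + HYPERELASTIC_KINDS


class MaterialError(ValueError):
    """Invalid material definition or evaluation outside the model's domain."""


class FitError(RuntimeError):
    """Curve fitting failed (degenerate data or non-convergence)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstitutiveModel:
    """A material law with named coefficients.

    ``params`` keys by kind:
      elastic: ``e`` (MPa); neo_hookean: ``mu`` (MPa, alias ``c10``);
      mooney_rivlin: ``c10``, ``c01`` (MPa);
      ogden: ``mu`` and ``alpha`` as equal-length sequences (terms).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise MaterialError(f"unknown material kind {self.kind!r}")
        p = dict(self.params)
        if self.kind == "neo_hookean" and "mu" not in p and "c10" in p:
            p["mu"] = p.pop("c10")
            object.__setattr__(self, "params", p)
        required = {
            "elastic": {"e"},
            "neo_hookean": {"mu"},
            "mooney_rivlin": {"c10", "c01"},
            "ogden": {"mu", "alpha"},
        }[self.kind]
        missing = required - set(self.params)
        if missing:
            raise MaterialError(f"{self.kind} model missing coefficients {sorted(missing)}")
        if self.kind == "ogden":
            mu = np.atleast_1d(np.asarray(self.params["mu"], dtype=float))
            alpha = np.atleast_1d(np.asarray(self.params["alpha"], dtype=float))
            if mu.shape != alpha.shape or mu.size < 1:
                raise MaterialError("ogden model needs >= 1 (mu, alpha) term pairs of equal length")

    def ogden_terms(self) -> tuple[np.ndarray, np.ndarray]:
        mu = np.atleast_1d(np.asarray(self.params["mu"], dtype=float))
        alpha = np.atleast_1d(np.asarray(self.params["alpha"], dtype=float))
        return mu, alpha

    def small_strain_shear_modulus(self) -> float:
        """Equivalent shear modulus in the infinitesimal-strain limit (MPa)."""
        if self.kind == "elastic":
            raise MaterialError("elastic model stores E, not a hyperelastic shear modulus")
        if self.kind == "neo_hookean":
            return 2.0 * self.params["mu"]
        if self.kind == "mooney_rivlin":
            return 2.0 * (self.params["c10"] + self.params["c01"])
        mu, _ = self.ogden_terms()
        return float(np.sum(mu))


@dataclass(frozen=True)
class StressStrainCurve:
    """Ordered uniaxial tensile samples (stretch lambda, stress sigma [MPa])."""

    stretch: np.ndarray
    stress: np.ndarray
    provenance: str = "synthetic"  # "measured" | "synthetic"

    def __post_init__(self):
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        if lam.ndim != 1 or lam.shape != sig.shape:
            raise ValueError("stretch and stress must be equal-length 1-D arrays")
        if lam.size < 2:
            raise ValueError("need at least 2 samples")
        if np.any(lam < 1.0 - 1e-12):
            raise ValueError("tensile data requires stretch >= 1")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("stretch must be strictly increasing")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", sig)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "measured") -> "StressStrainCurve":
        """Read a tensile curve from a CSV with header ``stretch,stress_mpa``."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {"stretch", "stress_mpa"} - set(reader.fieldnames):
                raise ValueError(f"{path}: expected header 'stretch,stress_mpa'")
            rows = [(float(r["stretch"]), float(r["stress_mpa"])) for r in reader]
        lam, sig = zip(*rows)
        return cls(np.array(lam), np.array(sig), provenance=provenance)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["stretch", "stress_mpa"])
            writer.writerows(zip(self.stretch, self.stress))


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of one constitutive model to a tensile curve."""

    model: ConstitutiveModel
    r_square: float
    rmse: float
    confidence_intervals: dict  # coefficient name -> (low, high), 95%
    n_samples: int

    def coefficient_in_ci(self, name: str, value: float) -> bool:
        lo, hi = self.confidence_intervals[name]
        return lo <= value <= hi

    def to_json(self, path: str | Path | None = None) -> str:
        record = {
            "model": self.model.kind,
            "formula": _FORMULAS[self.model.kind],
            "coefficients": {k: (list(np.atleast_1d(v).astype(float))
                                 if np.ndim(v) else float(v))
                             for k, v in self.model.params.items()},
            "confidence_intervals_95": {k: [float(lo), float(hi)]
                                        for k, (lo, hi) in self.confidence_intervals.items()},
            "r_square": float(self.r_square),
            "rmse_mpa": float(self.rmse),
            "n_samples": int(self.n_samples),
        }
        text = json.dumps(record, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


_FORMULAS = {
    "elastic": "sigma = E*(lambda-1)",
    "neo_hookean": "sigma = 2*(lambda^2 - 1/lambda)*mu",
    "mooney_rivlin": "sigma = 2*(lambda^2 - 1/lambda)*(C10 + C01/lambda)",
    "ogden": "sigma = mu1*(lambda^alpha1 - lambda^(-alpha1/2))",
}


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def invariants(stretches: Sequence[float]) -> tuple[float, float, float]:
    """Invariants (I1, I2, I3) of the Green deformation tensor from principal
    stretches (lambda1, lambda2, lambda3).

    I1 = sum lambda_i^2, I2 = sum over pairs lambda_i^2 lambda_j^2,
    I3 = prod lambda_i^2.
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,):
        raise MaterialError("expected three principal stretches")
    if np.any(lam <= 0):
        raise MaterialError("principal stretches must be strictly positive")
    l2 = lam**2
    i1 = float(l2.sum())
    i2 = float(l2[0] * l2[1] + l2[1] * l2[2] + l2[2] * l2[0])
    i3 = float(l2.prod())
    return i1, i2, i3


def uniaxial_stretch_triple(lam: float) -> tuple[float, float, float]:
    """Incompressible uniaxial stretch state: (lam, lam^-1/2, lam^-1/2)."""
    if lam <= 0:
        raise MaterialError("stretch must be strictly positive")
    t = lam ** (-0.5)
    return (float(lam), t, t)


def sef_value(model: ConstitutiveModel, stretches: Sequence[float]) -> float:
    """Strain-energy density W (MPa) at the given principal stretches.

    Hyperelastic kinds only; W vanishes in the undeformed state.
    """
    if model.kind not in HYPERELASTIC_KINDS:
        raise MaterialError(f"sef_value undefined for kind {model.kind!r}")
    i1, i2, _ = invariants(stretches)
    if model.kind == "neo_hookean":
        return model.params["mu"] * (i1 - 3.0)
    if model.kind == "mooney_rivlin":
        return model.params["c10"] * (i1 - 3.0) + model.params["c01"] * (i2 - 3.0)
    mu, alpha = model.ogden_terms()
    lam = np.asarray(stretches, dtype=float)
    return float(np.sum(2.0 * mu / alpha**2
                        * (lam[0]**alpha + lam[1]**alpha + lam[2]**alpha - 3.0)))


# ---------------------------------------------------------------------------
# Uniaxial stress laws (the fitting formulas)
# ---------------------------------------------------------------------------

def uniaxial_stress(model: ConstitutiveModel, lam) -> np.ndarray | float:
    """Uniaxial tensile stress sigma (MPa) at stretch lambda.

    Evaluates the same closed forms used for coefficient fitting (module
    docstring); vectorized over ``lam``.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise MaterialError("stretch must be strictly positive")
    if model.kind == "elastic":
        out = model.params["e"] * (lam_arr - 1.0)
    elif model.kind == "neo_hookean":
        out = 2.0 * (lam_arr**2 - 1.0 / lam_arr) * model.params["mu"]
    elif model.kind == "mooney_rivlin":
        out = 2.0 * (lam_arr**2 - 1.0 / lam_arr) * (
            model.params["c10"] + model.params["c01"] / lam_arr)
    else:
        mu, alpha = model.ogden_terms()
        out = np.zeros_like(lam_arr)
        for m, a in zip(mu, alpha):
            out = out + m * (lam_arr**a - lam_arr**(-0.5 * a))
    return out if np.ndim(lam) else float(out)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

# (names, initial guess, lower bounds, upper bounds) per kind
_FIT_SETUP = {
    "elastic": (["e"], [0.1], [0.0], [np.inf]),
    "neo_hookean": (["mu"], [0.1], [0.0], [np.inf]),
    "mooney_rivlin": (["c10", "c01"], [0.1, 0.1], [0.0, 0.0], [np.inf, np.inf]),
    "ogden": (["mu1", "alpha1"], [0.1, 2.0], [0.0, 0.1], [np.inf, 10.0]),
}


def _model_from_vector(kind: str, theta: np.ndarray) -> ConstitutiveModel:
    if kind == "elastic":
        return ConstitutiveModel("elastic", {"e": float(theta[0])})
    if kind == "neo_hookean":
        return ConstitutiveModel("neo_hookean", {"mu": float(theta[0])})
    if kind == "mooney_rivlin":
        return ConstitutiveModel("mooney_rivlin", {"c10": float(theta[0]), "c01": float(theta[1])})
    return ConstitutiveModel("ogden", {"mu": [float(theta[0])], "alpha": [float(theta[1])]})


def fit_material(curve: StressStrainCurve, kind: str) -> FitResult:
    """Fit one constitutive model to a tensile curve by bounded nonlinear
    least squares.

    Deterministic: fixed initial guesses (all moduli 0.1 MPa, Ogden alpha 2)
    and bounds (coefficients >= 0, alpha in [0.1, 10]).  Reports R^2 (1 -
    SS_res/SS_tot on stresses), RMSE (MPa), and 95% confidence intervals from
    the linearized covariance at the optimum (t-quantile).
    """
    if kind not in KINDS:
        raise MaterialError(f"unknown material kind {kind!r}")
    names, x0, lo, hi = _FIT_SETUP[kind]
    n_par = len(names)
    lam, sig = curve.stretch, curve.stress
    n = lam.size
    min_samples = 3 if n_par == 1 else 5
    if n < min_samples:
        raise FitError(f"{kind} fit needs >= {min_samples} samples, got {n}")
    if np.ptp(lam) < 1e-12:
        raise FitError("degenerate curve: constant stretch (rank-deficient fit)")

    def residuals(theta):
        return uniaxial_stress(_model_from_vector(kind, theta), lam) - sig

    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"{kind} fit did not converge: {sol.message}")

    model = _model_from_vector(kind, sol.x)
    res = sol.fun
    ss_res = float(res @ res)
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    r_square = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / n))

    # 95% CIs: linearized covariance (J'J)^-1 * s^2 with a t quantile.
    dof = max(n - n_par, 1)
    s2 = ss_res / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular Jacobian in {kind} fit") from exc
    tq = stats.t.ppf(0.975, dof)
    half = tq * np.sqrt(np.maximum(np.diag(cov), 0.0))
    cis = {name: (float(sol.x[i] - half[i]), float(sol.x[i] + half[i]))
           for i, name in enumerate(names)}
    return FitResult(model=model, r_square=r_square, rmse=rmse,
                     confidence_intervals=cis, n_samples=n)
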