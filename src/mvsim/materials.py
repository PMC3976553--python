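"""Constitutive models for mitral valve tissue.

Leaflets are modeled as an anisotropic Fung-type hyperelastic membrane,
W = (c/2)(exp(Q) - 1) with a quadratic exponent in the planar Green-Lagrange
strain expressed in the material frame (direction 1 = circumferential,
direction 2 = radial).  Chordae tendineae are incompressible Ogden fibers
loaded uniaxially.  Stresses are kPa throughout this module; geometry-level
unit conversion happens in the solver.

The printed parameter defaults are *representative* soft-tissue values, not
measurements: the package exposes :func:`fit_params` so users can fit the
models to digitized biaxial / uniaxial test data (CSV) instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InvalidParameterError

__all__ = [
    "FungParams",
    "OgdenParams",
    "TissueProps",
    "PlanarStrain",
    "MaterialSet",
    "fung_energy",
    "fung_pk2_stress",
    "ogden_energy",
    "ogden_nominal_stress",
    "ogden_axial_force",
    "fit_params",
    "FitResult",
    "biaxial_response",
    "representative_materials",
    "read_curve_csv",
    "write_curve_csv",
]

CHORDAL_TYPES = ("posterior_marginal", "anterior_marginal", "strut")


@dataclass(frozen=True)
class FungParams:
    """Fung exponent coefficients: Q = a1*E11^2 + a2*E22^2 + 2*a3*E11*E22 + a4*E12^2.

    ``c`` is the stress-like scale in kPa; a1/a2 weight the circumferential and
    radial directions, a3 couples them, a4 weights in-plane shear.  Convexity of
    the quadratic form requires a1*a2 > a3^2.
    """

    c: float
    a1: float
    a2: float
    a3: float
    a4: float

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise InvalidParameterError(f"Fung scale c must be > 0, got {self.c}")
        if not (self.a1 > 0 and self.a2 > 0 and self.a4 > 0):
            raise InvalidParameterError("Fung exponents a1, a2, a4 must be > 0")
        if not (self.a1 * self.a2 - self.a3**2 > 0):
            raise InvalidParameterError(
                "Fung exponent form must be convex: a1*a2 - a3^2 > 0 "
                f"(got a1={self.a1}, a2={self.a2}, a3={self.a3})"
            )


@dataclass(frozen=True)
class OgdenParams:
    """Ogden model of order 1 or 2: shear moduli mu_i (kPa) and exponents alpha_i."""

    order: Literal[1, 2]
    mu: tuple[float, ...]
    alpha: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise InvalidParameterError(f"Ogden order must be 1 or 2, got {self.order}")
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        if len(self.mu) != self.order or len(self.alpha) != self.order:
            raise InvalidParameterError("mu and alpha must each have `order` entries")
        if sum(m * a for m, a in zip(self.mu, self.alpha)) <= 0:
            raise InvalidParameterError(
                "sum(mu_i * alpha_i) must be > 0 (positive small-strain shear modulus)"
            )

    @property
    def small_strain_shear_modulus(self) -> float:
        """mu0 = sum(mu_i * alpha_i) / 2 in kPa."""
        return 0.5 * sum(m * a for m, a in zip(self.mu, self.alpha))


@dataclass(frozen=True)
class TissueProps:
    """Geometric / inertial tissue properties (mm, mm^2, kg/m^3)."""

    thickness_anterior: float = 0.69
    thickness_posterior: float = 0.51
    area_posterior_marginal: float = 0.27
    area_anterior_marginal: float = 0.29
    area_strut: float = 0.61
    density: float = 1100.0
    poisson: float = 0.48

    def __post_init__(self) -> None:
        vals = (
            self.thickness_anterior,
            self.thickness_posterior,
            self.area_posterior_marginal,
            self.area_anterior_marginal,
            self.area_strut,
            self.density,
            self.poisson,
        )
        if any(not (v > 0) for v in vals):
            raise InvalidParameterError("all tissue properties must be positive")
        if not self.poisson < 0.5:
            raise InvalidParameterError("poisson must be < 0.5")

    def chordal_area(self, chordal_type: str) -> float:
        return {
            "posterior_marginal": self.area_posterior_marginal,
            "anterior_marginal": self.area_anterior_marginal,
            "strut": self.area_strut,
        }[chordal_type]


@dataclass(frozen=True)
class PlanarStrain:
    """Planar Green-Lagrange strain in the leaflet material frame.

    Components may be scalars or equally shaped arrays; E12 is the single
    stored off-diagonal component of the symmetric tensor.
    """

    E11: np.ndarray | float
    E22: np.ndarray | float
    E12: np.ndarray | float = 0.0

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.broadcast_arrays(
            np.asarray(self.E11, float),
            np.asarray(self.E22, float),
            np.asarray(self.E12, float),
        )


def _fung_Q(E11, E22, E12, p: FungParams):
    return p.a1 * E11**2 + p.a2 * E22**2 + 2.0 * p.a3 * E11 * E22 + p.a4 * E12**2


def fung_energy(E: PlanarStrain, p: FungParams):
    """Strain-energy density W = (c/2)(exp(Q) - 1) in kPa (= kJ/m^3)."""
    E11, E22, E12 = E.as_arrays()
    W = 0.5 * p.c * np.expm1(_fung_Q(E11, E22, E12, p))
    return W if W.ndim else float(W)


def fung_pk2_stress(E: PlanarStrain, p: FungParams):
    """Second Piola-Kirchhoff stress S = dW/dE, components (S11, S22, S12) in kPa."""
    E11, E22, E12 = E.as_arrays()
    ceQ = p.c * np.exp(_fung_Q(E11, E22, E12, p))
    S11 = ceQ * (p.a1 * E11 + p.a3 * E22)
    S22 = ceQ * (p.a3 * E11 + p.a2 * E22)
    S12 = ceQ * (p.a4 * E12)
    if S11.ndim:
        return S11, S22, S12
    return float(S11), float(S22), float(S12)


def _check_stretch(lam):
    lam = np.asarray(lam, float)
    if np.any(lam <= 0):
        raise InvalidParameterError("stretch must be > 0")
    return lam


def ogden_energy(lam, p: OgdenParams):
    """Incompressible uniaxial Ogden energy per reference volume, kPa.

    Transverse stretches are lam^(-1/2):
    W(lam) = sum_i (2 mu_i / alpha_i^2) (lam^alpha_i + 2 lam^(-alpha_i/2) - 3).
    """
    lam = _check_stretch(lam)
    W = np.zeros_like(lam)
    for m, a in zip(p.mu, p.alpha):
        W += (2.0 * m / a**2) * (lam**a + 2.0 * lam ** (-a / 2.0) - 3.0)
    return W if W.ndim else float(W)


def ogden_nominal_stress(lam, p: OgdenParams):
    """Uniaxial nominal (first PK) stress P(lam) = dW/dlam in kPa."""
    lam = _check_stretch(lam)
    P = np.zeros_like(lam)
    for m, a in zip(p.mu, p.alpha):
        P += (2.0 * m / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    return P if P.ndim else float(P)


def ogden_axial_force(lam, p: OgdenParams, reference_area_mm2: float, *, tension_only: bool = False):
    """Axial chordal force in newtons at stretch ``lam``.

    force = P(lam) * A_ref; with ``tension_only`` compressive response is
    clamped to zero (slack chordae buckle rather than push).
    """
    P_kpa = ogden_nominal_stress(lam, p)
    force = np.asarray(P_kpa, float) * 1e3 * reference_area_mm2 * 1e-6  # kPa*mm^2 -> N
    if tension_only:
        force = np.maximum(force, 0.0)
    return force if force.ndim else float(force)


@dataclass(frozen=True)
class MaterialSet:
    """Everything the solver needs: leaflet laws, chordal laws, tissue properties."""

    fung_anterior: FungParams
    fung_posterior: FungParams
    ogden: dict[str, OgdenParams]
    props: TissueProps = field(default_factory=TissueProps)
    tension_only: bool = True

    def __post_init__(self) -> None:
        missing = [t for t in CHORDAL_TYPES if t not in self.ogden]
        if missing:
            raise InvalidParameterError(f"missing Ogden parameters for chordal types {missing}")


def representative_materials() -> MaterialSet:
    """Representative (literature-scale, not patient-fitted) material set.

    Leaflet constants give ~100 kPa membrane stress near 18% biaxial strain
    with circumferential-dominant anisotropy; chordal constants give
    low-strain tangent moduli of a few MPa with strong exponential stiffening
    beyond ~10% stretch, marginal softer than strut.
    """
    return MaterialSet(
        fung_anterior=FungParams(c=5.0, a1=20.0, a2=14.0, a3=6.0, a4=10.0),
        fung_posterior=FungParams(c=3.0, a1=16.0, a2=12.0, a3=5.0, a4=8.0),
        ogden={
            "posterior_marginal": OgdenParams(order=1, mu=(1800.0,), alpha=(12.0,)),
            "anterior_marginal": OgdenParams(order=1, mu=(1800.0,), alpha=(12.0,)),
            "strut": OgdenParams(order=1, mu=(2600.0,), alpha=(13.0,)),
        },
    )


# ---------------------------------------------------------------------------
# Parameter fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    params: FungParams | OgdenParams
    rms_residual: float


def biaxial_response(E11, E22, p: FungParams):
    """(S11, S22) response of the Fung model on a biaxial strain path (no shear)."""
    S11, S22, _ = fung_pk2_stress(PlanarStrain(E11, E22, 0.0), p)
    return S11, S22


def _relative_residual(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    scale = 0.05 * float(np.max(np.abs(obs))) + np.abs(obs)
    return (pred - obs) / scale


def fit_params(
    curve: np.ndarray,
    model: Literal["fung_biaxial", "ogden"],
    order: int = 1,
    *,
    seed: int = 0,
    n_starts: int = 12,
    a4: float = 10.0,
) -> FitResult:
    """Least-squares constitutive fit with a seeded multi-start.

    ``curve`` layout:

    * ``fung_biaxial`` — columns (E11, E22, S11_kPa, S22_kPa), typically from
      several biaxial protocols (equibiaxial plus off-ratio legs).  The shear
      coefficient a4 is not identifiable from shear-free biaxial data and is
      held at the supplied value.
    * ``ogden`` — columns (stretch, nominal_stress_kPa) of a uniaxial test.

    Returns fitted parameters honoring the type invariants plus the RMS of the
    relative residual.  Raises :class:`FitError` for underdetermined or
    degenerate (all-zero stress) data.
    """
    curve = np.atleast_2d(np.asarray(curve, float))
    rng = np.random.default_rng(seed)

    if model == "fung_biaxial":
        if curve.shape[1] != 4:
            raise FitError("fung_biaxial expects columns (E11, E22, S11, S22)")
        n_free = 4  # c, a1, a2, a3
        if curve.shape[0] < 2 * n_free:
            raise FitError(f"need at least {2 * n_free} points, got {curve.shape[0]}")
        E11, E22, S11o, S22o = curve.T
        obs = np.concatenate([S11o, S22o])
        if np.max(np.abs(obs)) == 0:
            raise FitError("degenerate curve: all stresses zero")

        def resid(x):
            c, a1, a2, a3 = np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), x[3]
            Q = a1 * E11**2 + a2 * E22**2 + 2 * a3 * E11 * E22
            Q = np.minimum(Q, 50.0)  # guard overflow during search
            ceQ = c * np.exp(Q)
            pred = np.concatenate([ceQ * (a1 * E11 + a3 * E22), ceQ * (a3 * E11 + a2 * E22)])
            return _relative_residual(pred, obs)

        best = None
        for k in range(n_starts):
            x0 = np.array(
                [
                    np.log(10 ** rng.uniform(-1, 1.5)),
                    np.log(rng.uniform(2, 60)),
                    np.log(rng.uniform(2, 60)),
                    rng.uniform(0, 20),
                ]
            )
            try:
                sol = least_squares(resid, x0, method="lm", max_nfev=4000)
            except Exception:
                continue
            c, a1, a2, a3 = np.exp(sol.x[0]), np.exp(sol.x[1]), np.exp(sol.x[2]), sol.x[3]
            if a1 * a2 - a3**2 <= 0:
                continue
            if best is None or sol.cost < best[0]:
                best = (sol.cost, (c, a1, a2, a3), sol.fun)
        if best is None:
            raise FitError("fung fit failed: no convex solution found")
        c, a1, a2, a3 = best[1]
        params = FungParams(c=c, a1=a1, a2=a2, a3=a3, a4=a4)
        rms = float(np.sqrt(np.mean(best[2] ** 2)))
        return FitResult(params=params, rms_residual=rms)

    if model == "ogden":
        if order not in (1, 2):
            raise FitError("ogden order must be 1 or 2")
        if curve.shape[1] != 2:
            raise FitError("ogden expects columns (stretch, stress)")
        n_free = 2 * order
        if curve.shape[0] < 2 * n_free:
            raise FitError(f"need at least {2 * n_free} points, got {curve.shape[0]}")
        lam, Po = curve.T
        if np.any(lam <= 0):
            raise FitError("stretches must be positive")
        if np.max(np.abs(Po)) == 0:
            raise FitError("degenerate curve: all stresses zero")

        def resid(x):
            mu = np.exp(x[:order])
            al = x[order:]
            pred = np.zeros_like(lam)
            for m, a in zip(mu, al):
                pred += (2 * m / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
            return _relative_residual(pred, Po)

        best = None
        for k in range(n_starts):
            x0 = np.concatenate(
                [
                    np.log(10 ** rng.uniform(0, 3, order)),
                    rng.uniform(1.5, 20, order),
                ]
            )
            try:
                sol = least_squares(
                    resid,
                    x0,
                    bounds=(
                        np.concatenate([np.full(order, -10.0), np.full(order, 0.2)]),
                        np.concatenate([np.full(order, 20.0), np.full(order, 40.0)]),
                    ),
                    max_nfev=4000,
                )
            except Exception:
                continue
            mu = tuple(np.exp(sol.x[:order]))
            al = tuple(sol.x[order:])
            if sum(m * a for m, a in zip(mu, al)) <= 0:
                continue
            if best is None or sol.cost < best[0]:
                best = (sol.cost, (mu, al), sol.fun)
        if best is None:
            raise FitError("ogden fit failed")
        mu, al = best[1]
        params = OgdenParams(order=order, mu=mu, alpha=al)
        return FitResult(params=params, rms_residual=float(np.sqrt(np.mean(best[2] ** 2))))

    raise FitError(f"unknown model {model!r}")


def read_curve_csv(path) -> np.ndarray:
    """Read a stress-strain curve CSV (header line optional)."""
    try:
        return np.loadtxt(path, delimiter=",", skiprows=1)
    except ValueError:
        return np.loadtxt(path, delimiter=",")


def write_curve_csv(path, curve: np.ndarray, header: str = "stretch_or_strain,stress_kPa") -> None:
    np.savetxt(path, np.asarray(curve, float), delimiter=",", header=header, comments="")
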