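"""Incompressible hyperelastic constitutive models for vascular tissue and grafts.

Implements closed-form strain energy, nominal (first Piola-Kirchhoff) stress and
tangent moduli for the material families used to describe PTFE (Gore-Tex)
vascular grafts and the aortic wall:

* five-parameter Mooney-Rivlin,  W = c10(I1-3) + c01(I2-3) + c20(I1-3)^2
  + c11(I1-3)(I2-3) + c02(I2-3)^2,
* three-parameter Yeoh,          W = sum_i ci0 (I1-3)^i,
* Ogden (1..3 terms),            W = sum_p mu_p/alpha_p (l1^a + l2^a + l3^a - 3),
* Holzapfel-Gasser-Ogden (HGO) with dispersed collagen-fiber families,
* a linear-elastic reference (E, nu) for graft comparison runs.

All models are treated as exactly incompressible (J = 1): volumetric terms in
the parameter records (d1) are carried for round-tripping but never evaluated.
Stretches are dimensionless; stresses and energy densities are in MPa.

The Ogden energy follows the mu_p/alpha_p normalisation, for which the
small-strain shear modulus is mu = (1/2) sum_p mu_p alpha_p; with a single
term and alpha = 2 it collapses to the neo-Hookean solid and with
(alpha1, alpha2) = (2, -2) to the two-term Mooney-Rivlin material.

The HGO fiber strain is E_a = kappa*(I1-3) + (1-3*kappa)*(I4a-1) with a
tension-only Macaulay bracket; kappa in [0, 1/3] measures fiber dispersion
(0 = perfectly aligned, 1/3 = isotropic).  A ``convention`` switch selects the
sign printed in some sources for the I4 coefficient (``"as_printed"`` uses
(1+3*kappa)); the default ``"standard"`` form is the one for which
kappa = 1/3 makes the response independent of fiber angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "DomainError",
    "IncompressibilityError",
    "ConfigurationError",
    "PrincipalStretches",
    "InvariantSet",
    "MooneyRivlin5Params",
    "Yeoh3Params",
    "OgdenParams",
    "HGOParams",
    "LinearElasticParams",
    "MaterialModel",
    "invariants_from_stretches",
    "strain_energy",
    "uniaxial_strain_energy",
    "uniaxial_nominal_stress",
    "uniaxial_stress_numeric",
    "small_strain_shear_modulus",
    "hgo_fiber_strain",
    "drucker_stability_report",
    "plane_stress_hoop_stress",
    "model_from_dict",
    "model_to_dict",
]

INCOMPRESSIBILITY_TOL = 1e-12


class DomainError(ValueError):
    """A kinematic quantity left its physical domain (e.g. stretch <= 0)."""


class IncompressibilityError(ValueError):
    """The stretch triple violates l1*l2*l3 = 1 beyond tolerance."""


class ConfigurationError(ValueError):
    """Unknown model tag or invalid parameter combination."""


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrincipalStretches:
    """Principal stretch ratios (l1, l2, l3), all strictly positive.

    Axis 1 is the loading (axial) direction in uniaxial tests, axis 2 the
    in-plane transverse direction.
    """

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        for lam in (self.l1, self.l2, self.l3):
            if not (lam > 0.0) or not math.isfinite(lam):
                raise DomainError(f"stretches must be positive and finite, got {lam}")

    @property
    def J(self) -> float:
        return self.l1 * self.l2 * self.l3

    def check_incompressible(self, tol: float = INCOMPRESSIBILITY_TOL) -> None:
        if abs(self.J - 1.0) > tol:
            raise IncompressibilityError(
                f"l1*l2*l3 = {self.J!r} violates incompressibility beyond {tol}"
            )


@dataclass(frozen=True)
class InvariantSet:
    """Deviatoric invariants plus per-fiber-family pseudo-invariants I4."""

    I1bar: float
    I2bar: float
    I3bar: float
    I4: tuple[float, ...] = ()


def invariants_from_stretches(
    stretches: PrincipalStretches,
    fiber_angles: Sequence[float] = (),
    *,
    require_incompressible: bool = True,
) -> InvariantSet:
    """Invariants of the (deviatoric) right Cauchy-Green tensor.

    I1 = sum li^2, I2 = sum of pairwise products li^2 lj^2, I3 = (l1 l2 l3)^2.
    For a fiber family at angle ``beta`` (radians) from axis 1 in the 1-2
    plane, I4 = l1^2 cos^2(beta) + l2^2 sin^2(beta) is the squared fiber
    stretch.
    """
    if require_incompressible:
        stretches.check_incompressible()
    a, b, c = stretches.l1**2, stretches.l2**2, stretches.l3**2
    i4 = tuple(
        a * math.cos(beta) ** 2 + b * math.sin(beta) ** 2 for beta in fiber_angles
    )
    return InvariantSet(I1bar=a + b + c, I2bar=a * b + b * c + a * c, I3bar=a * b * c, I4=i4)


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MooneyRivlin5Params:
    """Five-parameter Mooney-Rivlin constants, MPa.

    Signs are unconstrained: fitted graft constants legitimately include
    negative c10 (stability over a working stretch window is reported by
    :func:`drucker_stability_report`, not enforced here).  ``d1`` (MPa^-1) is
    the volumetric penalty coefficient, carried but unused under exact
    incompressibility.
    """

    c10: float
    c01: float
    c20: float
    c11: float
    c02: float
    d1: float = 0.0

    tag = "mooney_rivlin5"


@dataclass(frozen=True)
class Yeoh3Params:
    """Three-parameter Yeoh constants, MPa; c10 > 0 (shear modulus 2*c10)."""

    c10: float
    c20: float
    c30: float

    tag = "yeoh3"

    def __post_init__(self) -> None:
        if not self.c10 > 0.0:
            raise ConfigurationError("Yeoh c10 must be positive (mu = 2*c10)")


@dataclass(frozen=True)
class OgdenParams:
    """Ogden terms [(mu_p MPa, alpha_p), ...], 1 <= N <= 3.

    The effective shear modulus (1/2) sum mu_p alpha_p must be positive.
    """

    terms: tuple[tuple[float, float], ...]

    tag = "ogden"

    def __post_init__(self) -> None:
        terms = tuple((float(m), float(a)) for m, a in self.terms)
        object.__setattr__(self, "terms", terms)
        if not 1 <= len(terms) <= 3:
            raise ConfigurationError("Ogden model supports 1..3 terms")
        if not sum(m * a for m, a in terms) > 0.0:
            raise ConfigurationError(
                "Ogden effective shear modulus (1/2)*sum(mu_p*alpha_p) must be > 0"
            )


@dataclass(frozen=True)
class HGOParams:
    """Holzapfel-Gasser-Ogden constants.

    c10, k1 in MPa; k2 dimensionless (> 0); kappa in [0, 1/3] is the fiber
    dispersion.  ``fiber_angles`` are family mean directions in radians,
    measured from the circumferential axis in the wall tangent plane (at most
    three families; the common arterial arrangement is two symmetric families
    at +/- beta).
    """

    c10: float
    k1: float
    k2: float
    kappa: float
    fiber_angles: tuple[float, ...] = (math.radians(45.0), math.radians(-45.0))
    convention: str = "standard"  # "standard" => (1-3k); "as_printed" => (1+3k)

    tag = "hgo"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fiber_angles", tuple(float(b) for b in self.fiber_angles))
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-15:
            raise ConfigurationError("kappa must lie in [0, 1/3]")
        if self.k1 < 0.0 or not self.k2 > 0.0:
            raise ConfigurationError("require k1 >= 0 and k2 > 0")
        if not self.c10 > 0.0:
            raise ConfigurationError("HGO ground-matrix c10 must be positive")
        if len(self.fiber_angles) > 3:
            raise ConfigurationError("at most three fiber families")
        if self.convention not in ("standard", "as_printed"):
            raise ConfigurationError(f"unknown HGO convention {self.convention!r}")

    @property
    def i4_coefficient(self) -> float:
        if self.convention == "standard":
            return 1.0 - 3.0 * self.kappa
        return 1.0 + 3.0 * self.kappa


@dataclass(frozen=True)
class LinearElasticParams:
    """Isotropic linear-elastic reference (E in MPa, Poisson ratio nu)."""

    E: float
    nu: float

    tag = "linear_elastic"

    def __post_init__(self) -> None:
        if not self.E > 0.0:
            raise ConfigurationError("E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ConfigurationError("nu must lie in [0, 0.5)")


MaterialModel = Union[
    MooneyRivlin5Params, Yeoh3Params, OgdenParams, HGOParams, LinearElasticParams
]

_HYPERELASTIC_TAGS = ("mooney_rivlin5", "yeoh3", "ogden", "hgo")


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------


def _macaulay(x: float) -> float:
    return x if x > 0.0 else 0.0


def _hgo_fiber_strain_raw(params: HGOParams, i1: float, i4: float) -> float:
    return params.kappa * (i1 - 3.0) + params.i4_coefficient * (i4 - 1.0)


def hgo_fiber_strain(params: HGOParams, invariants: InvariantSet, family_index: int) -> float:
    """Fiber strain-like quantity E_a of one family, before Macaulay bracketing."""
    if not 0 <= family_index < len(invariants.I4):
        raise IndexError(
            f"family index {family_index} out of range for {len(invariants.I4)} families"
        )
    return _hgo_fiber_strain_raw(params, invariants.I1bar, invariants.I4[family_index])


def strain_energy(model: MaterialModel, state: PrincipalStretches | InvariantSet) -> float:
    """Strain energy density W (MPa), zero at the reference configuration.

    Ogden requires principal stretches; invariant-based models accept either a
    :class:`PrincipalStretches` (invariants are computed, with the model's own
    fiber angles for HGO) or a pre-built :class:`InvariantSet`.
    """
    tag = getattr(model, "tag", None)
    if tag == "ogden":
        if not isinstance(state, PrincipalStretches):
            raise ConfigurationError("Ogden strain energy requires principal stretches")
        state.check_incompressible()
        return sum(
            m / a * (state.l1**a + state.l2**a + state.l3**a - 3.0)
            for m, a in model.terms
        )

    if isinstance(state, PrincipalStretches):
        angles = model.fiber_angles if tag == "hgo" else ()
        inv = invariants_from_stretches(state, angles)
    else:
        inv = state
    x = inv.I1bar - 3.0
    y = inv.I2bar - 3.0

    if tag == "mooney_rivlin5":
        return (
            model.c10 * x
            + model.c01 * y
            + model.c20 * x**2
            + model.c11 * x * y
            + model.c02 * y**2
        )
    if tag == "yeoh3":
        return model.c10 * x + model.c20 * x**2 + model.c30 * x**3
    if tag == "hgo":
        w = model.c10 * x
        for i4 in inv.I4:
            e = _macaulay(_hgo_fiber_strain_raw(model, inv.I1bar, i4))
            w += model.k1 / (2.0 * model.k2) * math.expm1(model.k2 * e * e)
        return w
    if tag == "linear_elastic":
        raise ConfigurationError(
            "linear-elastic reference has no finite-strain energy; "
            "use uniaxial_nominal_stress or the tube law directly"
        )
    raise ConfigurationError(f"unknown material model {model!r}")


# ---------------------------------------------------------------------------
# uniaxial response
# ---------------------------------------------------------------------------


def _as_array(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0) or not np.all(np.isfinite(lam)):
        raise DomainError("axial stretch must be positive and finite")
    return lam


def uniaxial_strain_energy(model: MaterialModel, lam_axial) -> np.ndarray | float:
    """W along the incompressible uniaxial path l = (lam, lam^-1/2, lam^-1/2)."""
    lam = _as_array(lam_axial)
    tag = model.tag
    if tag == "ogden":
        w = np.zeros_like(lam)
        for m, a in model.terms:
            w += m / a * (lam**a + 2.0 * lam ** (-a / 2.0) - 3.0)
        return w if w.ndim else float(w)

    i1 = lam**2 + 2.0 / lam
    x = i1 - 3.0
    if tag == "mooney_rivlin5":
        i2 = 2.0 * lam + lam**-2
        y = i2 - 3.0
        w = (
            model.c10 * x
            + model.c01 * y
            + model.c20 * x**2
            + model.c11 * x * y
            + model.c02 * y**2
        )
    elif tag == "yeoh3":
        w = model.c10 * x + model.c20 * x**2 + model.c30 * x**3
    elif tag == "hgo":
        w = model.c10 * x
        for beta in model.fiber_angles:
            i4 = lam**2 * math.cos(beta) ** 2 + math.sin(beta) ** 2 / lam
            e = np.maximum(
                model.kappa * x + model.i4_coefficient * (i4 - 1.0), 0.0
            )
            w = w + model.k1 / (2.0 * model.k2) * np.expm1(model.k2 * e * e)
    elif tag == "linear_elastic":
        w = 0.5 * model.E * (lam - 1.0) ** 2
    else:
        raise ConfigurationError(f"unknown material model {model!r}")
    return w if np.ndim(w) else float(w)


def uniaxial_nominal_stress(model: MaterialModel, lam_axial, *, cauchy: bool = False):
    """Nominal (first Piola) uniaxial stress P(lam) = dW/dlam, MPa.

    The transverse stretches follow lam^-1/2 (incompressible) and the
    transverse stress-free condition is eliminated analytically, so P(1) = 0
    exactly for every model.  With ``cauchy=True`` the Cauchy stress
    lam * P(lam) is returned instead.
    """
    lam = _as_array(lam_axial)
    tag = model.tag

    if tag == "ogden":
        p = np.zeros_like(lam)
        for m, a in model.terms:
            p += m * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    elif tag == "linear_elastic":
        p = model.E * (lam - 1.0)
    else:
        di1 = 2.0 * lam - 2.0 * lam**-2
        x = lam**2 + 2.0 / lam - 3.0
        if tag == "mooney_rivlin5":
            di2 = 2.0 - 2.0 * lam**-3
            y = 2.0 * lam + lam**-2 - 3.0
            w1 = model.c10 + 2.0 * model.c20 * x + model.c11 * y
            w2 = model.c01 + model.c11 * x + 2.0 * model.c02 * y
            p = w1 * di1 + w2 * di2
        elif tag == "yeoh3":
            w1 = model.c10 + 2.0 * model.c20 * x + 3.0 * model.c30 * x**2
            p = w1 * di1
        elif tag == "hgo":
            p = model.c10 * di1
            for beta in model.fiber_angles:
                cb2 = math.cos(beta) ** 2
                sb2 = math.sin(beta) ** 2
                i4 = lam**2 * cb2 + sb2 / lam
                di4 = 2.0 * lam * cb2 - sb2 * lam**-2
                e = model.kappa * x + model.i4_coefficient * (i4 - 1.0)
                active = e > 0.0
                psi = np.where(
                    active, model.k1 * e * np.exp(model.k2 * np.minimum(e, 50.0) ** 2), 0.0
                )
                p = p + psi * (model.kappa * di1 + model.i4_coefficient * di4)
        else:
            raise ConfigurationError(f"unknown material model {model!r}")
    if cauchy:
        p = lam * p
    return p if np.ndim(p) else float(p)


def uniaxial_stress_numeric(model: MaterialModel, lam_axial, h: float = 1e-7):
    """Central-difference dW/dlam along the uniaxial path (diagnostic oracle)."""
    lam = _as_array(lam_axial)
    wp = uniaxial_strain_energy(model, lam + h)
    wm = uniaxial_strain_energy(model, lam - h)
    out = (np.asarray(wp) - np.asarray(wm)) / (2.0 * h)
    return out if out.ndim else float(out)


def small_strain_shear_modulus(model: MaterialModel) -> float:
    """Analytic small-strain shear modulus mu (MPa).

    mu equals one third of the uniaxial tangent dP/dlam at lam = 1
    (incompressible identity E = 3 mu).  For HGO the tension-only fiber
    term is one-sided at the reference state; the value returned is the
    symmetric (two-sided average) tangent, which is what a central
    difference across lam = 1 measures: each family contributes
    k1 * ((1-3k)(2cos^2 b - sin^2 b))^2 / 6.
    """
    tag = model.tag
    if tag == "mooney_rivlin5":
        return 2.0 * (model.c10 + model.c01)
    if tag == "yeoh3":
        return 2.0 * model.c10
    if tag == "ogden":
        return 0.5 * sum(m * a for m, a in model.terms)
    if tag == "hgo":
        mu = 2.0 * model.c10
        for beta in model.fiber_angles:
            a = 2.0 * math.cos(beta) ** 2 - math.sin(beta) ** 2
            mu += model.k1 * (model.i4_coefficient * a) ** 2 / 6.0
        return mu
    if tag == "linear_elastic":
        return model.E / (2.0 * (1.0 + model.nu))
    raise ConfigurationError(f"unknown material model {model!r}")


# ---------------------------------------------------------------------------
# stability diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DruckerReport:
    """Uniaxial tangent-stability screen over a stretch window (report only)."""

    lam: np.ndarray
    tangent: np.ndarray
    stable: np.ndarray

    @property
    def all_stable(self) -> bool:
        return bool(np.all(self.stable))

    @property
    def unstable_lambdas(self) -> np.ndarray:
        return self.lam[~self.stable]


def drucker_stability_report(
    model: MaterialModel,
    stretch_window: tuple[float, float] = (0.8, 2.0),
    n: int = 201,
    h: float = 1e-6,
) -> DruckerReport:
    """Flag stretches where the uniaxial tangent modulus dP/dlam <= 0.

    A materially stable incompressible solid must stiffen monotonically along
    the uniaxial path; fitted Mooney-Rivlin sets with negative c10 can fail
    this away from the data window, which this screen reports without raising.
    """
    lo, hi = stretch_window
    if not (0.0 < lo < hi):
        raise DomainError("stretch window must satisfy 0 < lo < hi")
    lam = np.linspace(lo, hi, n)
    tang = (
        np.asarray(uniaxial_nominal_stress(model, lam + h))
        - np.asarray(uniaxial_nominal_stress(model, lam - h))
    ) / (2.0 * h)
    return DruckerReport(lam=lam, tangent=tang, stable=tang > 0.0)


# ---------------------------------------------------------------------------
# plane-stress hoop response (wall mechanics for the tube law)
# ---------------------------------------------------------------------------


def plane_stress_hoop_stress(model: MaterialModel, lam_theta, lam_z: float = 1.0):
    """Circumferential Cauchy stress of a thin incompressible wall, MPa.

    Plane stress through the thickness (sigma_r = 0) with fixed axial stretch
    (default 1) and radial stretch 1/(lam_theta*lam_z) from incompressibility.
    HGO fiber angles are measured from the circumferential direction.  For the
    linear-elastic reference the plane-strain-in-z hoop response
    E/(1-nu^2) * (lam_theta - 1) is used, consistent with the classical
    Moens-Korteweg tube stiffness.
    """
    lam = _as_array(lam_theta)
    lz = float(lam_z)
    lr = 1.0 / (lam * lz)
    tag = model.tag

    if tag == "linear_elastic":
        s = model.E / (1.0 - model.nu**2) * (lam - 1.0)
        return s if np.ndim(s) else float(s)
    if tag == "ogden":
        s = np.zeros_like(lam)
        for m, a in model.terms:
            s += m * (lam**a - lr**a)
        return s if s.ndim else float(s)

    a2, b2, c2 = lam**2, lz**2, lr**2
    i1 = a2 + b2 + c2
    x = i1 - 3.0
    # sigma_theta - sigma_r = 2*W1*(lt^2 - lr^2) + 2*W2*(lt^2*lz^2 - lr^2*lz^2)
    if tag == "mooney_rivlin5":
        i2 = a2 * b2 + b2 * c2 + a2 * c2
        y = i2 - 3.0
        w1 = model.c10 + 2.0 * model.c20 * x + model.c11 * y
        w2 = model.c01 + model.c11 * x + 2.0 * model.c02 * y
        s = 2.0 * w1 * (a2 - c2) + 2.0 * w2 * b2 * (a2 - c2)
    elif tag == "yeoh3":
        w1 = model.c10 + 2.0 * model.c20 * x + 3.0 * model.c30 * x**2
        s = 2.0 * w1 * (a2 - c2)
    elif tag == "hgo":
        w1 = np.full_like(lam, model.c10)
        s_fib = np.zeros_like(lam)
        for beta in model.fiber_angles:
            cb2 = math.cos(beta) ** 2
            sb2 = math.sin(beta) ** 2
            i4 = a2 * cb2 + b2 * sb2
            e = model.kappa * x + model.i4_coefficient * (i4 - 1.0)
            psi = np.where(
                e > 0.0, model.k1 * e * np.exp(model.k2 * np.minimum(e, 50.0) ** 2), 0.0
            )
            w1 = w1 + psi * model.kappa
            s_fib = s_fib + 2.0 * psi * model.i4_coefficient * a2 * cb2
        s = 2.0 * w1 * (a2 - c2) + s_fib
    else:
        raise ConfigurationError(f"unknown material model {model!r}")
    return s if np.ndim(s) else float(s)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def model_to_dict(model: MaterialModel) -> dict:
    """Flat key-value block (units: MPa, degrees) with a ``model`` tag."""
    tag = model.tag
    if tag == "mooney_rivlin5":
        return {
            "model": tag,
            "c10": model.c10,
            "c01": model.c01,
            "c20": model.c20,
            "c11": model.c11,
            "c02": model.c02,
            "d1": model.d1,
        }
    if tag == "yeoh3":
        return {"model": tag, "c10": model.c10, "c20": model.c20, "c30": model.c30}
    if tag == "ogden":
        return {
            "model": tag,
            "mu_p": [m for m, _ in model.terms],
            "alpha_p": [a for _, a in model.terms],
        }
    if tag == "hgo":
        return {
            "model": tag,
            "c10": model.c10,
            "k1": model.k1,
            "k2": model.k2,
            "kappa": model.kappa,
            "beta_deg": [math.degrees(b) for b in model.fiber_angles],
            "convention": model.convention,
        }
    if tag == "linear_elastic":
        return {"model": tag, "E": model.E, "nu": model.nu}
    raise ConfigurationError(f"unknown material model {model!r}")


def model_from_dict(block: dict) -> MaterialModel:
    """Inverse of :func:`model_to_dict`."""
    block = dict(block)
    tag = block.pop("model", None)
    if tag == "mooney_rivlin5":
        return MooneyRivlin5Params(
            c10=block["c10"],
            c01=block["c01"],
            c20=block["c20"],
            c11=block["c11"],
            c02=block["c02"],
            d1=block.get("d1", 0.0),
        )
    if tag == "yeoh3":
        return Yeoh3Params(c10=block["c10"], c20=block["c20"], c30=block["c30"])
    if tag == "ogden":
        return OgdenParams(terms=tuple(zip(block["mu_p"], block["alpha_p"])))
    if tag == "hgo":
        return HGOParams(
            c10=block["c10"],
            k1=block["k1"],
            k2=block["k2"],
            kappa=block["kappa"],
            fiber_angles=tuple(math.radians(b) for b in block.get("beta_deg", (45.0, -45.0))),
            convention=block.get("convention", "standard"),
        )
    if tag == "linear_elastic":
        return LinearElasticParams(E=block["E"], nu=block["nu"])
    raise ConfigurationError(f"unknown model tag {tag!r}")
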