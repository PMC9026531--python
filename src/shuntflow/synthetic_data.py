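"""Synthetic inputs for every pipeline stage.

No tensile records or patient geometries are distributed with the package, so
everything the pipeline consumes is generated here:

* uniaxial tensile datasets emulating PTFE (Gore-Tex) graft tests — a
  constitutive model curve plus seeded Gaussian stress noise, with specimen
  geometry metadata and an optional planted rupture point;
* the inlet velocity waveform of a pediatric cardiac cycle (systole 0.22 s,
  cycle 0.5 s, peak 1.4 m/s at 0.09 s) and a synthetic systemic outlet
  pressure profile (80-120 mmHg, phased with systole);
* idealized aorta--shunt--pulmonary-artery networks for the three modified
  Blalock-Taussig shunt placements: central (ascending aorta to pulmonary
  trunk), right (left subclavian to right pulmonary artery) and left
  (brachiocephalic trunk to left pulmonary artery).

Published graft and aortic wall constants used as generator defaults live in
this module (``YEOH_GRAFT_1`` etc.); all dimensions and shape numbers are
configurable.  Network dimensions are idealized pediatric values, not
patient-specific anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np

from .constitutive import (
    HGOParams,
    LinearElasticParams,
    MaterialModel,
    MooneyRivlin5Params,
    OgdenParams,
    Yeoh3Params,
    small_strain_shear_modulus,
    uniaxial_nominal_stress,
)
from .fitting import TensileDataset
from .hemodynamics import (
    MMHG_PA,
    Junction,
    OutletBC,
    Segment,
    VesselNetwork,
)

__all__ = [
    "YEOH_GRAFT_1",
    "YEOH_GRAFT_2",
    "MR5_GRAFT_1",
    "MR5_GRAFT_2",
    "OGDEN_AORTA",
    "LINEAR_SHUNT",
    "hgo_aorta_matched",
    "TensileGeneratorSpec",
    "generate_tensile",
    "InletWaveform",
    "default_waveform",
    "steady_inlet",
    "systemic_pressure_profile",
    "NetworkSpec",
    "build_network",
    "single_tube_network",
]

# ---------------------------------------------------------------------------
# published material constants (MPa)
# ---------------------------------------------------------------------------

#: Yeoh fits of two PTFE graft specimens (no.1: d=5 mm, h=0.5 mm;
#: no.2: d=3 mm, h=0.35 mm)
YEOH_GRAFT_1 = Yeoh3Params(c10=0.11, c20=-4.96e-6, c30=1.67e-10)
YEOH_GRAFT_2 = Yeoh3Params(c10=0.20, c20=-6.73e-6, c30=1.16e-10)

#: Five-parameter Mooney-Rivlin fits of the same specimens
MR5_GRAFT_1 = MooneyRivlin5Params(c10=-1.64, c01=2.59, c20=4.46e-7, c11=-2.39e-4, c02=0.44)
MR5_GRAFT_2 = MooneyRivlin5Params(c10=-2.2, c01=3.26, c20=3.86, c11=-8.6e-4, c02=0.62)

#: Two-term Ogden constants of the (isotropic) aortic wall
OGDEN_AORTA = OgdenParams(terms=((1.274, 24.074), (-1.211, 24.073)))

#: Linear-elastic graft reference (small-strain modulus of a 4.5 mm specimen)
LINEAR_SHUNT = LinearElasticParams(E=10.3, nu=0.49)


def hgo_aorta_matched(
    mu_target: float | None = None,
    k1: float = 0.5,
    k2: float = 5.0,
    kappa: float = 0.1,
    beta_deg: float = 45.0,
) -> HGOParams:
    """Anisotropic aortic wall with a stiffness-matched small-strain modulus.

    Published anisotropic aortic constants are not stated in the HGO (c10,
    k1, k2, kappa) parameterization, so the default anisotropic aorta is
    constructed here: two symmetric collagen-fiber families at +/- beta with
    moderate dispersion, whose ground-matrix c10 is chosen so the small-strain
    shear modulus equals ``mu_target`` (default: the isotropic Ogden aorta
    value).  Isotropic-vs-anisotropic scenario comparisons then isolate the
    effect of anisotropy rather than a bulk stiffness change.
    """
    if mu_target is None:
        mu_target = small_strain_shear_modulus(OGDEN_AORTA)
    beta = math.radians(beta_deg)
    probe = HGOParams(c10=1.0, k1=k1, k2=k2, kappa=kappa, fiber_angles=(beta, -beta))
    fiber_mu = small_strain_shear_modulus(probe) - 2.0
    c10 = (mu_target - fiber_mu) / 2.0
    if c10 <= 0:
        raise ValueError("fiber stiffness alone exceeds the target modulus")
    return HGOParams(c10=c10, k1=k1, k2=k2, kappa=kappa, fiber_angles=(beta, -beta))


# ---------------------------------------------------------------------------
# tensile-test generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TensileGeneratorSpec:
    """Recipe for one synthetic uniaxial tensile record.

    Stresses are the generating model's nominal-stress curve plus i.i.d.
    Gaussian noise of standard deviation ``noise_mpa`` (seeded).  If a rupture
    point (lam_f, sigma_y) is given it is appended as the terminal sample and
    must exceed every pre-rupture stress.
    """

    model: MaterialModel
    specimen_id: str = "synthetic"
    diameter_mm: float = 4.5
    thickness_mm: float = 0.35
    length_mm: float = 20.0
    stretch_max: float = 1.6
    n_samples: int = 100
    noise_mpa: float = 0.0
    rupture: tuple[float, float] | None = None  # (stretch, stress MPa)
    rate_mm_per_min: float = 30.0
    preload_mpa: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_mpa < 0:
            raise ValueError("noise must be non-negative")
        if not self.stretch_max > 1.0:
            raise ValueError("stretch grid must extend beyond 1")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")


def generate_tensile(spec: TensileGeneratorSpec) -> TensileDataset:
    """Draw one seeded tensile dataset from the generating model."""
    lam = np.linspace(1.0, spec.stretch_max, spec.n_samples)
    stress = np.asarray(uniaxial_nominal_stress(spec.model, lam), dtype=float)
    if spec.noise_mpa > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_mpa, size=lam.size)
    if spec.rupture is not None:
        lam_f, sigma_y = spec.rupture
        if lam_f <= lam[-1]:
            raise ValueError("rupture stretch must exceed the stretch grid")
        if sigma_y <= float(np.max(stress)):
            raise ValueError("rupture stress must exceed all pre-rupture stresses")
        lam = np.append(lam, lam_f)
        stress = np.append(stress, sigma_y)
    return TensileDataset(
        specimen_id=spec.specimen_id,
        diameter_mm=spec.diameter_mm,
        thickness_mm=spec.thickness_mm,
        length_mm=spec.length_mm,
        stretch=lam,
        stress=stress,
        rate_mm_per_min=spec.rate_mm_per_min,
        preload_mpa=spec.preload_mpa,
    )


# ---------------------------------------------------------------------------
# boundary-condition waveforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InletWaveform:
    """Periodic left-ventricular outflow velocity, m/s.

    Quarter-sine rise from the diastolic baseline to ``peak_velocity`` at
    ``t_peak``, smooth half-cosine fall back to baseline at end of systole,
    constant baseline through diastole; continuous periodic continuation.
    """

    period: float = 0.5
    systole: float = 0.22
    t_peak: float = 0.09
    peak_velocity: float = 1.4
    baseline_velocity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.t_peak < self.systole < self.period:
            raise ValueError("require 0 < t_peak < systole < period")
        if not self.peak_velocity >= self.baseline_velocity >= 0.0:
            raise ValueError("require peak >= baseline >= 0")

    def __call__(self, t) -> np.ndarray | float:
        tau = np.mod(np.asarray(t, dtype=float), self.period)
        vb, vp = self.baseline_velocity, self.peak_velocity
        rise = vb + (vp - vb) * np.sin(0.5 * np.pi * tau / self.t_peak)
        fall = vb + (vp - vb) * 0.5 * (
            1.0 + np.cos(np.pi * (tau - self.t_peak) / (self.systole - self.t_peak))
        )
        out = np.where(tau < self.t_peak, rise, np.where(tau < self.systole, fall, vb))
        return out if out.ndim else float(out)


def default_waveform() -> InletWaveform:
    """The default pediatric inlet waveform (cycle 0.5 s, peak 1.4 m/s)."""
    return InletWaveform()


@dataclass(frozen=True)
class _SteadyInlet:
    """Constant inlet velocity with a smooth start-up ramp (solver testing)."""

    velocity: float
    period: float = 0.5
    ramp: float = 0.1

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.ramp <= 0:
            out = np.full_like(t, self.velocity)
        else:
            s = np.clip(t / self.ramp, 0.0, 1.0)
            out = self.velocity * 0.5 * (1.0 - np.cos(np.pi * s))
        return out if out.ndim else float(out)


def steady_inlet(velocity: float, period: float = 0.5, ramp: float = 0.1) -> _SteadyInlet:
    return _SteadyInlet(velocity=velocity, period=period, ramp=ramp)


@dataclass(frozen=True)
class SystemicPressureProfile:
    """Synthetic aortic outlet pressure, mmHg sinusoid phased with systole.

    p(t) = mean - amplitude * cos(2 pi t / period): diastolic 80 mmHg at the
    cycle start, peak 120 mmHg mid-cycle.  Returns Pa.
    """

    period: float = 0.5
    low_mmhg: float = 80.0
    high_mmhg: float = 120.0

    def __call__(self, t) -> float:
        mean = 0.5 * (self.low_mmhg + self.high_mmhg)
        amp = 0.5 * (self.high_mmhg - self.low_mmhg)
        out = (mean - amp * np.cos(2.0 * np.pi * np.asarray(t, float) / self.period)) * MMHG_PA
        return out if np.ndim(out) else float(out)


def systemic_pressure_profile(period: float = 0.5) -> SystemicPressureProfile:
    return SystemicPressureProfile(period=period)


# ---------------------------------------------------------------------------
# network builder
# ---------------------------------------------------------------------------

# idealized pediatric dimensions, mm: (length, inner radius, wall thickness)
_DEFAULT_DIMS: dict[str, tuple[float, float, float]] = {
    "asc_aorta": (25.0, 6.0, 0.9),
    "arch_a": (12.0, 5.5, 0.85),
    "arch_b": (12.0, 5.0, 0.8),
    "desc_aorta": (60.0, 4.5, 0.75),
    "brachiocephalic": (12.0, 3.0, 0.5),
    "brachiocephalic_distal": (10.0, 2.8, 0.5),
    "l_carotid": (15.0, 2.5, 0.45),
    "l_subclavian": (10.0, 2.5, 0.45),
    "l_subclavian_distal": (10.0, 2.3, 0.45),
    "pa_trunk": (15.0, 4.0, 0.6),
    "rpa": (20.0, 3.0, 0.5),
    "lpa": (20.0, 3.0, 0.5),
}


@dataclass(frozen=True)
class NetworkSpec:
    """Configuration of the aorta--shunt--pulmonary-artery network.

    ``placement`` selects where the modified Blalock-Taussig shunt is
    inserted.  ``aorta_model`` picks the systemic/pulmonary wall description
    (isotropic Ogden or stiffness-matched anisotropic HGO) and
    ``shunt_model`` the graft wall (linear elastic or hyperelastic Yeoh).
    ``material_scale`` multiplies every wall constant (stiffness scaling for
    sensitivity studies).  Dimension overrides are (length, radius, thickness)
    triples in mm keyed by segment name.
    """

    placement: str = "central"  # central | right | left
    aorta_model: str = "ogden"  # ogden | hgo
    shunt_model: str = "linear"  # linear | yeoh
    shunt_diameter_mm: float = 3.5
    shunt_thickness_mm: float = 0.35
    shunt_length_mm: float = 20.0
    pulmonary_pressure_mmhg: float = 20.0
    anastomosis_loss: float = 1.0  # minor-loss K at both shunt anastomoses
    branch_resistance: float = 1.8e8  # Pa s/m^3, supra-aortic outlet terminations
    descending_resistance: float = 2.5e7  # Pa s/m^3, descending-aorta termination
    material_scale: float = 1.0
    dims_mm: dict = field(default_factory=dict)
    aorta_material: MaterialModel | None = None
    shunt_material: MaterialModel | None = None

    def __post_init__(self) -> None:
        if self.placement not in ("central", "right", "left"):
            raise ValueError(f"unknown shunt placement {self.placement!r}")
        if self.aorta_model not in ("ogden", "hgo"):
            raise ValueError(f"unknown aorta model {self.aorta_model!r}")
        if self.shunt_model not in ("linear", "yeoh"):
            raise ValueError(f"unknown shunt model {self.shunt_model!r}")


def _scale_material(model: MaterialModel, s: float) -> MaterialModel:
    if s == 1.0:
        return model
    tag = model.tag
    if tag == "ogden":
        return OgdenParams(terms=tuple((m * s, a) for m, a in model.terms))
    if tag == "yeoh3":
        return Yeoh3Params(c10=model.c10 * s, c20=model.c20 * s, c30=model.c30 * s)
    if tag == "hgo":
        return replace(model, c10=model.c10 * s, k1=model.k1 * s)
    if tag == "linear_elastic":
        return replace(model, E=model.E * s)
    if tag == "mooney_rivlin5":
        return MooneyRivlin5Params(
            c10=model.c10 * s,
            c01=model.c01 * s,
            c20=model.c20 * s,
            c11=model.c11 * s,
            c02=model.c02 * s,
            d1=model.d1,
        )
    raise ValueError(f"cannot scale {model!r}")


def build_network(spec: NetworkSpec) -> VesselNetwork:
    """Assemble the vessel network for one shunt placement.

    Topology (a directed tree rooted at the aortic root): ascending aorta ->
    arch with three supra-aortic branches -> descending aorta; the shunt
    leaves its placement-specific parent and feeds the pulmonary side, whose
    two terminal arteries end at constant-pressure outlets.  Systemic outlets
    carry the synthetic time-varying pressure profile.
    """
    aorta = spec.aorta_material or (
        OGDEN_AORTA if spec.aorta_model == "ogden" else hgo_aorta_matched()
    )
    shunt_mat = spec.shunt_material or (
        LINEAR_SHUNT if spec.shunt_model == "linear" else YEOH_GRAFT_2
    )
    aorta = _scale_material(aorta, spec.material_scale)
    shunt_mat = _scale_material(shunt_mat, spec.material_scale)

    dims = dict(_DEFAULT_DIMS)
    dims.update(spec.dims_mm)
    dims["shunt"] = (
        spec.shunt_length_mm,
        0.5 * spec.shunt_diameter_mm,
        spec.shunt_thickness_mm,
    )

    def seg(name: str, material: MaterialModel) -> Segment:
        L, r, h = dims[name]
        return Segment(
            name=name, length=L * 1e-3, radius=r * 1e-3, thickness=h * 1e-3, material=material
        )

    systemic = ["asc_aorta", "arch_a", "arch_b", "desc_aorta", "l_carotid"]
    pulmonary = ["pa_trunk", "rpa", "lpa"]
    K = spec.anastomosis_loss

    if spec.placement == "central":
        names = systemic + ["brachiocephalic", "l_subclavian", "shunt"] + pulmonary
        junctions = [
            Junction("asc_aorta", ("shunt", "brachiocephalic", "arch_a"), loss={"shunt": K}),
            Junction("arch_a", ("l_carotid", "arch_b")),
            Junction("arch_b", ("l_subclavian", "desc_aorta")),
            Junction("shunt", ("pa_trunk",), loss={"shunt": K}),
            Junction("pa_trunk", ("rpa", "lpa")),
        ]
        systemic_outlets = ["brachiocephalic", "l_carotid", "l_subclavian", "desc_aorta"]
        pulmonary_outlets = ["rpa", "lpa"]
    elif spec.placement == "right":
        names = systemic + [
            "brachiocephalic",
            "l_subclavian",
            "l_subclavian_distal",
            "shunt",
        ] + pulmonary
        junctions = [
            Junction("asc_aorta", ("brachiocephalic", "arch_a")),
            Junction("arch_a", ("l_carotid", "arch_b")),
            Junction("arch_b", ("l_subclavian", "desc_aorta")),
            Junction("l_subclavian", ("l_subclavian_distal", "shunt"), loss={"shunt": K}),
            Junction("shunt", ("rpa", "pa_trunk"), loss={"shunt": K}),
            Junction("pa_trunk", ("lpa",)),
        ]
        systemic_outlets = [
            "brachiocephalic",
            "l_carotid",
            "l_subclavian_distal",
            "desc_aorta",
        ]
        pulmonary_outlets = ["rpa", "lpa"]
    else:  # left
        names = systemic + [
            "brachiocephalic",
            "brachiocephalic_distal",
            "l_subclavian",
            "shunt",
        ] + pulmonary
        junctions = [
            Junction("asc_aorta", ("brachiocephalic", "arch_a")),
            Junction("brachiocephalic", ("brachiocephalic_distal", "shunt"), loss={"shunt": K}),
            Junction("arch_a", ("l_carotid", "arch_b")),
            Junction("arch_b", ("l_subclavian", "desc_aorta")),
            Junction("shunt", ("lpa", "pa_trunk"), loss={"shunt": K}),
            Junction("pa_trunk", ("rpa",)),
        ]
        systemic_outlets = [
            "brachiocephalic_distal",
            "l_carotid",
            "l_subclavian",
            "desc_aorta",
        ]
        pulmonary_outlets = ["rpa", "lpa"]

    segments = []
    for name in names:
        if name == "shunt":
            segments.append(seg(name, shunt_mat))
        elif name in pulmonary:
            segments.append(seg(name, aorta))  # pulmonary wall treated aorta-like
        else:
            segments.append(seg(name, aorta))

    # Systemic outlets: the synthetic 80-120 mmHg profile is the distal
    # reference of a resistive termination (peripheral vascular beds); a pure
    # prescribed-pressure outlet at several systemic branches of a lossless
    # junction tree admits parasitic recirculation loops in 1-D.
    sys_profile = systemic_pressure_profile()
    p_pa = spec.pulmonary_pressure_mmhg * MMHG_PA
    outlets = {
        name: OutletBC(
            "pressure",
            sys_profile,
            resistance=(
                spec.descending_resistance
                if name == "desc_aorta"
                else spec.branch_resistance
            ),
        )
        for name in systemic_outlets
    }
    outlets.update({name: OutletBC("pressure", p_pa) for name in pulmonary_outlets})
    return VesselNetwork(
        segments=segments,
        junctions=junctions,
        inlet="asc_aorta",
        outlets=outlets,
        shunt="shunt",
    )


def single_tube_network(
    material: MaterialModel,
    length: float = 0.1,
    radius: float = 2e-3,
    thickness: float = 3e-4,
    outlet: OutletBC | None = None,
    name: str = "tube",
) -> VesselNetwork:
    """A one-segment network (SI units) for solver validation studies."""
    segment = Segment(
        name=name, length=length, radius=radius, thickness=thickness, material=material
    )
    return VesselNetwork(
        segments=[segment],
        junctions=[],
        inlet=name,
        outlets={name: outlet or OutletBC("pressure", 0.0)},
        shunt=None,
    )
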