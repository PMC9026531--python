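# Methods

`shuntflow` models the mechanics and hemodynamics of the modified
Blalock–Taussig shunt (MBTS): a PTFE (Gore-Tex) conduit placed between a
systemic artery and the pulmonary circulation in cyanotic congenital heart
disease. The package covers three connected problems: (i) describing the
graft and aortic wall with incompressible hyperelastic constitutive models,
(ii) identifying those models from uniaxial tensile tests, and (iii)
propagating the constitutive choice into pulsatile hemodynamics of the
aorta–shunt–pulmonary-artery system with a reduced-order
fluid–structure-interaction (FSI) solver.

## Constitutive models

All wall materials are treated as exactly incompressible (J = 1, deviatoric
and total invariants coincide). Implemented strain-energy densities, with
stresses in MPa:

* **Five-parameter Mooney–Rivlin**
  W = c10(I1−3) + c01(I2−3) + c20(I1−3)² + c11(I1−3)(I2−3) + c02(I2−3)².
  Coefficient signs are unconstrained — fitted PTFE constants legitimately
  include negative c10 — so material stability over a working stretch window
  is a *reported diagnostic* (`drucker_stability_report`, which flags
  stretches where the uniaxial tangent dP/dλ ≤ 0), never a constructor
  constraint.
* **Three-parameter Yeoh** W = Σᵢ ci0 (I1−3)ⁱ with c10 > 0.
* **Ogden** (1–3 terms) W = Σₚ (μₚ/αₚ)(λ₁^αₚ + λ₂^αₚ + λ₃^αₚ − 3). With this
  normalisation the small-strain shear modulus is μ = ½ Σ μₚαₚ; one term
  with α = 2 is the neo-Hookean solid, and (α₁, α₂) = (2, −2) recovers the
  two-term Mooney–Rivlin material. These reductions are exercised as exact
  identities in the tests.
* **Holzapfel–Gasser–Ogden (HGO)** for the anisotropic arterial wall:
  W = c10(I1−3) + (k1/2k2) Σ_α [exp(k2⟨Ē_α⟩²) − 1], with the dispersed-fiber
  strain Ē_α = κ(I1−3) + (1−3κ)(I4_α−1) and a tension-only Macaulay bracket.
  κ ∈ [0, 1/3] measures fiber dispersion: κ = 0 is perfectly aligned,
  κ = 1/3 makes the Ī4 coefficient vanish and the response isotropic. Some
  printings of the fiber-strain formula carry (1+3κ) instead of (1−3κ); that
  variant contradicts the κ = 1/3 isotropy limit, so (1−3κ) is the default
  and the as-printed form is available behind the `convention="as_printed"`
  switch. The orientation-density integral defining κ is documented but not
  evaluated — κ is a direct input. Two symmetric fiber families at ±45° from
  the circumferential direction are the default; the angle is configurable
  because the source experiments report none.
* **Linear elastic** (E, ν) as the graft reference model.

The small-strain shear modulus of the HGO model deserves a note: the
Macaulay bracket makes the fiber stiffness one-sided at the reference state.
The value returned is the two-sided average tangent — what a central
difference across λ = 1 measures — with each family contributing
k1((1−3κ)(2cos²β − sin²β))²/6.

Uniaxial nominal (first Piola) stress P(λ) = dW/dλ is evaluated in closed
form along the incompressible uniaxial path (λ, λ^−½, λ^−½), with the
transverse stress-free condition eliminated analytically; P(1) = 0 exactly.
A central-difference differentiator of W serves as the independent oracle in
the tests (tolerance 1e−6 relative away from the stress-free point, where
relative error is undefined and the identity P(1) = 0 is asserted exactly).

## Fitting

Constants are identified from tensile records (stretch vs nominal stress,
MPa, on the undeformed cross-section — the convention of tensile-machine
output) by bounded nonlinear least squares in stress space
(`scipy.optimize.least_squares`, trust-region reflective), with a
16-point Latin-hypercube multi-start (seed 20220407 by default) over the
bounds: |c| ≤ 10 MPa for Mooney–Rivlin/Yeoh coefficients, |α| ≤ 30 for Ogden
exponents, k2 ∈ (0, 100], κ ∈ [0, 1/3].

Success is declared in **curve space**, not parameter space: a single
uniaxial path cannot identify all five Mooney–Rivlin parameters (the
near-zero and wildly specimen-dependent c20/c11 values of published fits
illustrate the same degeneracy). The fit result therefore carries the
Jacobian condition number at the solution and per-parameter identifiability
flags, raised when the condition number exceeds the configured threshold.
The default threshold is 1e3, a conservative practical-non-identifiability
cutoff in the spirit of collinearity condition indices; both linear-in-
parameter families have data-independent conditioning (Yeoh ≈ 23,
five-parameter Mooney–Rivlin ≈ 1e4 on a typical uniaxial grid), so the
five-parameter family always flags and Yeoh never does.

Preload handling: stresses are shifted so the record starts at the stated
preload and stretch is re-referenced to the preloaded state. Load rate is
metadata only (the source tests found the response rate-insensitive between
50 and 250 mm/min). The small-strain modulus is an origin-constrained OLS
slope over λ ≤ 1.05 (configurable); ultimate strength is the record maximum
with a "no rupture detected" flag for monotone records.

## Synthetic data

No tensile records or patient geometry are deposited anywhere, so the
`synthetic_data` module generates every input:

* **Tensile records**: closed-form model curve plus i.i.d. Gaussian stress
  noise (seeded `numpy` Generator), defaults n = 100 samples over
  λ ∈ [1, 1.6], noise 0.05 MPa — a few percent of the stress scale, typical
  of soft-polymer tensile benches. Specimen geometry defaults to a 4.5 mm /
  0.35 mm wall graft; a rupture point can be planted as the terminal sample.
* **Inlet waveform**: pediatric left-ventricular outflow velocity — cycle
  0.5 s, systole 0.22 s, quarter-sine rise to the 1.4 m/s peak at 0.09 s,
  half-cosine fall to the diastolic baseline (default 0 m/s, configurable
  floor), periodic and continuous. The shape is a smooth idealization; the
  five shape numbers are all configurable.
* **Systemic outlet pressure**: 80–120 mmHg sinusoid phased with systole
  (diastolic 80 at cycle start), since no numeric profile is published.
* **Networks**: idealized pediatric aorta–shunt–pulmonary-artery trees for
  the three MBTS placements — central (ascending aorta → pulmonary trunk),
  right (left subclavian → right pulmonary artery), left (brachiocephalic →
  left pulmonary artery). Default dimensions are idealized pediatric values
  (aortic radius 6 mm, shunt 3.5 mm diameter / 0.35 mm wall), all
  configurable; they are *not* patient CT geometry, and no statistical
  anatomy emulation is attempted.

Wall material assignments: aorta and pulmonary artery share either the
isotropic two-term Ogden set (μ1 = 1.274, α1 = 24.074, μ2 = −1.211,
α2 = 24.073 MPa; small-strain shear modulus ≈ 0.759 MPa) or an anisotropic
HGO set; the shunt is either linear elastic (E = 10.3 MPa, ν = 0.49) or the
hyperelastic Yeoh fit of the 3 mm graft specimen. Published anisotropic
aortic constants are not stated in the HGO (c10, k1, k2, κ)
parameterization, so the default anisotropic aorta is *constructed*:
moderate dispersion (κ = 0.1), two families at ±45°, k1 = 0.5 MPa, k2 = 5,
and c10 chosen so the small-strain shear modulus equals the isotropic Ogden
value. Isotropic-vs-anisotropic comparisons therefore isolate anisotropy
rather than a bulk stiffness change; this is a design choice of the package,
documented here because the underlying parameter mapping is ambiguous.

## Reduced-order hemodynamics

The solver realizes the incompressible Newtonian FSI problem (blood density
1060 kg/m³, viscosity 3.5 mPa·s — a constant-viscosity rheology; a
generalized η(γ̇) hook is deliberately out of scope) as the classical 1-D
area–flow system per segment,

    A_t + Q_x = 0,
    Q_t + (αQ²/A)_x + (A/ρ) p_x = −8πν Q/A,

with the parabolic-profile closure (momentum-flux coefficient α = 4/3,
Poiseuille friction). The wall enters through an algebraic tube law from
thin-walled quasi-static equilibrium of the incompressible wall at fixed
axial stretch (wall inertia dropped; interface displacement/velocity/
traction matching is then satisfied by construction):

    p(A) = σθ(λ) · (h/λ) / (λ r0),   λ = √(A/A0),

where σθ is the circumferential Cauchy stress of the assigned material under
plane stress and h/λ the deformed thickness. This is the energy-consistent
membrane law (p = d/dA of the wall strain energy per unit length — an oracle
the tests exercise at 1e−6) and reproduces the Moens–Korteweg speed
c = √(Eh/(2ρr0(1−ν²))) exactly in the linearized linear-elastic limit. A
consequence worth noting: a linear-elastic hoop law has a pressure limit
point near λ = 2 from wall thinning; tube laws verify dp/dA > 0 over an
admissible window (default λ ∈ [0.5, 1.8]) at construction and the solver
guards the valid branch at run time.

Numerics: explicit two-step MacCormack (second order in the interior),
adaptive time step at CFL 0.8 against λ_max = |u| + c, c = √(A p'(A)/ρ).
Constitutive responses are sampled once per tube law onto a shared dense
stretch grid (4096 points, derivative by central differencing of the closed
form) so in-loop evaluations are O(1) table lookups. Boundary and junction
states are closed with linearly interpolated characteristic invariants
W± = u ± f(A), f(A) = ∫ c/a da, including the friction source along the
characteristic path.

Junctions conserve mass exactly (Newton solve per step, analytic Jacobian,
residual tolerance ~1e−11 scaled) and impose continuity of total pressure
p + ½ρu², with an optional per-member minor-loss term ½Kρu|u|. Two losses
are assigned by the network builder at the shunt anastomoses (K = 1 at entry
and exit): a 3.5 mm conduit joined abruptly to vessels several times its
calibre dissipates its dynamic head there, and without this surrogate for
the 3-D anastomosis losses the energy-conserving 1-D junctions would
predict order-50 m/s shunt jets limited only by wall friction. With K = 1
the model produces shunt velocities of 2.5–3.5 m/s and shunt flows around
1.8 L/min at an 80–120/20 mmHg systemic/pulmonary split — the clinically
familiar range for an MBTS — along with diastolic systemic runoff.

Boundary conditions follow the source problem: prescribed inlet velocity
waveform at the aortic root; constant 20 mmHg at the pulmonary outlets;
the 80–120 mmHg profile at systemic outlets. One departure, made after
observing the failure mode: several *pure* prescribed-pressure systemic
outlets on a lossless junction tree admit a parasitic recirculation loop
(sustained ±25 m/s circulation through the arch with no damping mechanism),
so systemic outlets are terminated by a peripheral resistance whose distal
reference is the 80–120 mmHg profile (branches 1.8e8, descending aorta
2.5e7 Pa·s/m³ — chosen for a physiologic flow split at pediatric cardiac
output). `OutletBC(resistance=0)` recovers the pure prescribed-pressure
outlet; a non-reflecting outlet exists for validation runs.

Runs march whole cardiac cycles until the cycle-to-cycle relative L2 change
of (A, Q) falls below a tolerance (default 1e−3; the strongly pinned
boundary conditions reach ~1e−4–1e−7 by cycle 3) or a cycle cap is hit;
solutions carry a `converged` flag, and metrics refuse unconverged input.
A per-cycle volume budget (inflow, outflow, stored volume at full step
resolution) is attached to every solution. On the classical validation
configurations the cycle inflow–outflow balance closes to ≤1e−6 of cycle
inflow at 2.5 mm resolution; on the full default network the closure error
of the boundary characteristic treatment is ≈2e−5 of cycle inflow at the
default 10 mm resolution (second-order in Δx).

Default problem sizes were chosen for desk-scale runs: Δx = 10 mm
(minimum 4 nodes per segment), ≤6 cycles, ~3,600 steps per cycle on the
default network (≈20 s per scenario on one core). The grid-refinement study
(Δx = 10/5/2.5 mm, 3 fixed cycles) shows monotone peak-pressure refinement
with empirical order ≈1 — boundary/junction closures are first order, the
interior second order.

## Metrics and scenario comparison

From (A, Q, p): wall shear stress τw = 4μQ/(πR³) with deformed R = √(A/π)
(signed with the flow; the parabolic closure is a lower-fidelity analogue of
3-D near-wall gradients); TAWSS as the final-cycle mean of |τw| — the
averaging window and magnitude convention are a package choice since no
definition is printed in the source; thin-wall biaxial von Mises stress
σvm = (√3/2)·pR/h in kPa; radial displacement √(A/π) − √(A0/π) in mm; and
the shunt mid-segment flow series with cycle mean/peak in mL/min.

`compare_scenarios` runs a (aorta model × shunt model × placement) matrix
and reports per-cell metrics plus pairwise deviations; the relative
deviation between two cycles is max_t|x1−x2| / max(|x1|, |x2|, 1e−12),
symmetric up to sign in the choice of baseline. Unconverged or failing cells
produce explicit status rows, not an aborted report.

Because the geometry is idealized and the order reduced, scenario effects
are validated as *directions and orderings*, never magnitudes: swapping the
aorta from isotropic Ogden to stiffness-matched anisotropic HGO perturbs the
shunt-flow cycle most strongly for the central placement (the shunt then
hangs directly on the reconfigured wall); scaling all wall constants ×10
reduces peak radial displacement about tenfold and raises pulse-wave speed.
The 3-D patient-specific magnitudes (~200 vs ~150 kPa wall-stress maxima,
the 12% central shunt-flow deviation, ~20% descending-aorta WSS difference)
depend on anatomy and bending stress concentrations that a 1-D model cannot
and does not claim to reproduce.

## What passing tests do and do not show

The synthetic tensile generator draws from the same model families the
fitter estimates, with homoskedastic Gaussian noise: recovery tests
demonstrate the estimator is correct and well-conditioned where
identifiable, not that PTFE follows a Yeoh law. The network generator uses
idealized straight segments: solver tests demonstrate conservation,
convergence and classical limits, not patient-specific prediction.
Curvature, tapering, anastomosis angles, wall viscoelasticity, damage and
thrombus growth are all out of scope.

## Numerical edge cases

Tie-breaks and degenerate inputs are handled as follows: ultimate strength
of an all-zero record returns 0 with the no-rupture flag; fits with fewer
samples than max(parameters+1, 8) are precondition errors; Ogden starts with
|α| < 0.5 are nudged to 2 to avoid the degenerate α = 0 axis; junction
Newton steps are clamped to |Δλ| ≤ 0.05 and a solve that stalls below 1e−6
scaled residual is accepted mid-transient rather than aborting (the maximum
residual is reported on the solution); areas leaving the tabulated stretch
range or the monotone pressure branch raise a solver error naming the
segment.
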