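"""Reduced-order pulsatile hemodynamics of compliant vessel networks.

The three-dimensional fluid-structure interaction problem (incompressible
Newtonian blood in hyperelastic vessels, with matched interface displacement,
velocity and traction) is reduced to the classical 1-D area-flow (A, Q)
system per vessel segment:

    dA/dt + dQ/dx = 0
    dQ/dt + d(alpha Q^2/A)/dx + (A/rho) dp/dx = -8 pi (mu/rho) Q/A

with a parabolic (Poiseuille) velocity profile, giving the momentum-flux
coefficient alpha = 4/3 and the friction term above.  The wall momentum
balance enters through an algebraic tube law p(A): thin-walled quasi-static
equilibrium of the incompressible wall at fixed axial stretch,

    p(A) = (h / r) sigma_theta(lam),   lam = sqrt(A/A0),  r = lam r0,

where sigma_theta is the circumferential Cauchy stress of the assigned
constitutive model under plane stress (wall inertia is dropped; the interface
conditions are then satisfied by construction of the tube law and the no-slip
consistent friction closure).  For a linear-elastic wall this reduces to
p = (E h / (1 - nu^2)) (lam - 1) / r and reproduces the Moens-Korteweg pulse
wave speed c = sqrt(E h / (2 rho r0 (1 - nu^2))) in the linearized limit.

Integration is an explicit second-order MacCormack predictor-corrector with
adaptive time step at a fixed CFL number against the local wave speed
c = sqrt(A (dp/dA) / rho).  Junctions conserve mass exactly and impose
continuity of total pressure p + rho u^2 / 2, with an optional per-member
minor-loss coefficient (used at the shunt anastomoses, where the abrupt
calibre change dissipates dynamic head).  Boundary conditions: prescribed
inlet velocity waveform, prescribed (possibly time-varying) outlet pressure,
or a non-reflecting outlet.  Everything is deterministic.

Internally SI units are used throughout; constitutive models speak MPa and
are converted at the tube-law boundary.  1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constitutive import MaterialModel, plane_stress_hoop_stress

__all__ = [
    "MMHG_PA",
    "MPA_PA",
    "FluidProperties",
    "TubeLaw",
    "TubeLawStabilityError",
    "SolverError",
    "tube_law_from_material",
    "Segment",
    "Junction",
    "OutletBC",
    "VesselNetwork",
    "SolverOptions",
    "SegmentSolution",
    "FlowSolution",
    "solve_pulsatile",
    "shunt_flow_series",
    "ShuntFlow",
]

MMHG_PA = 133.322
MPA_PA = 1e6

# shared stretch grid for all tube-law tables (uniform => O(1) interpolation)
_LAM_LO, _LAM_HI, _LAM_N = 0.35, 2.3, 4096
_LAM_GRID = np.linspace(_LAM_LO, _LAM_HI, _LAM_N)
_LAM_D = _LAM_GRID[1] - _LAM_GRID[0]


class TubeLawStabilityError(ValueError):
    """dp/dA is non-positive somewhere in the admissible stretch range."""


class SolverError(RuntimeError):
    """The time integration failed (CFL floor, negative area, junction solve)."""


@dataclass(frozen=True)
class FluidProperties:
    """Blood density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1060.0
    viscosity: float = 0.0035

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.viscosity > 0):
            raise ValueError("density and viscosity must be positive")


class TubeLaw:
    """Algebraic pressure-area law of a thin incompressible vessel wall.

    Parameters
    ----------
    material:
        Any constitutive model from :mod:`shuntflow.constitutive`.
    A0, h:
        Reference lumen area (m^2) and wall thickness (m).
    axial_stretch:
        Fixed axial pre-stretch (only 1.0 is exercised by the pipeline).
    admissible:
        Stretch window over which elastic stability (dp/dA > 0) is verified
        at construction.
    """

    def __init__(
        self,
        material: MaterialModel,
        A0: float,
        h: float,
        axial_stretch: float = 1.0,
        admissible: tuple[float, float] = (0.5, 1.8),
    ):
        if not (A0 > 0 and h > 0):
            raise ValueError("A0 and h must be positive")
        self.material = material
        self.A0 = float(A0)
        self.h = float(h)
        self.r0 = math.sqrt(A0 / math.pi)
        self.axial_stretch = float(axial_stretch)

        lam = _LAM_GRID
        sigma = np.asarray(
            plane_stress_hoop_stress(material, lam, self.axial_stretch), dtype=float
        ) * MPA_PA
        # Laplace equilibrium with the *deformed* wall thickness h/lam (the
        # wall is incompressible and axially fixed): p = sigma * (h/lam)/(lam r0).
        # This is the energy-consistent membrane law, p = dE_wall/dA with
        # E_wall = 2 pi r0 h W(lam) per unit length, and it preserves the
        # Moens-Korteweg limit.
        self._p_tab = self.h * sigma / (lam**2 * self.r0)

        def p_of(lam_v):
            s = np.asarray(
                plane_stress_hoop_stress(material, lam_v, self.axial_stretch), float
            )
            return self.h * s * MPA_PA / (lam_v**2 * self.r0)

        eps = 1e-6
        dp_dlam = (p_of(lam + eps) - p_of(lam - eps)) / (2.0 * eps)
        self._dpdA_tab = dp_dlam / (2.0 * lam * self.A0)

        lo, hi = admissible
        mask = (lam >= lo) & (lam <= hi)
        bad = mask & (self._dpdA_tab <= 0.0)
        if np.any(bad):
            raise TubeLawStabilityError(
                f"dp/dA <= 0 at circumferential stretch {lam[bad][0]:.4f} "
                f"for {material.tag} wall"
            )
        # monotone prefix of p(lam), used for pressure -> area inversion
        # (some laws reach a limit point from wall thinning beyond lam ~ 2)
        incr = np.diff(self._p_tab) > 0.0
        stop = int(np.argmin(incr)) + 1 if not incr.all() else _LAM_N
        self._mono_n = max(stop, 2)

    # vectorized table lookups --------------------------------------------
    def _lam(self, A) -> np.ndarray:
        return np.sqrt(np.asarray(A, float) / self.A0)

    def pressure(self, A) -> np.ndarray:
        """Transmural pressure (Pa) at lumen area A (m^2); p(A0) = 0.

        Evaluated from the closed-form wall response (the solver's internal
        tables are a consistent sampled copy).
        """
        lam = self._lam(A)
        sigma = plane_stress_hoop_stress(self.material, lam, self.axial_stretch)
        out = self.h * np.asarray(sigma) * MPA_PA / (lam**2 * self.r0)
        return out if np.ndim(out) else float(out)

    def pressure_of_lam(self, lam):
        out = np.interp(lam, _LAM_GRID, self._p_tab)
        return out if np.ndim(out) else float(out)

    def dpdA(self, A) -> np.ndarray:
        out = np.interp(self._lam(A), _LAM_GRID, self._dpdA_tab)
        return out if np.ndim(out) else float(out)

    def area_of_pressure(self, p) -> float:
        """Inverse law A(p) by table inversion over the monotone branch."""
        n = self._mono_n
        lam = np.interp(p, self._p_tab[:n], _LAM_GRID[:n])
        return lam**2 * self.A0


def tube_law_from_material(
    material: MaterialModel, A0: float, h: float, axial_stretch: float = 1.0
) -> TubeLaw:
    """Build the thin-wall pressure-area law for a segment material."""
    return TubeLaw(material, A0, h, axial_stretch)


# ---------------------------------------------------------------------------
# network description
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """One vessel segment (SI units: m)."""

    name: str
    length: float
    radius: float
    thickness: float
    material: MaterialModel

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.radius > 0 and self.thickness > 0):
            raise ValueError(f"segment {self.name}: dimensions must be positive")

    @property
    def A0(self) -> float:
        return math.pi * self.radius**2


@dataclass
class Junction:
    """Distal end of ``parent`` feeds the proximal ends of ``children``.

    ``loss`` maps member name (parent or child) to a dimensionless minor-loss
    coefficient K; the lost head is K * rho * u |u| / 2 of that member's
    velocity.  Default: lossless total-pressure continuity.
    """

    parent: str
    children: tuple[str, ...]
    loss: dict = field(default_factory=dict)


@dataclass
class OutletBC:
    """Outlet boundary: (time-varying) pressure, optionally behind a
    peripheral resistance, or non-reflecting.

    With ``resistance`` R > 0 the boundary enforces p = p_ref(t) + R Q,
    i.e. the prescribed pressure is the distal reference of a resistive
    termination.  R = 0 recovers the pure prescribed-pressure outlet.
    """

    kind: str  # "pressure" | "nonreflecting"
    pressure: float | Callable[[float], float] | None = None
    resistance: float = 0.0  # Pa s / m^3

    def __post_init__(self) -> None:
        if self.kind not in ("pressure", "nonreflecting"):
            raise ValueError(f"unknown outlet kind {self.kind!r}")
        if self.kind == "pressure" and self.pressure is None:
            raise ValueError("pressure outlet requires a value or callable")
        if self.resistance < 0:
            raise ValueError("outlet resistance must be non-negative")

    def value(self, t: float) -> float:
        if callable(self.pressure):
            return float(self.pressure(t))
        return float(self.pressure or 0.0)


class VesselNetwork:
    """Directed tree of compliant segments from one inlet to the outlets."""

    def __init__(
        self,
        segments: Sequence[Segment],
        junctions: Sequence[Junction],
        inlet: str,
        outlets: dict[str, OutletBC],
        shunt: str | None = None,
    ):
        self.segments = {s.name: s for s in segments}
        if len(self.segments) != len(segments):
            raise ValueError("duplicate segment names")
        self.junctions = list(junctions)
        self.inlet = inlet
        self.outlets = dict(outlets)
        self.shunt = shunt
        self._validate()

    def _validate(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.segments)
        for j in self.junctions:
            if j.parent not in self.segments:
                raise ValueError(f"junction parent {j.parent!r} unknown")
            for c in j.children:
                if c not in self.segments:
                    raise ValueError(f"junction child {c!r} unknown")
                g.add_edge(j.parent, c)
        if self.inlet not in self.segments:
            raise ValueError(f"inlet segment {self.inlet!r} unknown")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("network contains a cycle")
        if len(self.segments) > 1 and not nx.is_weakly_connected(g):
            raise ValueError("network is not connected")
        for name in self.segments:
            preds = list(g.predecessors(name))
            if name == self.inlet:
                if preds:
                    raise ValueError("inlet segment cannot have a parent")
            elif len(preds) != 1:
                raise ValueError(f"segment {name!r} must have exactly one parent")
        leaves = {n for n in g.nodes if g.out_degree(n) == 0}
        if set(self.outlets) != leaves:
            raise ValueError(
                f"outlet BCs {sorted(self.outlets)} do not match terminal "
                f"segments {sorted(leaves)}"
            )
        if self.shunt is not None and self.shunt not in self.segments:
            raise ValueError(f"shunt segment {self.shunt!r} unknown")
        self._graph = g

    def downstream_outlets(self, name: str) -> list[str]:
        import networkx as nx

        return [o for o in self.outlets if nx.has_path(self._graph, name, o)]

    def path(self, src: str, dst: str) -> list[str]:
        import networkx as nx

        return nx.shortest_path(self._graph, src, dst)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverOptions:
    """Explicit-scheme configuration.

    dx is a target spatial step (m); each segment uses at least ``min_nodes``
    grid points.  The run stops early once the cycle-to-cycle L2 change of
    pressure and flow drops below ``convergence_tol`` (relative), after at
    least two full cycles.
    """

    cfl: float = 0.8
    dx: float = 0.01
    min_nodes: int = 4
    n_cycles: int = 8
    convergence_tol: float = 1e-3
    save_per_cycle: int = 256
    alpha: float = 4.0 / 3.0  # parabolic-profile momentum-flux coefficient
    dt_floor: float = 1e-9
    junction_tol: float = 1e-11
    junction_max_iter: int = 40


@dataclass
class SegmentSolution:
    """Saved time series for one segment on its node grid."""

    name: str
    x: np.ndarray  # (nx,)
    A: np.ndarray  # (nt, nx) m^2
    Q: np.ndarray  # (nt, nx) m^3/s
    p: np.ndarray  # (nt, nx) Pa
    A0: float
    h: float
    r0: float


@dataclass
class FlowSolution:
    """Network solution sampled on a (slightly non-uniform) time grid."""

    t: np.ndarray
    segments: dict[str, SegmentSolution]
    period: float
    converged: bool
    residual_history: list
    n_cycles_run: int
    network: VesselNetwork
    fluid: FluidProperties
    options: SolverOptions
    n_steps: int = 0
    junction_residual_max: float = 0.0
    #: per completed cycle: dict(inflow_m3, outflow_m3, stored_start_m3,
    #: stored_end_m3) accumulated at full time-step resolution
    volume_budget: list = field(default_factory=list)

    def final_cycle_mask(self) -> np.ndarray:
        """Samples belonging to the last completed cycle."""
        t_end = self.n_cycles_run * self.period
        return (self.t > t_end - self.period + 1e-12) & (self.t <= t_end + 1e-12)


class _SegState:
    """Runtime state and precomputed tables for one segment."""

    def __init__(self, seg: Segment, fluid: FluidProperties, opts: SolverOptions):
        self.name = seg.name
        self.tube = tube_law_from_material(seg.material, seg.A0, seg.thickness)
        n = max(opts.min_nodes, int(round(seg.length / opts.dx)) + 1)
        self.n = n
        self.x = np.linspace(0.0, seg.length, n)
        self.dx = self.x[1] - self.x[0]
        self.A0 = seg.A0
        rho = fluid.density
        self.c_tab = np.sqrt(
            np.maximum(_LAM_GRID**2 * seg.A0 * self.tube._dpdA_tab, 0.0) / rho
        )
        # Riemann function f(lam) = int_{A0}^{A} c/a da = int_1^lam 2 c / l dl
        integrand = 2.0 * self.c_tab / _LAM_GRID
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * _LAM_D)]
        )
        i1 = int(np.searchsorted(_LAM_GRID, 1.0))
        f1 = np.interp(1.0, _LAM_GRID, cum)
        self.f_tab = cum - f1
        self.fric = 8.0 * math.pi * fluid.viscosity / rho
        # runtime validity ceiling: table edge, or the wall's limit point
        self.lam_hi = float(_LAM_GRID[min(self.tube._mono_n, _LAM_N) - 1]) - 2e-3
        # state
        self.A = np.full(n, seg.A0)
        self.Q = np.zeros(n)

    def lam(self) -> np.ndarray:
        return np.sqrt(self.A / self.A0)

    def interp(self, tab: np.ndarray, lam) -> np.ndarray:
        return np.interp(lam, _LAM_GRID, tab)

    def lam_from_f(self, fval: float) -> float:
        return float(np.interp(fval, self.f_tab, _LAM_GRID))

    def lam_from_p(self, pval: float) -> float:
        n = self.tube._mono_n
        return float(np.interp(pval, self.tube._p_tab[:n], _LAM_GRID[:n]))


class _JuncState:
    """Stacked tables and Newton state for one junction."""

    def __init__(self, junc: Junction, segs: dict[str, "_SegState"], rho: float):
        self.parent = segs[junc.parent]
        self.children = [segs[c] for c in junc.children]
        members = [self.parent] + self.children
        self.m = len(members)
        self.P = np.vstack([s.tube._p_tab for s in members])
        self.F = np.vstack([s.f_tab for s in members])
        self.C = np.vstack([s.c_tab for s in members])
        self.A0v = np.array([s.A0 for s in members])
        self.K = np.array(
            [junc.loss.get(s.name, 0.0) for s in members]
        )
        self.sgn = np.array([-1.0] + [1.0] * (self.m - 1))  # u = W + sgn * f
        self.rho = rho
        self.lam = np.ones(self.m)
        self.rows = np.arange(self.m)

    def _lookup(self, lam: np.ndarray):
        pos = np.clip((lam - _LAM_LO) / _LAM_D, 0.0, _LAM_N - 1.001)
        i = pos.astype(int)
        fr = pos - i
        r = self.rows
        p = self.P[r, i] * (1 - fr) + self.P[r, i + 1] * fr
        f = self.F[r, i] * (1 - fr) + self.F[r, i + 1] * fr
        c = self.C[r, i] * (1 - fr) + self.C[r, i + 1] * fr
        return p, f, c

    def solve(self, W: np.ndarray, tol: float, max_iter: int):
        """Newton solve for end stretches given characteristic invariants W."""
        lam = self.lam.copy()
        rho = self.rho
        m = self.m
        scale_q = max(float(np.max(self.A0v)), 1e-8)
        jac = np.zeros((m, m))
        for it in range(max_iter):
            p, f, c = self._lookup(lam)
            u = W + self.sgn * f
            A = lam**2 * self.A0v
            q = A * u
            tot = p + 0.5 * rho * u * u + self.sgn * 0.5 * self.K * rho * u * np.abs(u)
            res = np.empty(m)
            res[0] = q[0] - q[1:].sum()
            res[1:] = tot[0] - tot[1:]
            err = abs(res[0]) / scale_q + np.abs(res[1:]).sum() / (rho * 1.0e2)
            if err < tol:
                self.lam = lam
                return lam, u, A, err
            du = self.sgn * 2.0 * c / lam
            dq = 2.0 * lam * self.A0v * u + A * du
            dp = 2.0 * rho * c * c / lam
            dtot = dp + rho * u * du + self.sgn * self.K * rho * np.abs(u) * du
            jac[:, :] = 0.0
            jac[0, 0] = dq[0]
            jac[0, 1:] = -dq[1:]
            jac[1:, 0] = dtot[0]
            jac[self.rows[1:], self.rows[1:]] = -dtot[1:]
            try:
                step = np.linalg.solve(jac, res)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SolverError(f"singular junction Jacobian at {self.parent.name}") from exc
            step = np.clip(step, -0.05, 0.05)
            lam = np.clip(lam - step, _LAM_LO + 1e-6, _LAM_HI - 1e-6)
        # accept a slightly loose solve rather than abort mid-transient
        if err < 1e-6:
            self.lam = lam
            return lam, u, A, err
        raise SolverError(
            f"junction at parent {self.parent.name!r} failed to converge (err={err:.3e})"
        )


def _foot_interp(w_end: float, w_prev: float, xi: float) -> float:
    xi = min(max(xi, 0.0), 1.0)
    return (1.0 - xi) * w_end + xi * w_prev


def solve_pulsatile(
    network: VesselNetwork,
    fluid: FluidProperties,
    inlet,
    options: SolverOptions | None = None,
    initial_pressures: dict[str, float] | None = None,
) -> FlowSolution:
    """March the 1-D network through repeated cardiac cycles.

    ``inlet`` must be callable, v(t) in m/s, with a ``period`` attribute in
    seconds (e.g. :class:`shuntflow.synthetic_data.InletWaveform`).  Runs for
    at most ``options.n_cycles`` cycles, stopping early when the
    cycle-to-cycle relative L2 change of pressure and flow falls below
    ``options.convergence_tol``; the returned solution is flagged
    ``converged`` accordingly.
    """
    opts = options or SolverOptions()
    rho = fluid.density
    T = float(inlet.period)

    segs = {name: _SegState(seg, fluid, opts) for name, seg in network.segments.items()}
    juncs = [_JuncState(j, segs, rho) for j in network.junctions]

    # quasi-static initialisation: each segment at the mean pressure of its
    # reachable outlets (non-reflecting outlets contribute 0)
    init = initial_pressures or {}
    for name, st in segs.items():
        if name in init:
            p0 = init[name]
        else:
            vals = [
                network.outlets[o].value(0.0)
                if network.outlets[o].kind == "pressure"
                else 0.0
                for o in network.downstream_outlets(name)
            ]
            p0 = float(np.mean(vals)) if vals else 0.0
        lam0 = st.lam_from_p(p0)
        st.A[:] = lam0**2 * st.A0
        st.Q[:] = 0.0
    for j in juncs:
        j.lam = np.array([s.lam()[0] for s in [j.parent] + j.children])

    inlet_seg = segs[network.inlet]
    order = list(segs.values())

    t = 0.0
    n_steps = 0
    max_jerr = 0.0
    save_dt = T / opts.save_per_cycle
    next_save = 0.0
    t_saved: list[float] = []
    saved: dict[str, list[np.ndarray]] = {name: [] for name in segs}

    def record():
        t_saved.append(t)
        for name, st in segs.items():
            saved[name].append(np.concatenate([st.A, st.Q]))

    record()
    next_save = save_dt

    residual_history: list[tuple[int, float]] = []
    converged = False
    cycles_done = 0
    t_end = opts.n_cycles * T

    def total_volume() -> float:
        return sum(float(np.trapezoid(s.A, dx=s.dx)) for s in order)

    volume_budget: list[dict] = []
    v_in_acc = 0.0
    v_out_acc = 0.0
    stored_start = total_volume()

    while t < t_end - 1e-12:
        # wave speeds and time step
        dt = np.inf
        fields = {}
        for st in order:
            lam = st.lam()
            if lam.min() < _LAM_LO + 2e-3 or lam.max() > st.lam_hi or np.any(st.A <= 0):
                raise SolverError(
                    f"area out of admissible range in segment {st.name!r} "
                    f"(stretch {lam.min():.3f}..{lam.max():.3f}) at t={t:.4f}s"
                )
            c = st.interp(st.c_tab, lam)
            u = st.Q / st.A
            p = st.interp(st.tube._p_tab, lam)
            f = st.interp(st.f_tab, lam)
            fields[st.name] = (lam, c, u, p, f)
            dt = min(dt, st.dx / float(np.max(np.abs(u) + c)))
        dt *= opts.cfl
        if dt < opts.dt_floor:
            raise SolverError(f"time step collapsed below floor at t={t:.4f}s")
        dt = min(dt, t_end - t)

        tn = t + dt

        # interior MacCormack sweep
        new_AQ = {}
        for st in order:
            lam, c, u, p, f = fields[st.name]
            A, Q = st.A, st.Q
            dx = st.dx
            G = opts.alpha * Q * Q / A
            r = dt / dx
            # predictor (forward differences), nodes 0..n-2
            As = A[:-1] - r * (Q[1:] - Q[:-1])
            Qs = (
                Q[:-1]
                - r * (G[1:] - G[:-1])
                - dt * ((A[:-1] / rho) * (p[1:] - p[:-1]) / dx + st.fric * Q[:-1] / A[:-1])
            )
            if np.any(As <= 0):
                raise SolverError(f"negative predicted area in segment {st.name!r} at t={t:.4f}s")
            lam_s = np.sqrt(As / st.A0)
            p_s = st.interp(st.tube._p_tab, lam_s)
            G_s = opts.alpha * Qs * Qs / As
            # corrector (backward differences on starred), nodes 1..n-2
            An = 0.5 * (A[1:-1] + As[1:] - r * (Qs[1:] - Qs[:-1]))
            Qn = 0.5 * (
                Q[1:-1]
                + Qs[1:]
                - r * (G_s[1:] - G_s[:-1])
                - dt * ((As[1:] / rho) * (p_s[1:] - p_s[:-1]) / dx + st.fric * Qs[1:] / As[1:])
            )
            A_new = A.copy()
            Q_new = Q.copy()
            A_new[1:-1] = An
            Q_new[1:-1] = Qn
            new_AQ[st.name] = (A_new, Q_new)

        # boundary updates from time-n characteristics --------------------
        # inlet: prescribed velocity, backward characteristic from interior
        # (invariants pick up the friction source -8 pi nu u / A along the path)
        lam, c, u, p, f = fields[network.inlet]
        st = inlet_seg
        xi = (c[0] - u[0]) * dt / st.dx
        w2 = _foot_interp(u[0] - f[0], u[1] - f[1], xi) - dt * st.fric * u[0] / st.A[0]
        v_in = float(inlet(tn))
        lam_in = st.lam_from_f(v_in - w2)
        A_new, Q_new = new_AQ[st.name]
        A_new[0] = lam_in**2 * st.A0
        Q_new[0] = v_in * A_new[0]

        # outlets
        for name, bc in network.outlets.items():
            st = segs[name]
            lam, c, u, p, f = fields[name]
            xi = (u[-1] + c[-1]) * dt / st.dx
            w1 = (
                _foot_interp(u[-1] + f[-1], u[-2] + f[-2], xi)
                - dt * st.fric * u[-1] / st.A[-1]
            )
            if bc.kind == "pressure":
                p_ref = bc.value(tn)
                if bc.resistance == 0.0:
                    lam_o = st.lam_from_p(p_ref)
                    u_o = w1 - float(np.interp(lam_o, _LAM_GRID, st.f_tab))
                else:
                    # Newton on p(lam) = p_ref + R * A(lam) * (w1 - f(lam))
                    R = bc.resistance
                    lam_o = lam[-1]
                    for _ in range(30):
                        f_o = float(np.interp(lam_o, _LAM_GRID, st.f_tab))
                        p_o = float(np.interp(lam_o, _LAM_GRID, st.tube._p_tab))
                        c_o = float(np.interp(lam_o, _LAM_GRID, st.c_tab))
                        u_o = w1 - f_o
                        A_o = lam_o**2 * st.A0
                        g = p_o - p_ref - R * A_o * u_o
                        dg = (
                            2.0 * rho * c_o**2 / lam_o
                            - R * (2.0 * lam_o * st.A0 * u_o - A_o * 2.0 * c_o / lam_o)
                        )
                        step = g / dg
                        lam_o -= max(min(step, 0.05), -0.05)
                        if abs(g) < 1e-8 * max(abs(p_ref), 1e3):
                            break
                    u_o = w1 - float(np.interp(lam_o, _LAM_GRID, st.f_tab))
            else:  # nonreflecting: incoming invariant pinned at reference
                lam_o = st.lam_from_f(0.5 * w1)
                u_o = 0.5 * w1
            A_new, Q_new = new_AQ[name]
            A_new[-1] = lam_o**2 * st.A0
            Q_new[-1] = u_o * A_new[-1]

        # junctions
        for j in juncs:
            W = np.empty(j.m)
            stp = j.parent
            lam, c, u, p, f = fields[stp.name]
            xi = (u[-1] + c[-1]) * dt / stp.dx
            W[0] = (
                _foot_interp(u[-1] + f[-1], u[-2] + f[-2], xi)
                - dt * stp.fric * u[-1] / stp.A[-1]
            )
            for k, stc in enumerate(j.children, start=1):
                lam, c, u, p, f = fields[stc.name]
                xi = (c[0] - u[0]) * dt / stc.dx
                W[k] = (
                    _foot_interp(u[0] - f[0], u[1] - f[1], xi)
                    - dt * stc.fric * u[0] / stc.A[0]
                )
            lam_j, u_j, A_j, err = j.solve(W, opts.junction_tol, opts.junction_max_iter)
            max_jerr = max(max_jerr, err)
            A_new, Q_new = new_AQ[stp.name]
            A_new[-1] = A_j[0]
            Q_new[-1] = u_j[0] * A_j[0]
            for k, stc in enumerate(j.children, start=1):
                A_new, Q_new = new_AQ[stc.name]
                A_new[0] = A_j[k]
                Q_new[0] = u_j[k] * A_j[k]

        # boundary-flux volume budget (trapezoid at full step resolution)
        q_in_old = segs[network.inlet].Q[0]
        q_in_new = new_AQ[network.inlet][1][0]
        v_in_acc += 0.5 * (q_in_old + q_in_new) * dt
        for name in network.outlets:
            q_old = segs[name].Q[-1]
            q_new = new_AQ[name][1][-1]
            v_out_acc += 0.5 * (q_old + q_new) * dt

        for st in order:
            st.A, st.Q = new_AQ[st.name]
        t = tn
        n_steps += 1

        if t >= next_save - 1e-12:
            record()
            next_save += save_dt

        # cycle-to-cycle convergence check
        if t >= (cycles_done + 1) * T - 1e-12:
            cycles_done += 1
            stored_end = total_volume()
            volume_budget.append(
                {
                    "inflow_m3": v_in_acc,
                    "outflow_m3": v_out_acc,
                    "stored_start_m3": stored_start,
                    "stored_end_m3": stored_end,
                }
            )
            v_in_acc = 0.0
            v_out_acc = 0.0
            stored_start = stored_end
            if cycles_done >= 2:
                res = _cycle_residual(t_saved, saved, T, cycles_done)
                residual_history.append((cycles_done, res))
                if res < opts.convergence_tol:
                    converged = True
                    break

    return _package_solution(
        network,
        fluid,
        opts,
        segs,
        t_saved,
        saved,
        T,
        converged,
        residual_history,
        cycles_done,
        n_steps,
        max_jerr,
        volume_budget,
    )


def _cycle_residual(t_saved, saved, T, k) -> float:
    """Relative L2 change between cycles k and k-1 (A- and Q-based)."""
    t_arr = np.asarray(t_saved)
    grid = np.linspace(0.0, T, 129)[:-1]
    num = 0.0
    den = 0.0
    for series in saved.values():
        S = np.asarray(series)  # (nt, 2n)
        cur = np.empty((grid.size, S.shape[1]))
        prev = np.empty_like(cur)
        for col in range(S.shape[1]):
            cur[:, col] = np.interp((k - 1) * T + grid, t_arr, S[:, col])
            prev[:, col] = np.interp((k - 2) * T + grid, t_arr, S[:, col])
        num += float(np.sum((cur - prev) ** 2))
        den += float(np.sum(cur**2))
    return math.sqrt(num / max(den, 1e-300))


def _package_solution(
    network,
    fluid,
    opts,
    segs,
    t_saved,
    saved,
    T,
    converged,
    residual_history,
    cycles_done,
    n_steps,
    max_jerr,
    volume_budget=None,
) -> FlowSolution:
    t_arr = np.asarray(t_saved)
    out = {}
    for name, st in segs.items():
        S = np.asarray(saved[name])
        n = st.n
        A = S[:, :n]
        Q = S[:, n:]
        p = np.interp(np.sqrt(A / st.A0), _LAM_GRID, st.tube._p_tab)
        seg = network.segments[name]
        out[name] = SegmentSolution(
            name=name,
            x=st.x,
            A=A,
            Q=Q,
            p=p,
            A0=st.A0,
            h=seg.thickness,
            r0=seg.radius,
        )
    return FlowSolution(
        t=t_arr,
        segments=out,
        period=T,
        converged=converged,
        residual_history=residual_history,
        n_cycles_run=cycles_done,
        network=network,
        fluid=fluid,
        options=opts,
        n_steps=n_steps,
        junction_residual_max=max_jerr,
        volume_budget=volume_budget or [],
    )


# ---------------------------------------------------------------------------
# shunt flow extraction
# ---------------------------------------------------------------------------


@dataclass
class ShuntFlow:
    """Shunt mid-segment volumetric flow over the final cycle."""

    t: np.ndarray  # s, re-phased to [0, T)
    q: np.ndarray  # m^3/s
    mean_ml_min: float
    peak_ml_min: float


def shunt_flow_series(
    solution: FlowSolution, network: VesselNetwork | None = None
) -> ShuntFlow:
    """Flow at the shunt mid-node over the final cycle, with cycle statistics.

    Refuses to report from an unconverged solution (the final cycle would not
    be periodic); pass a solution whose ``converged`` flag is set.
    """
    net = network or solution.network
    if net.shunt is None:
        raise ValueError("network has no shunt segment")
    if not solution.converged:
        raise SolverError(
            "solution not converged "
            f"(residual history {solution.residual_history}); refusing shunt series"
        )
    seg = solution.segments[net.shunt]
    mask = solution.final_cycle_mask()
    t = solution.t[mask]
    q = seg.Q[mask, seg.Q.shape[1] // 2]
    tt = t - (solution.n_cycles_run - 1) * solution.period
    mean = float(np.trapezoid(q, t) / (t[-1] - t[0])) if t.size > 1 else float(q.mean())
    to_ml_min = 1e6 * 60.0
    return ShuntFlow(
        t=tt,
        q=q,
        mean_ml_min=mean * to_ml_min,
        peak_ml_min=float(np.max(np.abs(q))) * to_ml_min,
    )
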