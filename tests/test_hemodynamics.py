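"""Solver unit tests: tube law, classical limits, junctions, determinism.

Network-scale pulsatile runs (periodicity, grid convergence on the full
system, scenario effects) live in the acceptance suite; here every case is a
small, fast configuration with an analytic or structural expectation.
"""

import numpy as np
import pytest

from shuntflow.constitutive import (
    LinearElasticParams,
    MooneyRivlin5Params,
    OgdenParams,
)
from shuntflow.hemodynamics import (
    FluidProperties,
    Junction,
    OutletBC,
    Segment,
    SolverError,
    SolverOptions,
    TubeLaw,
    TubeLawStabilityError,
    VesselNetwork,
    shunt_flow_series,
    solve_pulsatile,
    tube_law_from_material,
)
from shuntflow.metrics import measure_pulse_wave_speed
from shuntflow.synthetic_data import single_tube_network, steady_inlet


NEO_HOOKEAN = OgdenParams(terms=((0.5, 2.0),))
SOFT_ELASTIC = LinearElasticParams(E=1.0, nu=0.49)


class TestTubeLaw:
    def test_reference_state_zero_pressure(self):
        tl = tube_law_from_material(SOFT_ELASTIC, np.pi * 4e-6, 3e-4)
        assert tl.pressure(tl.A0) == 0.0

    def test_linear_elastic_small_strain_value(self):
        # Laplace law with deformed radius and thickness at lam = 1.01
        E, nu, h, r0 = 10.3, 0.49, 0.35e-3, 1.75e-3
        tl = tube_law_from_material(LinearElasticParams(E=E, nu=nu), np.pi * r0**2, h)
        lam = 1.01
        expected = (E * 1e6 * h / (1 - nu**2)) * (lam - 1.0) / (lam**2 * r0)
        assert tl.pressure(lam**2 * tl.A0) == pytest.approx(expected, rel=1e-10)

    def test_neo_hookean_energy_consistency(self):
        """p(A) equals the A-derivative of the wall strain energy per length."""
        A0, h = np.pi * (2e-3) ** 2, 3e-4
        tl = tube_law_from_material(NEO_HOOKEAN, A0, h)
        r0 = np.sqrt(A0 / np.pi)

        def wall_energy(A):
            lam = np.sqrt(A / A0)
            W = sum(
                m / a * (lam**a + 1.0 + lam**-a - 3.0) for m, a in NEO_HOOKEAN.terms
            ) * 1e6
            return 2 * np.pi * r0 * h * W

        lam = np.concatenate([np.linspace(0.8, 0.95, 10), np.linspace(1.05, 1.6, 20)])
        A = A0 * lam**2
        dA = A0 * 1e-7
        p_num = (wall_energy(A + dA) - wall_energy(A - dA)) / (2 * dA)
        np.testing.assert_allclose(tl.pressure(A), p_num, rtol=1e-6)

    def test_unstable_wall_rejected_naming_stretch(self):
        floppy = MooneyRivlin5Params(c10=0.05, c01=-0.4, c20=0, c11=0, c02=0)
        with pytest.raises(TubeLawStabilityError, match="stretch"):
            TubeLaw(floppy, np.pi * 4e-6, 3e-4)

    def test_pressure_area_inverse_round_trip(self):
        tl = tube_law_from_material(SOFT_ELASTIC, np.pi * 4e-6, 3e-4)
        A = 1.21 * tl.A0
        # table-based inverse: accuracy limited by the sampled law
        assert tl.area_of_pressure(tl.pressure(A)) == pytest.approx(A, rel=1e-4)


class TestClassicalLimits:
    def test_poiseuille_pressure_drop(self):
        """Steady low-Re flow in a compliant tube recovers Hagen-Poiseuille."""
        net = single_tube_network(SOFT_ELASTIC, length=0.1, radius=2e-3, thickness=3e-4)
        opts = SolverOptions(dx=0.005, n_cycles=4, convergence_tol=1e-10, save_per_cycle=100)
        sol = solve_pulsatile(net, FluidProperties(), steady_inlet(0.005, ramp=0.15), opts)
        seg = sol.segments["tube"]
        Q = seg.Q[-1]
        dp = seg.p[-1, 0] - seg.p[-1, -1]
        dp_poiseuille = 8 * 0.0035 * 0.1 * Q.mean() / (np.pi * (2e-3) ** 4)
        assert dp == pytest.approx(dp_poiseuille, rel=0.01)

    def test_rigid_tube_steady_mass_conservation(self):
        """Near-rigid wall, steady inflow: outlet flow equals inlet flow."""
        stiff = LinearElasticParams(E=2000.0, nu=0.49)
        net = single_tube_network(
            stiff, length=0.03, radius=2e-3, thickness=3e-4,
            outlet=OutletBC("nonreflecting"),
        )
        opts = SolverOptions(dx=0.0075, n_cycles=2, convergence_tol=1e-15, save_per_cycle=50)
        sol = solve_pulsatile(
            net, FluidProperties(), steady_inlet(0.05, period=0.1, ramp=0.03), opts
        )
        Q = sol.segments["tube"].Q[-1]
        assert abs(Q[-1] - Q[0]) / abs(Q[0]) < 1e-10

    def test_moens_korteweg_pulse_wave_speed(self):
        E, nu, h, r0 = 0.5, 0.49, 3e-4, 2e-3
        c_mk = np.sqrt(E * 1e6 * h / (2 * 1060.0 * r0 * (1 - nu**2)))
        net = single_tube_network(
            LinearElasticParams(E=E, nu=nu),
            length=0.25,
            radius=r0,
            thickness=h,
            outlet=OutletBC("nonreflecting"),
        )

        class Pulse:
            period = 0.25

            def __call__(self, t):
                t = np.asarray(t, float)
                out = np.where(t < 0.01, 0.005 * np.sin(np.pi * t / 0.01) ** 2, 0.0)
                return out if out.ndim else float(out)

        opts = SolverOptions(dx=0.002, n_cycles=1, save_per_cycle=2000, convergence_tol=0.0)
        sol = solve_pulsatile(net, FluidProperties(), Pulse(), opts)
        c = measure_pulse_wave_speed(sol, "tube", 0.05, 0.20)
        assert c == pytest.approx(c_mk, rel=0.03)


def y_network(loss=0.0):
    segs = [
        Segment("parent", 0.04, 3e-3, 4e-4, SOFT_ELASTIC),
        Segment("child_a", 0.04, 2.2e-3, 3e-4, SOFT_ELASTIC),
        Segment("child_b", 0.04, 2.2e-3, 3e-4, SOFT_ELASTIC),
    ]
    juncs = [Junction("parent", ("child_a", "child_b"), loss={"child_a": loss, "child_b": loss})]
    outs = {n: OutletBC("pressure", 0.0) for n in ("child_a", "child_b")}
    return VesselNetwork(segs, juncs, inlet="parent", outlets=outs)


class TestJunctions:
    def test_steady_junction_mass_balance(self):
        net = y_network()
        fluid = FluidProperties(viscosity=0.05)
        opts = SolverOptions(dx=0.01, n_cycles=3, convergence_tol=1e-13, save_per_cycle=50)
        sol = solve_pulsatile(net, fluid, steady_inlet(0.1, period=0.25, ramp=0.05), opts)
        qp = sol.segments["parent"].Q[-1, -1]
        qc = sol.segments["child_a"].Q[-1, 0] + sol.segments["child_b"].Q[-1, 0]
        assert abs(qp - qc) / abs(qp) < 1e-10

    def test_symmetric_children_split_evenly(self):
        net = y_network()
        fluid = FluidProperties(viscosity=0.05)
        opts = SolverOptions(dx=0.01, n_cycles=3, convergence_tol=1e-13, save_per_cycle=50)
        sol = solve_pulsatile(net, fluid, steady_inlet(0.01, period=0.25, ramp=0.05), opts)
        qa = sol.segments["child_a"].Q[-1, 0]
        qb = sol.segments["child_b"].Q[-1, 0]
        assert qa == pytest.approx(qb, rel=1e-9)

    def test_total_pressure_continuity_without_loss(self):
        net = y_network(loss=0.0)
        fluid = FluidProperties(viscosity=0.05)
        opts = SolverOptions(dx=0.01, n_cycles=3, convergence_tol=1e-13, save_per_cycle=50)
        sol = solve_pulsatile(net, fluid, steady_inlet(0.01, period=0.25, ramp=0.05), opts)
        rho = fluid.density
        sp = sol.segments["parent"]
        sa = sol.segments["child_a"]
        tot_p = sp.p[-1, -1] + 0.5 * rho * (sp.Q[-1, -1] / sp.A[-1, -1]) ** 2
        tot_a = sa.p[-1, 0] + 0.5 * rho * (sa.Q[-1, 0] / sa.A[-1, 0]) ** 2
        assert tot_p == pytest.approx(tot_a, abs=1e-4)

    def test_loss_coefficient_dissipates_head(self):
        fluid = FluidProperties(viscosity=0.05)
        opts = SolverOptions(dx=0.01, n_cycles=3, convergence_tol=1e-13, save_per_cycle=50)
        inlet = steady_inlet(0.01, period=0.25, ramp=0.05)
        p_free = solve_pulsatile(y_network(0.0), fluid, inlet, opts)
        p_loss = solve_pulsatile(y_network(2.0), fluid, inlet, opts)
        # with losses the parent must run at higher pressure to push the same inflow
        assert p_loss.segments["parent"].p[-1, 0] > p_free.segments["parent"].p[-1, 0]


class TestSolverBehaviour:
    def test_deterministic_rerun_bit_identical(self):
        net = single_tube_network(SOFT_ELASTIC, length=0.1, radius=2e-3, thickness=3e-4)
        opts = SolverOptions(dx=0.01, n_cycles=2, convergence_tol=0.0, save_per_cycle=64)
        inlet = steady_inlet(0.01, ramp=0.1)
        s1 = solve_pulsatile(net, FluidProperties(), inlet, opts)
        s2 = solve_pulsatile(net, FluidProperties(), inlet, opts)
        assert np.array_equal(s1.segments["tube"].p, s2.segments["tube"].p)
        assert np.array_equal(s1.segments["tube"].Q, s2.segments["tube"].Q)

    def test_grid_convergence_order_on_pulse(self):
        """Halving dx changes the mid-tube peak pressure at order >= 1."""
        E, h, r0 = 0.5, 3e-4, 2e-3
        peaks = []

        class Pulse:
            period = 0.25

            def __call__(self, t):
                t = np.asarray(t, float)
                out = np.where(t < 0.02, 0.01 * np.sin(np.pi * t / 0.02) ** 2, 0.0)
                return out if out.ndim else float(out)

        for dx in (0.016, 0.008, 0.004):
            net = single_tube_network(
                LinearElasticParams(E=E, nu=0.49),
                length=0.24,
                radius=r0,
                thickness=h,
                outlet=OutletBC("nonreflecting"),
            )
            opts = SolverOptions(dx=dx, n_cycles=1, save_per_cycle=3000, convergence_tol=0.0)
            sol = solve_pulsatile(net, FluidProperties(), Pulse(), opts)
            seg = sol.segments["tube"]
            mid = np.argmin(np.abs(seg.x - 0.12))
            peaks.append(float(seg.p[:, mid].max()))
        e1, e2 = abs(peaks[0] - peaks[1]), abs(peaks[1] - peaks[2])
        assert e2 < e1  # monotone refinement
        assert np.log2(e1 / e2) >= 1.0

    def test_unconverged_solution_refused_by_shunt_series(self):
        segs = [
            Segment("feed", 0.05, 3e-3, 4e-4, SOFT_ELASTIC),
            Segment("graft", 0.05, 2e-3, 3e-4, SOFT_ELASTIC),
        ]
        net = VesselNetwork(
            segs,
            [Junction("feed", ("graft",))],
            inlet="feed",
            outlets={"graft": OutletBC("pressure", 0.0)},
            shunt="graft",
        )
        opts = SolverOptions(dx=0.01, n_cycles=1, convergence_tol=1e-14, save_per_cycle=64)
        sol = solve_pulsatile(net, FluidProperties(), steady_inlet(0.01), opts)
        assert not sol.converged
        with pytest.raises(SolverError):
            shunt_flow_series(sol)

    def test_stiffer_wall_faster_wave_smaller_distension(self):
        """Scaling the wall constants x10 raises wave speed, cuts displacement."""
        results = {}

        class Pulse:
            period = 0.25

            def __call__(self, t):
                t = np.asarray(t, float)
                out = np.where(t < 0.02, 0.05 * np.sin(np.pi * t / 0.02) ** 2, 0.0)
                return out if out.ndim else float(out)

        for scale in (1.0, 10.0):
            mat = OgdenParams(terms=tuple((m * scale, a) for m, a in NEO_HOOKEAN.terms))
            net = single_tube_network(
                mat, length=0.25, radius=2e-3, thickness=3e-4,
                outlet=OutletBC("nonreflecting"),
            )
            opts = SolverOptions(dx=0.004, n_cycles=1, save_per_cycle=2000, convergence_tol=0.0)
            sol = solve_pulsatile(net, FluidProperties(), Pulse(), opts)
            seg = sol.segments["tube"]
            results[scale] = {
                "c": measure_pulse_wave_speed(sol, "tube", 0.05, 0.2),
                "disp": float(np.max(np.sqrt(seg.A / np.pi) - np.sqrt(seg.A0 / np.pi))),
            }
        assert results[10.0]["c"] > results[1.0]["c"]
        assert results[10.0]["disp"] < results[1.0]["disp"]


class TestNetworkValidation:
    def test_cycle_rejected(self):
        segs = [
            Segment("a", 0.05, 3e-3, 4e-4, SOFT_ELASTIC),
            Segment("b", 0.05, 3e-3, 4e-4, SOFT_ELASTIC),
        ]
        with pytest.raises(ValueError):
            VesselNetwork(
                segs,
                [Junction("a", ("b",)), Junction("b", ("a",))],
                inlet="a",
                outlets={},
            )

    def test_missing_outlet_bc_rejected(self):
        segs = [
            Segment("a", 0.05, 3e-3, 4e-4, SOFT_ELASTIC),
            Segment("b", 0.05, 3e-3, 4e-4, SOFT_ELASTIC),
        ]
        with pytest.raises(ValueError):
            VesselNetwork(segs, [Junction("a", ("b",))], inlet="a", outlets={})

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            Segment("bad", -0.05, 3e-3, 4e-4, SOFT_ELASTIC)
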