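"""Forward beam mechanics: moments, integration, shapes, mirroring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import spindlebridge as sb
from spindlebridge.beam import (
    DegenerateRodError,
    ParameterizationBreakdownError,
    bending_moment,
    integrate_rod,
    forward_spindle_shape,
    mirror_full_spindle,
)


class TestBendingMoment:
    def test_pole_rod_moment_vanishes_on_axis_without_clamp_moment(self):
        loads = sb.BoundaryLoads(33.0, 280.0, 0.0)
        assert bending_moment("p", 0.0, loads, hk_um=5.0) == 0.0

    def test_kfibre_moment_vanishes_at_kinetochore_height(self):
        loads = sb.BoundaryLoads(12.0, 480.0, 7.0)
        assert bending_moment("k", 5.0, loads, hk_um=5.0) == 0.0

    def test_unknown_rod_rejected(self):
        with pytest.raises(ValueError):
            bending_moment("q", 1.0, sb.BoundaryLoads(1.0, 1.0), 5.0)

    @given(
        y=st.floats(-10, 10),
        f0=st.floats(0, 200),
        fk=st.floats(0, 1000),
        m0=st.floats(-50, 50),
        hk=st.floats(0.5, 8),
    )
    @settings(max_examples=200, deadline=None)
    def test_bridge_moment_is_junction_balance_of_other_rods(self, y, f0, fk, m0, hk):
        """M_b = M_p - M_k holds identically (moment balance at the junction)."""
        loads = sb.BoundaryLoads(f0, fk, m0)
        mb = bending_moment("b", y, loads, hk)
        mp = bending_moment("p", y, loads, hk)
        mk = bending_moment("k", y, loads, hk)
        assert mb == pytest.approx(mp - mk, rel=0, abs=1e-9 * max(1.0, abs(mp)))


class TestIntegrateRod:
    def test_zero_loads_give_straight_line(self, hela_architecture):
        loads = sb.BoundaryLoads(0.0, 0.0, 0.0)
        slope = math.tan(math.radians(64.0))
        rod = integrate_rod("p", 0.0, 4.3, 0.0, slope, loads,
                            hela_architecture, 5.0)
        assert np.allclose(rod.y_um, rod.x_um * slope, atol=1e-12)
        assert np.allclose(rod.slope, slope, atol=1e-12)

    @pytest.mark.parametrize("rod_id,x0,x1", [("p", 0.0, 4.3), ("b", 4.3, 5.55),
                                              ("k", 4.3, 5.05)])
    def test_midpoint_scheme_matches_adaptive_integrator(
        self, rod_id, x0, x1, hela_architecture, reference_loads
    ):
        """Fixed-step RK2 endpoint agrees with a high-order adaptive solve
        of the same ODE to better than 0.1%."""
        hk = 5.0
        y0, s0 = (0.0, math.tan(math.radians(64.0)))
        if rod_id != "p":
            start = integrate_rod("p", 0.0, 4.3, 0.0, s0, reference_loads,
                                  hela_architecture, hk)
            _, y0, s0 = start.end_state
        kappa = {"p": hela_architecture.kappa_p, "k": hela_architecture.kappa_k,
                 "b": hela_architecture.kappa_b}[rod_id]

        def rhs(x, u):
            y, s = u
            m = bending_moment(rod_id, y, reference_loads, hk)
            return [s, -m * (1 + s * s) ** 1.5 / kappa]

        ref = solve_ivp(rhs, [x0, x1], [y0, s0], method="DOP853",
                        rtol=1e-12, atol=1e-14)
        rod = integrate_rod(rod_id, x0, x1, y0, s0, reference_loads,
                            hela_architecture, hk)
        assert rod.y_um[-1] == pytest.approx(ref.y[0, -1], rel=1e-3)
        assert rod.slope[-1] == pytest.approx(ref.y[1, -1], rel=1e-3, abs=1e-4)

    def test_grid_convergence_on_step_halving(self, hela_architecture,
                                              reference_loads):
        coarse = integrate_rod("p", 0.0, 4.3, 0.0, math.tan(math.radians(64.0)),
                               reference_loads, hela_architecture, 5.0,
                               n_steps=50)
        fine = integrate_rod("p", 0.0, 4.3, 0.0, math.tan(math.radians(64.0)),
                             reference_loads, hela_architecture, 5.0,
                             n_steps=100)
        assert fine.y_um[-1] == pytest.approx(coarse.y_um[-1], rel=5e-3)

    def test_zero_rigidity_rod_under_moment_is_degenerate(self, hela_geometry):
        arch = sb.FibreArchitecture(n_k=17, n_b=0)
        loads = sb.BoundaryLoads(30.0, 300.0)
        with pytest.raises(DegenerateRodError):
            integrate_rod("b", 4.3, 5.55, 4.8, 0.3, loads, arch, 5.0)

    def test_near_vertical_rod_reports_breakdown(self, hela_architecture):
        # strong clamping moment curls the rod upward past the slope bound
        loads = sb.BoundaryLoads(0.0, 0.0, -4000.0)
        with pytest.raises(ParameterizationBreakdownError):
            integrate_rod("p", 0.0, 5.0, 0.0, 1.0, loads,
                          hela_architecture, 5.0)

    def test_invalid_step_count_rejected(self, hela_architecture):
        with pytest.raises(ValueError):
            integrate_rod("p", 0.0, 1.0, 0.0, 1.0, sb.BoundaryLoads(1, 1),
                          hela_architecture, 5.0, n_steps=1)


class TestForwardShape:
    def test_zero_loads_make_all_rods_collinear(self, hela_geometry,
                                                hela_architecture):
        shape = forward_spindle_shape(
            hela_geometry, hela_architecture, sb.BoundaryLoads(0, 0, 0), 3.0
        )
        slope = math.tan(hela_geometry.theta0_rad)
        for rod in shape.rods.values():
            assert np.allclose(rod.y_um, rod.x_um * slope, atol=1e-12)

    def test_rods_share_position_and_slope_at_junction(
        self, hela_geometry, hela_architecture, reference_loads
    ):
        shape = forward_spindle_shape(
            hela_geometry, hela_architecture, reference_loads, 4.3
        )
        for rid in ("k", "b"):
            rod = shape.rods[rid]
            assert rod.x_um[0] == pytest.approx(shape.xj_um, abs=1e-12)
            assert rod.y_um[0] == pytest.approx(shape.hj_um, abs=1e-9)
            assert rod.slope[0] == pytest.approx(shape.junction_slope, abs=1e-9)

    def test_junction_outside_half_spindle_rejected(self, hela_geometry,
                                                    hela_architecture):
        with pytest.raises(ValueError):
            forward_spindle_shape(hela_geometry, hela_architecture,
                                  sb.BoundaryLoads(10, 100), 5.6)

    def test_solution_shape_flattens_at_midplane(self, hela_solution):
        """At the solved force balance the bridging fibre is horizontal at
        the spindle midpoint (reflection symmetry)."""
        assert abs(hela_solution.shape.midpoint_slope) < 1e-3


class TestMirror:
    def test_full_contour_is_reflection_symmetric(self, hela_geometry,
                                                  hela_architecture,
                                                  reference_loads):
        L = hela_geometry.L_um
        shape = forward_spindle_shape(hela_geometry, hela_architecture,
                                      reference_loads, 4.3)
        full = mirror_full_spindle(shape, L)
        for rid in ("p", "k"):
            left = full[rid]
            right = full[rid + "'"]
            assert np.allclose(L - right[::-1, 0], left[:, 0])
            assert np.allclose(right[::-1, 1], left[:, 1])
        # bridging contour symmetric about L/2
        b = full["b"]
        assert np.allclose(b[:, 1], b[::-1, 1])

    def test_no_kink_at_midplane_when_midpoint_slope_vanishes(
        self, hela_solution, hela_geometry
    ):
        full = mirror_full_spindle(hela_solution.shape, hela_geometry.L_um)
        b = full["b"]
        i = np.argmin(np.abs(b[:, 0] - hela_geometry.L_um / 2))
        left_slope = (b[i, 1] - b[i - 1, 1]) / (b[i, 0] - b[i - 1, 0])
        right_slope = (b[i + 1, 1] - b[i, 1]) / (b[i + 1, 0] - b[i, 0])
        assert left_slope == pytest.approx(-right_slope, abs=2e-3)

    def test_both_poles_on_axis(self, hela_solution, hela_geometry):
        full = mirror_full_spindle(hela_solution.shape, hela_geometry.L_um)
        assert full["p"][0, 1] == pytest.approx(0.0, abs=1e-12)
        assert full["p'"][-1, 1] == pytest.approx(0.0, abs=1e-12)
        assert full["p'"][-1, 0] == pytest.approx(hela_geometry.L_um, abs=1e-12)
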