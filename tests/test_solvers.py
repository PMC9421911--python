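"""Self-consistent maps, closed forms, Newton acceleration and diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import floryfit as ff
from floryfit import solvers
from floryfit.errors import DomainError, OnePhaseRegionError


def _fprime_root(chi: float) -> float:
    """Independent bracketed root of f'(phi) = 0 on the dilute side (N = 1)."""
    return optimize.brentq(
        lambda p: math.log(p) - math.log1p(-p) + chi * (1 - 2 * p),
        1e-12, 0.5 - 1e-9, xtol=1e-15,
    )


class TestSymmetricMap:
    def test_midpoint_is_fixed(self):
        for chi in (0.5, 2.0, 7.0):
            assert ff.map_g(0.5, chi) == pytest.approx(0.5, abs=1e-15)

    @given(phi=st.floats(-5.0, 5.0), chi=st.floats(0.1, 30.0))
    def test_total_on_reals(self, phi, chi):
        g = ff.map_g(phi, chi)
        assert math.isfinite(g) and 0.0 <= g <= 1.0

    def test_iteration_from_gl_guess_reaches_bracketed_root(self):
        chi = 3.0
        target = _fprime_root(chi)
        assert target == pytest.approx(0.0707, abs=5e-5)  # frozen from the oracle
        phi = 0.5 - math.sqrt(6 * (chi - 2)) / 4
        for _ in range(60):
            phi = ff.map_g(phi, chi)
        assert phi == pytest.approx(target, abs=1e-10)

    def test_map_derivative_is_marginal_at_critical_point(self):
        assert abs(ff.map_g_prime(0.5, 2.0)) - 1.0 == pytest.approx(0.0, abs=1e-14)


class TestSolveSymmetric:
    def test_collapses_at_critical_point(self):
        pair = ff.solve_binodal_symmetric(2.0 + 1e-9)
        assert pair.phi_minus == pytest.approx(0.5, abs=1e-4)
        assert pair.phi_plus == pytest.approx(0.5, abs=1e-4)

    def test_branch_reflection(self):
        for order in (1, 2, None):
            pair = ff.solve_binodal_symmetric(3.0, order=order)
            assert pair.phi_minus + pair.phi_plus == 1.0

    def test_second_order_beats_first_order(self):
        target = math.log(_fprime_root(3.0))
        e1 = abs(math.log(ff.solve_binodal_symmetric(3.0, order=1).phi_minus) - target)
        e2 = abs(math.log(ff.solve_binodal_symmetric(3.0, order=2).phi_minus) - target)
        assert e2 < e1

    def test_exponential_scaling_at_large_chi(self):
        """phi_-^bin ~ e^{-chi}: bounded ratio and unit log-slope."""
        pair = ff.solve_binodal_symmetric(10.0)
        assert 0.1 < pair.phi_minus / math.exp(-10.0) < 10.0
        chis = np.linspace(9.0, 11.0, 5)
        ts = [math.log(ff.solve_binodal_symmetric(float(c)).phi_minus) for c in chis]
        slope = np.polyfit(chis, ts, 1)[0]
        assert slope == pytest.approx(-1.0, rel=0.01)

    def test_one_phase_region_raises(self):
        with pytest.raises(OnePhaseRegionError):
            ff.solve_binodal_symmetric(1.8)


class TestGeneralMap:
    @given(phi=st.floats(1e-3, 0.45), chi=st.floats(2.05, 8.0))
    def test_reduces_to_scalar_map_at_N1(self, phi, chi):
        """On a symmetric pair, G acts as g on each branch with
        phi_+ + phi_- = 1 preserved to 1e-12."""
        s = ff.PolymerSolventSystem(N=1, chi=chi)
        out = ff.map_G((phi, 1.0 - phi), s)
        assert out[0] == pytest.approx(ff.map_g(phi, chi), abs=1e-12)
        assert out[1] == pytest.approx(ff.map_g(1.0 - phi, chi), abs=1e-12)
        assert out[0] + out[1] == pytest.approx(1.0, abs=1e-12)

    def test_oracle_binodal_is_fixed_point(self, asymmetric_system, oracle_pair):
        out = ff.map_G(oracle_pair.as_tuple(), asymmetric_system)
        assert out[0] == pytest.approx(oracle_pair.phi_minus, rel=1e-10)
        assert out[1] == pytest.approx(oracle_pair.phi_plus, rel=1e-10)

    def test_iteration_from_gl_guess_matches_oracle(self, asymmetric_system, oracle_pair):
        pair = ff.solve_binodal(asymmetric_system, method="iterate", tol=1e-12, max_iter=200)
        assert pair.phi_minus == pytest.approx(oracle_pair.phi_minus, abs=1e-8)
        assert pair.phi_plus == pytest.approx(oracle_pair.phi_plus, abs=1e-8)

    def test_orbit_starts_at_gl_guess(self, asymmetric_system):
        orbit = ff.solve_binodal_orbit(asymmetric_system, method="iterate")
        gl = ff.gl_binodal(asymmetric_system.N, asymmetric_system.chi)
        assert orbit.iterates[0] == (gl.phi_minus, gl.phi_plus)


class TestClosedForms:
    @pytest.mark.parametrize("N, chi", [(1, 3.0), (3, 1.5), (10, 2.0), (100, 1.2), (5, 2.0)])
    def test_equals_map_applications_to_gl_guess(self, N, chi):
        """Order k closed form is exactly k applications of G to the GL pair."""
        s = ff.PolymerSolventSystem(N=N, chi=chi)
        gl = ff.gl_binodal(N, chi)
        g1 = ff.map_G(gl.as_tuple(), s)
        g2 = ff.map_G(g1, s)
        c1 = ff.closed_form_binodal(s, order=1)
        c2 = ff.closed_form_binodal(s, order=2)
        assert c1.phi_minus == pytest.approx(g1[0], rel=1e-12)
        assert c1.phi_plus == pytest.approx(g1[1], rel=1e-12)
        assert c2.phi_minus == pytest.approx(g2[0], rel=1e-12)
        assert c2.phi_plus == pytest.approx(g2[1], rel=1e-12)

    def test_second_order_accuracy_at_large_N(self):
        cp = ff.critical_point(100)
        s = ff.PolymerSolventSystem(N=100, chi=1.5 * cp.chi_c)
        c2 = ff.closed_form_binodal(s, order=2)
        o = ff.oracle_binodal(s)
        # dilute branch spans decades: compare in ln(phi); dense branch is
        # order one: compare phi itself.  Both within 10%.
        assert c2.log_phi_minus == pytest.approx(o.log_phi_minus, rel=0.10)
        assert c2.phi_plus == pytest.approx(o.phi_plus, rel=0.10)

    def test_branch_swap_transformation(self):
        """Under the polymer-solvent relabeling (phi -> 1-phi, N -> 1/N,
        chi -> N chi) A and B swap and D is invariant."""
        N, chi = 5.0, 2.0
        c = ff.closed_form_coefficients(ff.PolymerSolventSystem(N=N, chi=chi))
        Np, chip = 1.0 / N, N * chi
        rootN = math.sqrt(Np)
        chi_c_p = 0.5 * (1 + 1 / rootN) ** 2
        alpha = math.sqrt(6 * (chip - chi_c_p)) * Np**0.75 / (1 + rootN) ** 2
        Delta = 1.0 / (1 + rootN)
        gamma = 1.0 - 1.0 / Np
        A_p = 2 * alpha * (gamma + 2 * chip * Delta)
        B_p = 2 * Np * alpha * (2 * chip * (1 - Delta) - gamma)
        D_p = math.expm1(-A_p) * math.expm1(-B_p) / (-math.expm1(-(A_p + B_p)))
        assert A_p == pytest.approx(c.B, rel=1e-12)
        assert B_p == pytest.approx(c.A, rel=1e-12)
        assert D_p == pytest.approx(c.D, rel=1e-12)

    def test_reduced_params_degenerate_at_N1(self):
        rp = ff.reduced_params(ff.PolymerSolventSystem(N=1, chi=3.0))
        assert rp.Delta == 0.5 and rp.gamma == 0.0
        assert rp.x == pytest.approx(2 * rp.y, rel=1e-14)

    def test_one_phase_region_raises(self):
        with pytest.raises(OnePhaseRegionError):
            ff.closed_form_binodal(ff.PolymerSolventSystem(N=3, chi=1.0))


class TestDiluteScaling:
    def test_reduces_to_exp_minus_chi_at_N1(self):
        s = ff.PolymerSolventSystem(N=1, chi=25.0)
        assert ff.dilute_scaling(s) / math.exp(-25.0) == pytest.approx(1.0, abs=1e-12)

    def test_exponent_matches_oracle_slope_at_N2(self):
        chis = np.linspace(8.0, 12.0, 9)
        ts = [ff.oracle_binodal(ff.PolymerSolventSystem(N=2, chi=float(c))).log_phi_minus
              for c in chis]
        slope = np.polyfit(chis, ts, 1)[0]
        # d ln(phi_-)/d chi from the scaling law is -N
        assert slope == pytest.approx(-2.0, rel=0.02)

    def test_binodal_decays_faster_than_spinodal(self):
        ratios = []
        for chi in (6.0, 10.0, 14.0):
            s = ff.PolymerSolventSystem(N=1, chi=chi)
            ratios.append(ff.dilute_scaling(s) / ff.spinodal_dilute_scaling(1, chi))
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[2] < 1e-3


class TestImprovedMaps:
    def test_fixed_points_preserved(self, asymmetric_system, oracle_pair):
        star = _fprime_root(3.0)
        assert ff.improved_map_h(star, 3.0) == pytest.approx(star, abs=1e-12)
        out = ff.improved_map_H(oracle_pair.as_tuple(), asymmetric_system)
        assert out[0] == pytest.approx(oracle_pair.phi_minus, rel=1e-9)
        assert out[1] == pytest.approx(oracle_pair.phi_plus, rel=1e-9)

    def test_reduces_to_plain_map_when_derivative_vanishes(self):
        # deep dilute branch: g' ~ 2 chi phi -> 0, so h ~ g
        chi = 20.0
        phi = 1e-9
        assert ff.improved_map_h(phi, chi) == pytest.approx(ff.map_g(phi, chi), rel=1e-6)

    def test_strictly_faster_than_plain_map_in_slow_regime(self):
        """At chi = 2.2 (slow transition region) the Newton-accelerated orbit
        contracts strictly faster per iterate than the plain map."""
        chi = 2.2
        star = _fprime_root(chi)
        phi_plain = phi_newton = 0.5 - math.sqrt(6 * (chi - 2)) / 4
        for _ in range(4):
            phi_plain = ff.map_g(phi_plain, chi)
            phi_newton = ff.improved_map_h(phi_newton, chi)
            assert abs(phi_newton - star) < abs(phi_plain - star)

    def test_rapid_convergence_at_large_N(self):
        """Newton-accelerated orbits reach 1e-6 agreement in ln(phi) with the
        oracle within a handful of iterations across the N = 100 phase space."""
        cp = ff.critical_point(100)
        for frac in np.linspace(1.08, 2.0, 7):
            s = ff.PolymerSolventSystem(N=100, chi=float(cp.chi_c * frac))
            orbit = ff.solve_binodal_orbit(s, method="improved", tol=1e-13, max_iter=30)
            o = ff.oracle_binodal(s)
            needed = None
            for i, (pm, pp) in enumerate(orbit.iterates):
                if pm > 0 and abs(math.log(pm) - o.log_phi_minus) < 1e-6 \
                        and abs(math.log(pp) - math.log(o.phi_plus)) < 1e-6:
                    needed = i
                    break
            assert needed is not None and needed <= 6


class TestJacobian:
    def test_matches_centered_finite_differences(self, asymmetric_system):
        pair = (0.1, 0.7)
        J = ff.jacobian(pair, asymmetric_system)
        h = 1e-7
        for j in range(2):
            qp, qm = list(pair), list(pair)
            qp[j] += h
            qm[j] -= h
            Gp = ff.map_G(tuple(qp), asymmetric_system)
            Gm = ff.map_G(tuple(qm), asymmetric_system)
            assert J[0, j] == pytest.approx((Gp[0] - Gm[0]) / (2 * h), abs=1e-6)
            assert J[1, j] == pytest.approx((Gp[1] - Gm[1]) / (2 * h), abs=1e-6)

    def test_contractive_at_binodal(self, asymmetric_system, oracle_pair):
        J = ff.jacobian(oracle_pair.as_tuple(), asymmetric_system)
        assert max(abs(np.linalg.eigvals(J))) < 1.0

    def test_N1_spectrum_contains_scalar_derivative(self):
        s = ff.PolymerSolventSystem(N=1, chi=3.0)
        o = ff.oracle_binodal(s)
        eigs = np.linalg.eigvals(ff.jacobian(o.as_tuple(), s))
        gp = ff.map_g_prime(o.phi_minus, 3.0)
        assert min(abs(eigs - gp)) < 1e-6


class TestSolverContracts:
    @pytest.mark.parametrize("method", ["second_order", "iterate", "improved"])
    def test_N1_branch_symmetry(self, method):
        pair = ff.solve_binodal(ff.PolymerSolventSystem(N=1, chi=3.0), method=method)
        assert pair.phi_minus + pair.phi_plus == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("N", [1, 3, 10, 100])
    def test_branches_monotone_in_chi(self, N):
        cp = ff.critical_point(N)
        grid = cp.chi_c + np.arange(1, 51) / 50 * (2 * cp.chi_c)
        lo, hi = [], []
        for chi in grid:
            p = ff.solve_binodal(ff.PolymerSolventSystem(N=N, chi=float(chi)))
            lo.append(p.log_phi_minus)
            hi.append(p.phi_plus)
        assert np.all(np.diff(lo) < 0)
        assert np.all(np.diff(hi) > 0)

    def test_converged_residual_contract(self, asymmetric_system):
        pair = ff.solve_binodal(asymmetric_system, method="improved", tol=1e-10)
        assert pair.residual < 1e-8

    def test_near_critical_guard_returns_gl_pair(self):
        cp = ff.critical_point(3)
        pair = ff.solve_binodal(ff.PolymerSolventSystem(N=3, chi=cp.chi_c + 1e-8))
        assert pair.method == "gl"

    def test_unknown_method_raises(self, asymmetric_system):
        with pytest.raises(DomainError):
            ff.solve_binodal(asymmetric_system, method="magic")

    def test_deep_dilute_branch_extended_precision(self):
        """At chi = 700 the dilute branch is e^{-700}, far below double
        underflow thresholds for intermediate quantities; the solver and the
        oracle must still agree in ln(phi_-)."""
        s = ff.PolymerSolventSystem(N=1, chi=700.0)
        p = ff.solve_binodal(s, method="improved")
        o = ff.oracle_binodal(s)
        assert p.log_phi_minus == pytest.approx(-700.0, abs=1e-6)
        assert p.log_phi_minus == pytest.approx(o.log_phi_minus, abs=1e-8)


class TestDiagnostics:
    def test_marginal_contour_passes_through_critical_point(self):
        field = solvers.map_g_field([2.0], [0.5])
        assert field[0, 0] == pytest.approx(0.0, abs=1e-14)

    def test_empty_grid_raises(self):
        with pytest.raises(DomainError):
            solvers.map_g_field([], [0.5])
        with pytest.raises(DomainError):
            solvers.flow_field(ff.PolymerSolventSystem(N=3, chi=1.5), [], [0.5])

    def test_flow_fixed_points(self, asymmetric_system):
        """One stable fixed point (the binodal) off the diagonal; the two
        diagonal fixed points sit at the spinodal and are not attractors."""
        fps = solvers.classify_fixed_points(asymmetric_system)
        kinds = [fp.kind for fp in fps]
        assert kinds[0] == "stable"
        assert fps[0].pair[0] != fps[0].pair[1]
        spi = ff.spinodal(asymmetric_system)
        assert fps[1].pair[0] == pytest.approx(spi.phi_minus, abs=1e-10)
        assert fps[2].pair[0] == pytest.approx(spi.phi_plus, abs=1e-10)
        assert all(k != "stable" for k in kinds[1:])
        for fp in fps:
            G = ff.map_G(fp.pair, asymmetric_system)
            assert abs(G[0] - fp.pair[0]) < 1e-8
            assert abs(G[1] - fp.pair[1]) < 1e-8

    def test_flow_field_shapes(self, asymmetric_system):
        fl = solvers.flow_field(asymmetric_system, np.linspace(0.02, 0.3, 4),
                                np.linspace(0.5, 0.9, 5))
        assert fl.velocity_minus.shape == (4, 5)
        assert len(fl.fixed_points) == 3
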