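"""Self-consistent binodal solvers for the Flory-Huggins model.

The coexistence conditions mu(phi_+) = mu(phi_-), Pi(phi_+) = Pi(phi_-) are
rewritten as a fixed-point problem.  Defining the two exponents from a trial
pair (phi_-, phi_+),

    x = 2 chi (phi_+ - phi_-),
    y = gamma (phi_+ - phi_-) + chi (phi_+^2 - phi_-^2),   gamma = 1 - 1/N,

the chemical-potential equality gives phi_-/phi_+ = exp(-N(x - y)) and the
osmotic-pressure equality, after substitution, yields the update

    phi_+' = (1 - e^{-y}) / (1 - e^{-N(x-y) - y}),
    phi_-' = phi_+' e^{-N(x-y)}.

This vector operator G is a contraction near the binodal; iterating it from
the Ginzburg-Landau pair converges to the coexistence concentrations.  For
N = 1 the operator degenerates to the scalar logistic map
g(phi) = 1 / (1 + e^{chi (1 - 2 phi)}) with the exact branch symmetry
phi_+ = 1 - phi_-.

One and two applications of G to the Ginzburg-Landau guess admit closed
forms in the reduced parameters alpha (Ginzburg-Landau half-width) and
Delta = phi_c, with exponents

    A = 2 alpha (gamma + 2 chi Delta),
    B = 2 N alpha (2 chi (1 - Delta) - gamma),
    D = (1 - e^{-A})(1 - e^{-B}) / (1 - e^{-A-B})   (= phi_+^(1) - phi_-^(1)).

A and B swap, and D is invariant, under the polymer-solvent relabeling
(phi -> 1 - phi, N -> 1/N, chi -> N chi) that exchanges the two branches.

Both maps admit a Newton-accelerated ("improved") variant obtained by a
first-order expansion of the self-consistent operator:
h(phi) = phi + (g(phi) - phi)/(1 - g'(phi)) in 1D and
H(phi) = phi + (1 - J)^{-1} (G(phi) - phi) in 2D, J the Jacobian of G.

The dilute branch is carried in the log domain throughout: it decays as
exp(-N(chi - gamma)), so plain doubles underflow routinely; when
ln(phi_-) < -650 the solver switches to extended precision (mpmath).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import mpmath as mp
import numpy as np

from .errors import ConvergenceError, DomainError, NumericError, OnePhaseRegionError
from . import thermo
from .types import (
    BinodalPair,
    ClosedFormCoefficients,
    IterationOrbit,
    PolymerSolventSystem,
    ReducedParams,
)

__all__ = [
    "map_g",
    "map_g_prime",
    "improved_map_h",
    "solve_binodal_symmetric",
    "map_G",
    "jacobian",
    "improved_map_H",
    "reduced_params",
    "closed_form_coefficients",
    "closed_form_binodal",
    "dilute_scaling",
    "dilute_scaling_log",
    "solve_binodal",
    "solve_binodal_orbit",
    "map_g_field",
    "flow_field",
    "classify_fixed_points",
    "FixedPoint",
    "FlowField",
]

#: Newton correction denominators with magnitude below this fall back to a
#: plain map step (the correction is singular at the critical point, where
#: |g'| = 1).
SINGULAR_TOL = 1e-14

#: Below this value of ln(phi_-) double precision underflows and the solvers
#: switch to extended precision.
LOG_UNDERFLOW = -650.0

#: Solvers treat chi - chi_c below this as effectively critical and return
#: the Ginzburg-Landau pair directly (the maps are non-contractive there).
NEAR_CRITICAL_GUARD = 1e-6


# ----------------------------------------------------------------------
# symmetric N = 1 map
# ----------------------------------------------------------------------

def map_g(phi, chi):
    """One application of the symmetric (N = 1) binodal map.

    g(phi) = 1 / (1 + e^{chi (1 - 2 phi)}), the rearranged f'(phi) = 0
    condition.  Total on the reals (the Ginzburg-Landau guess may lie
    outside (0, 1)); its fixed points are phi_-^bin, 1/2 and phi_+^bin.
    """
    z = np.multiply(chi, 1.0 - 2.0 * np.asarray(phi, dtype=float))
    out = np.exp(-np.logaddexp(0.0, z))
    return out if out.ndim else float(out)


def _log_map_g(t: float, chi: float) -> float:
    """ln g(e^t): log-domain step for the dilute branch."""
    phi = math.exp(t)
    return -np.logaddexp(0.0, chi * (1.0 - 2.0 * phi))


def map_g_prime(phi, chi):
    """g'(phi) = 2 chi g (1 - g); equals 1 exactly at (phi_c, chi_c) = (1/2, 2)."""
    g = map_g(phi, chi)
    out = 2.0 * np.asarray(chi, dtype=float) * g * (1.0 - g)
    return out if out.ndim else float(out)


def improved_map_h(phi: float, chi: float) -> float:
    """Newton-accelerated 1D map h(phi) = phi + (g(phi) - phi)/(1 - g'(phi)).

    Solves the self-consistent equation to first order at each step; reduces
    to the plain map when g'(phi) = 0 and falls back to it when the
    denominator is singular (|1 - g'| < 1e-14).
    """
    value, _ = _improved_step_1d(phi, chi)
    return value


def _improved_step_1d(phi: float, chi: float) -> tuple[float, bool]:
    g = map_g(phi, chi)
    denom = 1.0 - map_g_prime(phi, chi)
    if abs(denom) < SINGULAR_TOL:
        return g, True
    return phi + (g - phi) / denom, False


def solve_binodal_symmetric(
    chi: float,
    order: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> BinodalPair:
    """Binodal of the symmetric N = 1 system.

    Parameters
    ----------
    chi : float
        Interaction strength; must exceed chi_c = 2.
    order : {1, 2, None}
        1 or 2 returns the closed form after that many applications of g to
        the Ginzburg-Landau guess; None iterates the Newton-accelerated map
        to the residual tolerance.

    The returned pair satisfies phi_+ = 1 - phi_- exactly (the dense branch
    is constructed from the dilute one by reflection).
    """
    if chi <= 2.0:
        raise OnePhaseRegionError(f"chi = {chi} <= chi_c = 2: one-phase region")
    delta_chi = chi - 2.0
    w = math.sqrt(6.0 * delta_chi) / 4.0
    phi0 = 0.5 - w  # dilute-branch Ginzburg-Landau guess
    if delta_chi < NEAR_CRITICAL_GUARD:
        return BinodalPair(0.5 - w, 0.5 + w, method="gl", iterations=0,
                           residual=_residual_symmetric(0.5 - w, chi))
    if order is not None:
        if order not in (1, 2):
            raise DomainError("order must be 1, 2 or None")
        t = _log_map_g(math.log(phi0), chi) if phi0 > 0 else math.log(map_g(phi0, chi))
        if order == 2:
            t = _log_map_g(t, chi)
        phi_minus = math.exp(t)
        return BinodalPair(phi_minus, 1.0 - phi_minus, method=f"order{order}",
                           iterations=order, residual=_residual_symmetric(phi_minus, chi),
                           log_phi_minus=t)
    # Newton-accelerated iteration
    phi = phi0
    for i in range(1, max_iter + 1):
        phi, _ = _improved_step_1d(phi, chi)
        res = _residual_symmetric(phi, chi)
        if res < tol:
            return BinodalPair(phi, 1.0 - phi, method="improved", iterations=i,
                               residual=res)
    raise ConvergenceError(
        f"symmetric solver did not reach residual {tol} in {max_iter} iterations "
        f"(chi={chi}, last residual={res})"
    )


def _residual_symmetric(phi_minus: float, chi: float) -> float:
    """Common-tangent residual of a symmetric pair (phi, 1 - phi).

    By symmetry Pi always matches; the residual is |mu| = |f'(phi_-)|.
    """
    if not (0.0 < phi_minus < 1.0):
        return math.inf
    return abs(
        math.log(phi_minus) - math.log1p(-phi_minus) + chi * (1.0 - 2.0 * phi_minus)
    )


# ----------------------------------------------------------------------
# general-N 2D map
# ----------------------------------------------------------------------

def _exponents(phi_minus: float, phi_plus: float, N: float, chi: float) -> tuple[float, float]:
    """The pair exponents x = 2 chi d and y = gamma d + chi (phi_+^2 - phi_-^2)."""
    gamma = 1.0 - 1.0 / N
    d = phi_plus - phi_minus
    x = 2.0 * chi * d
    y = gamma * d + chi * (phi_plus + phi_minus) * d
    return x, y


def _map_G_core(phi_minus: float, phi_plus: float, N: float, chi: float
                ) -> tuple[float, float, float]:
    """One application of G; returns (phi_-', phi_+', ln phi_-').

    Uses expm1/log so that e^{-N(x-y)} never underflows silently: the dilute
    branch is produced in the log domain first.
    """
    if phi_plus == phi_minus:
        # diagonal limit: G maps the diagonal to itself,
        # P = (gamma + 2 chi phi) / [(gamma + 2 chi phi) + N (2 chi - gamma - 2 chi phi)]
        gamma = 1.0 - 1.0 / N
        q = gamma + 2.0 * chi * phi_minus
        r = N * (2.0 * chi - gamma - 2.0 * chi * phi_minus)
        P = q / (q + r)
        return P, P, math.log(P) if P > 0 else -math.inf
    x, y = _exponents(phi_minus, phi_plus, N, chi)
    s = N * (x - y)
    num = -math.expm1(-y)
    den = -math.expm1(-(s + y))
    if den == 0.0 or not math.isfinite(num) or not math.isfinite(den):
        raise NumericError(
            f"non-finite intermediate in map G at pair=({phi_minus}, {phi_plus}), "
            f"N={N}, chi={chi}: y={y}, s={s}"
        )
    phi_plus_new = num / den
    if phi_plus_new <= 0.0 or not math.isfinite(phi_plus_new):
        raise NumericError(
            f"map G produced invalid dense branch {phi_plus_new} at "
            f"pair=({phi_minus}, {phi_plus}), N={N}, chi={chi}"
        )
    t_new = math.log(phi_plus_new) - s
    return math.exp(t_new), phi_plus_new, t_new


def map_G(pair, system: PolymerSolventSystem) -> tuple[float, float]:
    """One application of the general-N vector operator G.

    ``pair`` is (phi_minus, phi_plus); any real pair is accepted (the
    Ginzburg-Landau guess can lie outside (0, 1)).  At N = 1 the operator
    reproduces the scalar map g on each branch with phi_+ + phi_- = 1.
    """
    m, p, _ = _map_G_core(pair[0], pair[1], system.N, system.chi)
    return (m, p)


def jacobian(pair, system: PolymerSolventSystem) -> np.ndarray:
    """Analytic 2x2 Jacobian of G at ``pair``, ordered (phi_-, phi_+).

    Convergence of the orbit requires the eigenvalue moduli to be < 1 at the
    binodal fixed point; the moduli reach 1 at the critical point.
    """
    u, v = float(pair[0]), float(pair[1])
    N, chi = system.N, system.chi
    gamma = 1.0 - 1.0 / N
    x, y = _exponents(u, v, N, chi)
    s = N * (x - y)
    num = -math.expm1(-y)
    den = -math.expm1(-(s + y))
    if den == 0.0:
        raise NumericError(f"singular denominator in Jacobian at pair=({u}, {v})")
    P = num / den
    ey = math.exp(-y)
    esy = math.exp(-(s + y))
    es = math.exp(-s)
    dy_du = -(gamma + 2.0 * chi * u)
    dy_dv = gamma + 2.0 * chi * v
    dx_du = -2.0 * chi
    dx_dv = 2.0 * chi
    ds_du = N * (dx_du - dy_du)
    ds_dv = N * (dx_dv - dy_dv)
    dP_dy = ey / den - num * esy / den**2
    dP_ds = -num * esy / den**2
    dP_du = dP_dy * dy_du + dP_ds * ds_du
    dP_dv = dP_dy * dy_dv + dP_ds * ds_dv
    dM_du = es * (dP_du - P * ds_du)
    dM_dv = es * (dP_dv - P * ds_dv)
    J = np.array([[dM_du, dM_dv], [dP_du, dP_dv]], dtype=float)
    if not np.all(np.isfinite(J)):
        raise NumericError(f"non-finite Jacobian entries at pair=({u}, {v}): {J}")
    return J


def improved_map_H(pair, system: PolymerSolventSystem) -> tuple[float, float]:
    """Newton-accelerated 2D map H(phi) = phi + (1 - J)^{-1} (G(phi) - phi).

    Falls back to a plain G step when the 2x2 resolvent is singular
    (|det(1 - J)| < 1e-14); the orbit records such fallbacks.
    """
    out, _ = _improved_step_2d(pair, system)
    return out


def _improved_step_2d(pair, system: PolymerSolventSystem) -> tuple[tuple[float, float], bool]:
    G = map_G(pair, system)
    try:
        J = jacobian(pair, system)
    except NumericError:
        return G, True
    M = np.eye(2) - J
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    if abs(det) < SINGULAR_TOL:
        return G, True
    rhs = np.array([G[0] - pair[0], G[1] - pair[1]])
    delta = np.linalg.solve(M, rhs)
    return (float(pair[0] + delta[0]), float(pair[1] + delta[1])), False


# ----------------------------------------------------------------------
# reduced parameters and closed forms
# ----------------------------------------------------------------------

def reduced_params(system: PolymerSolventSystem) -> ReducedParams:
    """Reduced parameters (alpha, Delta) with the exponents at the GL guess.

    alpha is the Ginzburg-Landau half-width, Delta = phi_c.  At the guess
    phi_{+/-} = Delta +/- alpha the exponents collapse to x = 4 chi alpha and
    y = 2 alpha (gamma + 2 chi Delta); at N = 1 (Delta = 1/2, gamma = 0)
    x = 2 y and the 2D map degenerates to the scalar one.
    """
    cp = thermo.critical_point(system.N)
    delta_chi = system.chi - cp.chi_c
    if delta_chi < 0.0:
        raise OnePhaseRegionError(
            f"chi = {system.chi} < chi_c = {cp.chi_c}: one-phase region"
        )
    alpha = thermo.gl_half_width(system.N, delta_chi)
    Delta = cp.phi_c
    x = 4.0 * system.chi * alpha
    y = 2.0 * alpha * (cp.gamma + 2.0 * system.chi * Delta)
    return ReducedParams(alpha=alpha, Delta=Delta, gamma=cp.gamma, x=x, y=y)


def closed_form_coefficients(system: PolymerSolventSystem) -> ClosedFormCoefficients:
    """First-order exponents A, B and second-order coefficient D.

    A = y at the GL guess; B = N(x - y) at the GL guess;
    D = (1 - e^{-A})(1 - e^{-B})/(1 - e^{-A-B}) is the first-order pair
    width phi_+^(1) - phi_-^(1).
    """
    rp = reduced_params(system)
    N, chi = system.N, system.chi
    A = 2.0 * rp.alpha * (rp.gamma + 2.0 * chi * rp.Delta)
    B = 2.0 * N * rp.alpha * (2.0 * chi * (1.0 - rp.Delta) - rp.gamma)
    D = _pair_width(A, B)
    return ClosedFormCoefficients(A=A, B=B, D=D)


def _pair_width(A: float, B: float) -> float:
    """(1 - e^{-A})(1 - e^{-B})/(1 - e^{-A-B}), branch-swap invariant."""
    return math.expm1(-A) * math.expm1(-B) / (-math.expm1(-(A + B)))


def closed_form_binodal(system: PolymerSolventSystem, order: int = 2) -> BinodalPair:
    """Explicit first- or second-order self-consistent binodal.

    order=1:  phi_+ = (1 - e^{-A})/(1 - e^{-A-B}),  phi_- = phi_+ e^{-B}.
    order=2:  re-evaluate the exponents on the order-1 pair,
              y1 = D (gamma + chi S), s1 = N D (2 chi - gamma - chi S) with
              S the order-1 pair sum, and apply the update once more.

    These equal one (resp. two) applications of the operator G to the
    Ginzburg-Landau guess; both stay inside (0, 1) for every chi > chi_c.
    """
    if order not in (1, 2):
        raise DomainError("order must be 1 or 2")
    c = closed_form_coefficients(system)
    N, chi = system.N, system.chi
    gamma = 1.0 - 1.0 / N
    P1 = -math.expm1(-c.A) / -math.expm1(-(c.A + c.B))
    t1 = math.log(P1) - c.B
    if order == 1:
        m1 = math.exp(t1)
        return _pack_pair(system, m1, P1, t1, "first_order", 1)
    m1 = math.exp(t1)
    S = P1 + m1
    y1 = c.D * (gamma + chi * S)
    s1 = N * (c.D * 2.0 * chi - y1)
    P2 = -math.expm1(-y1) / -math.expm1(-(s1 + y1))
    t2 = math.log(P2) - s1
    return _pack_pair(system, math.exp(t2), P2, t2, "second_order", 2)


def _pack_pair(system, phi_minus, phi_plus, log_phi_minus, method, iterations):
    res = _residual_general(system, log_phi_minus, phi_plus)
    return BinodalPair(
        phi_minus=phi_minus,
        phi_plus=phi_plus,
        method=method,
        iterations=iterations,
        residual=res,
        log_phi_minus=log_phi_minus,
    )


def _residual_general(system: PolymerSolventSystem, t_minus: float, phi_plus: float) -> float:
    """max(|dmu|, |dPi|) with the dilute branch given as t = ln(phi_-)."""
    if not (phi_plus < 1.0) or not math.isfinite(t_minus) or t_minus >= 0.0:
        return math.inf
    N, chi = system.N, system.chi
    gamma = 1.0 - 1.0 / N
    pm = math.exp(t_minus)
    mu_m = (t_minus + 1.0) / N - math.log1p(-pm) - 1.0 + chi * (1.0 - 2.0 * pm)
    mu_p = (math.log(phi_plus) + 1.0) / N - math.log1p(-phi_plus) - 1.0 + chi * (1.0 - 2.0 * phi_plus)
    Pi_m = -math.log1p(-pm) - gamma * pm - chi * pm * pm
    Pi_p = -math.log1p(-phi_plus) - gamma * phi_plus - chi * phi_plus * phi_plus
    return max(abs(mu_p - mu_m), abs(Pi_p - Pi_m))


# ----------------------------------------------------------------------
# scaling law
# ----------------------------------------------------------------------

def dilute_scaling_log(system: PolymerSolventSystem) -> float:
    """ln of the large-chi dilute binodal scaling, -N (chi - gamma).

    Obtained by substituting the trivial guess (phi_-, phi_+) = (0, 1) into
    the self-consistent operator: e^{-x} -> e^{-2 chi}, e^{-y} -> e^{-gamma - chi},
    hence phi_-^bin ~ e^{-N (chi - gamma)}.  At N = 1 this is the e^{-chi} law.
    """
    gamma = 1.0 - 1.0 / system.N
    return -system.N * (system.chi - gamma)


def dilute_scaling(system: PolymerSolventSystem) -> float:
    """Approximate dilute binodal branch, exp(-N (chi - gamma)); valid chi >> chi_c."""
    return math.exp(dilute_scaling_log(system))


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------

_METHODS = ("gl", "first_order", "second_order", "iterate", "improved", "oracle")


def solve_binodal(
    system: PolymerSolventSystem,
    method: str = "improved",
    tol: float = 1e-10,
    max_iter: int = 50,
) -> BinodalPair:
    """Compute the binodal pair by the requested method.

    Methods: ``gl`` (Ginzburg-Landau, unclipped), ``first_order`` /
    ``second_order`` (closed forms), ``iterate`` (plain map G),
    ``improved`` (Newton-accelerated map H, the default), ``oracle``
    (high-precision common-tangent construction from
    :mod:`floryfit.reference`).

    For chi - chi_c < 1e-6 the Ginzburg-Landau pair is returned directly:
    the maps are non-contractive at criticality.
    """
    if method not in _METHODS:
        raise DomainError(f"unknown method {method!r}; choose from {_METHODS}")
    if method == "oracle":
        from . import reference

        return reference.oracle_binodal(system)
    cp = thermo.critical_point(system.N)
    if system.chi <= cp.chi_c:
        raise OnePhaseRegionError(
            f"chi = {system.chi} <= chi_c = {cp.chi_c}: one-phase region"
        )
    if method == "gl":
        return thermo.gl_binodal(system.N, system.chi)
    if method in ("first_order", "second_order"):
        return closed_form_binodal(system, order=1 if method == "first_order" else 2)
    orbit = solve_binodal_orbit(system, method=method, tol=tol, max_iter=max_iter)
    return _orbit_to_pair(system, orbit, tol)


def solve_binodal_orbit(
    system: PolymerSolventSystem,
    method: str = "improved",
    tol: float = 1e-10,
    max_iter: int = 50,
) -> IterationOrbit:
    """Iterate the (plain or Newton-accelerated) map and record the orbit.

    The first entry of the orbit is the Ginzburg-Landau initial guess.
    Branch identity phi_- <= phi_+ is enforced by ordering after every step.
    """
    if method not in ("iterate", "improved"):
        raise DomainError("orbit methods are 'iterate' and 'improved'")
    cp = thermo.critical_point(system.N)
    if system.chi <= cp.chi_c:
        raise OnePhaseRegionError(
            f"chi = {system.chi} <= chi_c = {cp.chi_c}: one-phase region"
        )
    if dilute_scaling_log(system) < LOG_UNDERFLOW:
        return _solve_orbit_mp(system, method, tol, max_iter)
    guess = thermo.gl_binodal(system.N, system.chi)
    pair = (guess.phi_minus, guess.phi_plus)
    orbit = IterationOrbit(method=method, iterates=[pair], residuals=[guess.residual])
    if system.chi - cp.chi_c < NEAR_CRITICAL_GUARD:
        return orbit
    for i in range(1, max_iter + 1):
        if method == "improved":
            pair, fellback = _improved_step_2d(pair, system)
            if fellback:
                orbit.fallback_steps.append(i)
        else:
            pair = map_G(pair, system)
        if pair[0] > pair[1]:
            pair = (pair[1], pair[0])
        t = math.log(pair[0]) if pair[0] > 0 else -math.inf
        res = _residual_general(system, t, pair[1])
        orbit.iterates.append(pair)
        orbit.residuals.append(res)
        if res < tol:
            break
    return orbit


def _orbit_to_pair(system: PolymerSolventSystem, orbit: IterationOrbit, tol: float) -> BinodalPair:
    pair = orbit.iterates[-1]
    res = orbit.residuals[-1]
    cp = thermo.critical_point(system.N)
    if len(orbit) == 1:  # near-critical guard returned the GL pair
        g = thermo.gl_binodal(system.N, system.chi)
        return g
    if res >= tol:
        raise ConvergenceError(
            f"{orbit.method} map did not reach residual {tol} within "
            f"{len(orbit) - 1} iterations (N={system.N}, chi={system.chi}, "
            f"last residual={res})"
        )
    if (
        abs(pair[1] - pair[0]) < 1e-12
        and system.chi > cp.chi_c + NEAR_CRITICAL_GUARD
    ):
        raise ConvergenceError(
            f"collapsed pair {pair} at chi={system.chi} > chi_c={cp.chi_c}: "
            "orbit converged to the trivial diagonal"
        )
    t = getattr(orbit, "log_phi_minus", None)
    if t is None:
        t = math.log(pair[0]) if pair[0] > 0 else -math.inf
    return BinodalPair(
        phi_minus=pair[0],
        phi_plus=pair[1],
        method=orbit.method,
        iterations=len(orbit) - 1,
        residual=res,
        log_phi_minus=t,
    )


def _solve_orbit_mp(system: PolymerSolventSystem, method: str, tol: float, max_iter: int
                    ) -> IterationOrbit:
    """Extended-precision orbit for ln(phi_-) < -650 (deep dilute branch).

    The working precision grows with chi so that the dense branch
    1 - phi_+ ~ e^{-(gamma + chi)} stays resolvable as a plain difference.
    """
    dps = max(80, int(0.4343 * (system.chi + 1.0)) + 40)
    with mp.workdps(dps):
        N = mp.mpf(system.N)
        chi = mp.mpf(system.chi)
        gamma = 1 - 1 / N
        cp = thermo.critical_point(system.N)
        alpha = mp.sqrt(6 * (chi - mp.mpf(cp.chi_c))) * N**mp.mpf("0.75") / (1 + mp.sqrt(N)) ** 2
        pair = (mp.mpf(cp.phi_c) - alpha, mp.mpf(cp.phi_c) + alpha)
        orbit = IterationOrbit(method=method, iterates=[(float(pair[0]), float(pair[1]))],
                               residuals=[math.inf])

        def G_mp(p):
            d = p[1] - p[0]
            x = 2 * chi * d
            y = gamma * d + chi * (p[1] + p[0]) * d
            s = N * (x - y)
            P = -mp.expm1(-y) / -mp.expm1(-(s + y))
            return (P * mp.exp(-s), P)

        def residual_mp(p):
            if not (0 < p[0] < p[1] < 1):
                return mp.inf
            mu = lambda q: (mp.log(q) + 1) / N - mp.log(1 - q) - 1 + chi * (1 - 2 * q)
            Pi = lambda q: -mp.log(1 - q) - gamma * q - chi * q * q
            return max(abs(mu(p[1]) - mu(p[0])), abs(Pi(p[1]) - Pi(p[0])))

        for i in range(1, max_iter + 1):
            if method == "improved":
                # finite-difference Jacobian in mp precision
                Gp = G_mp(pair)
                h = mp.mpf(10) ** (-30)
                J = mp.matrix(2, 2)
                for j in range(2):
                    q = list(pair)
                    q[j] += h
                    Gq = G_mp(tuple(q))
                    J[0, j] = (Gq[0] - Gp[0]) / h
                    J[1, j] = (Gq[1] - Gp[1]) / h
                M = mp.eye(2) - J
                det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
                if abs(det) < mp.mpf(10) ** (-40):
                    pair = Gp
                    orbit.fallback_steps.append(i)
                else:
                    rhs = mp.matrix([Gp[0] - pair[0], Gp[1] - pair[1]])
                    delta = mp.lu_solve(M, rhs)
                    pair = (pair[0] + delta[0], pair[1] + delta[1])
            else:
                pair = G_mp(pair)
            if pair[0] > pair[1]:
                pair = (pair[1], pair[0])
            res = residual_mp(pair)
            orbit.iterates.append((float(pair[0]), float(pair[1])))
            orbit.residuals.append(float(res))
            if res < tol:
                break
        # store the exact log of the dilute branch on the orbit for callers
        orbit.log_phi_minus = float(mp.log(pair[0])) if pair[0] > 0 else -math.inf
    return orbit


# ----------------------------------------------------------------------
# convergence diagnostics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint:
    """A fixed point of the flow dphi/dt = G(phi) - phi with its stability."""

    pair: tuple[float, float]
    kind: str  # 'stable', 'saddle' or 'unstable'
    eigenvalues: tuple[complex, complex]


@dataclass
class FlowField:
    """Velocity field of the continuous flow on a (phi_-, phi_+) grid."""

    phi_minus_grid: np.ndarray
    phi_plus_grid: np.ndarray
    velocity_minus: np.ndarray
    velocity_plus: np.ndarray
    fixed_points: list[FixedPoint] = field(default_factory=list)


def map_g_field(chi_values, phi_values) -> np.ndarray:
    """|g'(phi)| - 1 on a rectangular (chi, phi) grid (rows index chi).

    Negative values mark the contractive (stable-orbit) region; the zero
    contour passes exactly through the critical point (1/2, 2).
    """
    chi_arr = np.atleast_1d(np.asarray(chi_values, dtype=float))
    phi_arr = np.atleast_1d(np.asarray(phi_values, dtype=float))
    if chi_arr.size == 0 or phi_arr.size == 0:
        raise DomainError("diagnostic grid must be non-empty")
    C, P = np.meshgrid(chi_arr, phi_arr, indexing="ij")
    return np.abs(map_g_prime(P, C)) - 1.0


def flow_field(system: PolymerSolventSystem, phi_minus_values, phi_plus_values) -> FlowField:
    """Velocity field G(phi) - phi of the promoted continuous flow.

    The discrete orbit phi^(i+1) = G(phi^(i)) is promoted to
    dphi/dt = G(phi) - phi, whose fixed points and stability match those of
    the map; the classified fixed points are attached to the result.
    """
    u = np.atleast_1d(np.asarray(phi_minus_values, dtype=float))
    v = np.atleast_1d(np.asarray(phi_plus_values, dtype=float))
    if u.size == 0 or v.size == 0:
        raise DomainError("diagnostic grid must be non-empty")
    U, V = np.meshgrid(u, v, indexing="ij")
    Wm = np.empty_like(U)
    Wp = np.empty_like(U)
    for idx in np.ndindex(U.shape):
        try:
            m, p = map_G((U[idx], V[idx]), system)
            Wm[idx] = m - U[idx]
            Wp[idx] = p - V[idx]
        except NumericError:
            Wm[idx] = np.nan
            Wp[idx] = np.nan
    return FlowField(U, V, Wm, Wp, fixed_points=classify_fixed_points(system))


def _flow_jacobian(system: PolymerSolventSystem, pair, h: float = 1e-7) -> np.ndarray:
    """Centered-difference Jacobian of G - I (G is 0/0 on the diagonal, so the
    analytic form is not available there)."""
    J = np.empty((2, 2))
    for j in range(2):
        qp = list(pair)
        qm = list(pair)
        qp[j] += h
        qm[j] -= h
        Gp = map_G(tuple(qp), system)
        Gm = map_G(tuple(qm), system)
        J[0, j] = (Gp[0] - Gm[0]) / (2 * h)
        J[1, j] = (Gp[1] - Gm[1]) / (2 * h)
    return J - np.eye(2)


def classify_fixed_points(system: PolymerSolventSystem) -> list[FixedPoint]:
    """Fixed points of the flow: the binodal plus the diagonal (spinodal) pair.

    On the diagonal phi_- = phi_+ the limit of G is again diagonal and its
    fixed-point condition reduces to the spinodal quadratic, so the two
    diagonal fixed points sit exactly at the spinodal concentrations.  The
    off-diagonal fixed point is the binodal, the flow's unique attractor.
    Stability is read off the eigenvalues of the flow Jacobian d(G - I).
    """
    from . import reference

    out: list[FixedPoint] = []
    binodal = reference.oracle_binodal(system)
    spi = thermo.spinodal(system)
    for pair in [
        (binodal.phi_minus, binodal.phi_plus),
        (spi.phi_minus, spi.phi_minus),
        (spi.phi_plus, spi.phi_plus),
    ]:
        A = _flow_jacobian(system, pair)
        lam = np.linalg.eigvals(A)
        re = np.real(lam)
        if np.all(re < 0):
            kind = "stable"
        elif np.all(re > 0):
            kind = "unstable"
        else:
            kind = "saddle"
        out.append(FixedPoint(pair=pair, kind=kind, eigenvalues=(complex(lam[0]), complex(lam[1]))))
    return out
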