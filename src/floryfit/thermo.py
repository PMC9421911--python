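"""Two-component Flory-Huggins free energy and its exactly solvable landmarks.

The model describes mixing of a polymer of effective chain length ``N`` with
a structureless solvent on a lattice.  With polymer volume fraction ``phi``
(the solvent occupies ``1 - phi``) and k_B T = 1, the free energy density per
lattice site is

    f(phi) = (phi / N) ln(phi) + (1 - phi) ln(1 - phi) + chi phi (1 - phi).

The first two terms are the entropy of mixing, the third the effective
polymer-solvent contact energy.  This module provides f and its analytic
derivatives, the spinodal (f'' = 0), the critical point (f'' = f''' = 0) and
the Ginzburg-Landau (fourth-order near-critical) binodal.  All coexistence
solvers live in :mod:`floryfit.solvers` and :mod:`floryfit.reference`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

from .errors import DomainError, OnePhaseRegionError
from .types import (
    BinodalPair,
    ChemicalState,
    CriticalPoint,
    PolymerSolventSystem,
    SpinodalPair,
)

__all__ = [
    "free_energy_density",
    "chemical_potential",
    "osmotic_pressure",
    "chemical_state",
    "d2f",
    "d3f",
    "d4f",
    "critical_point",
    "spinodal",
    "spinodal_near_critical",
    "spinodal_dilute_scaling",
    "gl_binodal",
    "gl_half_width",
]


def free_energy_density(system: PolymerSolventSystem, phi):
    """Free energy per lattice site, f(phi), in units of k_B T.

    Accepts scalars or arrays.  The endpoints phi = 0 and phi = 1 are taken
    by continuity (x ln x -> 0); values outside [0, 1] raise
    :class:`DomainError`.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0.0) or np.any(phi_arr > 1.0):
        raise DomainError("phi must lie in [0, 1]")
    f = (
        special.xlogy(phi_arr, phi_arr) / system.N
        + special.xlogy(1.0 - phi_arr, 1.0 - phi_arr)
        + system.chi * phi_arr * (1.0 - phi_arr)
    )
    return f if f.ndim else float(f)


def _check_open_interval(phi) -> np.ndarray:
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0.0) or np.any(phi_arr >= 1.0):
        raise DomainError("phi must lie strictly in (0, 1); mu and Pi diverge at the endpoints")
    return phi_arr


def chemical_potential(system: PolymerSolventSystem, phi):
    """mu(phi) = f'(phi) = (ln phi + 1)/N - ln(1 - phi) - 1 + chi (1 - 2 phi)."""
    p = _check_open_interval(phi)
    mu = (np.log(p) + 1.0) / system.N - np.log1p(-p) - 1.0 + system.chi * (1.0 - 2.0 * p)
    return mu if mu.ndim else float(mu)


def osmotic_pressure(system: PolymerSolventSystem, phi):
    """Pi(phi) = phi f'(phi) - f(phi) = -ln(1 - phi) - gamma phi - chi phi^2.

    gamma = 1 - 1/N is the chain-length asymmetry parameter.
    """
    p = _check_open_interval(phi)
    gamma = 1.0 - 1.0 / system.N
    Pi = -np.log1p(-p) - gamma * p - system.chi * p * p
    return Pi if Pi.ndim else float(Pi)


def chemical_state(system: PolymerSolventSystem, phi: float) -> ChemicalState:
    """Bundle (mu, Pi) at one composition."""
    return ChemicalState(
        mu=chemical_potential(system, phi), Pi=osmotic_pressure(system, phi)
    )


def d2f(system: PolymerSolventSystem, phi):
    """f''(phi) = 1/(N phi) + 1/(1 - phi) - 2 chi; the spinodal is its zero set."""
    p = _check_open_interval(phi)
    out = 1.0 / (system.N * p) + 1.0 / (1.0 - p) - 2.0 * system.chi
    return out if out.ndim else float(out)


def d3f(system: PolymerSolventSystem, phi):
    """f'''(phi) = -1/(N phi^2) + 1/(1 - phi)^2."""
    p = _check_open_interval(phi)
    out = -1.0 / (system.N * p * p) + 1.0 / (1.0 - p) ** 2
    return out if out.ndim else float(out)


def d4f(system: PolymerSolventSystem, phi):
    """f''''(phi) = 2/(N phi^3) + 2/(1 - phi)^3."""
    p = _check_open_interval(phi)
    out = 2.0 / (system.N * p**3) + 2.0 / (1.0 - p) ** 3
    return out if out.ndim else float(out)


def critical_point(N: float) -> CriticalPoint:
    """Critical point of the N-chain model.

    Solving f''(phi_c) = f'''(phi_c) = 0 simultaneously gives

        chi_c = (1 + 1/sqrt(N))^2 / 2,   phi_c = 1 / (1 + sqrt(N)),

    together with the asymmetry parameter gamma = 1 - 1/N.  For N = 1 this
    reduces to chi_c = 2, phi_c = 1/2, gamma = 0.
    """
    if not (N >= 1.0) or not math.isfinite(N):
        raise DomainError(f"chain length N must be >= 1, got {N}")
    rootN = math.sqrt(N)
    return CriticalPoint(
        chi_c=0.5 * (1.0 + 1.0 / rootN) ** 2,
        phi_c=1.0 / (1.0 + rootN),
        gamma=1.0 - 1.0 / N,
    )


def spinodal(system: PolymerSolventSystem) -> SpinodalPair:
    """Both roots of f''(phi) = 0.

    The condition 1/(N phi) + 1/(1 - phi) = 2 chi is the quadratic
    2 chi phi^2 - (2 chi - gamma) phi + 1/N = 0 (after division by N), with
    gamma = 1 - 1/N.  The dilute root is recovered from the root product
    phi_- phi_+ = 1/(2 N chi) for numerical stability at large chi.

    Raises :class:`OnePhaseRegionError` when chi < chi_c(N).
    """
    N, chi = system.N, system.chi
    cp = critical_point(N)
    b = 2.0 * chi - cp.gamma
    disc = b * b - 8.0 * chi / N
    if disc < 0.0:
        raise OnePhaseRegionError(
            f"chi = {chi} < chi_c = {cp.chi_c}: no spinodal in the one-phase region"
        )
    phi_plus = (b + math.sqrt(disc)) / (4.0 * chi)
    phi_minus = 1.0 / (2.0 * N * chi * phi_plus)
    return SpinodalPair(phi_minus=phi_minus, phi_plus=phi_plus)


def spinodal_near_critical(N: float, delta_chi: float) -> SpinodalPair:
    """Leading-order spinodal expansion about the critical point.

    Expanding f'' about (phi_c, chi_c) (where f''_c = f'''_c = 0) gives
    (1/2) f''''_c dphi^2 = 2 dchi, i.e.

        phi_{+/-}^spi = phi_c +/- sqrt(2 dchi) N^{3/4} / (1 + sqrt(N))^2,

    the half-width shrinking as sqrt(dchi).
    """
    if delta_chi < 0.0:
        raise DomainError("delta_chi must be >= 0")
    cp = critical_point(N)
    w = math.sqrt(2.0 * delta_chi) * N**0.75 / (1.0 + math.sqrt(N)) ** 2
    return SpinodalPair(phi_minus=cp.phi_c - w, phi_plus=cp.phi_c + w)


def spinodal_dilute_scaling(N: float, chi: float) -> float:
    """Power-law form of the dilute spinodal root at large chi (or large N).

    Neglecting the solvent term in f'' = 0 gives phi_-^spi ~ 1/(2 N chi),
    a chi^-1 power law -- qualitatively different from the exponential decay
    of the dilute *binodal* branch.
    """
    return 1.0 / (2.0 * N * chi)


def gl_half_width(N: float, delta_chi: float) -> float:
    """Half-width of the Ginzburg-Landau binodal, sqrt(6 dchi) N^{3/4} / (1+sqrt N)^2."""
    return math.sqrt(6.0 * delta_chi) * N**0.75 / (1.0 + math.sqrt(N)) ** 2


def gl_binodal(N: float, chi: float) -> BinodalPair:
    """Ginzburg-Landau (near-critical) binodal.

    Expanding f about (phi_c, chi_c) and truncating at fourth order leaves a
    symmetric double well u(dphi) = -dchi dphi^2 + (f''''_c / 24) dphi^4
    whose common tangent touches at

        phi_{+/-} = phi_c +/- sqrt(12 dchi / f''''_c)
                  = phi_c +/- sqrt(6 dchi) N^{3/4} / (1 + sqrt(N))^2.

    The pair is sqrt(3) wider than the near-critical spinodal.  Far from the
    critical point the dilute branch leaves (0, 1); values are returned
    *unclipped*, since the self-consistent maps are defined on all of R and
    use this pair as their initial guess.
    """
    cp = critical_point(N)
    delta_chi = chi - cp.chi_c
    if delta_chi < 0.0:
        raise OnePhaseRegionError(
            f"chi = {chi} < chi_c = {cp.chi_c}: no binodal in the one-phase region"
        )
    w = gl_half_width(N, delta_chi)
    phi_minus, phi_plus = cp.phi_c - w, cp.phi_c + w
    residual = math.inf
    if 0.0 < phi_minus and phi_plus < 1.0 and phi_minus < phi_plus:
        system = PolymerSolventSystem(N=N, chi=chi) if chi > 0 else None
        if system is not None:
            dmu = chemical_potential(system, phi_plus) - chemical_potential(system, phi_minus)
            dPi = osmotic_pressure(system, phi_plus) - osmotic_pressure(system, phi_minus)
            residual = max(abs(dmu), abs(dPi))
    log_phi_minus = math.log(phi_minus) if phi_minus > 0 else math.nan
    return BinodalPair(
        phi_minus=phi_minus,
        phi_plus=phi_plus,
        method="gl",
        iterations=0,
        residual=residual,
        log_phi_minus=log_phi_minus,
    )
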