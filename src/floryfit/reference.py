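"""High-precision common-tangent binodal oracle.

Solves mu(phi_+) = mu(phi_-), Pi(phi_+) = Pi(phi_-) directly by nested
bracketed root-finding, independent of the self-consistent maps, so it can
serve as ground truth for them:

* outer loop: 1D root-find on the chemical-potential level mu.  For
  chi > chi_c the function mu(phi) has a local maximum at the dilute
  spinodal root and a local minimum at the dense one, so each level
  mu in (mu(phi_+^spi), mu(phi_-^spi)) picks exactly one composition on the
  dilute branch (0, phi_-^spi) and one on the dense branch (phi_+^spi, 1).
  The mismatch Pi(phi_+(mu)) - Pi(phi_-(mu)) is strictly increasing in mu
  (dPi = phi dmu), so it brackets a unique root.
* inner loops: bracketed 1D solves per branch; the dilute branch is solved
  in t = ln(phi) (it decays exponentially in N chi) and the dense branch in
  w = ln(1 - phi).
* a final 2D Newton polish in (t, phi_+) tightens the last digits.

When the dilute branch is deeper than double precision allows
(ln(phi_-) < -650) the whole construction runs in extended precision.
Not intended to be fast; this is a correctness oracle.
"""

from __future__ import annotations

import math

import mpmath as mp
import numpy as np
from scipy import optimize

from .errors import ConvergenceError, NumericError, OnePhaseRegionError
from . import solvers, thermo
from .types import BinodalPair, OracleOptions, PolymerSolventSystem

__all__ = ["oracle_binodal", "oracle_binodal_curve"]


def _mu_log(t: float, N: float, chi: float) -> float:
    """mu at phi = e^t, stable for very negative t."""
    phi = math.exp(t)
    return (t + 1.0) / N - math.log1p(-phi) - 1.0 + chi * (1.0 - 2.0 * phi)


def _mu_dense(w: float, N: float, chi: float) -> float:
    """mu at phi = 1 - e^w, stable for phi near 1."""
    phi = -math.expm1(w)
    return (math.log(phi) + 1.0) / N - w - 1.0 + chi * (1.0 - 2.0 * phi)


def _Pi_log(t: float, N: float, chi: float) -> float:
    phi = math.exp(t)
    gamma = 1.0 - 1.0 / N
    return -math.log1p(-phi) - gamma * phi - chi * phi * phi


def _Pi_dense(w: float, N: float, chi: float) -> float:
    phi = -math.expm1(w)
    gamma = 1.0 - 1.0 / N
    return -w - gamma * phi - chi * phi * phi


def oracle_binodal(system: PolymerSolventSystem, options: OracleOptions | None = None) -> BinodalPair:
    """Numerically exact binodal pair with residual below ``options.tol``.

    Raises :class:`OnePhaseRegionError` for chi <= chi_c and
    :class:`ConvergenceError` (with bracket state) if a bracket cannot be
    established.
    """
    opts = options or OracleOptions()
    cp = thermo.critical_point(system.N)
    if system.chi <= cp.chi_c:
        raise OnePhaseRegionError(
            f"chi = {system.chi} <= chi_c = {cp.chi_c}: one-phase region"
        )
    if solvers.dilute_scaling_log(system) < solvers.LOG_UNDERFLOW:
        return _oracle_mp(system, opts)
    N, chi = system.N, system.chi
    spi = thermo.spinodal(system)
    t_spi = math.log(spi.phi_minus)
    w_spi = math.log1p(-spi.phi_plus)
    mu_hi = _mu_log(t_spi, N, chi)   # local max of mu, on the dilute side
    mu_lo = _mu_dense(w_spi, N, chi)  # local min of mu, on the dense side
    if not mu_lo < mu_hi:
        raise ConvergenceError(
            f"degenerate mu bracket [{mu_lo}, {mu_hi}] at chi={chi}, N={N} "
            "(too close to the critical point)"
        )

    def dilute_root(m: float) -> float:
        # mu is increasing on (0, phi_-^spi); find t with mu(e^t) = m
        c0 = 1.0 / N - 1.0 + chi
        t_lo = min(N * (m - c0) - 2.0, t_spi - 2.0)
        for _ in range(opts.max_bisections):
            if _mu_log(t_lo, N, chi) < m:
                break
            t_lo -= 10.0
        else:
            raise ConvergenceError(f"no dilute bracket for mu={m} (t_lo={t_lo})")
        return optimize.brentq(lambda t: _mu_log(t, N, chi) - m, t_lo, t_spi,
                               xtol=1e-15, rtol=8.9e-16, maxiter=opts.max_bisections)

    def dense_root(m: float) -> float:
        # mu is increasing on (phi_+^spi, 1), i.e. decreasing in w
        c1 = 1.0 / N - 1.0 - chi
        w_lo = min(-(m - c1) - 2.0, w_spi - 2.0)
        for _ in range(opts.max_bisections):
            if _mu_dense(w_lo, N, chi) > m:
                break
            w_lo -= 10.0
        else:
            raise ConvergenceError(f"no dense bracket for mu={m} (w_lo={w_lo})")
        return optimize.brentq(lambda w: _mu_dense(w, N, chi) - m, w_lo, w_spi,
                               xtol=1e-15, rtol=8.9e-16, maxiter=opts.max_bisections)

    def mismatch(m: float) -> float:
        return _Pi_dense(dense_root(m), N, chi) - _Pi_log(dilute_root(m), N, chi)

    eps = 1e-9 * (mu_hi - mu_lo)
    a, b = mu_lo + eps, mu_hi - eps
    fa, fb = mismatch(a), mismatch(b)
    shrink = 0
    while fa * fb > 0 and shrink < 60:
        # mismatch is monotone; a lost sign change means the root sits in the
        # excluded margin -- tighten it
        eps *= 0.1
        a, b = mu_lo + eps, mu_hi - eps
        fa, fb = mismatch(a), mismatch(b)
        shrink += 1
    if fa * fb > 0:
        raise ConvergenceError(
            f"Pi-mismatch does not change sign on mu bracket [{a}, {b}] "
            f"(values {fa}, {fb}) at N={N}, chi={chi}"
        )
    mu_star = optimize.brentq(mismatch, a, b, xtol=1e-15, rtol=8.9e-16,
                              maxiter=opts.max_bisections)
    t = dilute_root(mu_star)
    w = dense_root(mu_star)
    t, w = _newton_polish(N, chi, t, w)
    res = _residual_tw(N, chi, t, w)
    if not res < opts.tol:
        t, w = _newton_polish(N, chi, t, w)  # one more round before giving up
        res = _residual_tw(N, chi, t, w)
    if not res < opts.tol:
        raise ConvergenceError(
            f"oracle residual {res} above tol {opts.tol} at N={N}, chi={chi}"
        )
    return BinodalPair(phi_minus=math.exp(t), phi_plus=-math.expm1(w),
                       method="oracle", iterations=0, residual=res,
                       log_phi_minus=t)


def _residual_tw(N: float, chi: float, t: float, w: float) -> float:
    """max(|dmu|, |dPi|) evaluated in the well-conditioned log charts."""
    return max(
        abs(_mu_dense(w, N, chi) - _mu_log(t, N, chi)),
        abs(_Pi_dense(w, N, chi) - _Pi_log(t, N, chi)),
    )


def _newton_polish(N: float, chi: float, t: float, w: float,
                   rounds: int = 4) -> tuple[float, float]:
    """Newton on F(t, w) = (dmu, dPi) with t = ln phi_-, w = ln(1 - phi_+).

    Working in the log charts keeps both branches well conditioned: the
    dilute branch decays exponentially and the dense branch hugs phi = 1.
    Derivatives: dmu/dt = phi_- f''(phi_-), dPi/dt = phi_-^2 f''(phi_-);
    dmu/dw = -(1 - phi_+) f''(phi_+), dPi/dw = -phi_+ (1 - phi_+) f''(phi_+).
    """
    for _ in range(rounds):
        pm = math.exp(t)
        q = math.exp(w)          # 1 - phi_plus
        pp = -math.expm1(w)      # phi_plus
        F0 = _mu_dense(w, N, chi) - _mu_log(t, N, chi)
        F1 = _Pi_dense(w, N, chi) - _Pi_log(t, N, chi)
        f2m = 1.0 / (N * pm) + 1.0 / (1.0 - pm) - 2.0 * chi
        f2p = 1.0 / (N * pp) + 1.0 / q - 2.0 * chi
        # rows: (dmu, dPi); columns: (t, w)
        J00, J01 = -pm * f2m, -q * f2p
        J10, J11 = -pm * pm * f2m, -pp * q * f2p
        det = J00 * J11 - J01 * J10
        if det == 0.0 or not math.isfinite(det):
            break
        dt = (-F0 * J11 + F1 * J01) / det
        dw = (-F1 * J00 + F0 * J10) / det
        if not (math.isfinite(dt) and math.isfinite(dw)):
            break
        t_new, w_new = t + dt, w + dw
        if t_new >= 0.0 or w_new >= 0.0:
            break
        t, w = t_new, w_new
    return t, w


def _oracle_mp(system: PolymerSolventSystem, opts: OracleOptions) -> BinodalPair:
    """Extended-precision oracle for dilute branches below double range."""
    dps = max(50, int(opts.precision_bits * 0.302) + 10)
    with mp.workdps(dps):
        N = mp.mpf(system.N)
        chi = mp.mpf(system.chi)
        gamma = 1 - 1 / N

        def mu_t(t):
            phi = mp.exp(t)
            return (t + 1) / N - mp.log1p(-phi) - 1 + chi * (1 - 2 * phi)

        def Pi_t(t):
            phi = mp.exp(t)
            return -mp.log1p(-phi) - gamma * phi - chi * phi * phi

        def mu_L(L):
            # dense branch in the L = ln(1 - phi_+) chart: -ln(1-phi) = -L exactly
            q = mp.exp(L)
            return (mp.log1p(-q) + 1) / N - L - 1 + chi * (2 * q - 1)

        def Pi_L(L):
            q = mp.exp(L)
            phi = 1 - q
            return -L - gamma * phi - chi * phi * phi

        # seed with the scaling law and a 2D Newton on (t, L = ln(1 - phi_+))
        t0 = mp.mpf(solvers.dilute_scaling_log(system))
        # dense seed: 1 - phi_+ ~ e^{-gamma - chi} from the trivial-guess limit
        L0 = -(gamma + chi)

        def F(t, L):
            return (mu_L(L) - mu_t(t), Pi_L(L) - Pi_t(t))

        t, L = t0, L0
        for _ in range(opts.max_bisections):
            f0, f1 = F(t, L)
            if max(abs(f0), abs(f1)) < mp.mpf(opts.tol) / 100:
                break
            h = mp.mpf(10) ** (-dps // 2)
            f0t, f1t = F(t + h, L)
            f0L, f1L = F(t, L + h)
            J = mp.matrix([[(f0t - f0) / h, (f0L - f0) / h],
                           [(f1t - f1) / h, (f1L - f1) / h]])
            delta = mp.lu_solve(J, mp.matrix([-f0, -f1]))
            t, L = t + delta[0], L + delta[1]
        f0, f1 = F(t, L)
        res = float(max(abs(f0), abs(f1)))
        if not res < opts.tol:
            raise ConvergenceError(
                f"extended-precision oracle residual {res} above tol {opts.tol} "
                f"at N={system.N}, chi={system.chi}"
            )
        phi_plus = float(1 - mp.exp(L))
        phi_minus = float(mp.exp(t))
        return BinodalPair(phi_minus=phi_minus, phi_plus=phi_plus, method="oracle",
                           iterations=0, residual=res, log_phi_minus=float(t))


def oracle_binodal_curve(N: float, chi_grid, options: OracleOptions | None = None
                         ) -> list[BinodalPair]:
    """Oracle binodal along a chi grid (continuation along the branch).

    Per-point failures are re-raised annotated with the offending chi value.
    """
    out: list[BinodalPair] = []
    for chi in np.asarray(chi_grid, dtype=float):
        try:
            out.append(oracle_binodal(PolymerSolventSystem(N=N, chi=float(chi)), options))
        except (ConvergenceError, NumericError) as exc:
            raise ConvergenceError(f"oracle failed at chi={chi}: {exc}") from exc
    return out
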