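"""Fit experimental binodal measurements to the Flory-Huggins model.

The model layer is dimensionless; this module owns all unit handling.  A
measurement is (variant, temperature [K], concentration [mol/L or g/L],
branch).  Concentrations map to volume fractions through
phi = c * M / rho (molar mass M, protein mass density rho), and temperature
maps to the interaction parameter through the enthalpic form

    chi(delta_eps, T) = delta_eps / (R T),

with delta_eps the effective per-lattice-site contact energy in kJ/mol and R
the gas constant, so that phase separation weakens on heating (UCST), as
observed for A1-LCD.

The global fit shares one effective chain length N across all variants and
assigns each variant its own delta_eps.  Predicted coexistence
concentrations come from the second-order closed-form binodal; residuals are
taken in ln(concentration) with both branches pooled, because the dilute and
dense branches differ by orders of magnitude (the dilute branch decays
exponentially in N chi).  Optimization uses nested deterministic 1D searches
(coarse grid + bounded Brent), so fits are bit-reproducible.

The fitted per-variant contact energies E = -N delta_eps are then decomposed
into per-residue contributions by solving the linear composition model
E_variant = E_0 + sum_i n_i dE_i.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DomainError, FormatError
from . import thermo
from .data import A1_LCD_MW_KDA, A1_LCD_RESIDUES, PROTEIN_DENSITY_G_CM3

__all__ = [
    "GAS_CONSTANT_KJ",
    "BinodalMeasurement",
    "FitConfig",
    "VariantFitResult",
    "GlobalFit",
    "ResidueEnergySolution",
    "concentration_to_volume_fraction",
    "volume_fraction_to_concentration",
    "chi_from_temperature",
    "critical_temperature",
    "predict_binodal_concentrations",
    "fit_global",
    "variant_energy_report",
    "parse_variant_label",
    "residue_energy_solve",
    "solve_energy_equations",
    "pairwise_difference_estimates",
]

#: Gas constant in kJ / (mol K); thermal energy in molar units so that
#: delta_eps carries kJ/mol.
GAS_CONSTANT_KJ = 8.31446261815324e-3

_UNITS = ("mol/L", "g/L")
_BRANCHES = ("dilute", "dense", "cloud_point")


@dataclass(frozen=True)
class BinodalMeasurement:
    """One experimental coexistence point."""

    variant: str
    temperature_K: float
    concentration: float
    unit: str
    branch: str

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise FormatError(f"unknown concentration unit {self.unit!r}; expected one of {_UNITS}")
        if self.branch not in _BRANCHES:
            raise FormatError(f"unknown branch {self.branch!r}; expected one of {_BRANCHES}")
        if not self.temperature_K > 0:
            raise DomainError(f"temperature must be positive, got {self.temperature_K}")
        if not self.concentration > 0:
            raise DomainError(f"concentration must be positive, got {self.concentration}")


def concentration_to_volume_fraction(
    c: float,
    unit: str = "mol/L",
    molecular_weight_kda: float = A1_LCD_MW_KDA,
    density_g_cm3: float = PROTEIN_DENSITY_G_CM3,
):
    """Convert concentration to volume fraction, phi = c M / rho.

    For c in mol/L, phi = c * (MW in g/mol) / (rho in g/L); for c in g/L,
    phi = c / rho.  Example: 1 mM at MW = 13.1 kDa and rho = 1.35 g/cm^3
    gives phi = 0.001 * 13100 / 1350 = 9.704e-3.
    """
    rho_g_L = density_g_cm3 * 1000.0
    # mol/L converts via the mass concentration c * MW so that datasets
    # expressed consistently in either unit map to bitwise-identical phi
    if unit == "mol/L":
        return np.divide(np.multiply(c, molecular_weight_kda * 1000.0), rho_g_L)
    if unit == "g/L":
        return np.divide(c, rho_g_L)
    raise FormatError(f"unknown concentration unit {unit!r}; expected one of {_UNITS}")


def volume_fraction_to_concentration(
    phi: float,
    unit: str = "mol/L",
    molecular_weight_kda: float = A1_LCD_MW_KDA,
    density_g_cm3: float = PROTEIN_DENSITY_G_CM3,
):
    """Inverse of :func:`concentration_to_volume_fraction` (exact roundtrip)."""
    rho_g_L = density_g_cm3 * 1000.0
    if unit == "mol/L":
        return np.divide(phi, molecular_weight_kda * 1000.0 / rho_g_L)
    if unit == "g/L":
        return np.multiply(phi, rho_g_L)
    raise FormatError(f"unknown concentration unit {unit!r}; expected one of {_UNITS}")


def chi_from_temperature(delta_eps_kj_mol: float, temperature_K):
    """chi = delta_eps / (R T): purely enthalpic, decreasing in T for delta_eps > 0."""
    T = np.asarray(temperature_K, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be positive")
    out = delta_eps_kj_mol / (GAS_CONSTANT_KJ * T)
    return out if out.ndim else float(out)


def critical_temperature(delta_eps_kj_mol: float, N: float) -> float:
    """Temperature at which chi(delta_eps, T) = chi_c(N) (UCST)."""
    chi_c = thermo.critical_point(N).chi_c
    return delta_eps_kj_mol / (GAS_CONSTANT_KJ * chi_c)


# ----------------------------------------------------------------------
# forward model
# ----------------------------------------------------------------------

def _closed_form_order2_log(N: float, chi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized second-order closed-form binodal: (ln phi_-, ln phi_+).

    Entries with chi <= chi_c come back as NaN.  This is the same algebra as
    :func:`floryfit.solvers.closed_form_binodal`, vectorized over chi for
    the fitting inner loop.
    """
    chi = np.asarray(chi, dtype=float)
    rootN = math.sqrt(N)
    chi_c = 0.5 * (1.0 + 1.0 / rootN) ** 2
    phi_c = 1.0 / (1.0 + rootN)
    gamma = 1.0 - 1.0 / N
    with np.errstate(invalid="ignore", divide="ignore"):
        dchi = chi - chi_c
        alpha = np.where(dchi > 0, np.sqrt(np.maximum(dchi, 0.0) * 6.0) * N**0.75
                         / (1.0 + rootN) ** 2, np.nan)
        A = 2.0 * alpha * (gamma + 2.0 * chi * phi_c)
        B = 2.0 * N * alpha * (2.0 * chi * (1.0 - phi_c) - gamma)
        P1 = np.expm1(-A) / np.expm1(-(A + B))
        t1 = np.log(P1) - B
        m1 = np.exp(t1)
        D = P1 - m1
        S = P1 + m1
        y1 = D * (gamma + chi * S)
        s1 = N * (2.0 * chi * D - y1)
        P2 = np.expm1(-y1) / np.expm1(-(s1 + y1))
        lp = np.log(P2)
        return lp - s1, lp


def predict_binodal_concentrations(
    N: float,
    delta_eps: float,
    temperatures,
    unit: str = "mol/L",
    molecular_weight_kda: float = A1_LCD_MW_KDA,
    density_g_cm3: float = PROTEIN_DENSITY_G_CM3,
) -> pd.DataFrame:
    """Predicted dilute/dense coexistence concentrations over a temperature grid.

    Supercritical temperatures (chi <= chi_c) produce NaN rows.
    """
    T = np.asarray(temperatures, dtype=float)
    chi = delta_eps / (GAS_CONSTANT_KJ * T)
    t_lo, t_hi = _closed_form_order2_log(N, chi)
    scale = volume_fraction_to_concentration(1.0, unit, molecular_weight_kda, density_g_cm3)
    return pd.DataFrame({
        "temperature_K": T,
        "chi": chi,
        "dilute": np.exp(t_lo) * scale,
        "dense": np.exp(t_hi) * scale,
    })


# ----------------------------------------------------------------------
# global fit
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Configuration of the global binodal fit."""

    reference_variant: str = "WT"
    molecular_weight_kda: float = A1_LCD_MW_KDA
    density_g_cm3: float = PROTEIN_DENSITY_G_CM3
    include_cloud_points: bool = False
    n_residues: int = A1_LCD_RESIDUES  # deterministic N initialisation
    N_bounds: tuple[float, float] = (10.0, 800.0)
    eps_bounds: tuple[float, float] = (0.05, 20.0)  # kJ/mol
    xatol_N: float = 1e-6
    xatol_eps: float = 1e-9
    #: weight of the smooth penalty applied to measurements whose temperature
    #: is supercritical for the trial parameters
    supercritical_penalty: float = 100.0


@dataclass(frozen=True)
class VariantFitResult:
    """Per-variant fit: site contact energy and derived protein-level energies."""

    variant: str
    delta_eps: float  # kJ/mol per lattice-site contact
    E: float          # protein-protein contact energy -N * delta_eps, kJ/mol
    delta_E: float    # E_variant - E_reference, kJ/mol
    rss: float        # residual sum of squares in ln(concentration)
    n_points: int


@dataclass(frozen=True)
class GlobalFit:
    """Result of the shared-N fit across variants."""

    N: float
    variants: dict[str, VariantFitResult]
    reference_variant: str
    conversion: tuple[float, float]  # (density g/cm^3, molecular weight kDa)
    total_rss: float
    excluded_variants: list[str] = field(default_factory=list)


def _variant_objective(N: float, delta_eps: float, T: np.ndarray, log_phi: np.ndarray,
                       branch_code: np.ndarray, penalty: float) -> float:
    """Pooled squared ln-residuals of one variant at (N, delta_eps).

    branch_code: 0 = dilute, 1 = dense, 2 = cloud point (compared against the
    critical composition).
    """
    chi = delta_eps / (GAS_CONSTANT_KJ * T)
    t_lo, t_hi = _closed_form_order2_log(N, chi)
    log_phi_c = -math.log1p(math.sqrt(N))
    pred = np.choose(branch_code, [t_lo, t_hi, np.full_like(t_lo, log_phi_c)])
    chi_c = 0.5 * (1.0 + 1.0 / math.sqrt(N)) ** 2
    bad = ~np.isfinite(pred)
    with np.errstate(invalid="ignore"):
        r = np.where(bad, 0.0, log_phi - pred)
    sse = float(np.nansum(r * r))
    if np.any(bad):
        # smooth barrier pushing chi back above chi_c for the offending points
        sse += float(np.sum((penalty * (chi_c - chi[bad]) / chi_c + 1.0) ** 2))
    return sse


def _refine_scalar(f, lo: float, hi: float, n_grid: int, xatol: float) -> tuple[float, float]:
    """Deterministic 1D minimisation: coarse grid, then bounded Brent around
    the best grid cell.  No stochastic restarts, so results are reproducible."""
    xs = np.linspace(lo, hi, n_grid)
    vals = [f(x) for x in xs]
    i = int(np.argmin(vals))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(f, bounds=(a, b), method="bounded",
                                   options={"xatol": xatol, "maxiter": 500})
    if res.fun <= vals[i]:
        return float(res.x), float(res.fun)
    return float(xs[i]), float(vals[i])


def fit_global(measurements, config: FitConfig | None = None) -> GlobalFit:
    """Fit one shared N and per-variant delta_eps to binodal measurements.

    ``measurements`` is an iterable of :class:`BinodalMeasurement` (or a
    DataFrame with columns variant, temperature_K, concentration, unit,
    branch).  Cloud-point rows are excluded from the objective unless
    ``config.include_cloud_points`` is set, in which case they are treated
    as estimates of the critical concentration.  Variants with no usable
    points are reported in ``excluded_variants``.
    """
    cfg = config or FitConfig()
    if isinstance(measurements, pd.DataFrame):
        rows = [BinodalMeasurement(str(r.variant), float(r.temperature_K),
                                   float(r.concentration), str(r.unit), str(r.branch))
                for r in measurements.itertuples(index=False)]
    else:
        rows = list(measurements)
    groups: dict[str, list[BinodalMeasurement]] = {}
    for m in rows:
        groups.setdefault(m.variant, []).append(m)

    usable: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    excluded: list[str] = []
    for variant, ms in groups.items():
        keep = [m for m in ms if m.branch != "cloud_point" or cfg.include_cloud_points]
        if not keep:
            excluded.append(variant)
            continue
        # canonical row order makes the objective exactly invariant under
        # reordering of the input measurements
        keep.sort(key=lambda m: (m.temperature_K, m.branch, m.concentration, m.unit))
        T = np.array([m.temperature_K for m in keep])
        phi = np.array([
            concentration_to_volume_fraction(m.concentration, m.unit,
                                             cfg.molecular_weight_kda, cfg.density_g_cm3)
            for m in keep
        ])
        branch_code = np.array([_BRANCHES.index(m.branch) for m in keep])
        usable[variant] = (T, np.log(phi), branch_code)
    if not usable:
        raise DomainError("no usable measurements: every variant was excluded")

    def eps_init(T: np.ndarray, log_phi: np.ndarray, branch_code: np.ndarray, N: float) -> float:
        # seed from the highest-temperature dilute point via the exponential
        # dilute scaling ln(phi) ~ -N (chi - gamma)
        gamma = 1.0 - 1.0 / N
        dil = branch_code == 0
        if np.any(dil):
            i = int(np.argmax(np.where(dil, T, -np.inf)))
        else:
            i = int(np.argmax(T))
        chi0 = gamma - log_phi[i] / N
        return max(chi0 * GAS_CONSTANT_KJ * T[i], cfg.eps_bounds[0] * 1.01)

    def fit_variant(N: float, data) -> tuple[float, float]:
        T, log_phi, branch_code = data
        e0 = min(max(eps_init(T, log_phi, branch_code, N), cfg.eps_bounds[0]), cfg.eps_bounds[1])
        lo = max(cfg.eps_bounds[0], 0.5 * e0)
        hi = min(cfg.eps_bounds[1], 2.0 * e0)
        f = lambda e: _variant_objective(N, e, T, log_phi, branch_code, cfg.supercritical_penalty)
        return _refine_scalar(f, lo, hi, 25, cfg.xatol_eps)

    def outer(N: float) -> float:
        return sum(fit_variant(N, d)[1] for d in usable.values())

    N0 = float(cfg.n_residues)
    lo = max(cfg.N_bounds[0], 0.5 * N0)
    hi = min(cfg.N_bounds[1], 2.5 * N0)
    N_hat, total = _refine_scalar(outer, lo, hi, 33, cfg.xatol_N)

    results: dict[str, VariantFitResult] = {}
    for variant, data in sorted(usable.items()):
        e_hat, rss = fit_variant(N_hat, data)
        results[variant] = VariantFitResult(
            variant=variant, delta_eps=e_hat, E=-N_hat * e_hat, delta_E=math.nan,
            rss=rss, n_points=len(data[0]),
        )
    ref = cfg.reference_variant
    if ref in results:
        E_ref = results[ref].E
        results = {
            v: VariantFitResult(r.variant, r.delta_eps, r.E, r.E - E_ref, r.rss, r.n_points)
            for v, r in results.items()
        }
    return GlobalFit(N=N_hat, variants=results, reference_variant=ref,
                     conversion=(cfg.density_g_cm3, cfg.molecular_weight_kda),
                     total_rss=total, excluded_variants=sorted(excluded))


def variant_energy_report(fit: GlobalFit) -> pd.DataFrame:
    """Tabulate (variant, delta_eps, E, delta_E, rss); reference row has dE = 0."""
    rows = [
        {
            "variant": r.variant,
            "delta_eps_kJ_mol": r.delta_eps,
            "E_kJ_mol": r.E,
            "delta_E_kJ_mol": r.delta_E,
            "rss": r.rss,
            "n_points": r.n_points,
        }
        for r in fit.variants.values()
    ]
    return pd.DataFrame(rows).sort_values("variant").reset_index(drop=True)


# ----------------------------------------------------------------------
# residue-level energy decomposition
# ----------------------------------------------------------------------

_LABEL_RE = re.compile(r"([+-]\d+)([A-Z])")


def parse_variant_label(label: str) -> dict[str, int]:
    """Parse a +/- nX composition label, e.g. '-12F+12Y' -> {'F': -12, 'Y': 12}."""
    matches = _LABEL_RE.findall(label.replace(" ", ""))
    if not matches:
        raise FormatError(f"cannot parse composition from variant label {label!r}")
    out: dict[str, int] = {}
    for n, res in matches:
        out[res] = out.get(res, 0) + int(n)
    return out


@dataclass(frozen=True)
class ResidueEnergySolution:
    """Per-residue contributions dE_i solving dE_variant = sum_i dn_i dE_i."""

    per_residue: dict[str, float]
    E0: float
    residual: float
    uncertainties: dict[str, float] = field(default_factory=dict)

    def reconstruct(self, composition: dict[str, int]) -> float:
        return self.E0 + sum(n * self.per_residue.get(r, 0.0) for r, n in composition.items())


def solve_energy_equations(equations: list[tuple[dict[str, float], float]]
                           ) -> ResidueEnergySolution:
    """Solve linear equations sum_i c_i dE_i = value for the per-residue dE_i.

    Exact solve when the system is square and nonsingular, least squares when
    overdetermined.  A rank-deficient system raises :class:`DomainError`
    listing the unresolved residue combinations (null-space directions).
    """
    residues = sorted({r for coeffs, _ in equations for r in coeffs})
    A = np.array([[coeffs.get(r, 0.0) for r in residues] for coeffs, _ in equations])
    b = np.array([v for _, v in equations], dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < len(residues):
        _, _, Vt = np.linalg.svd(A)
        null = Vt[rank:]
        combos = [
            " + ".join(f"{c:+.3g}*dE_{r}" for c, r in zip(row, residues) if abs(c) > 1e-10)
            for row in null
        ]
        raise DomainError(
            "rank-deficient residue system; unresolved combinations: " + "; ".join(combos)
        )
    sol, res_sq, *_ = np.linalg.lstsq(A, b, rcond=None)
    fitted = A @ sol
    residual = float(np.sqrt(np.sum((b - fitted) ** 2)))
    # per-unknown spread from the least-squares covariance when overdetermined
    unc: dict[str, float] = {}
    dof = len(equations) - len(residues)
    if dof > 0 and residual > 0:
        sigma2 = residual**2 / dof
        cov = sigma2 * np.linalg.inv(A.T @ A)
        unc = {r: float(np.sqrt(cov[i, i])) for i, r in enumerate(residues)}
    return ResidueEnergySolution(
        per_residue={r: float(v) for r, v in zip(residues, sol)},
        E0=0.0,
        residual=residual,
        uncertainties=unc,
    )


def residue_energy_solve(delta_E_table: dict[str, float],
                         composition_deltas: dict[str, dict[str, int]] | None = None
                         ) -> ResidueEnergySolution:
    """Decompose variant dE values into per-residue contributions.

    ``delta_E_table`` maps variant label -> dE_variant (kJ/mol).  Composition
    deltas default to parsing the +/- nX labels.  Because dE is measured
    relative to the reference sequence, the composition-independent offset
    E_0 cancels and the linear system is dE_variant = sum_i dn_i dE_i.
    """
    if composition_deltas is None:
        composition_deltas = {v: parse_variant_label(v) for v in delta_E_table}
    equations = [
        ({r: float(n) for r, n in composition_deltas[v].items()}, dE)
        for v, dE in delta_E_table.items()
    ]
    return solve_energy_equations(equations)


def pairwise_difference_estimates(delta_E_table: dict[str, float],
                                  residue_a: str, residue_b: str,
                                  composition_deltas: dict[str, dict[str, int]] | None = None
                                  ) -> pd.DataFrame:
    """Independent per-variant estimates of dE_a - dE_b.

    Applies to variants whose composition change is an exact swap
    (+n of a, -n of b, or the reverse): each such variant gives one estimate
    (dE_a - dE_b) = dE_variant / dn_a.  The spread across variants is the
    quoted uncertainty of the mean difference.
    """
    if composition_deltas is None:
        composition_deltas = {v: parse_variant_label(v) for v in delta_E_table}
    rows = []
    for v, dE in delta_E_table.items():
        comp = composition_deltas[v]
        na, nb = comp.get(residue_a, 0), comp.get(residue_b, 0)
        others = {r: n for r, n in comp.items() if r not in (residue_a, residue_b) and n != 0}
        if na != 0 and na == -nb and not others:
            rows.append({"variant": v, "estimate": dE / na})
    if not rows:
        raise DomainError(
            f"no variant isolates the {residue_a}-{residue_b} swap in the table"
        )
    return pd.DataFrame(rows)
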