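"""Core value types shared across the thermodynamics, solver and oracle layers.

Everything in the model layer is dimensionless: energies are measured in
units of k_B T, lengths in lattice sites, and concentrations as volume
fractions phi in (0, 1).  Unit handling (kelvin, kJ/mol, mol/L, g/L) lives
exclusively in :mod:`floryfit.fitting`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError


@dataclass(frozen=True)
class PolymerSolventSystem:
    """One thermodynamic state of the two-component Flory-Huggins model.

    Parameters
    ----------
    N : float
        Effective chain length, i.e. the number of lattice sites occupied by
        one solute molecule.  Real values >= 1 are allowed; fits to protein
        data routinely produce non-integer N.
    chi : float
        Flory interaction parameter in units of k_B T; must be positive.
    """

    N: float
    chi: float

    def __post_init__(self) -> None:
        if not (self.N >= 1.0) or not math.isfinite(self.N):
            raise DomainError(f"chain length N must be >= 1, got {self.N}")
        if not (self.chi > 0.0) or not math.isfinite(self.chi):
            raise DomainError(f"interaction strength chi must be > 0, got {self.chi}")


@dataclass(frozen=True)
class CriticalPoint:
    """Critical interaction strength and composition.

    chi_c = (1 + 1/sqrt(N))^2 / 2 and phi_c = 1/(1 + sqrt(N)); the asymmetry
    parameter gamma = 1 - 1/N vanishes in the symmetric N = 1 case.
    """

    chi_c: float
    phi_c: float
    gamma: float


@dataclass(frozen=True)
class SpinodalPair:
    """Dilute/dense roots of f''(phi) = 0 (local stability boundary)."""

    phi_minus: float
    phi_plus: float


@dataclass(frozen=True)
class ChemicalState:
    """Chemical potential mu = f'(phi) and osmotic pressure Pi = phi f' - f.

    At a valid binodal pair both quantities agree between the coexisting
    phases to the solver tolerance (common tangent construction).
    """

    mu: float
    Pi: float


@dataclass(frozen=True)
class BinodalPair:
    """Coexisting dilute/dense volume fractions plus solver metadata.

    ``log_phi_minus`` carries ln(phi_minus) exactly even when phi_minus
    underflows double precision (the dilute branch decays like
    exp(-N(chi - gamma)), so underflow is routine at large N*chi).
    ``residual`` is max(|mu_+ - mu_-|, |Pi_+ - Pi_-|); it may be infinite for
    unconverged approximations whose dilute branch leaves (0, 1), e.g. the
    Ginzburg-Landau guess far from the critical point.
    """

    phi_minus: float
    phi_plus: float
    method: str
    iterations: int = 0
    residual: float = math.nan
    log_phi_minus: float = math.nan

    def __post_init__(self) -> None:
        if math.isnan(self.log_phi_minus) and self.phi_minus > 0.0:
            object.__setattr__(self, "log_phi_minus", math.log(self.phi_minus))

    def as_tuple(self) -> tuple[float, float]:
        return (self.phi_minus, self.phi_plus)


@dataclass
class IterationOrbit:
    """Trajectory of map iterates, for convergence diagnostics.

    ``iterates[0]`` is always the initial guess (the Ginzburg-Landau pair).
    ``fallback_steps`` lists iteration indices at which a Newton-accelerated
    step was replaced by a plain map step because the linear correction was
    singular.
    """

    method: str
    iterates: list[tuple[float, float]] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    fallback_steps: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iterates)


@dataclass(frozen=True)
class ReducedParams:
    """Reduced parametrisation of the general-N self-consistent solution.

    alpha is the Ginzburg-Landau half-width and Delta = phi_c the critical
    composition; together they encode (N, chi) through
    N = ((1-Delta)/Delta)^2 and chi = chi_c + alpha^2 / (6 Delta (1-Delta)^3).
    x and y are the two binodal exponents evaluated at the Ginzburg-Landau
    guess (they are recomputed from the current pair at every map iterate).
    """

    alpha: float
    Delta: float
    gamma: float
    x: float
    y: float


@dataclass(frozen=True)
class ClosedFormCoefficients:
    """Exponents of the closed-form binodal expressions.

    A and B swap under the polymer-solvent relabeling
    (phi -> 1 - phi, N -> 1/N, chi -> N chi), which exchanges the dilute and
    dense branches; the second-order coefficient D is invariant under it.
    """

    A: float
    B: float
    D: float


@dataclass(frozen=True)
class OracleOptions:
    """Options for the high-precision common-tangent oracle."""

    tol: float = 1e-12
    max_bisections: int = 200
    precision_bits: int = 200

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise DomainError("tol must be positive")
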