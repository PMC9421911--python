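"""Synthetic coexistence datasets emulating temperature-resolved protein
LLPS measurements.

The generator mirrors the structure of published A1-LCD-style datasets: for
each protein variant, dilute- and dense-phase concentrations are measured
over a grid of temperatures below the variant's critical temperature, with
multiplicative (lognormal) measurement noise.  The forward model is the
second-order closed-form binodal combined with chi = delta_eps / (R T) and
the concentration/volume-fraction conversion -- exactly the model the fitter
inverts, so a noiseless dataset is recoverable to optimizer tolerance.

Ground-truth parameters travel in a JSON sidecar so that generated fixtures
are self-describing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from . import fitting
from .data import A1_LCD_MW_KDA, PROTEIN_DENSITY_G_CM3

__all__ = ["SyntheticDatasetSpec", "generate_synthetic_binodal", "write_synthetic_dataset"]


def _default_variants() -> dict[str, float]:
    # WT-like site contact energy with one stickier and one weaker variant;
    # the spread corresponds to protein-level dE of roughly +/- 15 kJ/mol
    # at N = 150, comparable to the measured A1-LCD variant range.
    return {"WT": 1.59, "STICKY": 1.70, "WEAK": 1.50}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Study conditions for one synthetic dataset.

    Defaults: 3 variants, 15 temperatures spanning 270-305 K (all subcritical
    for every variant), one point per branch per temperature, and 5%
    multiplicative lognormal noise.
    """

    true_N: float = 150.0
    variant_delta_eps: dict[str, float] = field(default_factory=_default_variants)
    temperatures: tuple[float, ...] = tuple(np.linspace(270.0, 305.0, 15))
    noise_sigma: float = 0.05
    points_per_branch: int = 1
    molecular_weight_kda: float = A1_LCD_MW_KDA
    density_g_cm3: float = PROTEIN_DENSITY_G_CM3
    unit: str = "mol/L"


def generate_synthetic_binodal(spec: SyntheticDatasetSpec, seed: int
                               ) -> tuple[pd.DataFrame, dict]:
    """Generate a measurement table plus its ground-truth metadata.

    Temperatures at which a variant is supercritical (chi <= chi_c) yield no
    rows for that variant; if every (variant, temperature) combination is
    supercritical a :class:`DomainError` is raised.  The same seed always
    produces the identical table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for variant in sorted(spec.variant_delta_eps):
        delta_eps = spec.variant_delta_eps[variant]
        T = np.asarray(spec.temperatures, dtype=float)
        chi = np.array([fitting.chi_from_temperature(delta_eps, t) for t in T])
        t_lo, t_hi = fitting._closed_form_order2_log(spec.true_N, chi)
        for Ti, lo, hi in zip(T, t_lo, t_hi):
            if not (math.isfinite(lo) and math.isfinite(hi)):
                continue  # supercritical at this temperature
            for log_phi, branch in ((lo, "dilute"), (hi, "dense")):
                c = fitting.volume_fraction_to_concentration(
                    math.exp(log_phi), spec.unit, spec.molecular_weight_kda,
                    spec.density_g_cm3)
                for _ in range(spec.points_per_branch):
                    noisy = c * math.exp(spec.noise_sigma * rng.standard_normal())
                    rows.append({
                        "variant": variant,
                        "temperature_K": round(float(Ti), 6),
                        "concentration": float(noisy),
                        "unit": spec.unit,
                        "branch": branch,
                    })
    if not rows:
        raise DomainError(
            "empty dataset: all requested temperatures are supercritical for "
            "every variant"
        )
    df = pd.DataFrame(rows)
    metadata = {
        "true_N": spec.true_N,
        "variant_delta_eps": dict(sorted(spec.variant_delta_eps.items())),
        "temperatures": [float(t) for t in spec.temperatures],
        "noise_sigma": spec.noise_sigma,
        "points_per_branch": spec.points_per_branch,
        "molecular_weight_kda": spec.molecular_weight_kda,
        "density_g_cm3": spec.density_g_cm3,
        "unit": spec.unit,
        "seed": int(seed),
        "critical_temperatures_K": {
            v: fitting.critical_temperature(e, spec.true_N)
            for v, e in sorted(spec.variant_delta_eps.items())
        },
    }
    return df, metadata


def write_synthetic_dataset(df: pd.DataFrame, metadata: dict, csv_path, sidecar_path=None) -> None:
    """Write the measurement CSV and its JSON ground-truth sidecar.

    Fixed float formatting keeps identical seeds byte-identical on disk.
    """
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False, float_format="%.12g")
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".truth.json")
    Path(sidecar_path).write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
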