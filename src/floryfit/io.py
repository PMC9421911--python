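"""Readers and writers for the package's plain-text formats.

Measurement CSV schema (one row per coexistence point):

    variant,temperature_K,concentration,unit,branch

with ``unit`` in {mol/L, g/L} and ``branch`` in {dilute, dense, cloud_point}.
Temperatures are always kelvin.  Validation errors carry line numbers.
Fit results are written both as CSV (per-variant table) and JSON (full
result, including the shared N and conversion constants).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .errors import FormatError
from .fitting import BinodalMeasurement, GlobalFit, variant_energy_report
from .types import IterationOrbit

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements_csv",
    "write_measurements_csv",
    "write_fit_report",
    "read_fit_report",
    "write_orbit_csv",
]

MEASUREMENT_COLUMNS = ("variant", "temperature_K", "concentration", "unit", "branch")


def read_measurements_csv(path) -> list[BinodalMeasurement]:
    """Read and validate a measurement table; errors cite the offending line."""
    path = Path(path)
    out: list[BinodalMeasurement] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(MEASUREMENT_COLUMNS) - set(reader.fieldnames):
            missing = set(MEASUREMENT_COLUMNS) - set(reader.fieldnames or [])
            raise FormatError(f"{path}: header missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(BinodalMeasurement(
                    variant=row["variant"].strip(),
                    temperature_K=float(row["temperature_K"]),
                    concentration=float(row["concentration"]),
                    unit=row["unit"].strip(),
                    branch=row["branch"].strip(),
                ))
            except (TypeError, ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {i}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no measurement rows")
    return out


def write_measurements_csv(measurements, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for m in measurements:
            writer.writerow([m.variant, repr(m.temperature_K), repr(m.concentration),
                             m.unit, m.branch])


def write_fit_report(fit: GlobalFit, json_path=None, csv_path=None) -> dict:
    """Serialize a global fit; returns the JSON-ready dict."""
    payload = {
        "N": fit.N,
        "reference_variant": fit.reference_variant,
        "conversion": {
            "density_g_cm3": fit.conversion[0],
            "molecular_weight_kda": fit.conversion[1],
        },
        "total_rss": fit.total_rss,
        "excluded_variants": fit.excluded_variants,
        "variants": {
            v: {
                "delta_eps_kJ_mol": r.delta_eps,
                "E_kJ_mol": r.E,
                "delta_E_kJ_mol": r.delta_E,
                "rss": r.rss,
                "n_points": r.n_points,
            }
            for v, r in fit.variants.items()
        },
    }
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if csv_path is not None:
        variant_energy_report(fit).to_csv(csv_path, index=False, float_format="%.12g")
    return payload


def read_fit_report(json_path) -> dict:
    payload = json.loads(Path(json_path).read_text())
    for key in ("N", "variants"):
        if key not in payload:
            raise FormatError(f"{json_path}: fit report missing key {key!r}")
    return payload


def write_orbit_csv(orbit: IterationOrbit, path) -> None:
    """Dump an iteration orbit (iterate index, pair, residual) for diagnostics."""
    df = pd.DataFrame({
        "iteration": range(len(orbit.iterates)),
        "phi_minus": [p[0] for p in orbit.iterates],
        "phi_plus": [p[1] for p in orbit.iterates],
        "residual": orbit.residuals,
        "fallback": [i in orbit.fallback_steps for i in range(len(orbit.iterates))],
    })
    df.to_csv(path, index=False, float_format="%.17g")
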