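"""Leaf δ13C → discrimination → c_i/c_a → intrinsic water-use efficiency.

C3 leaves discriminate against 13C during CO2 uptake. The discrimination

    Δ_plant = (δ13C_air − δ13C_plant) / (1 + δ13C_plant/1000)

maps linearly onto the intercellular-to-ambient CO2 ratio through the
simple two-fractionation model

    Δ_plant = a + (b − a) · c_i/c_a,

with a = 4.4‰ (diffusion in air) and b = 27‰ (net biochemical
fractionation appropriate to bulk leaf material). Intrinsic water-use
efficiency then follows from Fick's law and the 1.6 H2O:CO2 diffusivity
ratio:

    iWUE = A/g_s = c_a (1 − c_i/c_a) / 1.6   [µmol mol⁻¹].

This deliberately simple model neglects boundary-layer, mesophyll,
photorespiration and ternary corrections; it yields a leaf-lifetime
integrated c_i/c_a from dried herbarium material. c_i/c_a values outside
[0, 1] (possible under real isotope noise) are returned flagged, not
clamped, so downstream regressions see the same scatter the data carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core_data import AtmosphereSeries, SpecimenRecord, records_to_frame

__all__ = [
    "A_DIFFUSION", "B_BIOCHEMICAL",
    "IsotopeResult",
    "delta_plant",
    "ci_over_ca",
    "iwue",
    "specimen_iwue",
    "delta_from_ci_over_ca",
    "delta13c_plant_from_delta",
    "augment_with_iwue",
]

#: Fractionation from diffusion of CO2 in air, permil.
A_DIFFUSION = 4.4
#: Combined net biochemical fractionation for bulk leaf material, permil.
B_BIOCHEMICAL = 27.0


@dataclass(frozen=True)
class IsotopeResult:
    """Isotope-derived quantities for one specimen."""

    delta_plant: float  # permil
    ci_over_ca: float  # dimensionless
    ci: float  # ppm
    iwue: float  # umol mol^-1
    out_of_range: bool  # ci/ca outside [0, 1]


def delta_plant(d13c_plant, d13c_air):
    """Carbon isotope discrimination Δ_plant (‰)."""
    plant = np.asarray(d13c_plant, dtype=float)
    air = np.asarray(d13c_air, dtype=float)
    if np.any(plant == -1000.0):
        raise ValueError("delta13C_plant = -1000 permil is singular")
    out = (air - plant) / (1.0 + plant / 1000.0)
    scalar = np.ndim(d13c_plant) == 0 and np.ndim(d13c_air) == 0
    return float(out) if scalar else out


def ci_over_ca(delta, a: float = A_DIFFUSION, b: float = B_BIOCHEMICAL):
    """c_i/c_a from discrimination: (Δ − a)/(b − a).

    Values outside [0, 1] are returned as-is; callers flag them.
    """
    d = np.asarray(delta, dtype=float)
    out = (d - a) / (b - a)
    return float(out) if np.ndim(delta) == 0 else out


def iwue(ca, ratio):
    """Intrinsic water-use efficiency c_a (1 − c_i/c_a)/1.6, µmol mol⁻¹."""
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr <= 0):
        raise ValueError("c_a must be positive")
    out = ca_arr * (1.0 - np.asarray(ratio, dtype=float)) / 1.6
    scalar = np.ndim(ca) == 0 and np.ndim(ratio) == 0
    return float(out) if scalar else out


def delta_from_ci_over_ca(ratio, a: float = A_DIFFUSION,
                          b: float = B_BIOCHEMICAL):
    """Inverse of :func:`ci_over_ca`: Δ = a + (b − a)·(c_i/c_a)."""
    return a + (b - a) * np.asarray(ratio, dtype=float)


def delta13c_plant_from_delta(delta, d13c_air):
    """Invert the discrimination equation to a plant δ13C (‰).

    Used by the synthetic-data generator to back-compute leaf isotope
    values from a target c_i/c_a trajectory.
    """
    d = np.asarray(delta, dtype=float)
    air = np.asarray(d13c_air, dtype=float)
    return (air - d) / (1.0 + d / 1000.0)


def specimen_iwue(record: SpecimenRecord, atmosphere: AtmosphereSeries,
                  a: float = A_DIFFUSION, b: float = B_BIOCHEMICAL,
                  ) -> IsotopeResult | None:
    """Full isotope chain for one specimen; ``None`` when δ13C is absent.

    Raises :class:`~herbwue.core_data.AtmosphereError` when the collection
    year is outside the atmosphere series.
    """
    if record.delta13c is None:
        return None
    ca_t, d13_air = atmosphere.lookup(record.year)
    d = delta_plant(record.delta13c, d13_air)
    r = ci_over_ca(d, a=a, b=b)
    return IsotopeResult(
        delta_plant=d,
        ci_over_ca=r,
        ci=r * ca_t,
        iwue=iwue(ca_t, r),
        out_of_range=not (0.0 <= r <= 1.0),
    )


def augment_with_iwue(records: Iterable[SpecimenRecord],
                      atmosphere: AtmosphereSeries,
                      a: float = A_DIFFUSION, b: float = B_BIOCHEMICAL,
                      ) -> pd.DataFrame:
    """Specimen table with Δ_plant, c_i/c_a and iWUE columns appended."""
    records = list(records)
    df = records_to_frame(records)
    cols = {"delta_plant_permil": [], "ci_over_ca": [],
            "iwue_umol_mol": [], "ci_ca_out_of_range": []}
    for rec in records:
        res = specimen_iwue(rec, atmosphere, a=a, b=b)
        if res is None:
            cols["delta_plant_permil"].append(np.nan)
            cols["ci_over_ca"].append(np.nan)
            cols["iwue_umol_mol"].append(np.nan)
            cols["ci_ca_out_of_range"].append(False)
        else:
            cols["delta_plant_permil"].append(res.delta_plant)
            cols["ci_over_ca"].append(res.ci_over_ca)
            cols["iwue_umol_mol"].append(res.iwue)
            cols["ci_ca_out_of_range"].append(res.out_of_range)
    for k, v in cols.items():
        df[k] = v
    return df
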