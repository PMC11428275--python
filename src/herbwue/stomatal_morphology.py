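"""Anatomical maximum stomatal conductance from stomatal traits.

The theoretical maximum stomatal conductance to water vapour, g_smax,
is the diffusion-limited ceiling set by stomatal anatomy alone — every
stoma fully open:

    g_smax = (d_w / v) * D * a_max / (p + (pi/2) * sqrt(a_max / pi))

with d_w the diffusivity of water vapour in air at 25 degC, v the molar
volume of air, D the stomatal density, a_max the maximum pore area
(an ellipse, pi L^2 / 8, from pore length L) and p the pore depth, taken
equal to the guard-cell width (guard cells inflate to a circular
cross-section). All quantities are converted to SI before evaluation;
the interface speaks the units the data are published in (mm^-2, um).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import SpecimenRecord, records_to_frame

__all__ = [
    "D_W", "V_AIR",
    "GsmaxResult",
    "amax_from_pore_length",
    "gsmax",
    "leaf_gsmax",
    "augment_with_gsmax",
]

#: Diffusivity of water vapour in air at 25 degC, m^2 s^-1.
D_W = 2.49e-5
#: Molar volume of air at 25 degC, m^3 mol^-1.
V_AIR = 2.24e-2

_UM2_TO_M2 = 1e-12
_UM_TO_M = 1e-6
_PER_MM2_TO_PER_M2 = 1e6


@dataclass(frozen=True)
class GsmaxResult:
    """Anatomical conductance for one leaf.

    ``from_leaf_mean_length`` records that a_max came from a single
    pre-averaged pore length rather than per-stoma areas (mean of squares
    differs from square of the mean, so provenance matters).
    """

    amax: float  # um^2
    pore_depth: float  # um
    gsmax: float  # mol m^-2 s^-1
    from_leaf_mean_length: bool = False

    @property
    def gsmax_mmol(self) -> float:
        return self.gsmax * 1e3


def amax_from_pore_length(pore_length):
    """Maximum pore area (um^2) of an elliptical pore, pi L^2 / 8.

    Accepts a scalar or array of pore lengths in um.
    """
    L = np.asarray(pore_length, dtype=float)
    if np.any(L < 0):
        raise ValueError("pore length must be nonnegative")
    out = math.pi * L ** 2 / 8.0
    return float(out) if np.ndim(pore_length) == 0 else out


def gsmax(stomatal_density, amax, pore_depth):
    """Theoretical maximum stomatal conductance, mol m^-2 s^-1.

    Parameters
    ----------
    stomatal_density : float or array
        D, stomata per mm^2.
    amax : float or array
        Maximum pore area, um^2.
    pore_depth : float or array
        p, pore depth (guard-cell width), um.
    """
    D = np.asarray(stomatal_density, dtype=float) * _PER_MM2_TO_PER_M2
    a = np.asarray(amax, dtype=float) * _UM2_TO_M2
    p = np.asarray(pore_depth, dtype=float) * _UM_TO_M
    if np.any(D <= 0) or np.any(a <= 0) or np.any(p <= 0):
        raise ValueError("gsmax requires strictly positive D, a_max and p")
    depth_term = p + (math.pi / 2.0) * np.sqrt(a / math.pi)
    out = (D_W / V_AIR) * D * a / depth_term
    scalar = all(np.ndim(x) == 0 for x in (stomatal_density, amax, pore_depth))
    return float(out) if scalar else out


def leaf_gsmax(record: SpecimenRecord,
               per_stoma_lengths: Sequence[float] | None = None,
               ) -> GsmaxResult | None:
    """g_smax for one specimen; ``None`` when anatomy is incomplete.

    When the raw per-stoma pore lengths are available, a_max is computed
    per stoma and the ten (or however many) areas averaged, matching the
    measurement protocol. Otherwise a_max comes from the leaf-mean length
    stored on the record and the result is flagged.
    """
    if per_stoma_lengths is not None:
        lengths = np.asarray(per_stoma_lengths, dtype=float)
        if lengths.size == 0:
            raise ValueError("per_stoma_lengths is empty")
        amax = float(np.mean(amax_from_pore_length(lengths)))
        from_mean = False
    elif record.pore_length is not None:
        amax = amax_from_pore_length(record.pore_length)
        from_mean = True
    else:
        return None
    if record.stomatal_density is None or record.guard_cell_width is None:
        return None
    g = gsmax(record.stomatal_density, amax, record.guard_cell_width)
    return GsmaxResult(amax=amax, pore_depth=record.guard_cell_width,
                       gsmax=g, from_leaf_mean_length=from_mean)


def augment_with_gsmax(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    """Specimen table with appended a_max (um^2) and g_smax (mmol m^-2 s^-1).

    Specimens lacking anatomy get empty cells, never zeros.
    """
    records = list(records)
    df = records_to_frame(records)
    amax_col, gsmax_col = [], []
    for rec in records:
        res = leaf_gsmax(rec)
        amax_col.append(res.amax if res is not None else np.nan)
        gsmax_col.append(res.gsmax_mmol if res is not None else np.nan)
    df["amax_um2"] = amax_col
    df["gsmax_mmol_m2_s"] = gsmax_col
    return df
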