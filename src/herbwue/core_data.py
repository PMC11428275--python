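"""Data model, CSV I/O and validation for herbarium gas-exchange inference.

The pipeline's empirical unit is a single herbarium leaf (one
:class:`SpecimenRecord`): its stomatal anatomy (density ``D``, pore length
``L``, guard-cell width used as pore depth ``p``), bulk-leaf carbon isotope
composition (δ13C) and the structural/chemical traits (LMA, N per area)
needed to parameterise the biochemical model. Each specimen is anchored in
time through its collection year and the annual atmosphere record
(:class:`AtmosphereSeries`): ambient CO2 mole fraction ``c_a`` (ppm) and
δ13C of atmospheric CO2 (‰ vs VPDB).

Units are fixed per column and never auto-detected: ``D`` in mm⁻², lengths
in µm, δ13C in ‰, LMA and N_area in g m⁻². An empty CSV cell means
"not measured"; zero is a (rejected) measured value, never a sentinel.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenRecord",
    "AtmosphereSeries",
    "SpecimenTableError",
    "AtmosphereError",
    "RejectionReport",
    "read_specimen_table",
    "write_specimen_table",
    "read_atmosphere_series",
    "validate_records",
    "records_to_frame",
]

#: Mandatory CSV columns for a specimen table.
MANDATORY_COLUMNS = ("specimen_id", "species", "year")

#: Optional numeric columns, in canonical order.
OPTIONAL_COLUMNS = (
    "stomatal_density_per_mm2",
    "pore_length_um",
    "guard_cell_width_um",
    "delta13c_permil",
    "lma_g_m2",
    "n_area_g_m2",
)


class SpecimenTableError(ValueError):
    """Raised for malformed specimen tables; carries row context when known."""


class AtmosphereError(ValueError):
    """Raised for invalid atmosphere series or out-of-range year lookups."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One herbarium leaf's measured traits.

    ``stomatal_density`` is the leaf mean of five field-of-view counts
    (mm⁻²); ``pore_length`` the leaf mean of ten stomatal pore lengths (µm);
    ``guard_cell_width`` (µm) serves as the stomatal pore depth. δ13C, LMA
    and N_area are optional — ``None`` marks an absent measurement.
    """

    specimen_id: str
    species: str
    year: int
    stomatal_density: float | None = None  # mm^-2
    pore_length: float | None = None  # um
    guard_cell_width: float | None = None  # um
    delta13c: float | None = None  # permil vs VPDB
    lma: float | None = None  # g m^-2
    n_area: float | None = None  # g m^-2

    @property
    def sla(self) -> float | None:
        """Specific leaf area, m² g⁻¹ — the inverse of LMA."""
        if self.lma is None:
            return None
        return 1.0 / self.lma

    def has_anatomy(self) -> bool:
        return (
            self.stomatal_density is not None
            and self.pore_length is not None
            and self.guard_cell_width is not None
        )


class AtmosphereSeries:
    """Annual atmosphere record: year -> (c_a in ppm, δ13C_air in ‰).

    Years must be strictly increasing with no gaps in the declared range;
    c_a must be positive. Lookups outside the covered range raise
    :class:`AtmosphereError` rather than extrapolating.
    """

    def __init__(self, years: Sequence[int], ca: Sequence[float],
                 delta13c_air: Sequence[float]):
        years = np.asarray(years, dtype=int)
        ca = np.asarray(ca, dtype=float)
        d13 = np.asarray(delta13c_air, dtype=float)
        if not (len(years) == len(ca) == len(d13)):
            raise AtmosphereError("years, ca and delta13c_air lengths differ")
        if len(years) == 0:
            raise AtmosphereError("empty atmosphere series")
        if len(np.unique(years)) != len(years):
            raise AtmosphereError("duplicate years in atmosphere series")
        if np.any(np.diff(years) <= 0):
            raise AtmosphereError("years must be strictly increasing")
        if np.any(np.diff(years) != 1):
            raise AtmosphereError("atmosphere series has gaps between years")
        if np.any(ca <= 0):
            raise AtmosphereError("c_a must be positive")
        if np.any(~np.isfinite(ca)) or np.any(~np.isfinite(d13)):
            raise AtmosphereError("non-finite atmosphere values")
        self._years = years
        self._ca = ca
        self._d13 = d13

    @property
    def years(self) -> np.ndarray:
        return self._years.copy()

    @property
    def year_range(self) -> tuple[int, int]:
        return int(self._years[0]), int(self._years[-1])

    def covers(self, year: int) -> bool:
        return self._years[0] <= year <= self._years[-1]

    def _index(self, year) -> np.ndarray:
        year = np.asarray(year, dtype=int)
        lo, hi = self.year_range
        if np.any(year < lo) or np.any(year > hi):
            raise AtmosphereError(
                f"year outside atmosphere coverage {lo}-{hi}"
            )
        return year - lo

    def ca(self, year) -> float | np.ndarray:
        """c_a (ppm) for a year or array of years."""
        out = self._ca[self._index(year)]
        return float(out) if np.isscalar(year) or np.ndim(year) == 0 else out

    def delta13c_air(self, year) -> float | np.ndarray:
        """δ13C of atmospheric CO2 (‰) for a year or array of years."""
        out = self._d13[self._index(year)]
        return float(out) if np.isscalar(year) or np.ndim(year) == 0 else out

    def lookup(self, year: int) -> tuple[float, float]:
        """(c_a, δ13C_air) pair for one year."""
        i = self._index(year)
        return float(self._ca[i]), float(self._d13[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self._years, "ca_ppm": self._ca,
             "delta13c_air_permil": self._d13}
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, tuple[float, float]]
                     ) -> "AtmosphereSeries":
        years = sorted(mapping)
        ca = [mapping[y][0] for y in years]
        d13 = [mapping[y][1] for y in years]
        return cls(years, ca, d13)


def _parse_cell(raw, column: str, row_index: int, *, as_int: bool = False):
    """Parse one CSV cell; empty -> None; malformed -> row-level error."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    try:
        value = float(text)
        if as_int:
            if not value.is_integer():
                raise ValueError
            return int(value)
        return value
    except ValueError:
        raise SpecimenTableError(
            f"row {row_index}: malformed value {text!r} in column {column!r}"
        ) from None


def read_specimen_table(path: str | Path, **read_csv_kwargs) -> list[SpecimenRecord]:
    """Read a specimen CSV (UTF-8, header row, '.' decimal) into records.

    Missing optional cells become ``None``. A malformed numeric cell raises
    :class:`SpecimenTableError` naming the row and column; a missing
    mandatory column raises it naming the column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **read_csv_kwargs)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SpecimenTableError(f"missing mandatory column {col!r}")
    records: list[SpecimenRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        year = _parse_cell(row["year"], "year", i, as_int=True)
        if year is None:
            raise SpecimenTableError(f"row {i}: empty mandatory field 'year'")
        kwargs = {}
        for col, attr in zip(OPTIONAL_COLUMNS, (
                "stomatal_density", "pore_length", "guard_cell_width",
                "delta13c", "lma", "n_area")):
            kwargs[attr] = (_parse_cell(row[col], col, i)
                            if col in row else None)
        records.append(SpecimenRecord(
            specimen_id=str(row["specimen_id"]),
            species=str(row["species"]),
            year=year,
            **kwargs,
        ))
    return records


def records_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the canonical column order."""
    rows = []
    for r in records:
        rows.append({
            "specimen_id": r.specimen_id,
            "species": r.species,
            "year": r.year,
            "stomatal_density_per_mm2": r.stomatal_density,
            "pore_length_um": r.pore_length,
            "guard_cell_width_um": r.guard_cell_width,
            "delta13c_permil": r.delta13c,
            "lma_g_m2": r.lma,
            "n_area_g_m2": r.n_area,
        })
    return pd.DataFrame(rows, columns=MANDATORY_COLUMNS + OPTIONAL_COLUMNS)


def write_specimen_table(records: Iterable[SpecimenRecord],
                         path: str | Path) -> None:
    """Write records as CSV; absent values become empty cells.

    Numbers are written with :func:`repr` precision so a write/read round
    trip reproduces every field exactly.
    """
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")


def read_atmosphere_series(path: str | Path | None = None) -> AtmosphereSeries:
    """Read an atmosphere CSV; ``None`` loads the bundled 1927–2015 table.

    The bundled table is assembled by monotone interpolation of published
    annual-record anchor points (ice-core and direct-measurement c_a,
    declining δ13C_air) and is user-replaceable by passing a path.
    """
    if path is None:
        ref = importlib.resources.files("herbwue.data").joinpath(
            "atmosphere_1927_2015.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise AtmosphereError("atmosphere table needs year and ca columns")
    year = df[cols[0]].to_numpy()
    ca = df[cols[1]].to_numpy(dtype=float)
    d13 = (df[cols[2]].to_numpy(dtype=float) if len(cols) > 2
           else np.full(len(df), np.nan))
    return AtmosphereSeries(year, ca, d13)


@dataclass
class RejectionReport:
    """Itemised record rejections, serialisable as JSON lines."""

    rejections: list[dict] = field(default_factory=list)

    def add(self, record: SpecimenRecord, reason: str) -> None:
        self.rejections.append(
            {"specimen_id": record.specimen_id, "species": record.species,
             "year": record.year, "reason": reason})

    @property
    def total(self) -> int:
        return len(self.rejections)

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rejections:
            out[r["reason"]] = out.get(r["reason"], 0) + 1
        return out

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r) for r in self.rejections)


def validate_records(records: Sequence[SpecimenRecord],
                     atmosphere: AtmosphereSeries | None = None,
                     ) -> tuple[list[SpecimenRecord], RejectionReport]:
    """Drop records violating type invariants; report what was dropped.

    Checks: present traits strictly positive (density, lengths, LMA,
    N_area) and, when an atmosphere series is given, collection year within
    its coverage. Report-only: never raises. Idempotent.
    """
    report = RejectionReport()
    clean: list[SpecimenRecord] = []
    positive_fields = (
        ("stomatal_density", "nonpositive density"),
        ("pore_length", "nonpositive pore length"),
        ("guard_cell_width", "nonpositive guard cell width"),
        ("lma", "nonpositive LMA"),
        ("n_area", "nonpositive N_area"),
    )
    for rec in records:
        reason = None
        for attr, why in positive_fields:
            v = getattr(rec, attr)
            if v is not None and (not math.isfinite(v) or v <= 0):
                reason = why
                break
        if reason is None and atmosphere is not None and not atmosphere.covers(rec.year):
            reason = "year outside atmosphere coverage"
        if reason is None:
            clean.append(rec)
        else:
            report.add(rec, reason)
    return clean, report
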