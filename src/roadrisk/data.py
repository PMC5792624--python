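"""Areal-unit ingestion, validation and filtering.

The unit of analysis is an Indian state or Union Territory (UT) with its
population, a short span of annual road-death counts, and the covariates used
by the fatality regression: annual diesel consumption (a freight/taxi proxy),
national-highway length, urban population, and satellite-derived built-up
area. Island UTs, which have essentially no road network shared with the
mainland system, are flagged and excluded before analysis. Deaths occurring
at railway level crossings — where trains rather than road traffic are the
striking vehicle — may be supplied separately and are then subtracted
year-wise from the road-death counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_YEARS: tuple[int, ...] = (2010, 2011, 2012)

_REQUIRED_COLUMNS = (
    "unit_id",
    "name",
    "is_island",
    "population",
    "urban_population",
    "built_up_area_km2",
    "nh_length_km",
    "diesel_kt",
)

_COUNT_COLUMNS = ("population", "urban_population")
_NONNEG_COLUMNS = ("nh_length_km", "diesel_kt")


class SchemaError(ValueError):
    """Raised when an input table violates the canonical schema."""


@dataclass(frozen=True)
class AreaUnit:
    """One areal unit (state/UT) with population, deaths and covariates.

    ``deaths_by_year`` holds road deaths; if ``rail_deaths_by_year`` is
    non-empty those level-crossing deaths have *not* yet been removed and are
    subtracted year-wise by :func:`average_annual_fatalities`.
    """

    unit_id: str
    name: str
    is_island: bool
    population: float
    urban_population: float
    built_up_area_km2: float
    nh_length_km: float
    diesel_kt: float
    deaths_by_year: Mapping[int, float]
    rail_deaths_by_year: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"unit {self.unit_id!r}: population must be > 0")
        if self.urban_population < 0 or self.urban_population > self.population:
            raise ValueError(
                f"unit {self.unit_id!r}: urban_population must lie in [0, population]"
            )
        if self.built_up_area_km2 <= 0:
            raise ValueError(f"unit {self.unit_id!r}: built_up_area_km2 must be > 0")
        if self.nh_length_km < 0 or self.diesel_kt < 0:
            raise ValueError(f"unit {self.unit_id!r}: covariates must be >= 0")
        for year, count in self.deaths_by_year.items():
            if count < 0:
                raise ValueError(f"unit {self.unit_id!r}: deaths in {year} negative")
        for year, count in self.rail_deaths_by_year.items():
            if count < 0:
                raise ValueError(
                    f"unit {self.unit_id!r}: rail deaths in {year} negative"
                )


@dataclass(frozen=True)
class StudyFrame:
    """Ordered collection of :class:`AreaUnit` sharing one list of years."""

    units: tuple[AreaUnit, ...]
    years: tuple[int, ...] = DEFAULT_YEARS

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate unit_id values: {dupes}")
        for u in self.units:
            missing = [y for y in self.years if y not in u.deaths_by_year]
            if missing:
                raise SchemaError(
                    f"unit {u.unit_id!r}: deaths missing for years {missing}"
                )

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def unit(self, unit_id: str) -> AreaUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def to_dataframe(self) -> pd.DataFrame:
        """Canonical wide table, one row per unit."""
        rows = []
        for u in self.units:
            row = {
                "unit_id": u.unit_id,
                "name": u.name,
                "is_island": u.is_island,
                "population": u.population,
                "urban_population": u.urban_population,
                "built_up_area_km2": u.built_up_area_km2,
                "nh_length_km": u.nh_length_km,
                "diesel_kt": u.diesel_kt,
            }
            for y in self.years:
                row[f"deaths_{y}"] = u.deaths_by_year[y]
            if u.rail_deaths_by_year:
                for y in self.years:
                    row[f"rail_deaths_{y}"] = u.rail_deaths_by_year.get(y, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def load_area_units(
    path: str | Path, years: Sequence[int] = DEFAULT_YEARS
) -> StudyFrame:
    """Read the canonical ``units.csv`` into a validated :class:`StudyFrame`.

    Required columns: unit_id, name, is_island, population, urban_population,
    built_up_area_km2, nh_length_km, diesel_kt, and deaths_YYYY for every
    analysis year. Optional rail_deaths_YYYY columns carry railway-crossing
    deaths to be subtracted downstream. Any missing column, non-numeric
    count, or duplicate unit_id is rejected with the offending row named.
    """
    df = pd.read_csv(path, dtype={"unit_id": str, "name": str})
    death_cols = tuple(f"deaths_{y}" for y in years)
    missing = [c for c in _REQUIRED_COLUMNS + death_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    rail_cols = {y: f"rail_deaths_{y}" for y in years if f"rail_deaths_{y}" in df.columns}

    numeric_cols = list(_COUNT_COLUMNS + _NONNEG_COLUMNS)
    numeric_cols += ["built_up_area_km2", *death_cols, *rail_cols.values()]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            row = df.loc[bad[0]]
            raise SchemaError(
                f"{path}: non-numeric value {row[col]!r} in column {col!r} "
                f"for unit_id {row['unit_id']!r}"
            )
        df[col] = coerced

    dup = df["unit_id"][df["unit_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate unit_id {dup.iloc[0]!r}")

    units = []
    for _, row in df.iterrows():
        units.append(
            AreaUnit(
                unit_id=row["unit_id"],
                name=row["name"],
                is_island=_parse_flag(row["is_island"], row["unit_id"]),
                population=float(row["population"]),
                urban_population=float(row["urban_population"]),
                built_up_area_km2=float(row["built_up_area_km2"]),
                nh_length_km=float(row["nh_length_km"]),
                diesel_kt=float(row["diesel_kt"]),
                deaths_by_year={y: float(row[f"deaths_{y}"]) for y in years},
                rail_deaths_by_year={
                    y: float(row[c]) for y, c in rail_cols.items()
                },
            )
        )
    return StudyFrame(units=tuple(units), years=tuple(years))


def _parse_flag(value, unit_id: str) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in {"true", "1", "yes"}:
            return True
        if v in {"false", "0", "no"}:
            return False
        raise SchemaError(f"unit {unit_id!r}: unparseable is_island flag {value!r}")
    return bool(value)


def filter_units(frame: StudyFrame) -> StudyFrame:
    """Drop island units, preserving the order of the rest. Idempotent."""
    kept = tuple(u for u in frame.units if not u.is_island)
    return StudyFrame(units=kept, years=frame.years)


def average_annual_fatalities(
    unit: AreaUnit,
    years: Sequence[int] = DEFAULT_YEARS,
    subtract_rail: bool = True,
) -> float:
    """Unweighted mean of yearly road deaths over the analysis years.

    Railway-crossing deaths, when recorded for the unit, are subtracted from
    the matching year before averaging (set ``subtract_rail=False`` if the
    source counts already exclude them). Raises if any analysis year is
    missing.
    """
    missing = [y for y in years if y not in unit.deaths_by_year]
    if missing:
        raise ValueError(f"unit {unit.unit_id!r}: no death count for years {missing}")
    totals = []
    for y in years:
        d = unit.deaths_by_year[y]
        if subtract_rail and unit.rail_deaths_by_year:
            d -= unit.rail_deaths_by_year.get(y, 0.0)
        totals.append(d)
    return float(sum(totals) / len(totals))


def fatality_rate(
    unit: AreaUnit,
    years: Sequence[int] = DEFAULT_YEARS,
    subtract_rail: bool = True,
    per: float = 100_000.0,
) -> float:
    """Average annual road deaths per 100,000 persons."""
    if unit.population <= 0:
        raise ValueError(f"unit {unit.unit_id!r}: population must be positive")
    return average_annual_fatalities(unit, years, subtract_rail) / unit.population * per


def validation_report(frame: StudyFrame) -> dict:
    """Machine-readable summary of the validated frame."""
    rates = [fatality_rate(u) for u in frame.units] if len(frame) else []
    return {
        "n_units": len(frame),
        "n_islands": sum(u.is_island for u in frame.units),
        "years": list(frame.years),
        "mean_fatality_rate_per_100k": (
            float(sum(rates) / len(rates)) if rates else None
        ),
    }


def write_canonical(
    frame: StudyFrame, csv_path: str | Path, report_path: str | Path | None = None
) -> None:
    """Write the validated canonical CSV plus an optional JSON report."""
    frame.to_dataframe().to_csv(csv_path, index=False)
    if report_path is not None:
        Path(report_path).write_text(json.dumps(validation_report(frame), indent=2))


__all__ = [
    "AreaUnit",
    "StudyFrame",
    "SchemaError",
    "DEFAULT_YEARS",
    "load_area_units",
    "filter_units",
    "average_annual_fatalities",
    "fatality_rate",
    "validation_report",
    "write_canonical",
]
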