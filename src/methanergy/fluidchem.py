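"""Site fluid-geochemistry tables: data model, readers/writers, validation.

One :class:`SiteSample` holds the measured physicochemical, geochemical and
isotopic parameters of a single sampling site (spring, river or groundwater
well). Concentrations are in µmol/L; "bdl" (below detection limit) cells are
stored as ``None`` and excluded from summaries — no imputation is performed.

The package ships the Santa Elena Ophiolite field dataset (nine sites: three
hyperalkaline springs, three surface-water and three groundwater-well
background sites) as a CSV fixture, loadable with :func:`load_seo_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Callable, Optional

import pandas as pd

__all__ = [
    "SiteSample",
    "ColumnDialect",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "read_site_table",
    "write_site_table",
    "validate_sample",
    "load_seo_fixture",
    "summarize_sites",
    "NUMERIC_FIELDS",
    "REQUIRED_FIELDS",
]

SITE_TYPES = ("spring", "river", "well")

#: canonical tokens interpreted as "no value" / below detection limit
NA_TOKENS = ("", "bdl", "Bdl", "BDL", "ND", "NA", "NaN", "nan")

#: detection limits kept as table metadata (µmol/L), never substituted
DETECTION_LIMITS_UM = {"don_uM": 0.1, "ch4_uM": 0.3}


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class ValidationError(ValueError):
    """Table-level constraint violated (e.g. duplicate site_id)."""


@dataclass
class SiteSample:
    """Measured fluid chemistry of one sampling site.

    All concentrations in µmol/L; ``None`` means not measured or below the
    detection limit. ``so4_uM`` is carried explicitly because the
    sulfate-coupled methane-oxidation reaction needs it, but it is absent
    from the packaged field dataset — downstream scenarios must supply an
    assumed value rather than the table silently inventing one.
    """

    site_id: str
    site_type: str
    temperature_C: float
    pH: float
    conductivity_uS_cm: Optional[float] = None
    tds_ppm: Optional[float] = None
    salinity_ppm: Optional[float] = None
    orp_mV: Optional[float] = None
    doc_uM: Optional[float] = None
    dic_uM: Optional[float] = None
    d13C_CO2_permil: Optional[float] = None
    tdn_uM: Optional[float] = None
    nox_uM: Optional[float] = None
    no2_uM: Optional[float] = None
    nh4_uM: Optional[float] = None
    don_uM: Optional[float] = None
    po4_uM: Optional[float] = None
    tdp_uM: Optional[float] = None
    ch4_uM: Optional[float] = None
    d13C_CH4_permil: Optional[float] = None
    h2_uM: Optional[float] = None
    d18O_permil: Optional[float] = None
    d2H_permil: Optional[float] = None
    so4_uM: Optional[float] = None


NUMERIC_FIELDS: tuple[str, ...] = tuple(
    f.name for f in fields(SiteSample) if f.name not in ("site_id", "site_type")
)

#: concentration fields that must be >= 0 when present
_CONCENTRATION_FIELDS = tuple(f for f in NUMERIC_FIELDS if f.endswith("_uM"))

REQUIRED_FIELDS = (
    "site_id",
    "site_type",
    "temperature_C",
    "pH",
    "dic_uM",
    "doc_uM",
    "ch4_uM",
    "h2_uM",
)


@dataclass
class ColumnDialect:
    """Maps canonical SiteSample field names onto a third-party table.

    ``column_map``: canonical field -> source column header (identity for
    fields not listed). ``scale``: canonical field -> multiplicative factor
    applied after parsing (e.g. 1000.0 for a table reporting mM where µM is
    canonical). No other unit conversion is attempted.
    """

    column_map: dict[str, str] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    na_tokens: tuple[str, ...] = NA_TOKENS

    def source_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


def _parse_cell(raw, dialect: ColumnDialect, row: int, column: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text in dialect.na_tokens:
        return None
    try:
        # decimal point only; reject locale-style decimal commas explicitly
        return float(text)
    except ValueError:
        raise ParseError(
            f"non-numeric value {text!r} at row {row}, column {column!r}"
        ) from None


def read_site_table(path: str | Path, dialect: ColumnDialect | None = None) -> list[SiteSample]:
    """Read a delimited site-chemistry table into SiteSample records.

    Raises :class:`SchemaError` if a required column is missing,
    :class:`ParseError` on non-numeric cells (naming row and column) and
    :class:`ValidationError` on duplicate site ids.
    """
    dialect = dialect or ColumnDialect()
    df = pd.read_csv(path, dtype=str, comment="#", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    for canonical in REQUIRED_FIELDS:
        if dialect.source_column(canonical) not in df.columns:
            raise SchemaError(
                f"required column {dialect.source_column(canonical)!r} "
                f"(field {canonical!r}) missing; found {list(df.columns)}"
            )

    samples: list[SiteSample] = []
    for i, row in df.iterrows():
        values: dict[str, object] = {}
        for f in fields(SiteSample):
            col = dialect.source_column(f.name)
            if col not in df.columns:
                continue
            raw = row[col]
            if f.name in ("site_id", "site_type"):
                values[f.name] = "" if raw is None or (isinstance(raw, float) and math.isnan(raw)) else str(raw).strip()
            else:
                parsed = _parse_cell(raw, dialect, int(i) + 2, col)
                if parsed is not None and f.name in dialect.scale:
                    parsed *= dialect.scale[f.name]
                values[f.name] = parsed
        samples.append(SiteSample(**values))  # type: ignore[arg-type]

    ids = [s.site_id for s in samples]
    dupes = {x for x in ids if ids.count(x) > 1}
    if dupes:
        raise ValidationError(f"duplicate site_id values: {sorted(dupes)}")
    return samples


def write_site_table(samples: Iterable[SiteSample], path: str | Path) -> None:
    """Write samples back to CSV; ``None`` becomes an empty cell.

    Numbers are emitted with ``repr`` (shortest round-trip decimal text), so
    read -> write -> read is lossless.
    """
    rows = []
    for s in samples:
        d = asdict(s)
        rows.append({k: ("" if v is None else v) for k, v in d.items()})
    pd.DataFrame(rows, columns=[f.name for f in fields(SiteSample)]).to_csv(
        path, index=False
    )


def validate_sample(s: SiteSample) -> list[str]:
    """Return human-readable invariant violations (empty list = valid)."""
    violations: list[str] = []
    if s.site_type not in SITE_TYPES:
        violations.append(f"site_type {s.site_type!r} not one of {SITE_TYPES}")
    if not s.site_id:
        violations.append("site_id is empty")
    if s.pH is None or not (0.0 < s.pH < 14.0):
        violations.append(f"pH {s.pH} outside (0, 14)")
    if s.temperature_C is None or not (0.0 < s.temperature_C < 60.0):
        violations.append(f"temperature_C {s.temperature_C} outside (0, 60)")
    for name in _CONCENTRATION_FIELDS:
        v = getattr(s, name)
        if v is not None and v < 0:
            violations.append(f"{name} = {v} is negative")
    return violations


def load_seo_fixture() -> list[SiteSample]:
    """The packaged Santa Elena Ophiolite dataset: 9 sites, values verbatim.

    Sulfate was not measured at these sites; ``so4_uM`` is ``None``
    throughout.
    """
    ref = resources.files("methanergy.data") / "seo_table1.csv"
    with resources.as_file(ref) as p:
        return read_site_table(p)


def summarize_sites(
    samples: Iterable[SiteSample],
    field_name: str,
    predicate: Callable[[SiteSample], bool] | None = None,
) -> dict:
    """Count/min/max/mean of one numeric field over samples passing ``predicate``.

    ``None`` values (below detection) are excluded; with no non-null values
    the min/max/mean are ``None`` and count is 0.
    """
    if field_name not in NUMERIC_FIELDS:
        raise KeyError(
            f"unknown numeric field {field_name!r}; valid fields: {NUMERIC_FIELDS}"
        )
    values = [
        getattr(s, field_name)
        for s in samples
        if (predicate is None or predicate(s)) and getattr(s, field_name) is not None
    ]
    if not values:
        return {"field": field_name, "count": 0, "min": None, "max": None, "mean": None}
    return {
        "field": field_name,
        "count": len(values),
        "min": min(values),
        "max": max(values),
        "mean": sum(values) / len(values),
    }
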