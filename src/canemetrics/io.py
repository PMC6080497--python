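"""Campaign data model and delimited-text input/output.

A campaign couples three tables:

* ``fields`` — one row per sugarcane field (ratoon cycle, area, dates),
* ``biometrics`` — non-destructive observations at sampling units (ESUs):
  stalk height ``H`` and diameter ``D`` in metres, longest leaf length,
  cane/plant counts per row-metre and effective LAI,
* ``biomass`` — destructive observations at biomass units (ESUBs): plant and
  cane masses, leaf biomass per cane, stalk mass density and wet contents.

On disk a campaign is a directory of three delimited files
(``fields.csv``, ``biometrics.csv``, ``biomass.csv``; tab also accepted).
Each file has a header row naming the columns and an optional second line
``#units,<unit>,...`` declaring the unit per column; values are converted to
SI (m, kg, kg/m^3, fractions) on read.  The deposited campaign workbook this
layout mirrors is not parsed directly; the column mapping here is this
package's own convention.

All internal quantities are SI.  Cane counts stay per row-metre of crop row
(the conversion to canes/m^2 divides by the row spacing; see
:mod:`canemetrics.allometry`).  Missing optional fields are ``None``, never
zero.
"""
from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from pathlib import Path

import pandas as pd

from .errors import FormatError

UNIT_KINDS = ("ESU", "ESUB", "INTENSIVE")
TIERS = ("instrument", "idealization")

# ---------------------------------------------------------------------------
# records


@dataclass
class BiometricRecord:
    """One non-destructive observation at a sampling unit on a visit day."""

    field_id: str
    unit_id: str
    unit_kind: str  # ESU | ESUB | INTENSIVE
    t: int  # days since start of growth
    corner: int | None = None  # replicate corner label 1-4
    tier: str | None = None  # instrument | idealization, for replicate blocks
    H: float | None = None  # stalk height, m
    D: float | None = None  # stalk diameter, m
    leaf_len: float | None = None  # longest leaf length, m
    C_row: float | None = None  # canes per row-metre
    P_row: float | None = None  # plants per row-metre
    LAI_eff: float | None = None  # effective LAI, m^2/m^2
    x: float | None = None  # position, m (or lon)
    y: float | None = None  # position, m (or lat)


@dataclass
class BiomassRecord:
    """One destructive observation (one plant sample) at an ESUB."""

    field_id: str
    unit_id: str
    t: int
    plant_mass: float | None = None  # kg
    canes_per_plant: float | None = None
    cane_mass: float | None = None  # kg, plant_mass / canes_per_plant
    BM_L: float | None = None  # leaf biomass per cane, kg
    rho_S: float | None = None  # stalk mass density, kg/m^3
    wet_content_stalk: float | None = None  # fraction
    wet_content_leaf: float | None = None  # fraction
    BM_S_measured: float | None = None  # measured stalk biomass per cane, kg
    tier: str | None = None  # tags repeated-weighing replicate blocks


@dataclass
class FieldInfo:
    """Static description of one field."""

    field_id: str
    ratoon_cycle: int | None = None
    area_ha: float | None = None
    start_of_growth: date | None = None
    harvest: date | None = None


@dataclass
class CampaignTable:
    """In-memory campaign: record lists plus any row-level read issues."""

    biometrics: list[BiometricRecord] = field(default_factory=list)
    biomass: list[BiomassRecord] = field(default_factory=list)
    fields: list[FieldInfo] = field(default_factory=list)
    issues: list[str] = field(default_factory=list, compare=False)

    def biometrics_frame(self) -> pd.DataFrame:
        return _records_to_frame(self.biometrics, BiometricRecord)

    def biomass_frame(self) -> pd.DataFrame:
        return _records_to_frame(self.biomass, BiomassRecord)

    def fields_frame(self) -> pd.DataFrame:
        return _records_to_frame(self.fields, FieldInfo)

    def field_ids(self) -> set[str]:
        return {f.field_id for f in self.fields}


def _records_to_frame(records, cls) -> pd.DataFrame:
    cols = [f.name for f in dc_fields(cls)]
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)


# ---------------------------------------------------------------------------
# unit handling

#: multiplicative factors to SI for each accepted unit label
_UNIT_FACTORS = {
    "m": 1.0, "cm": 0.01, "mm": 0.001, "km": 1000.0,
    "kg": 1.0, "g": 0.001, "t": 1000.0,
    "kg/m3": 1.0, "kg/m^3": 1.0, "g/cm3": 1000.0, "g/cm^3": 1000.0,
    "fraction": 1.0, "%": 0.01,
    "m2/m2": 1.0, "m^2/m^2": 1.0,
    "1/m": 1.0, "canes/m": 1.0, "plants/m": 1.0, "stalks/row/m": 1.0,
    "days": 1.0, "day": 1.0, "d": 1.0,
    "ha": 1.0, "": 1.0, "-": 1.0, "count": 1.0,
}

#: columns whose cells are numeric and may carry a unit
_NUMERIC_COLS = {
    "t", "corner", "H", "D", "leaf_len", "C_row", "P_row", "LAI_eff",
    "x", "y", "plant_mass", "canes_per_plant", "cane_mass", "BM_L",
    "rho_S", "wet_content_stalk", "wet_content_leaf", "BM_S_measured",
    "ratoon_cycle", "area_ha",
}

_MANDATORY = {
    "biometrics": ("field_id", "unit_id", "unit_kind", "t"),
    "biomass": ("field_id", "unit_id", "t"),
    "fields": ("field_id",),
}

_FILES = {
    "biometrics": BiometricRecord,
    "biomass": BiomassRecord,
    "fields": FieldInfo,
}


def _sniff_delimiter(header_line: str, configured: str | None) -> str:
    if configured:
        return configured
    return "\t" if header_line.count("\t") > header_line.count(",") else ","


def _parse_cell(name: str, raw: str, factor: float):
    raw = raw.strip()
    if raw == "":  # empty cell is an explicit null; tokens like "n/a" are errors
        return None, None
    if name in ("start_of_growth", "harvest"):
        try:
            return date.fromisoformat(raw), None
        except ValueError:
            return None, f"unparseable date {raw!r}"
    if name in _NUMERIC_COLS:
        try:
            value = float(raw) * factor
        except ValueError:
            return None, f"non-numeric value {raw!r}"
        if name in ("t", "corner", "ratoon_cycle"):
            return int(round(value)), None
        return value, None
    return raw, None


def _read_table(path: Path, cls, mandatory, delimiter_cfg, issues: list[str]):
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path.name}: empty file, no header")
        delim = _sniff_delimiter(first, delimiter_cfg)
        header = [h.strip() for h in first.rstrip("\n").split(delim)]
        rest = fh.readlines()

    known = {f.name for f in dc_fields(cls)}
    missing = [c for c in mandatory if c not in header]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s) {missing}")

    factors = {c: 1.0 for c in header}
    data_start = 2
    rows = list(csv.reader(rest, delimiter=delim))
    if rows and rows[0] and rows[0][0].startswith("#units"):
        units_row = rows[0]
        for col, unit in zip(header[1:], units_row[1:]):
            unit = unit.strip()
            if unit not in _UNIT_FACTORS:
                raise FormatError(f"{path.name}: unknown unit {unit!r} for column {col!r}")
            factors[col] = _UNIT_FACTORS[unit]
        rows = rows[1:]
        data_start = 3

    records = []
    for i, row in enumerate(rows):
        if not row or all(not c.strip() for c in row):
            continue
        lineno = data_start + i
        kwargs, bad = {}, []
        for col, raw in zip(header, row):
            if col not in known:
                continue
            value, err = _parse_cell(col, raw, factors.get(col, 1.0))
            if err:
                bad.append(f"column {col!r}: {err}")
            kwargs[col] = value
        for c in mandatory:
            if kwargs.get(c) is None:
                bad.append(f"column {c!r}: mandatory value missing")
        if bad:
            issues.append(f"{path.name} line {lineno}: " + "; ".join(bad))
            continue
        records.append(cls(**kwargs))
    return records


def read_campaign(path: str | Path, config: dict | None = None) -> CampaignTable:
    """Read a campaign directory into a :class:`CampaignTable`.

    Rows failing cell-level validation (non-numeric values, missing keys)
    are skipped and reported, with file and line number, in
    ``CampaignTable.issues``; structural problems (missing files or
    mandatory columns) raise :class:`~canemetrics.errors.FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"campaign path does not exist: {path}")
    delim = (config or {}).get("delimiter")
    issues: list[str] = []
    loaded: dict[str, list] = {}
    for name, cls in _FILES.items():
        fp = None
        for ext in (".csv", ".tsv"):
            cand = path / f"{name}{ext}"
            if cand.exists():
                fp = cand
                break
        if fp is None:
            loaded[name] = []
            continue
        loaded[name] = _read_table(fp, cls, _MANDATORY[name], delim, issues)
    if not any(loaded.values()):
        raise FormatError(f"no campaign tables found under {path}")
    return CampaignTable(
        biometrics=loaded["biometrics"],
        biomass=loaded["biomass"],
        fields=loaded["fields"],
        issues=issues,
    )


_SI_UNITS = {
    "H": "m", "D": "m", "leaf_len": "m", "x": "m", "y": "m",
    "C_row": "canes/m", "P_row": "plants/m", "LAI_eff": "m2/m2",
    "plant_mass": "kg", "cane_mass": "kg", "BM_L": "kg", "BM_S_measured": "kg",
    "rho_S": "kg/m3", "wet_content_stalk": "fraction",
    "wet_content_leaf": "fraction", "t": "days", "area_ha": "ha",
}


def _format_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return repr(v)  # shortest exact round-trip form
    return str(v)


def write_campaign(table: CampaignTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a campaign as three delimited files (SI units, with units line).

    ``read_campaign(write_campaign(T))`` reproduces ``T`` field-for-field
    (text exactly, numerics to 12 significant digits).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tables = {
        "biometrics": (table.biometrics, BiometricRecord),
        "biomass": (table.biomass, BiomassRecord),
        "fields": (table.fields, FieldInfo),
    }
    for name, (records, cls) in tables.items():
        cols = [f.name for f in dc_fields(cls)]
        ext = ".tsv" if delimiter == "\t" else ".csv"
        with open(path / f"{name}{ext}", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(cols)
            writer.writerow(["#units"] + [_SI_UNITS.get(c, "") for c in cols[1:]])
            for rec in records:
                writer.writerow([_format_cell(getattr(rec, c)) for c in cols])


# ---------------------------------------------------------------------------
# validation


@dataclass
class Violation:
    table: str
    key: str
    message: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"[{self.table}] {self.key}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    def ok(self) -> bool:
        return not self.violations

    def add(self, table, key, message, warning=False):
        (self.warnings if warning else self.violations).append(
            Violation(table, key, message)
        )


def _nonneg(report, table, key, name, value):
    if value is not None and value < 0:
        report.add(table, key, f"{name} must be >= 0, got {value}")


def validate_campaign(table: CampaignTable) -> ValidationReport:
    """Check every record invariant; never raises on content.

    A clean table yields an empty report.  Violations carry the table name
    and a ``field_id/unit_id/t`` key so offending records can be located.
    """
    report = ValidationReport()
    known_fields = table.field_ids()

    for f in table.fields:
        key = f.field_id
        if f.area_ha is not None and f.area_ha <= 0:
            report.add("fields", key, f"area must be > 0, got {f.area_ha}")
        if f.start_of_growth and f.harvest and f.harvest <= f.start_of_growth:
            report.add("fields", key, "harvest must be after start_of_growth")

    for r in table.biometrics:
        key = f"{r.field_id}/{r.unit_id}/t={r.t}"
        if known_fields and r.field_id not in known_fields:
            report.add("biometrics", key, f"unknown field_id {r.field_id!r}")
        if r.unit_kind not in UNIT_KINDS:
            report.add("biometrics", key, f"unit_kind must be one of {UNIT_KINDS}")
        if r.tier is not None and r.tier not in TIERS:
            report.add("biometrics", key, f"tier must be one of {TIERS}")
        if r.t is None or r.t < 0:
            report.add("biometrics", key, f"t must be >= 0, got {r.t}")
        for name in ("H", "D", "leaf_len", "C_row", "P_row", "LAI_eff"):
            _nonneg(report, "biometrics", key, name, getattr(r, name))
        if r.C_row is not None and r.P_row is not None and r.C_row < r.P_row:
            report.add("biometrics", key, f"C_row ({r.C_row}) < P_row ({r.P_row})")
        if r.corner is not None and not 1 <= r.corner <= 4:
            report.add("biometrics", key, f"corner must be 1-4, got {r.corner}")

    for r in table.biomass:
        key = f"{r.field_id}/{r.unit_id}/t={r.t}"
        if known_fields and r.field_id not in known_fields:
            report.add("biomass", key, f"unknown field_id {r.field_id!r}")
        if r.t is None or r.t < 0:
            report.add("biomass", key, f"t must be >= 0, got {r.t}")
        for name in ("plant_mass", "cane_mass", "BM_L", "BM_S_measured"):
            _nonneg(report, "biomass", key, name, getattr(r, name))
        if r.rho_S is not None and r.rho_S <= 0:
            report.add("biomass", key, f"rho_S must be > 0, got {r.rho_S}")
        for name in ("wet_content_stalk", "wet_content_leaf"):
            v = getattr(r, name)
            if v is not None and not 0.0 <= v <= 1.0:
                report.add("biomass", key, f"{name} must be in [0, 1], got {v}")
        if (
            r.plant_mass is not None
            and r.canes_per_plant
            and r.cane_mass is not None
        ):
            expected = r.plant_mass / r.canes_per_plant
            if abs(expected - r.cane_mass) > 1e-6 * max(1.0, abs(expected)):
                report.add(
                    "biomass", key,
                    f"cane_mass {r.cane_mass} inconsistent with "
                    f"plant_mass/canes_per_plant {expected}",
                    warning=True,
                )
    return report
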