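"""CSV readers/writers for the four dataset kinds, plus YAML configuration.

The on-disk schema is owned by this package: long format, snake_case
headers, decimal point, UTF-8, ISO-8601 dates/times, empty cells for
missing optional values.  Because real exports from loggers and
spreadsheets rarely arrive with these exact headers, every reader accepts
a *column map* (``{canonical_name: actual_header}``) so foreign files can
be ingested without editing them.

Kinds
-----
``"tpref"``         gradient-trial selected temperatures (one row per hourly
                    measure of one lizard)
``"body"``          field body temperatures with capture context
``"operative"``     copper-model operative temperature readings
``"availability"``  habitat availability points (4 per capture)
``"counts"``        microhabitat use/availability frequency cells
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime
from datetime import time as TimeOfDay
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .records import (
    DEFAULT_CATEGORIES,
    AvailabilityPoint,
    BodyTempRecord,
    CategoryTable,
    MicrohabitatCount,
    OperativeTempRecord,
    TprefMeasurement,
)

__all__ = [
    "SchemaError",
    "RowError",
    "LoadResult",
    "read_records",
    "write_records",
    "to_frame",
    "load_yaml_config",
    "category_table_from_config",
    "KIND_COLUMNS",
]

log = logging.getLogger("thermoreg.io")


class SchemaError(ValueError):
    """The file header does not match the expected column dictionary."""


class RowError(ValueError):
    """A data row failed parsing or a record invariant.

    ``row`` is the 1-based data-row index, ``line`` the physical line
    number in the file (header is line 1).
    """

    def __init__(self, row: int, message: str):
        self.row = row
        self.line = row + 1
        super().__init__(f"row {row} (line {self.line}): {message}")


class LoadResult(Sequence):
    """Records plus per-row diagnostics from a permissive read."""

    def __init__(self, records: list, errors: list):
        self.records = records
        self.errors = errors

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __repr__(self) -> str:
        return f"LoadResult({len(self.records)} records, {len(self.errors)} rejected rows)"


# --------------------------------------------------------------------------
# column dictionaries

def _parse_float(s: str) -> float:
    return float(s)


def _parse_int(s: str) -> int:
    return int(s)


def _parse_time(s: str) -> TimeOfDay:
    return TimeOfDay.fromisoformat(s)


def _parse_date(s: str) -> Date:
    return Date.fromisoformat(s)


def _parse_datetime(s: str) -> datetime:
    return datetime.fromisoformat(s)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return str(value)  # shortest round-trip repr
    if isinstance(value, (TimeOfDay, Date, datetime)):
        return value.isoformat()
    return str(value)


@dataclass(frozen=True)
class _Column:
    name: str
    parse: Callable[[str], object]
    optional: bool = False


_KINDS: dict = {
    "tpref": (
        TprefMeasurement,
        [
            _Column("individual_id", str),
            _Column("species", str),
            _Column("sex", str),
            _Column("hour", _parse_int),
            _Column("tpref_c", _parse_float),
        ],
    ),
    "body": (
        BodyTempRecord,
        [
            _Column("species", str),
            _Column("tb_c", _parse_float),
            _Column("time", _parse_time, optional=True),
            _Column("date", _parse_date, optional=True),
            _Column("microhabitat", str, optional=True),
            _Column("ta_c", _parse_float, optional=True),
            _Column("ts_c", _parse_float, optional=True),
            _Column("height_cm", _parse_float, optional=True),
            _Column("refuge_cm", _parse_float, optional=True),
            _Column("svl_mm", _parse_float, optional=True),
            _Column("mass_g", _parse_float, optional=True),
        ],
    ),
    "operative": (
        OperativeTempRecord,
        [
            _Column("model_id", str),
            _Column("timestamp", _parse_datetime),
            _Column("microhabitat", str),
            _Column("orientation", str, optional=True),
            _Column("sun", str),
            _Column("te_c", _parse_float),
        ],
    ),
    "availability": (
        AvailabilityPoint,
        [
            _Column("capture_ref", str),
            _Column("direction", str),
            _Column("microhabitat", str, optional=True),
            _Column("ta_c", _parse_float, optional=True),
            _Column("ts_c", _parse_float, optional=True),
            _Column("height_cm", _parse_float, optional=True),
            _Column("refuge_cm", _parse_float, optional=True),
        ],
    ),
    "counts": (
        MicrohabitatCount,
        [
            _Column("group", str),
            _Column("microhabitat", str),
            _Column("count", _parse_int),
        ],
    ),
}

#: canonical column order per dataset kind
KIND_COLUMNS = {kind: [c.name for c in cols] for kind, (_, cols) in _KINDS.items()}

_TYPE_TO_KIND = {rectype: kind for kind, (rectype, _) in _KINDS.items()}


def _validate_extra(kind: str, record, categories: CategoryTable,
                    tpref_window: tuple) -> None:
    """Invariants that depend on configuration, not on the type itself."""
    if kind == "tpref":
        lo, hi = tpref_window
        if not lo <= record.tpref_c <= hi:
            raise ValueError(
                f"tpref_c={record.tpref_c} outside plausibility window [{lo}, {hi}]"
            )
    elif kind == "operative":
        categories.check_operative(record.microhabitat, record.orientation, record.sun)
    elif kind == "counts":
        # frequency tables may fold minor categories into an aggregate "other"
        if record.microhabitat != "other":
            categories.check_microhabitat(record.microhabitat)
    elif kind in ("body", "availability") and record.microhabitat is not None:
        categories.check_microhabitat(record.microhabitat)


def read_records(
    path,
    kind: str,
    *,
    column_map: Optional[Mapping[str, str]] = None,
    permissive: bool = False,
    categories: CategoryTable = DEFAULT_CATEGORIES,
    tpref_window: tuple = (5.0, 50.0),
):
    """Read one CSV file into typed records.

    In strict mode (default) the first bad row raises :class:`RowError`.
    With ``permissive=True`` bad rows are collected and the result is a
    :class:`LoadResult` sequence carrying the rejected-row diagnostics.

    ``column_map`` maps canonical column names to the headers actually
    present in the file, enabling ingestion of foreign exports.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown dataset kind {kind!r}; expected one of {sorted(_KINDS)}")
    rectype, columns = _KINDS[kind]
    colmap = dict(column_map or {})

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [colmap.get(c.name, c.name) for c in columns
               if colmap.get(c.name, c.name) not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} for kind {kind!r} "
            f"(present: {list(frame.columns)})"
        )

    records, errors = [], []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        values = {}
        try:
            rowmap = dict(zip(frame.columns, row))
            for col in columns:
                raw = rowmap[colmap.get(col.name, col.name)].strip()
                if raw == "" or raw.upper() in ("NA", "NAN"):
                    if col.optional:
                        values[col.name] = None
                        continue
                    raise ValueError(f"required column {col.name!r} is empty")
                try:
                    values[col.name] = col.parse(raw)
                except ValueError as exc:
                    raise ValueError(f"column {col.name!r}: cannot parse {raw!r} ({exc})")
            record = rectype(**values)
            _validate_extra(kind, record, categories, tpref_window)
        except ValueError as exc:
            err = RowError(i, str(exc))
            if not permissive:
                raise err from None
            errors.append(err)
            continue
        records.append(record)

    if errors:
        log.warning("%s: rejected %d of %d rows", path, len(errors), len(frame))
    return LoadResult(records, errors) if permissive else records


def write_records(records: Sequence, path, *, kind: Optional[str] = None) -> None:
    """Write homogeneous records to CSV in the canonical column order.

    An empty collection needs an explicit ``kind`` and produces a
    header-only file.
    """
    records = list(records)
    if not records:
        if kind is None:
            raise ValueError("cannot infer dataset kind from an empty collection; pass kind=")
    else:
        kinds = {_TYPE_TO_KIND.get(type(r)) for r in records}
        if None in kinds or len(kinds) != 1:
            raise ValueError(f"records are not a single known kind: {kinds}")
        inferred = kinds.pop()
        if kind is not None and kind != inferred:
            raise ValueError(f"kind={kind!r} does not match records of kind {inferred!r}")
        kind = inferred

    _, columns = _KINDS[kind]
    rows = [{c.name: _fmt(getattr(r, c.name)) for c in columns} for r in records]
    frame = pd.DataFrame(rows, columns=[c.name for c in columns])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")


def to_frame(records: Sequence) -> pd.DataFrame:
    """Tabulate homogeneous records as a DataFrame with canonical columns."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    kind = _TYPE_TO_KIND.get(type(records[0]))
    if kind is None:
        raise ValueError(f"unknown record type {type(records[0]).__name__}")
    _, columns = _KINDS[kind]
    return pd.DataFrame(
        [{c.name: getattr(r, c.name) for c in columns} for r in records]
    )


# --------------------------------------------------------------------------
# configuration

def load_yaml_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level of config must be a mapping")
    return cfg


def category_table_from_config(cfg: Mapping) -> CategoryTable:
    """Build a :class:`CategoryTable` from a config block, with defaults."""
    block = cfg.get("categories", {}) if cfg else {}
    return CategoryTable(
        microhabitats=frozenset(block.get("microhabitats",
                                          DEFAULT_CATEGORIES.microhabitats)),
        orientations=frozenset(block.get("orientations",
                                         DEFAULT_CATEGORIES.orientations)),
        sun=frozenset(block.get("sun", DEFAULT_CATEGORIES.sun)),
    )
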