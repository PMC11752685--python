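"""Read/write the tabular compound schema and the prediction CSV.

The input table — spreadsheet (first sheet) or comma-delimited CSV — carries
seven columns in a fixed order: name, ID, SMILES, Doses max, Activity, FUB,
CLint.  Binding is positional: header text is ignored, only column order
matters.  Doses max (the maximum therapeutic dose, mg/day) and Activity (the
binary cholestasis label) may be blank; FUB is the unbound plasma fraction in
(0, 1]; CLint is intrinsic hepatic clearance in µL/min/10⁶ hepatocytes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .descriptors import InvalidSmilesError, canonical_smiles

logger = logging.getLogger(__name__)

#: canonical internal column names, in the schema's fixed order
SCHEMA_COLUMNS = ("name", "chembl_id", "smiles", "dose_max", "activity", "fub", "clint")

_ABSENT_TOKENS = {"", "na", "nan", "none", "null"}


class CompoundTableError(ValueError):
    """Raised when a compound table cannot be read or has no valid rows."""


@dataclass(frozen=True)
class CompoundRecord:
    """One drug-like molecule with identity, exposure, PK and label fields."""

    name: str
    chembl_id: str
    smiles: str
    fub: float
    clint: float
    dose_max: Optional[float] = None  # therapeutic dose T_D, mg/day
    activity: Optional[int] = None  # binary cholestasis label

    def __post_init__(self):
        canonical_smiles(self.smiles)  # raises InvalidSmilesError
        if not (0.0 < self.fub <= 1.0):
            raise ValueError(f"fub must lie in (0, 1], got {self.fub}")
        if not (self.clint >= 0.0):
            raise ValueError(f"clint must be >= 0, got {self.clint}")
        if self.dose_max is not None and not (self.dose_max > 0):
            raise ValueError(f"dose_max must be > 0 when present, got {self.dose_max}")
        if self.activity is not None and self.activity not in (0, 1):
            raise ValueError(f"activity must be 0 or 1, got {self.activity}")


@dataclass
class CompoundTable:
    """Ordered collection of validated compound records."""

    records: list[CompoundRecord]
    source: str = "inline"

    def __post_init__(self):
        if not self.records:
            raise CompoundTableError("compound table is empty")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": r.name,
                "chembl_id": r.chembl_id,
                "smiles": r.smiles,
                "dose_max": r.dose_max,
                "activity": r.activity,
                "fub": r.fub,
                "clint": r.clint,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))


@dataclass(frozen=True)
class RowError:
    """A rejected input row: 0-based data-row index and the reason."""

    row: int
    reason: str


def _parse_optional_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        if value.strip().lower() in _ABSENT_TOKENS:
            return None
        return float(value)
    return float(value)


def _parse_optional_label(value) -> Optional[int]:
    parsed = _parse_optional_float(value)
    if parsed is None:
        return None
    if parsed not in (0.0, 1.0):
        raise ValueError(f"activity must be 0 or 1, got {parsed}")
    return int(parsed)


def _record_from_row(raw: Sequence) -> CompoundRecord:
    return CompoundRecord(
        name=str(raw[0]),
        chembl_id=str(raw[1]),
        smiles=str(raw[2]),
        dose_max=_parse_optional_float(raw[3]),
        activity=_parse_optional_label(raw[4]),
        fub=float(raw[5]),
        clint=float(raw[6]),
    )


def read_compound_table(
    path,
    format: Optional[str] = None,
    header: bool = True,
    strict: bool = False,
) -> tuple[CompoundTable, list[RowError]]:
    """Read a 7-column compound table from XLSX or CSV.

    Columns are bound by position in the fixed schema order; a header row is
    skipped by default (``header=False`` for headerless files).  Rows that
    fail validation (bad SMILES, out-of-range FUB/CLint, ...) are rejected
    and reported with their 0-based data-row index; with ``strict=True`` any
    rejected row raises instead.

    Returns ``(table, row_errors)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    header_arg = 0 if header else None
    if fmt == "xlsx":
        frame = pd.read_excel(path, sheet_name=0, header=header_arg, dtype=object)
    elif fmt == "csv":
        frame = pd.read_csv(path, header=header_arg, dtype=object, encoding="utf-8")
    else:
        raise CompoundTableError(f"unknown format {fmt!r}; expected 'xlsx' or 'csv'")

    if frame.shape[1] < len(SCHEMA_COLUMNS):
        raise CompoundTableError(
            f"{path}: expected >= {len(SCHEMA_COLUMNS)} columns "
            f"({', '.join(SCHEMA_COLUMNS)}), found {frame.shape[1]}"
        )
    if frame.shape[1] > len(SCHEMA_COLUMNS):
        logger.warning(
            "%s: ignoring %d extra column(s) beyond the 7-column schema",
            path,
            frame.shape[1] - len(SCHEMA_COLUMNS),
        )

    records: list[CompoundRecord] = []
    errors: list[RowError] = []
    for idx, raw in enumerate(frame.iloc[:, : len(SCHEMA_COLUMNS)].itertuples(index=False)):
        try:
            records.append(_record_from_row(list(raw)))
        except (ValueError, InvalidSmilesError, TypeError) as exc:
            err = RowError(row=idx, reason=str(exc))
            if strict:
                raise CompoundTableError(f"row {idx}: {exc}") from exc
            logger.warning("%s: rejected row %d: %s", path, idx, exc)
            errors.append(err)
    if not records:
        raise CompoundTableError(f"{path}: no valid rows")
    return CompoundTable(records=records, source=str(path)), errors


def write_compound_table(table: CompoundTable, path, format: Optional[str] = None) -> None:
    """Write a compound table back out in the 7-column schema (CSV or XLSX)."""
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    frame = table.to_frame()
    frame.columns = ["name", "ID", "SMILES", "Doses max", "Activity", "FUB", "CLint"]
    if fmt == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


def write_prediction_csv(results: Iterable, path) -> pd.DataFrame:
    """Write per-compound prediction results to CSV.

    One row per compound: the seven input fields, one K-corrected in vivo
    dose column per selected transporter (``dose_<transporter>``,
    mg/kg/day), the continuous vote-fraction score and the binary verdict.
    Floats are written with 17 significant digits so a re-read reproduces
    every value exactly.
    """
    results = list(results)
    if not results:
        raise ValueError("no prediction results to write")
    transporters = list(results[0].in_vivo_dose)
    rows = []
    for res in results:
        rec = res.compound
        row = {
            "name": rec.name,
            "ID": rec.chembl_id,
            "SMILES": rec.smiles,
            "Doses max": rec.dose_max,
            "Activity": rec.activity,
            "FUB": rec.fub,
            "CLint": rec.clint,
            "td_mg_per_kg_day": res.td_per_kg,
        }
        for t in transporters:
            row[f"dose_{t}"] = res.in_vivo_dose[t]
        row["score"] = res.score
        row["predicted_activity"] = res.predicted
        row["agrees"] = res.agrees
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format="%.17g")
    return frame
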