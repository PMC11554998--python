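"""Reading and writing the chemical and tabular formats the pipeline touches.

Input bioactivity tables arrive either as CSV (one molecule per row, SMILES in
a named column) or as SD files with activity stored in a named SD tag.  Every
input row or molecule block is accounted for: records that cannot be parsed
are emitted with a flag rather than silently dropped, so the downstream
curation log can reconcile counts against the raw file.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: Canonical unit symbols and their value in molar.
UNIT_TO_MOLAR: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "µM": 1e-6,
    "nM": 1e-9,
}

_UNIT_ALIASES = {
    "m": "M",
    "mm": "mM",
    "um": "µM",
    "µm": "µM",
    "μm": "µM",
    "micromolar": "µM",
    "nm": "nM",
    "nanomolar": "nM",
    "millimolar": "mM",
    "molar": "M",
}

#: Activity qualifiers as they appear in database exports.
QUALIFIERS = ("=", ">", "<", "none")


class ConfigurationError(ValueError):
    """A column mapping or option does not match the input."""


def normalize_unit(unit: str) -> str:
    """Map a free-text unit string onto one of M/mM/µM/nM.

    Matching is case-insensitive and tolerant of the micro sign being
    written as ``u`` (``"uM"`` ≡ ``"µM"``).
    """
    key = unit.strip()
    if key in UNIT_TO_MOLAR:
        return key
    canon = _UNIT_ALIASES.get(key.lower())
    if canon is None:
        raise ConfigurationError(f"unknown concentration unit: {unit!r}")
    return canon


@dataclass(frozen=True)
class RawRecord:
    """One input molecule with its as-reported activity and provenance.

    ``activity_value`` is kept exactly as reported (e.g. an EC50 of ``5`` with
    ``activity_units='µM'``); conversion to the -log10 molar scale happens in
    :mod:`purscreen.curation`.  Screening-library members typically carry no
    activity at all.
    """

    record_id: str
    structure: str
    activity_value: float | None = None
    activity_units: str | None = None
    activity_qualifier: str = "none"
    source: str = ""
    parse_pending: bool = False

    def __post_init__(self) -> None:
        if self.activity_value is not None and not self.activity_value > 0:
            raise ValueError(
                f"record {self.record_id}: activity_value must be positive, "
                f"got {self.activity_value}"
            )
        if self.activity_qualifier not in QUALIFIERS:
            raise ValueError(
                f"record {self.record_id}: bad qualifier {self.activity_qualifier!r}"
            )
        if self.activity_value is not None and self.activity_qualifier == "none":
            # a reported value with no stated qualifier is an exact value
            object.__setattr__(self, "activity_qualifier", "=")


_QUALIFIED_VALUE = re.compile(r"^\s*(>|<|>=|<=|=)?\s*([0-9.eE+-]+)\s*$")


def parse_activity_cell(cell: str) -> tuple[float | None, str]:
    """Split an activity cell like ``">10000"`` into (value, qualifier).

    Returns ``(None, "none")`` for empty cells.  ``>=``/``<=`` collapse onto
    the strict qualifier since downstream handling is identical.
    """
    text = str(cell).strip()
    if not text or text.lower() in {"nan", "na", "none"}:
        return None, "none"
    m = _QUALIFIED_VALUE.match(text)
    if m is None:
        raise ValueError(f"unparseable activity cell: {cell!r}")
    qual = m.group(1)
    value = float(m.group(2))
    if qual in (">", ">="):
        return value, ">"
    if qual in ("<", "<="):
        return value, "<"
    return value, "="


def read_molecule_table(
    path: str | Path, column_map: Mapping[str, str]
) -> list[RawRecord]:
    """Read a CSV bioactivity table into RawRecords.

    Parameters
    ----------
    path:
        CSV file with a header row.
    column_map:
        Maps the roles ``structure``, ``activity``, ``units`` (and optionally
        ``id`` and ``source``) onto column names in the file.  ``activity``
        and ``units`` may be omitted for screening libraries.  Alternatively
        ``units`` may be a fixed unit symbol embedded in the activity column
        name convention (pass ``units_value`` instead of ``units``).

    Rows whose structure cell is empty are emitted with ``parse_pending=True``
    rather than dropped, so the curation log can account for them.
    """
    path = Path(path)
    if "structure" not in column_map:
        raise ConfigurationError("column_map must name a 'structure' column")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for role in ("structure", "activity", "units", "id", "source", "qualifier"):
        col = column_map.get(role)
        if col is not None and col not in df.columns:
            raise ConfigurationError(
                f"mapped column {col!r} for role {role!r} not in {path.name} "
                f"(columns: {list(df.columns)})"
            )
    fixed_units = column_map.get("units_value")
    records: list[RawRecord] = []
    for i, row in df.iterrows():
        structure = row[column_map["structure"]].strip()
        rid = (
            row[column_map["id"]]
            if "id" in column_map
            else f"{path.name}:{i + 2}"  # header is line 1
        )
        source = row[column_map["source"]] if "source" in column_map else str(path)
        value: float | None = None
        qualifier = "none"
        units: str | None = None
        if "activity" in column_map:
            value, qualifier = parse_activity_cell(row[column_map["activity"]])
            if "qualifier" in column_map:
                cell = row[column_map["qualifier"]].strip()
                if cell in (">", "<", "="):
                    qualifier = cell
            if value is not None:
                if "units" in column_map:
                    units = normalize_unit(row[column_map["units"]])
                elif fixed_units is not None:
                    units = normalize_unit(fixed_units)
                else:
                    raise ConfigurationError(
                        "activity column mapped but no units column or fixed unit given"
                    )
        records.append(
            RawRecord(
                record_id=str(rid),
                structure=structure,
                activity_value=value,
                activity_units=units,
                activity_qualifier=qualifier,
                source=source,
                parse_pending=not structure,
            )
        )
    _check_unique_ids(records, path)
    return records


def read_smiles_file(path: str | Path) -> list[RawRecord]:
    """Read a one-SMILES-per-line file (optional second token = name)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"{path.name}:{i}"
            records.append(RawRecord(record_id=name, structure=smiles, source=str(path)))
    _check_unique_ids(records, path)
    return records


def read_sdf(path: str | Path, activity_tag: str | None = None) -> list[RawRecord]:
    """Read a V2000/V3000 SD file into RawRecords.

    When ``activity_tag`` is given, that SD property supplies the activity;
    the unit is taken from a trailing token of the tag value ("5.0 uM") or
    from a tag-name suffix after the last underscore ("EC50_uM").  Corrupt
    molecule blocks yield a record with ``parse_pending=True`` so that no
    block disappears without trace.
    """
    path = Path(path)
    unit_from_tag: str | None = None
    if activity_tag is not None and "_" in activity_tag:
        try:
            unit_from_tag = normalize_unit(activity_tag.rsplit("_", 1)[1])
        except ConfigurationError:
            unit_from_tag = None
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    records: list[RawRecord] = []
    for i, mol in enumerate(supplier):
        rid = f"{path.name}#{i}"
        if mol is None:
            records.append(
                RawRecord(record_id=rid, structure="", source=str(path), parse_pending=True)
            )
            continue
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        smiles = Chem.MolToSmiles(mol)
        value: float | None = None
        qualifier = "none"
        units: str | None = None
        if activity_tag is not None and mol.HasProp(activity_tag):
            cell = mol.GetProp(activity_tag).strip()
            tokens = cell.split()
            if len(tokens) == 2:
                value, qualifier = parse_activity_cell(tokens[0])
                units = normalize_unit(tokens[1])
            else:
                value, qualifier = parse_activity_cell(cell)
                units = unit_from_tag
            if value is not None and units is None:
                raise ConfigurationError(
                    f"activity tag {activity_tag!r} carries no unit "
                    "(expected a '_<unit>' suffix or a '<value> <unit>' cell)"
                )
        records.append(
            RawRecord(
                record_id=name or rid,
                structure=smiles,
                activity_value=value,
                activity_units=units,
                activity_qualifier=qualifier,
                source=str(path),
            )
        )
    _check_unique_ids(records, path)
    return records


def _check_unique_ids(records: Sequence[RawRecord], path: Path) -> None:
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise ValueError(f"duplicate record_id {r.record_id!r} in {path}")
        seen.add(r.record_id)


def write_table(records, path: str | Path) -> None:
    """Write any flat tabular result as UTF-8 CSV with full float precision.

    Accepts a DataFrame, a sequence of dicts, or a sequence of dataclasses
    exposing ``to_row()``.  The written file round-trips: reading it back
    reproduces every value bit-for-bit (floats are serialized with repr
    precision).
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if hasattr(r, "to_row"):
                rows.append(r.to_row())
            elif isinstance(r, Mapping):
                rows.append(dict(r))
            else:
                raise TypeError(f"cannot serialize {type(r).__name__} to a table row")
        df = pd.DataFrame(rows)
    # %.17g guarantees bit-exact float64 round-trips through text
    df.to_csv(path, index=False, float_format="%.17g", quoting=csv.QUOTE_MINIMAL)


def read_table(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_table` (floats parsed bit-exactly)."""
    return pd.read_csv(path, float_precision="round_trip")
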