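"""Study-specific six-dimension common data model (CDM) I/O.

Each institution's EHR extract is represented as six relational tables —
Demographic, Diagnosis, Prescription, Laboratory Result, Vital Sign, and
Smoking Behavior — stored as UTF-8 CSV files with ISO-8601 dates plus a
``manifest.json`` naming the institution and the tables actually present.
An institution may legitimately lack a dimension (e.g. no smoking table);
absence is recorded in the manifest rather than modelled as an empty file,
so downstream default-value policies are applied explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["CDMTableSet", "CDMValidationError", "read_cdm", "write_cdm", "load_schema"]

# column order is part of the on-disk contract (deterministic output)
TABLE_COLUMNS = {
    "demographic": ["patient_id", "birth_date", "sex"],
    "diagnosis": ["patient_id", "date", "code", "code_system", "setting"],
    "prescription": ["patient_id", "date", "atc_code", "days_supply"],
    "lab_result": ["patient_id", "date", "test_name", "value", "unit"],
    "vital_sign": ["patient_id", "date", "measure", "value"],
    "smoking": ["patient_id", "date", "status"],
}
REQUIRED_TABLES = ("demographic", "diagnosis", "prescription", "lab_result", "vital_sign")
OPTIONAL_TABLES = ("smoking",)
DATE_COLUMNS = {"birth_date", "date"}


class CDMValidationError(ValueError):
    """Validation failure with the offending file / row / column identified."""

    def __init__(self, message, file=None, row=None, column=None):
        loc = ", ".join(
            f"{k}={v}" for k, v in (("file", file), ("row", row), ("column", column))
            if v is not None
        )
        super().__init__(f"{message}" + (f" ({loc})" if loc else ""))
        self.file, self.row, self.column = file, row, column


def load_schema(path: str | Path | None = None) -> dict:
    """Load the schema config (vocabularies and enumerations).

    Without a path, the packaged default schema is used.
    """
    if path is None:
        ref = resources.files("cvdadapt") / "configs" / "schema.yaml"
        return yaml.safe_load(ref.read_text())
    return yaml.safe_load(Path(path).read_text())


@dataclass
class CDMTableSet:
    """One institution's EHR as validated relational tables.

    ``smoking`` is ``None`` (not an empty frame) when the institution does
    not record the dimension; ``absent_columns`` lists covariates with no
    source data at this institution (e.g. ``hemoglobin``).
    """

    institution: str
    demographic: pd.DataFrame
    diagnosis: pd.DataFrame
    prescription: pd.DataFrame
    lab_result: pd.DataFrame
    vital_sign: pd.DataFrame
    smoking: pd.DataFrame | None = None
    absent_columns: tuple[str, ...] = field(default_factory=tuple)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {name: getattr(self, name) for name in REQUIRED_TABLES}
        if self.smoking is not None:
            out["smoking"] = self.smoking
        return out

    def has_smoking(self) -> bool:
        return self.smoking is not None

    def validate(self, schema: dict | None = None) -> "CDMTableSet":
        schema = schema or load_schema()
        _validate_tables(self.tables(), schema)
        return self

    def equals(self, other: "CDMTableSet") -> bool:
        if self.institution != other.institution:
            return False
        if set(self.tables()) != set(other.tables()):
            return False
        for name, df in self.tables().items():
            a = _canonical(df, name).reset_index(drop=True)
            b = _canonical(other.tables()[name], name).reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


def _canonical(df: pd.DataFrame, name: str) -> pd.DataFrame:
    cols = TABLE_COLUMNS[name]
    df = df[cols].copy()
    sort_cols = [c for c in ("patient_id", "date", "birth_date") if c in cols]
    other = [c for c in cols if c not in sort_cols]
    df = df.sort_values(sort_cols + other, kind="stable").reset_index(drop=True)
    return df


def _validate_enum(df, column, allowed, file):
    bad = ~df[column].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CDMValidationError(
            f"value {df[column].iloc[row]!r} not in {sorted(allowed)}",
            file=file, row=row, column=column,
        )


def _validate_tables(tables: dict[str, pd.DataFrame], schema: dict) -> None:
    if "demographic" not in tables:
        raise CDMValidationError("demographic table is required")
    for name, df in tables.items():
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise CDMValidationError(f"missing columns {missing}", file=f"{name}.csv")
    demo = tables["demographic"]
    if demo["patient_id"].duplicated().any():
        row = int(np.flatnonzero(demo["patient_id"].duplicated().to_numpy())[0])
        raise CDMValidationError("duplicate patient_id", file="demographic.csv",
                                 row=row, column="patient_id")
    known = set(demo["patient_id"])
    vocab = schema["vocabularies"]
    _validate_enum(demo, "sex", vocab["sex"], "demographic.csv")
    for name, df in tables.items():
        file = f"{name}.csv"
        if name != "demographic" and len(df):
            orphan = ~df["patient_id"].isin(known)
            if orphan.any():
                row = int(np.flatnonzero(orphan.to_numpy())[0])
                raise CDMValidationError(
                    f"patient_id {df['patient_id'].iloc[row]!r} absent from demographic",
                    file=file, row=row, column="patient_id",
                )
        for col in TABLE_COLUMNS[name]:
            if col in DATE_COLUMNS:
                vals = pd.to_datetime(df[col], errors="coerce") if len(df) else df[col]
                if len(df) and pd.isna(vals).any():
                    row = int(np.flatnonzero(pd.isna(vals).to_numpy())[0])
                    raise CDMValidationError("unparseable date", file=file,
                                             row=row, column=col)
    diag = tables["diagnosis"]
    if len(diag):
        _validate_enum(diag, "code_system", vocab["code_system"], "diagnosis.csv")
        _validate_enum(diag, "setting", vocab["setting"], "diagnosis.csv")
    rx = tables["prescription"]
    if len(rx):
        neg = rx["days_supply"].astype(float) < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise CDMValidationError("days_supply must be >= 0",
                                     file="prescription.csv", row=row,
                                     column="days_supply")
    lab = tables["lab_result"]
    if len(lab):
        _validate_enum(lab, "test_name", vocab["test_name"], "lab_result.csv")
        notfinite = ~np.isfinite(lab["value"].astype(float))
        if notfinite.any():
            row = int(np.flatnonzero(notfinite.to_numpy())[0])
            raise CDMValidationError("lab value not finite", file="lab_result.csv",
                                     row=row, column="value")
    vit = tables["vital_sign"]
    if len(vit):
        _validate_enum(vit, "measure", vocab["measure"], "vital_sign.csv")
    if "smoking" in tables and len(tables["smoking"]):
        _validate_enum(tables["smoking"], "status", vocab["smoking_status"],
                       "smoking.csv")


def _parse_dates(df: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in TABLE_COLUMNS[name]:
        if col in DATE_COLUMNS:
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    return df


def read_cdm(directory: str | Path, schema: dict | str | Path | None = None) -> CDMTableSet:
    """Read and validate one institution's CDM directory.

    Requires one CSV per required dimension plus ``manifest.json``; optional
    tables listed absent in the manifest are recorded as absent, not empty.
    """
    directory = Path(directory)
    if isinstance(schema, (str, Path)):
        schema = load_schema(schema)
    schema = schema or load_schema()
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    else:
        present = [t for t in TABLE_COLUMNS if (directory / f"{t}.csv").exists()]
        manifest = {"institution": directory.name, "tables": present,
                    "absent_columns": []}
    tables: dict[str, pd.DataFrame] = {}
    for name in manifest["tables"]:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise CDMValidationError("required dimension file missing", file=path.name)
        df = pd.read_csv(path, dtype={"patient_id": str, "code": str,
                                      "atc_code": str})
        tables[name] = _parse_dates(df, name)
    for name in REQUIRED_TABLES:
        if name not in tables:
            raise CDMValidationError("required dimension file missing",
                                     file=f"{name}.csv")
    _validate_tables(tables, schema)
    return CDMTableSet(
        institution=manifest.get("institution", directory.name),
        demographic=tables["demographic"],
        diagnosis=tables["diagnosis"],
        prescription=tables["prescription"],
        lab_result=tables["lab_result"],
        vital_sign=tables["vital_sign"],
        smoking=tables.get("smoking"),
        absent_columns=tuple(manifest.get("absent_columns", [])),
    )


def write_cdm(cdm: CDMTableSet, directory: str | Path) -> list[Path]:
    """Write one CSV per present table plus a manifest; byte-deterministic.

    Rows are sorted by (patient_id, date, remaining columns) and dates are
    formatted as ISO-8601, so identical table sets produce identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in cdm.tables().items():
        out = _canonical(df, name)
        for col in out.columns:
            if col in DATE_COLUMNS:
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    manifest = {
        "institution": cdm.institution,
        "tables": sorted(cdm.tables()),
        "absent_columns": sorted(cdm.absent_columns),
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def drop_smoking(cdm: CDMTableSet) -> CDMTableSet:
    """Return a copy with the smoking dimension marked absent."""
    absent = tuple(sorted(set(cdm.absent_columns) | {"smoking"}))
    return replace(cdm, smoking=None, absent_columns=absent)
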