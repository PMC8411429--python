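"""Patient-level EHR record bundle and its on-disk CSV representation.

An :class:`EHRDataset` is six tidy tables keyed by patient id: patients,
Problem-List entries, treatment episodes, cardiac imaging studies with
LVEF, active medication orders, and referrals.  Dates are held as
``datetime64[ns]`` in memory and ISO-8601 strings on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

__all__ = ["EHRDataset", "SchemaError", "write_dataset", "read_dataset", "TABLE_SCHEMAS"]

# table name -> (required columns, date columns, bool columns)
TABLE_SCHEMAS: dict[str, tuple[list[str], list[str], list[str]]] = {
    "patients": (["patient_id", "birth_date", "sex", "alive"], ["birth_date"], ["alive"]),
    "problems": (["patient_id", "code", "onset_date"], ["onset_date"], []),
    "episodes": (["patient_id", "drug_name", "drug_class", "start_date"], ["start_date"], []),
    "imaging": (["patient_id", "modality", "study_date", "lvef"], ["study_date"], []),
    "medications": (
        ["patient_id", "drug_name", "pharm_class", "pharm_subclass", "active", "as_of_date"],
        ["as_of_date"],
        ["active"],
    ),
    "referrals": (["patient_id", "specialty", "referral_date"], ["referral_date"], []),
}

LVEF_BOUNDS = (5.0, 80.0)


class SchemaError(ValueError):
    """A table violates the dataset schema; names the file/table and column."""


@dataclass
class EHRDataset:
    """Bundle of patient-level EHR tables.

    All child-table patient ids must exist in ``patients`` and LVEF values
    must lie in [5, 80]; :meth:`validate` enforces this.
    """

    patients: pd.DataFrame
    problems: pd.DataFrame
    episodes: pd.DataFrame
    imaging: pd.DataFrame
    medications: pd.DataFrame
    referrals: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def validate(self) -> "EHRDataset":
        ids = set(self.patients["patient_id"])
        if self.patients["patient_id"].duplicated().any():
            raise SchemaError("patients: duplicate patient_id")
        for name, df in self.tables().items():
            required, _, _ = TABLE_SCHEMAS[name]
            for col in required:
                if col not in df.columns:
                    raise SchemaError(f"{name}: missing column {col!r}")
            if name != "patients" and len(df):
                orphans = set(df["patient_id"]) - ids
                if orphans:
                    raise SchemaError(
                        f"{name}: patient ids not in patients table: {sorted(orphans)[:5]}"
                    )
        if len(self.imaging):
            lv = self.imaging["lvef"]
            bad = ~lv.between(*LVEF_BOUNDS)
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"imaging: row {row}, column 'lvef': value {lv.loc[row]} "
                    f"outside {list(LVEF_BOUNDS)}"
                )
        return self

    def equals(self, other: "EHRDataset") -> bool:
        """Field-level equality of all six tables (order- and dtype-aware)."""
        return all(
            self.tables()[name].reset_index(drop=True).equals(
                other.tables()[name].reset_index(drop=True)
            )
            for name in TABLE_SCHEMAS
        )


def write_dataset(dataset: EHRDataset, directory) -> None:
    """Write one CSV per table into ``directory`` (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in dataset.tables().items():
        out = df.copy()
        for col in TABLE_SCHEMAS[name][1]:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(directory / f"{name}.csv", index=False)


def _read_table(path: Path, name: str) -> pd.DataFrame:
    required, date_cols, bool_cols = TABLE_SCHEMAS[name]
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    for col in date_cols:
        try:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path.name}: column {col!r}: {exc}") from exc
    for col in bool_cols:
        df[col] = df[col].astype(bool)
    return df


def read_dataset(directory) -> EHRDataset:
    """Read a dataset written by :func:`write_dataset`; validates schema."""
    directory = Path(directory)
    tables = {}
    for name in TABLE_SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"{path.name}: file not found in {directory}")
        tables[name] = _read_table(path, name)
    return EHRDataset(**tables).validate()
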