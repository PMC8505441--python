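"""Delimited-text readers and writers for the pipeline's tables.

Wide dialect: a ``patient_id`` column followed by one ``<analyte>__pre`` /
``<analyte>__post`` column per analyte, empty field = missing.  Long
dialect: ``patient_id, analyte_id, days_from_index, value``.  Reads and
writes round-trip exactly, including missing-cell placement.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from labmi.preprocessing import LONG_COLUMNS
from labmi.tables import BLOCKS, LabTable


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: file is empty") from err


def _to_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        raw = out[col].replace("", np.nan)
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: unparseable numeric value {raw.iloc[i]!r} in "
                f"column {col!r}, data row {i + 1}")
        out[col] = num
    return out


def read_lab_wide(path) -> LabTable:
    """Read a wide lab CSV into a :class:`LabTable`."""
    df = _read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: missing 'patient_id' column; expected "
                         "patient_id plus <analyte>__pre/<analyte>__post columns")
    value_cols = [c for c in df.columns if c != "patient_id"]
    parsed = []
    for c in value_cols:
        if "__" not in c or c.rsplit("__", 1)[1] not in BLOCKS:
            raise ValueError(
                f"{path}: column {c!r} is not of the form <analyte>__pre or "
                "<analyte>__post")
        a, b = c.rsplit("__", 1)
        parsed.append((a, b))
    df = _to_numeric(df, value_cols, path)
    df = df.set_index("patient_id")
    df.columns = pd.MultiIndex.from_tuples(parsed)
    return LabTable(df)


def write_lab_wide(table: LabTable, path) -> None:
    out = table.data.copy()
    out.columns = [f"{a}__{b}" for a, b in out.columns]
    out.index.name = "patient_id"
    out.to_csv(path, na_rep="")


def read_lab_long(path) -> pd.DataFrame:
    """Read long-format lab records (one row per measurement)."""
    df = _read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected header "
                         f"{list(LONG_COLUMNS)}")
    return _to_numeric(df, ["days_from_index", "value"], path)


def write_lab_long(records: pd.DataFrame, path) -> None:
    records.loc[:, list(LONG_COLUMNS)].to_csv(path, index=False)


def read_comorbidity(path) -> pd.DataFrame:
    """Read the binary patient x comorbidity-code table."""
    df = _read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: missing 'patient_id' column")
    df = _to_numeric(df, [c for c in df.columns if c != "patient_id"], path)
    df = df.set_index("patient_id")
    vals = df.to_numpy()
    if np.isnan(vals).any() or not np.isin(vals[~np.isnan(vals)], (0, 1)).all():
        raise ValueError(f"{path}: comorbidity table must be 0/1 with no blanks")
    return df.astype(np.int64)


def write_comorbidity(comorbidity: pd.DataFrame, path) -> None:
    out = comorbidity.copy()
    out.index.name = "patient_id"
    out.to_csv(path)


def write_metrics(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_manifest(path, **entries) -> None:
    """JSON sidecar recording configuration, seeds, and versions."""
    import labmi

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        return str(o)

    payload = {"labmi_version": labmi.__version__,
               "numpy_version": np.__version__,
               "pandas_version": pd.__version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
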