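"""Reading and writing the canonical long-format CSV.

One row per measurement, UTF-8, header required:
``subject,group,time_h,temp_C`` (time in hours, temperature in degC).
A wide layout (one column per sampling time) is accepted via
:func:`wide_to_long`.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .data import Dataset, DatasetError, REQUIRED_COLUMNS

__all__ = ["read_dataset", "write_dataset", "wide_to_long"]


def read_dataset(path, groups=None) -> Dataset:
    """Read and validate a long-format CSV into a :class:`Dataset`.

    Malformed content is reported with 1-based file line numbers (the
    header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"subject": str, "group": str}, float_precision="round_trip"
    )
    try:
        return Dataset(df, groups=groups)
    except DatasetError as exc:
        if exc.rows:
            lines = [int(r) + 2 for r in exc.rows[:10]]
            # rewrite row indices as file line numbers
            msg = re.sub(r"at row\(s\) \[[^\]]*\]", f"at line(s) {lines}", str(exc))
            raise DatasetError(f"{path.name}: {msg}", rows=exc.rows) from None
        raise DatasetError(f"{path.name}: {exc}") from None


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as the canonical long-format CSV (full float precision)."""
    dataset.df.loc[:, list(REQUIRED_COLUMNS)].to_csv(
        path, index=False, float_format="%.17g"
    )


def wide_to_long(df: pd.DataFrame, time_columns=None) -> pd.DataFrame:
    """Convert a wide table (one column per sampling time) to long format.

    ``time_columns`` maps column names to times in hours; by default any
    column whose name parses as a number (optionally suffixed ``h``) is
    treated as a sampling time.
    """
    if time_columns is None:
        time_columns = {}
        for col in df.columns:
            m = re.fullmatch(r"t?\s*([0-9]+(?:\.[0-9]+)?)\s*h?", str(col).strip())
            if m:
                time_columns[col] = float(m.group(1))
    if not time_columns:
        raise DatasetError("no time columns recognized in wide table")
    id_cols = [c for c in df.columns if c not in time_columns]
    if "subject" not in id_cols or "group" not in id_cols:
        raise DatasetError("wide table needs 'subject' and 'group' columns")
    long = df.melt(
        id_vars=["subject", "group"],
        value_vars=list(time_columns),
        var_name="_col",
        value_name="temp_C",
    )
    long["time_h"] = long["_col"].map(time_columns)
    return long.drop(columns="_col").loc[:, list(REQUIRED_COLUMNS)]
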