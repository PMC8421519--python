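"""Long-format temperature time-series container shared across the package.

The canonical layout is one row per measurement with columns
``subject`` (opaque id, unique across groups), ``group`` (label),
``time_h`` (hours since endotoxin injection) and ``temp_C`` (rectal
temperature in degrees Celsius).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["Dataset", "DatasetError", "REQUIRED_COLUMNS", "PLAUSIBLE_TEMP_RANGE"]

REQUIRED_COLUMNS = ("subject", "group", "time_h", "temp_C")

#: Plausibility band for murine rectal temperature; values outside trigger a
#: warning (possible unit or entry error) but are not rejected.
PLAUSIBLE_TEMP_RANGE = (20.0, 45.0)


class DatasetError(ValueError):
    """Invalid dataset contents; ``rows`` holds offending 0-based row indices."""

    def __init__(self, message: str, rows=()):
        super().__init__(message)
        self.rows = tuple(rows)


class Dataset:
    """Validated long-format collection of temperature time series.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain :data:`REQUIRED_COLUMNS`.  Extra columns are dropped.
    groups : sequence of str, optional
        Ordered group labels.  Defaults to order of first appearance.
    """

    def __init__(self, df: pd.DataFrame, groups=None):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["subject"] = df["subject"].astype(str)
        df["group"] = df["group"].astype(str)
        for col in ("time_h", "temp_C"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(~np.isfinite(coerced.to_numpy(dtype=float)))
            if bad.size:
                raise DatasetError(
                    f"non-numeric {col} at row(s) {[int(i) for i in bad[:10]]}", rows=bad
                )
            df[col] = coerced.astype(float)
        if (df["time_h"] < 0).any():
            bad = np.flatnonzero((df["time_h"] < 0).to_numpy())
            raise DatasetError(f"negative time_h at row(s) {[int(i) for i in bad[:10]]}", rows=bad)
        if (df["temp_C"] <= 0).any():
            bad = np.flatnonzero((df["temp_C"] <= 0).to_numpy())
            raise DatasetError(
                f"non-positive temp_C at row(s) {[int(i) for i in bad[:10]]}", rows=bad
            )
        dup = df.duplicated(subset=["subject", "time_h"], keep=False)
        if dup.any():
            bad = np.flatnonzero(dup.to_numpy())
            raise DatasetError(
                f"duplicate (subject, time_h) at row(s) {[int(i) for i in bad[:10]]}", rows=bad
            )
        lo, hi = PLAUSIBLE_TEMP_RANGE
        implausible = (df["temp_C"] < lo) | (df["temp_C"] > hi)
        if implausible.any():
            warnings.warn(
                f"{int(implausible.sum())} temperature value(s) outside the "
                f"plausibility band {PLAUSIBLE_TEMP_RANGE} degrees C",
                stacklevel=2,
            )
        # subjects must not straddle groups
        ngroups = df.groupby("subject")["group"].nunique()
        if (ngroups > 1).any():
            bad_subj = list(ngroups.index[ngroups > 1][:5])
            raise DatasetError(f"subject(s) appear in multiple groups: {bad_subj}")

        observed = list(pd.unique(df["group"]))
        if groups is None:
            groups = observed
        else:
            groups = [str(g) for g in groups]
            unknown = set(observed) - set(groups)
            if unknown:
                raise DatasetError(f"group label(s) not in `groups`: {sorted(unknown)}")
        self._df = df.reset_index(drop=True)
        self._groups = tuple(g for g in groups if g in observed)

    # -- accessors -----------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying long-format frame (treat as read-only)."""
        return self._df

    @property
    def groups(self) -> tuple:
        return self._groups

    @property
    def subjects(self) -> tuple:
        return tuple(pd.unique(self._df["subject"]))

    @property
    def n_obs(self) -> int:
        return len(self._df)

    def subjects_in(self, group: str) -> tuple:
        sub = self._df.loc[self._df["group"] == group, "subject"]
        return tuple(pd.unique(sub))

    def group_frame(self, group: str) -> pd.DataFrame:
        return self._df[self._df["group"] == group]

    def subject_frame(self, subject: str) -> pd.DataFrame:
        return self._df[self._df["subject"] == subject]

    # -- derived datasets ----------------------------------------------------
    def subset_subjects(self, subjects) -> "Dataset":
        """Restrict to the given subjects, preserving group order."""
        keep = set(map(str, subjects))
        df = self._df[self._df["subject"].isin(keep)]
        if df.empty:
            raise DatasetError("subject subset is empty")
        return Dataset(df, groups=self._groups)

    def merge_groups(self, a: str, b: str, label: str | None = None) -> "Dataset":
        """Relabel groups ``a`` and ``b`` as a single group.

        Used by whole-curve comparisons that treat a pair of groups as one.
        """
        if a not in self._groups or b not in self._groups:
            raise DatasetError(f"unknown group in pair ({a!r}, {b!r})")
        if a == b:
            raise DatasetError("cannot merge a group with itself")
        merged = label if label is not None else f"{a}+{b}"
        df = self._df.copy()
        df.loc[df["group"].isin([a, b]), "group"] = merged
        new_groups = []
        for g in self._groups:
            if g == a:
                new_groups.append(merged)
            elif g != b:
                new_groups.append(g)
        return Dataset(df, groups=new_groups)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self._groups == other._groups and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"Dataset({self.n_obs} measurements, "
            f"{len(self.subjects)} subjects, groups={list(self._groups)})"
        )
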