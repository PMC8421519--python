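"""Pair-indexed statistics tables with optional multiplicity adjustment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["PairwiseTable", "bh_adjust"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


@dataclass
class PairwiseTable:
    """Statistics for unordered group pairs.

    ``table`` has columns ``group1``, ``group2``, ``statistic``, ``p_raw``,
    ``p_adj`` (equal to ``p_raw`` when ``adjustment == "none"``).  Lookup is
    symmetric in pair order.  ``extra`` carries table-level context such as
    an omnibus ANOVA statistic or the LR degrees of freedom.
    """

    table: pd.DataFrame
    method: str
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records, method: str, adjustment: str = "none", extra: dict | None = None
    ) -> "PairwiseTable":
        """Build from (group1, group2, statistic, p_raw) tuples; adjust if asked."""
        df = pd.DataFrame(
            records, columns=["group1", "group2", "statistic", "p_raw"]
        )
        if adjustment == "benjamini-hochberg":
            df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        elif adjustment == "none":
            df["p_adj"] = df["p_raw"]
        else:
            raise ValueError(f"unknown adjustment {adjustment!r}")
        return cls(df, method=method, adjustment=adjustment, extra=extra or {})

    def _row(self, a: str, b: str) -> pd.Series:
        t = self.table
        m = ((t["group1"] == a) & (t["group2"] == b)) | (
            (t["group1"] == b) & (t["group2"] == a)
        )
        if not m.any():
            raise KeyError(f"pair ({a!r}, {b!r}) not in table")
        return t[m].iloc[0]

    def p_value(self, a: str, b: str, adjusted: bool = True) -> float:
        return float(self._row(a, b)["p_adj" if adjusted else "p_raw"])

    def statistic(self, a: str, b: str) -> float:
        return float(self._row(a, b)["statistic"])

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> pd.Series:
        col = "p_adj" if adjusted else "p_raw"
        return self.table[col] < alpha

    def __len__(self) -> int:
        return len(self.table)
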