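"""Collapse case versions to unique reports.

A spontaneous-report case accumulates versions as follow-up information
arrives; each version has its own ``primaryid`` but shares the ``caseid``.
The convention implemented here keeps, per case, the version with the most
recent FDA receipt date (``fda_dt``), breaking ties by the numerically larger
``primaryid``, and removes any case present in the deleted-case list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import RawQuarter, date_sort_key


@dataclass(frozen=True)
class DedupReport:
    """Audit counts for one deduplication pass."""

    total_in: int
    kept: int
    removed_duplicates: int
    removed_deleted: int

    def __post_init__(self):
        if self.kept + self.removed_duplicates + self.removed_deleted != self.total_in:
            raise ValueError("deduplication audit counts do not balance")


def deduplicate(demo: pd.DataFrame, deleted_caseids: set[str] | None = None
                ) -> tuple[np.ndarray, DedupReport]:
    """Return surviving primaryids (sorted numerically) and an audit report.

    Partial ``fda_dt`` values are compared on (year, month-or-0, day-or-0):
    a monotone total order in which a vaguer date never beats a more recent
    fully-resolved one in the common all-day-resolved case.  The rule is
    idempotent and independent of input order.
    """
    deleted_caseids = deleted_caseids or set()
    total_in = len(demo)
    if total_in == 0:
        return np.array([], dtype=str), DedupReport(0, 0, 0, 0)
    df = demo[["primaryid", "caseid"]].copy()
    df["_fda"] = date_sort_key(demo["fda_dt"])
    df["_pid"] = pd.to_numeric(df["primaryid"], errors="coerce").fillna(-1).astype("int64")
    deleted_mask = df["caseid"].isin(deleted_caseids)
    removed_deleted = int(deleted_mask.sum())
    live = df[~deleted_mask]
    best = (live.sort_values(["caseid", "_fda", "_pid"])
                .groupby("caseid", sort=False).tail(1))
    surviving = best.sort_values("_pid")["primaryid"].to_numpy(dtype=str)
    report = DedupReport(total_in=total_in, kept=len(surviving),
                         removed_duplicates=total_in - removed_deleted - len(surviving),
                         removed_deleted=removed_deleted)
    return surviving, report


def restrict_quarter(quarter: RawQuarter, surviving) -> RawQuarter:
    """Filter every table of a quarter to the surviving primaryids."""
    keep = set(surviving)
    frames = {}
    for kind in ("demo", "drug", "reac", "outc", "ther", "indi"):
        df = quarter.table(kind)
        frames[kind] = df[df["primaryid"].isin(keep)].reset_index(drop=True)
    return replace(quarter, **frames)
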