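"""Time to onset: days from therapy start of the matched drug to the event.

Only fully day-resolved dates enter the calculation; partial dates, missing
dates and negative intervals are excluded and tallied, so the retained count
plus the exclusion tally always equals the cohort size.  Day 0 (same-day
onset) is valid.  The summary uses 30-day bins [30(k-1), 30k) for k = 1..12
plus a terminal ">360" bin, with median and quartiles by linear interpolation
between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up
from .io import RawQuarter

EXCLUSION_KEYS = ("missing_event_date", "partial_event_date",
                  "missing_start_date", "partial_start_date", "negative_interval")

N_BINS = 12
BIN_WIDTH = 30


def _day_resolved(s: pd.Series) -> pd.Series:
    """Datetime for 8-digit calendar-valid strings, NaT otherwise."""
    t = s.fillna("").astype(str).str.strip()
    t = t.where(t.str.fullmatch(r"\d{8}").fillna(False), "")
    return pd.to_datetime(t, format="%Y%m%d", errors="coerce")


def compute_onsets(quarter: RawQuarter, matches: pd.DataFrame
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-report onset days for a cohort, plus an exclusion tally.

    ``matches`` is the (primaryid, drug_seq) frame from
    :func:`faerspv.cohort.match_cohort`; the therapy start is the earliest
    day-resolved start date among THER rows referencing a matched drug
    mention, the event date is the report's ``event_dt``.
    """
    ids = sorted(set(matches["primaryid"]))
    demo = quarter.demo[quarter.demo["primaryid"].isin(ids)]
    event = pd.Series(_day_resolved(demo["event_dt"]).values, index=demo["primaryid"])
    event_raw = pd.Series(demo["event_dt"].fillna("").str.strip().values,
                          index=demo["primaryid"])

    ther = quarter.ther.merge(
        matches.rename(columns={"drug_seq": "dsg_drug_seq"}),
        on=["primaryid", "dsg_drug_seq"], how="inner")
    ther = ther.assign(_start=_day_resolved(ther["start_dt"]),
                       _has_any=ther["start_dt"].fillna("").str.strip() != "")
    start = ther.groupby("primaryid")["_start"].min()
    has_any_start = ther.groupby("primaryid")["_has_any"].any()

    rows = []
    excl = {k: 0 for k in EXCLUSION_KEYS}
    for pid in ids:
        ev = event.get(pid, pd.NaT)
        if pd.isna(ev):
            if event_raw.get(pid, ""):
                excl["partial_event_date"] += 1
            else:
                excl["missing_event_date"] += 1
            continue
        st = start.get(pid, pd.NaT)
        if pd.isna(st):
            if bool(has_any_start.get(pid, False)):
                excl["partial_start_date"] += 1
            else:
                excl["missing_start_date"] += 1
            continue
        days = int((ev - st).days)
        if days < 0:
            excl["negative_interval"] += 1
            continue
        rows.append((pid, days))
    records = pd.DataFrame(rows, columns=["primaryid", "days"])
    return records, excl


def bin_label(k: int) -> str:
    if k > N_BINS:
        return f">{N_BINS * BIN_WIDTH}"
    return f"{(k - 1) * BIN_WIDTH}-{k * BIN_WIDTH - 1}"


@dataclass
class OnsetSummary:
    """Median/IQR and 30-day histogram of onset days."""

    n: int
    median_days: float
    q1_days: float
    q3_days: float
    bins: dict[str, int] = field(default_factory=dict)

    def bin_percentages(self) -> dict[str, float]:
        return {k: round_half_up(100.0 * v / self.n, 2) for k, v in self.bins.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.bin_percentages()
        return pd.DataFrame({"bin_label": list(self.bins),
                             "n": list(self.bins.values()),
                             "pct": [pct[k] for k in self.bins]})


def summarize_onsets(records: pd.DataFrame | np.ndarray | list) -> OnsetSummary:
    """Summarise onset days (a frame with a ``days`` column, or a sequence)."""
    if isinstance(records, pd.DataFrame):
        days = records["days"].to_numpy(dtype=float)
    else:
        days = np.asarray(records, dtype=float)
    if days.size == 0:
        raise ValueError("no onset records to summarise")
    q1, med, q3 = np.percentile(days, [25, 50, 75])  # linear interpolation
    edges = np.arange(0, (N_BINS + 1) * BIN_WIDTH + 1, BIN_WIDTH)
    counts, _ = np.histogram(np.clip(days, 0, N_BINS * BIN_WIDTH), bins=edges)
    bins = {bin_label(k): int(counts[k - 1]) for k in range(1, N_BINS + 2)}
    return OnsetSummary(n=int(days.size), median_days=float(med),
                        q1_days=float(q1), q3_days=float(q3), bins=bins)


def plot_onsets(summary: OnsetSummary, ax=None):
    """Bar chart of the 30-day onset histogram."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    labels = list(summary.bins)
    ax.bar(labels, list(summary.bins.values()), color="#7a3362")
    ax.set_xlabel("days from therapy start")
    ax.set_ylabel("reports")
    ax.tick_params(axis="x", rotation=60)
    return ax
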