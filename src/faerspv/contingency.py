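"""2x2 contingency tables for drug-event pairs.

For each event label L (a MedDRA preferred term, or a system organ class via
a PT->SOC map) against a fixed cohort within a deduplicated background:

======  ==============================  ==============================
cell    drug of interest                all other drugs
======  ==============================  ==============================
event   a = cohort reports with L       c = background reports with L
other   b = cohort reports without L    d = background reports without L
======  ==============================  ==============================

Counting is report-level at both hierarchy levels: a report listing the same
term twice (or two terms of one organ class) contributes one count, so
``a + b`` equals the cohort size and ``c + d`` the background size for every
label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import normalize_term
from .io import RawQuarter

log = logging.getLogger("faerspv")

UNMAPPED_SOC = "UNMAPPED"


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 counts for one drug-event pair."""

    a: float
    b: float
    c: float
    d: float
    label: str = ""
    level: str = "PT"

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n_total <= 0:
            raise ValueError("contingency table is empty")

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d


class PtSocMap:
    """Case-insensitive preferred-term -> system-organ-class mapping.

    MedDRA itself is licensed and is not shipped; users supply a two-column
    CSV (pt, soc) covering the terms they need.
    """

    def __init__(self, entries: dict[str, str]):
        self._map: dict[str, str] = {}
        for pt, soc in entries.items():
            key = normalize_term(pt)
            soc = str(soc).strip()
            if key in self._map and self._map[key] != soc:
                raise ValueError(f"PT {pt!r} maps to both {self._map[key]!r} and {soc!r}")
            self._map[key] = soc

    @classmethod
    def from_csv(cls, path: str | Path) -> "PtSocMap":
        df = pd.read_csv(path, dtype=str).fillna("")
        cols = {c.strip().lower(): c for c in df.columns}
        if "pt" not in cols or "soc" not in cols:
            raise ValueError(f"{path}: expected columns 'pt' and 'soc'")
        return cls(dict(zip(df[cols["pt"]], df[cols["soc"]])))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PtSocMap":
        return cls(dict(zip(frame["pt"], frame["soc"])))

    def get(self, pt: str, default: str | None = None) -> str | None:
        return self._map.get(normalize_term(pt), default)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self._map


def build_tables(quarter: RawQuarter, ids: set[str], level: str = "PT",
                 mapping: PtSocMap | None = None) -> pd.DataFrame:
    """Build every 2x2 table with a > 0 for a cohort against the background.

    Returns a frame with columns label, level, a, b, c, d, sorted by
    descending a then label.  At SOC level unmapped preferred terms are
    grouped under ``UNMAPPED`` with a logged count.
    """
    if not ids:
        raise ValueError("cohort is empty; no tables to build")
    level = level.upper()
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    if level == "SOC" and mapping is None:
        raise ValueError("SOC-level tables require a PT->SOC mapping")

    universe = quarter.report_ids()
    cohort = ids & universe
    n_cohort = len(cohort)
    n_background = len(universe) - n_cohort

    reac = quarter.reac[["primaryid", "pt"]].copy()
    reac = reac[reac["pt"].str.strip() != ""]
    reac["_key"] = reac["pt"].map(normalize_term)
    if level == "SOC":
        assert mapping is not None
        keys = reac["_key"].unique()
        soc_of = {k: mapping.get(k, UNMAPPED_SOC) for k in keys}
        n_unmapped = sum(1 for v in soc_of.values() if v == UNMAPPED_SOC)
        if n_unmapped:
            log.warning("%d preferred terms lack a SOC mapping; grouped under %s",
                        n_unmapped, UNMAPPED_SOC)
        reac["_key"] = reac["_key"].map(soc_of)
        reac["_label"] = reac["_key"]
    else:
        # representative verbatim spelling: first occurrence per normalised key
        reac["_label"] = reac["pt"].str.strip()

    pairs = reac.drop_duplicates(["primaryid", "_key"])
    labels = pairs.groupby("_key", sort=True)["_label"].first()
    in_cohort = pairs["primaryid"].isin(cohort)
    a = pairs[in_cohort].groupby("_key", sort=True).size()
    c = pairs[~in_cohort].groupby("_key", sort=True).size()

    out = pd.DataFrame({"label": labels, "a": a, "c": c}).fillna(0)
    out = out[out["a"] > 0]
    out["a"] = out["a"].astype("int64")
    out["c"] = out["c"].astype("int64")
    out["b"] = n_cohort - out["a"]
    out["d"] = n_background - out["c"]
    out["level"] = level
    out = out[["label", "level", "a", "b", "c", "d"]]
    return (out.sort_values(["a", "label"], ascending=[False, True])
               .reset_index(drop=True))


def tables_from_frame(frame: pd.DataFrame) -> list[ContingencyTable]:
    """Materialise ContingencyTable objects from a build_tables-shaped frame."""
    return [ContingencyTable(a=row.a, b=row.b, c=row.c, d=row.d,
                             label=row.label, level=row.level)
            for row in frame.itertuples(index=False)]
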