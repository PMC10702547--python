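"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS quarterly extracts are $-delimited text files with a header line and no
quoting or escape mechanism.  Each quarter ships several tables keyed by
``primaryid`` (a case-version identifier): DEMO (demographics and
administrative data), DRUG (drug mentions with role codes), REAC (MedDRA
preferred terms), OUTC (outcome codes), THER (therapy start/end dates) and
INDI (indications), plus a list of deleted case identifiers.

Dates are partial: ``yyyymmdd``, ``yyyymm`` or ``yyyy``.  They are kept as
strings in the table frames and interpreted on demand, so each downstream
stage can apply its own resolution rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

log = logging.getLogger("faerspv")

TABLE_KINDS = ("demo", "drug", "reac", "outc", "ther", "indi")

#: canonical columns per table, in output order
SCHEMAS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "occp_cod", "occr_country", "reporter_country"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
}

# Header-name synonyms, lower-cased.  FAERS schemas drifted over the years
# (e.g. the pre-2012 "ISR" era and "gndr_cod" for sex); the shipped map covers
# the 2019-2022 layout plus the common legacy aliases, and callers can extend
# it through the ``synonyms`` argument of read_table.
DEFAULT_SYNONYMS: dict[str, list[str]] = {
    "primaryid": ["isr"],
    "caseid": ["case", "case_id"],
    "sex": ["gndr_cod"],
    "drug_seq": ["drugseq"],
    "outc_cod": ["outc_code"],
}

MANDATORY: dict[str, list[str]] = {kind: ["primaryid"] for kind in TABLE_KINDS}


@dataclass(frozen=True)
class PartialDate:
    """A date known to year, month or day resolution."""

    year: int
    month: int | None = None
    day: int | None = None

    @property
    def resolution(self) -> str:
        if self.day is not None:
            return "day"
        return "month" if self.month is not None else "year"

    def sort_key(self) -> tuple[int, int, int]:
        """Monotone total order; missing components compare as earliest."""
        return (self.year, self.month or 0, self.day or 0)


_DAYS_IN_MONTH = (31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def parse_partial_date(text: str) -> PartialDate | None:
    """Parse a FAERS date string; never raises.

    8 digits give day resolution, 6 month, 4 year.  Anything else — empty,
    non-digit, out-of-range calendar components — returns None with a logged
    warning.
    """
    text = (text or "").strip()
    if not text:
        return None
    if not text.isdigit() or len(text) not in (4, 6, 8):
        log.warning("unparseable date %r", text)
        return None
    year = int(text[:4])
    if not 1900 <= year <= 2100:
        log.warning("date year out of range: %r", text)
        return None
    if len(text) == 4:
        return PartialDate(year)
    month = int(text[4:6])
    if not 1 <= month <= 12:
        log.warning("invalid month in date %r", text)
        return None
    if len(text) == 6:
        return PartialDate(year, month)
    day = int(text[6:8])
    max_day = _DAYS_IN_MONTH[month - 1]
    if month == 2 and not (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)):
        max_day = 28
    if not 1 <= day <= max_day:
        log.warning("invalid day in date %r", text)
        return None
    return PartialDate(year, month, day)


def date_sort_key(dates: pd.Series) -> pd.Series:
    """Vectorised monotone key for partial-date strings.

    Missing components are treated as earliest ("2020" < "20200101"); empty or
    malformed strings sort before everything.
    """
    s = dates.fillna("").astype(str).str.strip()
    ok = s.str.fullmatch(r"\d{4}|\d{6}|\d{8}")
    key = s.where(ok.fillna(False), "").str.pad(8, side="right", fillchar="0")
    return pd.to_numeric(key.replace("", "-1"), errors="coerce").fillna(-1).astype("int64")


@dataclass
class RawQuarter:
    """One or more pooled reporting periods as normalised table frames.

    All frame columns hold strings (empty string = absent), matching the
    lossless on-disk representation.  ``deleted_caseids`` lists cases the
    source flagged for removal.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    deleted_caseids: set[str] = field(default_factory=set)
    period_label: str = ""

    def table(self, kind: str) -> pd.DataFrame:
        return getattr(self, kind)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def report_ids(self) -> set[str]:
        return set(self.demo["primaryid"])

    def drop_orphans(self) -> "RawQuarter":
        """Drop rows in child tables whose primaryid is absent from DEMO.

        Spontaneous-report extracts are dirty; orphans are logged and removed
        rather than treated as fatal.
        """
        known = self.demo["primaryid"]
        out = {}
        for kind in TABLE_KINDS[1:]:
            df = self.table(kind)
            mask = df["primaryid"].isin(set(known))
            n_drop = int((~mask).sum())
            if n_drop:
                log.warning("%s: dropped %d orphan rows (primaryid not in DEMO)", kind, n_drop)
            out[kind] = df[mask].reset_index(drop=True)
        return replace(self, **out)


def empty_quarter(period_label: str = "") -> RawQuarter:
    frames = {k: pd.DataFrame({c: pd.Series(dtype=str) for c in cols})
              for k, cols in SCHEMAS.items()}
    return RawQuarter(period_label=period_label, **frames)


def _resolve_columns(header: list[str], kind: str,
                     synonyms: dict[str, list[str]] | None) -> dict[int, str]:
    """Map header positions to canonical column names, case-insensitively."""
    syn = {k: list(v) for k, v in DEFAULT_SYNONYMS.items()}
    for k, v in (synonyms or {}).items():
        syn.setdefault(k, []).extend(v)
    wanted = {}
    for canon in SCHEMAS[kind]:
        wanted[canon] = canon
        for alias in syn.get(canon, []):
            wanted[alias.lower()] = canon
    mapping = {}
    for i, name in enumerate(header):
        canon = wanted.get(name.strip().lower())
        if canon is not None and canon not in mapping.values():
            mapping[i] = canon
    return mapping


def read_table(path: str | Path, kind: str,
               synonyms: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Read one $-delimited table into a string-typed frame.

    Header names are matched case-insensitively against the canonical schema
    plus a synonym map; unknown columns are ignored, absent optional columns
    become empty strings.  Lines with the wrong field count are skipped and
    counted in ``frame.attrs["skipped"]``.  A missing mandatory column is a
    hard error naming the file and column.
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    with open(path, encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file (no header line)")
    header = lines[0].split("$")
    colmap = _resolve_columns(header, kind, synonyms)
    for col in MANDATORY[kind]:
        if col not in colmap.values():
            raise ValueError(f"{path}: mandatory column {col!r} not found in header")
    nfields = len(header)
    rows, skipped = [], 0
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("$")
        if len(parts) != nfields:
            skipped += 1
            continue
        rows.append([parts[i].strip() for i in colmap])
    got = pd.DataFrame(rows, columns=list(colmap.values()), dtype=str)
    frame = pd.DataFrame({c: got[c] if c in got.columns else [""] * len(got)
                          for c in SCHEMAS[kind]}, dtype=str)
    if skipped:
        log.warning("%s: skipped %d malformed lines", path, skipped)
    frame.attrs["skipped"] = skipped
    return frame


def read_deleted(path: str | Path) -> set[str]:
    """Read a deleted-case list, one caseid per line (header lines ignored)."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip()
            if tok and tok.isdigit():
                out.add(tok)
    return out


def _check_no_delimiter(df: pd.DataFrame, kind: str) -> None:
    for col in df.columns:
        bad = df[col].astype(str).str.contains(r"\$", regex=True)
        if bad.any():
            i = bad.idxmax()
            raise ValueError(
                f"{kind}.{col}: value {df.loc[i, col]!r} (primaryid "
                f"{df.loc[i, 'primaryid']!r}) contains the '$' delimiter; the "
                f"format has no escaping")


def write_quarter(quarter: RawQuarter, directory: str | Path) -> list[Path]:
    """Write a quarter as $-delimited files readable by :func:`read_table`.

    Lossless for string fields; values containing the delimiter are rejected
    because the format cannot escape them.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    label = quarter.period_label or "SIM"
    written = []
    for kind in TABLE_KINDS:
        df = quarter.table(kind)[SCHEMAS[kind]].astype(str)
        _check_no_delimiter(df, kind)
        path = directory / f"{kind.upper()}{label}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("$".join(SCHEMAS[kind]) + "\n")
            for row in df.itertuples(index=False):
                fh.write("$".join(row) + "\n")
        written.append(path)
    path = directory / f"DELETED{label}.txt"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("caseid\n")
        for cid in sorted(quarter.deleted_caseids):
            fh.write(cid + "\n")
    written.append(path)
    return written


def read_quarter(directory: str | Path, period_label: str = "",
                 synonyms: dict[str, list[str]] | None = None) -> RawQuarter:
    """Read every table of a quarter directory (DEMO*.txt, DRUG*.txt, ...).

    Missing child tables are tolerated (empty frame); a missing DEMO is a hard
    error.  Orphan child rows are dropped with a logged count.
    """
    directory = Path(directory)
    frames = {}
    for kind in TABLE_KINDS:
        paths = sorted(directory.glob(f"{kind.upper()}*.txt"))
        if not paths:
            if kind == "demo":
                raise FileNotFoundError(f"{directory}: no DEMO*.txt table found")
            frames[kind] = empty_quarter().table(kind)
            continue
        frames[kind] = pd.concat(
            [read_table(p, kind, synonyms) for p in paths], ignore_index=True)
    deleted: set[str] = set()
    for p in sorted(directory.glob("DELETED*.txt")):
        deleted |= read_deleted(p)
    q = RawQuarter(deleted_caseids=deleted, period_label=period_label or directory.name,
                   **frames)
    return q.drop_orphans()


def concat_quarters(quarters: list[RawQuarter], period_label: str = "pooled") -> RawQuarter:
    """Pool several quarters into one (deduplication is applied globally later)."""
    if not quarters:
        return empty_quarter(period_label)
    frames = {k: pd.concat([q.table(k) for q in quarters], ignore_index=True)
              for k in TABLE_KINDS}
    deleted = set().union(*(q.deleted_caseids for q in quarters))
    return RawQuarter(deleted_caseids=deleted, period_label=period_label, **frames)
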