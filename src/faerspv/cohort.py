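"""Primary-suspect cohort extraction and demographic characterisation.

A report belongs to the drug-of-interest cohort when at least one of its drug
mentions matches the query by case-insensitive substring containment (generic
or trade name, against the verbatim drug name and/or the active-ingredient
field) *and* that mention carries an accepted role code — by default ``PS``
(primary suspect), the reporter's designation of the drug most likely
responsible for the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import normalize_term, round_half_up
from .io import RawQuarter

log = logging.getLogger("faerspv")

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: years per unit of each age code (ISO-ish FAERS codes)
AGE_UNIT_YEARS = {
    "YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0,
}

OCCUPATION_LABELS = {
    "MD": "physician", "PH": "pharmacist", "HP": "health_profession",
    "CN": "consumer", "OT": "other_health_professional", "": "unknown",
}

#: outcome codes in decreasing seriousness; anything after HO folds into "other"
DEFAULT_OUTCOME_PRECEDENCE = ("DE", "LT", "DS", "HO")
OUTCOME_LABELS = {"DE": "death", "LT": "life_threatening", "DS": "disability",
                  "HO": "hospitalization"}


@dataclass(frozen=True)
class DrugQuery:
    """Names and matching rules identifying the drug of interest."""

    generic_names: tuple[str, ...] = ()
    trade_names: tuple[str, ...] = ()
    match_fields: tuple[str, ...] = ("drugname", "prod_ai")
    role_filter: frozenset[str] = frozenset({"PS"})

    def __post_init__(self):
        names = self.all_names()
        if not names:
            raise ValueError("drug query needs at least one non-empty name")
        bad = set(self.match_fields) - {"drugname", "prod_ai"}
        if bad:
            raise ValueError(f"unknown match fields: {sorted(bad)}")
        if not self.role_filter <= ROLE_CODES:
            raise ValueError(f"role filter outside {sorted(ROLE_CODES)}")

    def all_names(self) -> list[str]:
        return [normalize_term(n) for n in (*self.generic_names, *self.trade_names)
                if normalize_term(n)]


def match_cohort(quarter: RawQuarter, query: DrugQuery) -> pd.DataFrame:
    """Return matched (primaryid, drug_seq) pairs for the cohort.

    Matching is monotone in the name list: adding names can only grow the
    cohort.  The returned frame keeps one row per matched drug mention so the
    therapy table can be joined downstream.
    """
    names = query.all_names()
    drug = quarter.drug
    role_ok = drug["role_cod"].str.strip().str.upper().isin(query.role_filter)
    name_hit = np.zeros(len(drug), dtype=bool)
    for fld in query.match_fields:
        s = (drug[fld].fillna("").str.replace(r"\s+", " ", regex=True)
             .str.strip().str.casefold())
        for name in names:
            name_hit |= s.str.contains(name, regex=False).to_numpy()
    matched = drug.loc[role_ok & name_hit, ["primaryid", "drug_seq"]]
    return matched.drop_duplicates().reset_index(drop=True)


def cohort_ids(matches: pd.DataFrame) -> set[str]:
    return set(matches["primaryid"])


def age_in_years(age_value, age_unit: str) -> float | None:
    """Convert an (age value, unit code) pair to years; None when unconvertible."""
    if age_value is None or (isinstance(age_value, str) and not age_value.strip()):
        return None
    try:
        value = float(age_value)
    except (TypeError, ValueError):
        return None
    unit = (age_unit or "").strip().upper()
    if unit not in AGE_UNIT_YEARS:
        return None
    if value < 0:
        log.warning("negative age %r ignored", age_value)
        return None
    return value * AGE_UNIT_YEARS[unit]


@dataclass
class CohortSummary:
    """Cohort characterisation: counts and percentages per category group.

    Every group (sex, age band, outcome, reporter, country, reporting year)
    sums exactly to ``n_total`` — unknowns are explicit categories, never
    dropped — so the percentage columns of each group sum to 100 up to
    rounding.
    """

    n_total: int
    by_sex: dict[str, int] = field(default_factory=dict)
    by_age_group: dict[str, int] = field(default_factory=dict)
    by_outcome: dict[str, int] = field(default_factory=dict)
    by_reporter: dict[str, int] = field(default_factory=dict)
    by_country: dict[str, int] = field(default_factory=dict)
    by_year: dict[str, int] = field(default_factory=dict)

    def groups(self) -> dict[str, dict[str, int]]:
        return {"sex": self.by_sex, "age_group": self.by_age_group,
                "outcome": self.by_outcome, "reporter": self.by_reporter,
                "country": self.by_country, "year": self.by_year}

    def percentage(self, group: str, category: str) -> float:
        n = self.groups()[group].get(category, 0)
        return round_half_up(100.0 * n / self.n_total, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [("overall", "all", self.n_total, 100.0)]
        for gname, tallies in self.groups().items():
            for cat, n in tallies.items():
                rows.append((gname, cat, n, self.percentage(gname, cat)))
        return pd.DataFrame(rows, columns=["group", "category", "n", "pct"])


def _age_group(years: float | None) -> str:
    if years is None:
        return "unknown"
    if years < 18:
        return "<18"
    if years <= 65:
        return "18-65"
    return ">65"


def _tally(labels) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in labels:
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))


def summarize_cohort(quarter: RawQuarter, ids: set[str],
                     outcome_precedence: tuple[str, ...] = DEFAULT_OUTCOME_PRECEDENCE,
                     ) -> CohortSummary:
    """Tabulate demographics, most-serious outcome, reporter, country and year.

    A report may carry several outcome codes; one category per report is
    forced by a most-serious-outcome precedence (default DE > LT > DS > HO,
    everything else — CA, RI, OT or no outcome record — as "other").
    """
    if not ids:
        raise ValueError("cohort is empty")
    demo = quarter.demo[quarter.demo["primaryid"].isin(ids)]
    n_total = len(demo)

    sex = demo["sex"].str.strip().str.upper().map(
        {"M": "male", "F": "female"}).fillna("unknown")

    years = [age_in_years(v, u) for v, u in zip(demo["age"], demo["age_cod"])]
    age_groups = [_age_group(y) for y in years]

    rank = {code: i for i, code in enumerate(outcome_precedence)}
    outc = quarter.outc[quarter.outc["primaryid"].isin(ids)].copy()
    outc["_rank"] = outc["outc_cod"].str.strip().str.upper().map(rank)
    best = (outc.dropna(subset=["_rank"]).sort_values(["primaryid", "_rank"])
                .groupby("primaryid", sort=False).head(1))
    code_by_id = dict(zip(best["primaryid"], best["outc_cod"].str.strip().str.upper()))
    outcomes = [OUTCOME_LABELS.get(code_by_id.get(pid, ""), "other")
                for pid in demo["primaryid"]]

    reporter = demo["occp_cod"].str.strip().str.upper().map(
        lambda c: OCCUPATION_LABELS.get(c, "unknown"))

    country = demo["occr_country"].str.strip()
    country = country.where(country != "", demo["reporter_country"].str.strip())
    country = country.where(country != "", "unknown")

    year = demo["fda_dt"].str.strip().str[:4]
    year = year.where(year.str.fullmatch(r"\d{4}").fillna(False), "unknown")

    return CohortSummary(
        n_total=n_total,
        by_sex=_tally(sex),
        by_age_group=_tally(age_groups),
        by_outcome=_tally(outcomes),
        by_reporter=_tally(reporter),
        by_country=_tally(country),
        by_year=_tally(year),
    )
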