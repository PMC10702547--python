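"""End-to-end orchestration: ingest -> dedup -> cohort -> tables -> signals -> onset.

The stages mirror the selection funnel of a spontaneous-report drug-safety
study: pool quarterly extracts, collapse case versions, extract the
primary-suspect cohort, screen every event label at PT level (and SOC level
when a mapping is supplied), and summarise demographics and time to onset.
Outputs are CSV tables plus a JSON run report with the counts at every stage.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import DrugQuery, cohort_ids, match_cohort, summarize_cohort
from .contingency import PtSocMap, build_tables
from .dedup import deduplicate, restrict_quarter
from .io import concat_quarters, read_deleted, read_quarter
from .onset import compute_onsets, summarize_onsets
from .signals import DisproportionalityScreen

log = logging.getLogger("faerspv")


class PipelineError(RuntimeError):
    """A stage-level failure that should abort the run."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from a YAML file."""

    input_dirs: list[str] = field(default_factory=list)
    deleted_files: list[str] = field(default_factory=list)
    drug_generic: list[str] = field(default_factory=list)
    drug_trade: list[str] = field(default_factory=list)
    drug_roles: list[str] = field(default_factory=lambda: ["PS"])
    match_fields: list[str] = field(default_factory=lambda: ["drugname", "prod_ai"])
    pt_soc_map: str | None = None
    ic_mode: str = "standard"
    continuity: float = 0.0
    min_n: int = 0
    paper_style: bool = False
    out_dir: str = "faerspv_out"
    column_synonyms: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        drug = raw.pop("drug", {})
        raw.setdefault("drug_generic", drug.get("generic", []))
        raw.setdefault("drug_trade", drug.get("trade", []))
        raw.setdefault("drug_roles", drug.get("roles", ["PS"]))
        known = {f for f in cls.__dataclass_fields__}
        cfg = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known
        if unknown:
            log.warning("ignoring unknown config keys: %s", sorted(unknown))
        cfg.update({k: v for k, v in overrides.items() if v not in (None, (), [])})
        return cls(**cfg)

    def query(self) -> DrugQuery:
        return DrugQuery(generic_names=tuple(self.drug_generic),
                         trade_names=tuple(self.drug_trade),
                         match_fields=tuple(self.match_fields),
                         role_filter=frozenset(self.drug_roles))


@dataclass
class RunReport:
    """Counts at every stage plus configuration echo."""

    raw_reports: int = 0
    deduplicated_reports: int = 0
    removed_duplicates: int = 0
    removed_deleted: int = 0
    cohort_size: int = 0
    pt_tables: int = 0
    soc_tables: int = 0
    flag_counts: dict = field(default_factory=dict)
    onset_n: int = 0
    onset_median_days: float | None = None
    onset_iqr_days: tuple | None = None
    onset_exclusions: dict = field(default_factory=dict)
    version: str = ""
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def run(config: RunConfig) -> RunReport:
    """Execute all stages; on failure, partial outputs are removed."""
    from . import __version__

    out_dir = Path(config.out_dir)
    fresh = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        report = _run_stages(config, out_dir, written)
        report.version = __version__
        report.config = {k: v for k, v in config.__dict__.items()}
        path = out_dir / "run_report.json"
        report.to_json(path)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        if fresh:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _run_stages(config: RunConfig, out_dir: Path, written: list[Path]) -> RunReport:
    if not config.input_dirs:
        raise PipelineError("no input directories configured")
    quarters = [read_quarter(d, synonyms=config.column_synonyms)
                for d in config.input_dirs]
    pooled = concat_quarters(quarters)
    for f in config.deleted_files:
        pooled.deleted_caseids |= read_deleted(f)
    report = RunReport(raw_reports=pooled.n_reports)
    log.info("ingest: %d raw reports from %d director%s", pooled.n_reports,
             len(quarters), "y" if len(quarters) == 1 else "ies")

    surviving, audit = deduplicate(pooled.demo, pooled.deleted_caseids)
    pooled = restrict_quarter(pooled, surviving)
    report.deduplicated_reports = audit.kept
    report.removed_duplicates = audit.removed_duplicates
    report.removed_deleted = audit.removed_deleted
    log.info("dedup: kept %d of %d (removed %d duplicates, %d deleted cases)",
             audit.kept, audit.total_in, audit.removed_duplicates,
             audit.removed_deleted)

    query = config.query()
    matches = match_cohort(pooled, query)
    ids = cohort_ids(matches)
    report.cohort_size = len(ids)
    if not ids:
        raise PipelineError(
            f"empty cohort: no report matches drug query "
            f"generic={list(query.generic_names)} trade={list(query.trade_names)} "
            f"roles={sorted(query.role_filter)}")
    log.info("cohort: %d reports", len(ids))

    summary = summarize_cohort(pooled, ids)
    p = out_dir / "cohort_summary.csv"
    summary.to_frame().to_csv(p, index=False, float_format="%.12g")
    written.append(p)

    pt_results = DisproportionalityScreen.from_quarter(
        pooled, ids, level="PT", ic_mode=config.ic_mode,
        continuity=config.continuity).fit()
    report.pt_tables = len(pt_results.frame)
    report.flag_counts = pt_results.flag_counts()
    p = out_dir / "pt_signals.csv"
    pt_results.to_csv(p, paper_style=config.paper_style, min_n=config.min_n)
    written.append(p)
    log.info("signals: %d PT tables, %d all-four signals", report.pt_tables,
             report.flag_counts["all_four"])

    if config.pt_soc_map:
        mapping = PtSocMap.from_csv(config.pt_soc_map)
        soc_results = DisproportionalityScreen.from_quarter(
            pooled, ids, level="SOC", mapping=mapping, ic_mode=config.ic_mode,
            continuity=config.continuity).fit()
        report.soc_tables = len(soc_results.frame)
        p = out_dir / "soc_signals.csv"
        soc_results.to_csv(p, paper_style=config.paper_style)
        written.append(p)

    records, exclusions = compute_onsets(pooled, matches)
    report.onset_exclusions = exclusions
    if len(records):
        onset = summarize_onsets(records)
        report.onset_n = onset.n
        report.onset_median_days = onset.median_days
        report.onset_iqr_days = (onset.q1_days, onset.q3_days)
        p = out_dir / "onset_bins.csv"
        onset.to_frame().to_csv(p, index=False, float_format="%.12g")
        written.append(p)
        p = out_dir / "onset_summary.csv"
        import pandas as pd

        pd.DataFrame([{"n": onset.n, "median_days": onset.median_days,
                       "q1_days": onset.q1_days, "q3_days": onset.q3_days}]
                     ).to_csv(p, index=False, float_format="%.12g")
        written.append(p)
        log.info("onset: n=%d median=%.0f IQR=%.0f-%.0f", onset.n,
                 onset.median_days, onset.q1_days, onset.q3_days)
    else:
        log.warning("onset: no report had usable therapy-start and event dates")
    return report
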