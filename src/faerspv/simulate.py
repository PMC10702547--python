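"""Synthetic FAERS-like report generator with known ground truth.

The generator emulates the statistical structure a disproportionality screen
assumes: each case is exposed to the study drug (as primary suspect) with a
fixed probability, draws a report-length-distributed set of preferred terms
from a baseline vocabulary, and — for exposed cases — has those term
probabilities *tilted* by per-term relative reporting ratios lambda and
renormalised (a multinomial tilt, the implicit model under which ROR, PRR and
EBGM estimate lambda).  On top of that it reproduces the messiness the
pipeline must survive: duplicate case versions with later receipt dates,
deleted cases, role-coded concomitant drug mentions, repeated terms within a
report, partial or missing dates, and categorical demographics.

Defaults mirror the published characteristics of a real oncology-drug cohort
(sex/age/outcome/reporter/country mixes, log-normal onset with median 54 days
and IQR about 17-112) at a desk-scale database size.  ``expected_table``
gives the closed-form expected 2x2 counts of the generative model, so
parameter-recovery tests are well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contingency import ContingencyTable
from .io import RawQuarter, write_quarter


def default_vocabulary(n_pts: int = 60, n_socs: int = 10) -> pd.DataFrame:
    """A synthetic PT vocabulary with SOC assignments (clearly labelled as such).

    Terms are named SYNTH PT 001..; baseline reporting probabilities follow a
    Zipf-like decay, roughly matching the long tail of real event vocabularies.
    """
    pts = [f"SYNTH PT {i + 1:03d}" for i in range(n_pts)]
    socs = [f"SYNTH SOC {i % n_socs + 1:02d}" for i in range(n_pts)]
    w = 1.0 / (np.arange(n_pts) + 5.0)
    return pd.DataFrame({"pt": pts, "soc": socs, "baseline_prob": w / w.sum()})


#: categorical mixes matching a published oncology-drug cohort
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"M": 0.5157, "F": 0.3371, "": 0.1472},
    "age_group": {"<18": 0.0071, "18-65": 0.1186, ">65": 0.2629, "unknown": 0.6114},
    "occupation": {"HP": 0.1314, "MD": 0.3371, "PH": 0.0571, "CN": 0.4586,
                   "OT": 0.0100, "": 0.0058},
    "outcome": {"DE": 0.3314, "DS": 0.0114, "HO": 0.1786, "LT": 0.0129, "OT": 0.4657},
    "country": {"US": 0.7871, "FR": 0.0643, "IL": 0.0229, "ES": 0.0171, "BR": 0.0157,
                "GB": 0.0310, "DE": 0.0310, "JP": 0.0309},
}

#: date-quality mix for event/start dates: day-resolved, month-resolved, missing
DEFAULT_DATE_QUALITY = {"day": 0.60, "month": 0.10, "missing": 0.30}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model; a fixed seed gives identical output."""

    n_cases: int = 10_000
    seed: int = 0
    vocabulary: pd.DataFrame = field(default_factory=default_vocabulary)
    study_drug_generic: str = "ERDAFITINIB"
    study_drug_trade: str = "BALVERSA"
    exposure_prob: float = 0.02
    injected_associations: dict[str, float] = field(default_factory=dict)
    pts_geom_p: float = 0.45          # truncated-geometric report length
    max_pts_per_report: int = 8
    duplicate_prob: float = 0.10
    deleted_prob: float = 0.02
    onset_median_days: float = 54.0
    onset_sigma: float = 1.4
    demographics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()})
    date_quality: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DATE_QUALITY))
    window_start: str = "20190101"
    window_end: str = "20221231"
    n_background_drugs: int = 20
    concomitant_rate: float = 0.7     # Poisson mean of extra role-C mentions

    def __post_init__(self):
        if len(self.vocabulary) == 0:
            raise ValueError("vocabulary is empty")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        probs = self.vocabulary["baseline_prob"].to_numpy(dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("baseline_prob must be a probability vector")
        for pt, lam in self.injected_associations.items():
            if lam < 0:
                raise ValueError(f"lambda for {pt!r} must be >= 0")
            if pt not in set(self.vocabulary["pt"]):
                raise ValueError(f"injected PT {pt!r} not in vocabulary")
        for name, mix in {**{"date_quality": self.date_quality},
                          **self.demographics}.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")

    def pt_probs(self, exposed: bool) -> np.ndarray:
        """Per-term reporting probabilities, tilted by lambda for exposed cases."""
        q = self.vocabulary["baseline_prob"].to_numpy(dtype=float)
        if not exposed or not self.injected_associations:
            return q
        lam = np.ones_like(q)
        idx = {pt: i for i, pt in enumerate(self.vocabulary["pt"])}
        for pt, l in self.injected_associations.items():
            lam[idx[pt]] = l
        tilted = q * lam
        return tilted / tilted.sum()

    def length_pmf(self) -> np.ndarray:
        """P(K = k) for k = 1..max: geometric truncated by lumping the tail."""
        k = np.arange(1, self.max_pts_per_report + 1)
        p = self.pts_geom_p
        pmf = (1 - p) ** (k - 1) * p
        pmf[-1] = 1.0 - pmf[:-1].sum()
        return pmf


def _pick(rng: np.random.Generator, mix: dict[str, float], size: int) -> np.ndarray:
    keys = np.array(list(mix), dtype=object)
    return rng.choice(keys, size=size, p=np.array(list(mix.values())))


def _fmt_dates(days: np.ndarray, quality: np.ndarray) -> np.ndarray:
    """Render day offsets (from epoch) as yyyymmdd / yyyymm / '' per quality."""
    dt = pd.to_datetime(np.asarray(days, dtype="int64"), unit="D", origin="unix")
    full = dt.strftime("%Y%m%d").to_numpy(dtype=object)
    month = dt.strftime("%Y%m").to_numpy(dtype=object)
    out = np.where(quality == "day", full, np.where(quality == "month", month, ""))
    return out.astype(object)


def simulate(config: SimulationConfig) -> tuple[RawQuarter, pd.DataFrame]:
    """Generate one pooled raw quarter plus a ground-truth sidecar.

    The truth frame has one row per case: caseid, primaryid of the final
    version, exposure flag, and the drawn onset days (-1 when not drawn).  It
    is meant for tests only and is never consumed by the pipeline itself.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases
    vocab = cfg.vocabulary["pt"].to_numpy(dtype=object)

    caseid_num = 10_000_001 + np.arange(n)
    caseid = caseid_num.astype(str).astype(object)
    pid1 = (caseid_num * 10 + 1).astype(str).astype(object)

    exposed = rng.random(n) < cfg.exposure_prob
    k = np.minimum(rng.geometric(cfg.pts_geom_p, size=n), cfg.max_pts_per_report)

    # epoch-day window
    t0 = int(pd.Timestamp(cfg.window_start).timestamp() // 86400)
    t1 = int(pd.Timestamp(cfg.window_end).timestamp() // 86400)

    onset = np.full(n, -1.0)
    onset[exposed] = np.round(rng.lognormal(np.log(cfg.onset_median_days),
                                            cfg.onset_sigma, size=int(exposed.sum())))
    onset_bg = np.round(rng.exponential(60.0, size=n))
    start_day = rng.integers(t0, max(t0 + 1, t1 - 450), size=n)
    event_day = start_day + np.where(exposed, np.maximum(onset, 0), onset_bg)
    fda_day = np.minimum(event_day + rng.integers(5, 60, size=n), t1)

    evq = _pick(rng, cfg.date_quality, n)
    stq = _pick(rng, cfg.date_quality, n)
    event_dt = _fmt_dates(event_day, evq)
    start_dt = _fmt_dates(start_day, stq)
    fda_dt = _fmt_dates(fda_day, np.full(n, "day", dtype=object))

    # demographics
    sex = _pick(rng, cfg.demographics["sex"], n)
    agegrp = _pick(rng, cfg.demographics["age_group"], n)
    age = np.full(n, "", dtype=object)
    age_cod = np.full(n, "", dtype=object)
    known = agegrp != "unknown"
    lo = np.where(agegrp == "<18", 1, np.where(agegrp == "18-65", 18, 66))
    hi = np.where(agegrp == "<18", 17, np.where(agegrp == "18-65", 65, 90))
    drawn = rng.integers(lo, hi + 1)
    age[known] = drawn[known].astype(str)
    age_cod[known] = "YR"
    occp = _pick(rng, cfg.demographics["occupation"], n)
    country = _pick(rng, cfg.demographics["country"], n)

    demo = pd.DataFrame({
        "primaryid": pid1, "caseid": caseid, "fda_dt": fda_dt,
        "event_dt": event_dt, "age": age, "age_cod": age_cod, "sex": sex,
        "occp_cod": occp, "occr_country": country,
        "reporter_country": country}, dtype=str)

    # reactions: per-case draws from tilted (exposed) or baseline probabilities
    rows_pid = np.repeat(pid1, k)
    rows_exposed = np.repeat(exposed, k)
    m = len(rows_pid)
    pts = np.empty(m, dtype=object)
    q_bg, q_ex = cfg.pt_probs(False), cfg.pt_probs(True)
    n_ex = int(rows_exposed.sum())
    if m - n_ex:
        pts[~rows_exposed] = rng.choice(vocab, size=m - n_ex, p=q_bg)
    if n_ex:
        pts[rows_exposed] = rng.choice(vocab, size=n_ex, p=q_ex)
    reac = pd.DataFrame({"primaryid": rows_pid, "pt": pts}, dtype=str)

    # drugs: one PS per case plus Poisson-distributed role-C concomitants
    bg_names = np.array([f"SYNTH DRUG {i + 1:02d}" for i in range(cfg.n_background_drugs)],
                        dtype=object)
    study_variants = np.array(
        [cfg.study_drug_generic, f"{cfg.study_drug_generic} 8 MG TABLET",
         cfg.study_drug_trade, cfg.study_drug_trade.capitalize()], dtype=object)
    ps_name = np.where(exposed, rng.choice(study_variants, size=n),
                       rng.choice(bg_names, size=n))
    ps_ai = np.where(exposed, cfg.study_drug_generic, "")
    n_con = rng.poisson(cfg.concomitant_rate, size=n)
    # a few background cases mention the study drug concomitantly: the role
    # filter must keep them out of the cohort
    study_con = (~exposed) & (rng.random(n) < 0.003)
    n_con = n_con + study_con
    con_pid = np.repeat(pid1, n_con)
    con_seq = (np.arange(int(n_con.sum())) -
               np.repeat(np.cumsum(n_con) - n_con, n_con) + 2)
    con_name = rng.choice(bg_names, size=int(n_con.sum()))
    is_study_con = np.repeat(study_con, n_con) & (con_seq == 2)
    con_name[is_study_con] = cfg.study_drug_trade
    drug = pd.DataFrame({
        "primaryid": np.concatenate([pid1, con_pid]),
        "drug_seq": np.concatenate([np.full(n, "1", dtype=object),
                                    con_seq.astype(str).astype(object)]),
        "role_cod": np.concatenate([np.full(n, "PS", dtype=object),
                                    np.full(len(con_pid), "C", dtype=object)]),
        "drugname": np.concatenate([ps_name, con_name]),
        "prod_ai": np.concatenate([ps_ai, np.full(len(con_pid), "", dtype=object)]),
    }, dtype=str)

    outc_codes = _pick(rng, cfg.demographics["outcome"], n)
    extra = rng.random(n) < 0.15   # some reports carry a second outcome code
    outc = pd.DataFrame({
        "primaryid": np.concatenate([pid1, pid1[extra]]),
        "outc_cod": np.concatenate([outc_codes,
                                    _pick(rng, cfg.demographics["outcome"],
                                          int(extra.sum()))]),
    }, dtype=str)

    end_q = _pick(rng, cfg.date_quality, n)
    end_dt = _fmt_dates(event_day + rng.integers(0, 120, size=n), end_q)
    ther = pd.DataFrame({
        "primaryid": pid1, "dsg_drug_seq": np.full(n, "1", dtype=object),
        "start_dt": start_dt, "end_dt": end_dt}, dtype=str)

    indi = pd.DataFrame({
        "primaryid": pid1, "indi_drug_seq": np.full(n, "1", dtype=object),
        "indi_pt": np.where(exposed, "Transitional cell carcinoma",
                            "Product used for unknown indication")}, dtype=str)

    # duplicate versions: same caseid, primaryid version 2, later receipt date,
    # occasionally a changed demographic field
    tables = {"drug": drug, "reac": reac, "outc": outc, "ther": ther, "indi": indi}
    dup = rng.random(n) < cfg.duplicate_prob
    final_pid = pid1.copy()
    if dup.any():
        idx = np.flatnonzero(dup)
        pid2 = (caseid_num[idx] * 10 + 2).astype(str).astype(object)
        final_pid[idx] = pid2
        fda2 = _fmt_dates(np.minimum(fda_day[idx] + rng.integers(10, 100, size=len(idx)),
                                     t1 + 100), np.full(len(idx), "day", dtype=object))
        demo2 = demo.iloc[idx].copy()
        demo2["primaryid"] = pid2
        demo2["fda_dt"] = fda2
        flip = rng.random(len(idx)) < 0.3
        demo2.loc[np.asarray(flip), "sex"] = ""
        demo = pd.concat([demo, demo2], ignore_index=True)
        remap = dict(zip(pid1[idx], pid2))
        for name, df in tables.items():
            sub = df[df["primaryid"].isin(remap)].copy()
            sub["primaryid"] = sub["primaryid"].map(remap)
            tables[name] = pd.concat([df, sub], ignore_index=True)
    drug, reac, outc, ther, indi = (tables[k] for k in
                                    ("drug", "reac", "outc", "ther", "indi"))

    deleted = set(caseid[rng.random(n) < cfg.deleted_prob])

    label = f"{cfg.window_start[:4]}-{cfg.window_end[:4]}"
    quarter = RawQuarter(demo=demo, drug=drug, reac=reac, outc=outc, ther=ther,
                         indi=indi, deleted_caseids=deleted, period_label=label)
    truth = pd.DataFrame({
        "caseid": caseid, "primaryid": final_pid,
        "exposed": exposed.astype(int).astype(str),
        "deleted": np.isin(caseid, list(deleted)).astype(int).astype(str),
        "onset_days": onset.astype(int).astype(str)}, dtype=str)
    return quarter, truth


def write_simulated(config: SimulationConfig, directory: str | Path) -> Path:
    """Simulate and write FAERS-style files plus the ground-truth sidecar."""
    directory = Path(directory)
    quarter, truth = simulate(config)
    write_quarter(quarter, directory)
    truth_path = directory / "GROUND_TRUTH.csv"
    truth.to_csv(truth_path, index=False)
    cols = ["pt", "soc"]
    config.vocabulary[cols].to_csv(directory / "PT_SOC_MAP.csv", index=False)
    return truth_path


def _containment_prob(q: float, pmf: np.ndarray) -> float:
    """P(a report of tilt-q terms contains the term at least once)."""
    k = np.arange(1, len(pmf) + 1)
    return float(np.sum(pmf * (1.0 - (1.0 - q) ** k)))


def expected_table(config: SimulationConfig, pt: str) -> ContingencyTable:
    """Closed-form expected 2x2 counts of the generative model for one term.

    Accounts for deletion (deleted cases never reach the screen) and for
    duplicate collapse (each case contributes exactly one report).  Real-valued
    cells; for lambda = 1 everywhere the implied ROR/PRR/EBGM are exactly 1.
    """
    pts = list(config.vocabulary["pt"])
    if pt not in pts:
        raise ValueError(f"unknown PT {pt!r}")
    i = pts.index(pt)
    pmf = config.length_pmf()
    n_eff = config.n_cases * (1.0 - config.deleted_prob)
    n_exp = n_eff * config.exposure_prob
    n_bg = n_eff - n_exp
    pc_exp = _containment_prob(config.pt_probs(True)[i], pmf)
    pc_bg = _containment_prob(config.pt_probs(False)[i], pmf)
    a = n_exp * pc_exp
    c = n_bg * pc_bg
    return ContingencyTable(a=a, b=n_exp - a, c=c, d=n_bg - c, label=pt, level="PT")


def implied_ebgm(config: SimulationConfig, pt: str) -> float:
    """Relative reporting ratio implied by the expected 2x2 table."""
    t = expected_table(config, pt)
    return (t.a * t.n_total) / ((t.a + t.c) * (t.a + t.b))
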