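"""Disproportionality statistics and signal criteria.

Four estimators of relative reporting for a drug-event 2x2 table
(a, b, c, d; N = a+b+c+d):

* **ROR** — reporting odds ratio ``ad/(bc)`` with the log-normal interval
  ``exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.
* **PRR** — proportional reporting ratio ``a(c+d) / (c(a+b))`` paired with
  the Pearson chi-square ``(ad-bc)^2 N / ((a+b)(c+d)(a+c)(b+d))`` (no
  continuity correction).
* **IC** — the BCPNN information component ``log2(aN / ((a+c)(a+b)))``, i.e.
  log2 of observed over expected co-reporting.  Its lower bound IC025 is
  ``IC - 2*sqrt(V)``: in ``standard`` mode V is the classical closed-form
  BCPNN variance approximation; in ``fixed_offset`` mode ``sqrt(V)`` is held
  at 0.835 so IC025 = IC - 1.67, the convention of some published screens.
* **EBGM** — here the relative reporting ratio ``aN / ((a+c)(a+b))`` with a
  log-normal interval (a simplified MGPS without gamma-Poisson shrinkage;
  note EBGM = 2^IC by construction).

Signal criteria: ROR lower bound > 1 with N >= 3; PRR >= 2 with chi2 >= 4 and
N >= 3; IC025 > 0; EBGM05 > 2.  A pair is a *signal* when all four hold.
Undefined statistics (zero cells) propagate as NaN and count as not
significant, never as errors.

The module exposes a model/results pair: :class:`DisproportionalityScreen`
holds the tables and options, ``fit()`` returns :class:`ScreenResults` with
the estimates, interval bounds, flags and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, PtSocMap, build_tables
from .io import RawQuarter

LN2 = np.log(2.0)
FIXED_IC_HALFWIDTH = 1.67

RESULT_COLUMNS = ["label", "level", "n", "ror", "ror_lo", "ror_hi", "prr", "chi2",
                  "ic", "ic025", "ebgm", "ebgm05",
                  "ror_sig", "prr_sig", "bcpnn_sig", "mgps_sig", "all_four"]


def _cells(a, b, c, d, continuity=0.0):
    arrs = [np.asarray(x, dtype=float) for x in (a, b, c, d)]
    if continuity:
        arrs = [x + continuity for x in arrs]
    return arrs


def _lognormal_bounds(point, a, b, c, d):
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        lo = np.exp(np.log(point) - 1.96 * se)
        hi = np.exp(np.log(point) + 1.96 * se)
    bad = (a <= 0) | (b <= 0) | (c <= 0) | (d <= 0)
    return np.where(bad, np.nan, lo), np.where(bad, np.nan, hi)


def ror_stats(a, b, c, d, continuity: float = 0.0):
    """Vectorised ROR with 95% log-normal bounds; NaN on any zero cell."""
    a, b, c, d = _cells(a, b, c, d, continuity)
    with np.errstate(divide="ignore", invalid="ignore"):
        point = (a * d) / (b * c)
    point = np.where((a <= 0) | (b <= 0) | (c <= 0) | (d <= 0), np.nan, point)
    lo, hi = _lognormal_bounds(point, a, b, c, d)
    return point, lo, hi


def prr_stats(a, b, c, d, continuity: float = 0.0):
    """Vectorised PRR and Pearson chi-square; NaN on zero margins."""
    a, b, c, d = _cells(a, b, c, d, continuity)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a * (c + d)) / (c * (a + b))
        chi2 = ((a * d - b * c) ** 2 * n) / ((a + b) * (c + d) * (a + c) * (b + d))
    prr = np.where((c <= 0) | (a + b <= 0), np.nan, prr)
    margins_ok = (a + b > 0) & (c + d > 0) & (a + c > 0) & (b + d > 0)
    chi2 = np.where(margins_ok, chi2, np.nan)
    return prr, chi2


def ebgm_stats(a, b, c, d, continuity: float = 0.0):
    """Vectorised relative reporting ratio with 95% log-normal bounds."""
    a, b, c, d = _cells(a, b, c, d, continuity)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        point = (a * n) / ((a + c) * (a + b))
    point = np.where((a <= 0) | (a + b <= 0) | (a + c <= 0), np.nan, point)
    lo, hi = _lognormal_bounds(point, a, b, c, d)
    return point, lo, hi


def _ic_variance_standard(a, b, c, d):
    """Closed-form approximation of the posterior variance of the IC.

    The classical BCPNN setup places Beta priors on the marginal and joint
    reporting probabilities (here gamma11 = alpha1 = beta1 = 1,
    alpha = beta = 2) and propagates their posterior variances to the log2
    ratio via the delta method.
    """
    n = a + b + c + d
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
    v = ((n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
         + (n - (a + b) + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha))
         + (n - (a + c) + beta - beta1) / ((a + c + beta1) * (1 + n + beta)))
    return v / LN2 ** 2


def ic_stats(a, b, c, d, mode: str = "standard", continuity: float = 0.0):
    """Vectorised information component and its lower 95% bound IC025."""
    if mode not in ("standard", "fixed_offset"):
        raise ValueError(f"unknown IC variance mode {mode!r}")
    a, b, c, d = _cells(a, b, c, d, continuity)
    ebgm, _, _ = ebgm_stats(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = np.log2(ebgm)
    if mode == "fixed_offset":
        half = FIXED_IC_HALFWIDTH
    else:
        half = 2.0 * np.sqrt(_ic_variance_standard(a, b, c, d))
    return ic, ic - half


# -- scalar convenience wrappers over one table ------------------------------

def ror(table: ContingencyTable, continuity: float = 0.0):
    point, lo, hi = ror_stats(table.a, table.b, table.c, table.d, continuity)
    return float(point), float(lo), float(hi)


def prr_chi2(table: ContingencyTable, continuity: float = 0.0):
    prr, chi2 = prr_stats(table.a, table.b, table.c, table.d, continuity)
    return float(prr), float(chi2)


def ic(table: ContingencyTable, mode: str = "standard", continuity: float = 0.0):
    icv, ic025 = ic_stats(table.a, table.b, table.c, table.d, mode, continuity)
    return float(icv), float(ic025)


def ebgm(table: ContingencyTable, continuity: float = 0.0):
    point, lo, hi = ebgm_stats(table.a, table.b, table.c, table.d, continuity)
    return float(point), float(lo), float(hi)


def evaluate_criteria(frame: pd.DataFrame) -> pd.DataFrame:
    """Attach the four signal flags and their conjunction to a result frame.

    NaN statistics never satisfy a criterion.  The PRR >= 2 boundary is
    inclusive; N is the observed co-report count a, untouched by any
    continuity correction.
    """
    out = frame.copy()
    n = out["n"]
    with np.errstate(invalid="ignore"):
        out["ror_sig"] = (out["ror_lo"] > 1.0) & (n >= 3)
        out["prr_sig"] = (out["prr"] >= 2.0) & (out["chi2"] >= 4.0) & (n >= 3)
        out["bcpnn_sig"] = out["ic025"] > 0.0
        out["mgps_sig"] = out["ebgm05"] > 2.0
    for col in ("ror_sig", "prr_sig", "bcpnn_sig", "mgps_sig"):
        out[col] = out[col].fillna(False).astype(bool)
    out["all_four"] = out["ror_sig"] & out["prr_sig"] & out["bcpnn_sig"] & out["mgps_sig"]
    return out


@dataclass
class DisproportionalityScreen:
    """Model object: a batch of 2x2 tables plus estimation options.

    Parameters
    ----------
    tables
        A frame with columns label, level, a, b, c, d (as produced by
        :func:`faerspv.contingency.build_tables`) or a list of
        :class:`ContingencyTable`.
    ic_mode
        "standard" (closed-form BCPNN variance, default) or "fixed_offset"
        (IC025 = IC - 1.67).
    continuity
        Additive continuity correction applied to all four cells before
        estimation (0 by default; 0.5 gives the Haldane-Anscombe variant for
        robustness studies).  Signal-count thresholds always use the raw a.
    """

    tables: pd.DataFrame | list[ContingencyTable]
    ic_mode: str = "standard"
    continuity: float = 0.0
    _frame: pd.DataFrame = dataclass_field(init=False, repr=False, default=None)

    def __post_init__(self):
        if isinstance(self.tables, pd.DataFrame):
            frame = self.tables.copy()
            if "label" not in frame.columns:
                frame["label"] = [str(i) for i in range(len(frame))]
            if "level" not in frame.columns:
                frame["level"] = "PT"
        else:
            frame = pd.DataFrame(
                [(t.label, t.level, t.a, t.b, t.c, t.d) for t in self.tables],
                columns=["label", "level", "a", "b", "c", "d"])
        missing = {"a", "b", "c", "d"} - set(frame.columns)
        if missing:
            raise ValueError(f"tables lack columns {sorted(missing)}")
        if self.ic_mode not in ("standard", "fixed_offset"):
            raise ValueError(f"unknown IC variance mode {self.ic_mode!r}")
        self._frame = frame.reset_index(drop=True)

    @classmethod
    def from_quarter(cls, quarter: RawQuarter, ids: set[str], level: str = "PT",
                     mapping: PtSocMap | None = None, **options
                     ) -> "DisproportionalityScreen":
        """Build the screen directly from a deduplicated quarter and cohort."""
        return cls(build_tables(quarter, ids, level=level, mapping=mapping), **options)

    def fit(self) -> "ScreenResults":
        f = self._frame
        a, b, c, d = (f[k].to_numpy(dtype=float) for k in "abcd")
        out = f[["label", "level"]].copy()
        out["n"] = f["a"].to_numpy()
        out["ror"], out["ror_lo"], out["ror_hi"] = ror_stats(a, b, c, d, self.continuity)
        out["prr"], out["chi2"] = prr_stats(a, b, c, d, self.continuity)
        out["ic"], out["ic025"] = ic_stats(a, b, c, d, self.ic_mode, self.continuity)
        out["ebgm"], out["ebgm05"], ebgm95 = ebgm_stats(a, b, c, d, self.continuity)
        out = evaluate_criteria(out)
        out["ebgm95"] = ebgm95
        out = (out.sort_values(["n", "label"], ascending=[False, True])
                  .reset_index(drop=True))
        return ScreenResults(frame=out[RESULT_COLUMNS + ["ebgm95"]], model=self)


@dataclass
class ScreenResults:
    """Fitted screen: per-label estimates, interval bounds and flags."""

    frame: pd.DataFrame
    model: DisproportionalityScreen

    @property
    def signals(self) -> pd.DataFrame:
        """Labels satisfying all four criteria simultaneously."""
        return self.frame[self.frame["all_four"]].reset_index(drop=True)

    def flag_counts(self) -> dict[str, int]:
        return {c: int(self.frame[c].sum())
                for c in ("ror_sig", "prr_sig", "bcpnn_sig", "mgps_sig", "all_four")}

    def to_csv(self, path, paper_style: bool = False, min_n: int = 0) -> None:
        """Write the result table; ``paper_style`` adds 2-decimal columns."""
        out = self.frame[self.frame["n"] >= min_n].copy()
        if paper_style:
            for col in ("ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025",
                        "ebgm", "ebgm05"):
                out[col + "_2dp"] = out[col].round(2)
        out.to_csv(path, index=False, float_format="%.12g")

    def summary(self, top: int = 20) -> str:
        """Human-readable table of the strongest associations by report count."""
        f = self.frame.head(top)
        lines = [
            "Disproportionality screen "
            f"({len(self.frame)} labels, ic_mode={self.model.ic_mode}, "
            f"continuity={self.model.continuity})",
            f"signals (all four criteria): {int(self.frame['all_four'].sum())}",
            "",
            f"{'label':<40s} {'n':>6s} {'ROR':>9s} {'(95% CI)':>19s} "
            f"{'PRR':>8s} {'chi2':>9s} {'IC':>6s} {'IC025':>7s} {'EBGM':>9s} sig",
        ]
        for r in f.itertuples(index=False):
            ci = f"({r.ror_lo:.2f}-{r.ror_hi:.2f})" if np.isfinite(r.ror_lo) else "(-)"
            lines.append(
                f"{r.label[:40]:<40s} {r.n:>6d} {r.ror:>9.2f} {ci:>19s} "
                f"{r.prr:>8.2f} {r.chi2:>9.2f} {r.ic:>6.2f} {r.ic025:>7.2f} "
                f"{r.ebgm:>9.2f} {'*' if r.all_four else ''}")
        return "\n".join(lines)

    def plot_top(self, n: int = 15, ax=None):
        """Horizontal bar chart of EBGM for the top-n signals (log scale)."""
        import matplotlib.pyplot as plt

        sig = self.signals.head(n)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * max(len(sig), 4) + 1))
        ax.barh(sig["label"][::-1], sig["ebgm"][::-1], color="#33627a")
        ax.set_xscale("log")
        ax.set_xlabel("EBGM (relative reporting ratio)")
        ax.axvline(1.0, color="0.4", lw=0.8)
        return ax


def screen(tables, ic_mode: str = "standard", continuity: float = 0.0) -> ScreenResults:
    """One-call screen over a table frame or list of ContingencyTable."""
    return DisproportionalityScreen(tables, ic_mode=ic_mode, continuity=continuity).fit()
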