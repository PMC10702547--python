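"""The four disproportionality statistics, their invariants and criteria."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faerspv.contingency import ContingencyTable
from faerspv.signals import (
    DisproportionalityScreen,
    ebgm,
    evaluate_criteria,
    ic,
    prr_chi2,
    ror,
    screen,
)

cells = st.integers(min_value=1, max_value=2000)
tables = st.builds(ContingencyTable, a=cells, b=cells, c=cells, d=cells)

SYMMETRIC = ContingencyTable(5, 5, 5, 5)
HAND = ContingencyTable(10, 90, 100, 9800)


class TestPointEstimates:
    def test_symmetric_table_is_null(self):
        r, lo, hi = ror(SYMMETRIC)
        assert r == 1.0 and lo < 1.0 < hi
        assert prr_chi2(SYMMETRIC) == (1.0, 0.0)
        assert ic(SYMMETRIC)[0] == 0.0
        assert ebgm(SYMMETRIC)[0] == 1.0

    def test_hand_arithmetic(self):
        # ad/(bc) = 98000/9000; a(c+d)/(c(a+b)) = 10*9900/(100*100);
        # aN/((a+c)(a+b)) = 100000/(110*100)
        assert ror(HAND)[0] == pytest.approx(98000 / 9000, rel=1e-12)
        prr, chi2 = prr_chi2(HAND)
        assert prr == pytest.approx(9.9, rel=1e-12)
        assert chi2 == pytest.approx(73.545455473941, rel=1e-9)
        assert ebgm(HAND)[0] == pytest.approx(100000 / 11000, rel=1e-12)
        assert ic(HAND)[0] == pytest.approx(math.log2(100000 / 11000), rel=1e-12)

    def test_chi2_against_scipy(self):
        from scipy.stats import chi2_contingency

        for t in (HAND, ContingencyTable(3, 17, 40, 940), SYMMETRIC):
            expected = chi2_contingency([[t.a, t.b], [t.c, t.d]],
                                        correction=False).statistic
            assert prr_chi2(t)[1] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_fixed_offset_mode(self):
        icv, ic025 = ic(HAND, mode="fixed_offset")
        assert ic025 == pytest.approx(icv - 1.67, rel=1e-12)

    def test_standard_ic025_below_ic(self):
        icv, ic025 = ic(HAND, mode="standard")
        assert ic025 < icv


class TestZeroCellPolicy:
    def test_zero_cells_give_nan_not_errors(self):
        t = ContingencyTable(0, 10, 5, 100)
        assert math.isnan(ror(t)[0])
        assert math.isnan(ebgm(t)[0])
        assert math.isnan(ic(t)[0])
        t2 = ContingencyTable(4, 10, 0, 100)
        assert math.isnan(ror(t2)[0])
        assert math.isnan(prr_chi2(t2)[0])

    def test_continuity_option_restores_finiteness(self):
        t = ContingencyTable(4, 10, 0, 100)
        assert math.isfinite(ror(t, continuity=0.5)[0])

    def test_nan_statistics_never_flag(self):
        res = screen([ContingencyTable(0, 10, 5, 100, label="z")])
        assert not res.frame[["ror_sig", "prr_sig", "bcpnn_sig",
                              "mgps_sig", "all_four"]].any().any()


class TestInvariants:
    @given(tables, st.integers(min_value=2, max_value=7))
    @settings(max_examples=150, deadline=None)
    def test_scale_invariance(self, t, k):
        big = ContingencyTable(t.a * k, t.b * k, t.c * k, t.d * k)
        assert ror(big)[0] == pytest.approx(ror(t)[0], rel=1e-9)
        assert prr_chi2(big)[0] == pytest.approx(prr_chi2(t)[0], rel=1e-9)
        assert prr_chi2(big)[1] == pytest.approx(k * prr_chi2(t)[1], rel=1e-9)
        assert ebgm(big)[0] == pytest.approx(ebgm(t)[0], rel=1e-9)
        assert ic(big)[0] == pytest.approx(ic(t)[0], rel=1e-9, abs=1e-9)

    @given(tables)
    @settings(max_examples=150, deadline=None)
    def test_ror_transpose_symmetric(self, t):
        swapped = ContingencyTable(t.a, t.c, t.b, t.d)  # drug/event axes swapped
        assert ror(swapped)[0] == pytest.approx(ror(t)[0], rel=1e-9)

    @given(cells, cells, st.integers(min_value=2, max_value=9))
    @settings(max_examples=100, deadline=None)
    def test_null_case_exact(self, a, b, k):
        # background has the same event share -> prr = 1, ic = 0 exactly
        t = ContingencyTable(a, b, k * a, k * b)
        assert prr_chi2(t)[0] == 1.0
        assert ic(t)[0] == 0.0

    @given(tables)
    @settings(max_examples=150, deadline=None)
    def test_ic_is_log2_ebgm(self, t):
        assert ic(t)[0] == pytest.approx(math.log2(ebgm(t)[0]), rel=1e-12, abs=1e-12)

    @given(tables)
    @settings(max_examples=150, deadline=None)
    def test_geometric_mean_of_bounds_is_point(self, t):
        for stat in (ror, ebgm):
            point, lo, hi = stat(t)
            assert math.sqrt(lo * hi) == pytest.approx(point, rel=1e-9)

    @given(tables)
    @settings(max_examples=100, deadline=None)
    def test_ror_prr_strictly_monotone_in_a(self, t):
        # EBGM/IC are deliberately absent: a appears in both margins of the
        # relative reporting ratio, so they are not monotone in a
        # (e.g. (1,1,1,5) and (2,1,1,5) both give EBGM = 2).
        up = ContingencyTable(t.a + 1, t.b, t.c, t.d)
        assert ror(up)[0] > ror(t)[0]
        assert prr_chi2(up)[0] > prr_chi2(t)[0]


class TestCriteria:
    @staticmethod
    def frame(**kw):
        base = dict(label="x", level="PT", n=10, ror=2.0, ror_lo=1.5, ror_hi=3.0,
                    prr=2.5, chi2=10.0, ic=1.0, ic025=0.5, ebgm=2.5, ebgm05=2.2)
        base.update(kw)
        return pd.DataFrame([base])

    def test_published_soc_row_passes_all_four(self):
        # reported organ-class row: 123 cases, ROR lower bound 3.82,
        # PRR 4.31 (chi2 318.30), IC025 0.44, EBGM05 3.58
        out = evaluate_criteria(self.frame(n=123, ror_lo=3.82, prr=4.31,
                                           chi2=318.30, ic025=0.44, ebgm05=3.58))
        assert out.loc[0, ["ror_sig", "prr_sig", "bcpnn_sig", "mgps_sig",
                           "all_four"]].all()

    def test_n_below_three_blocks_ror_and_prr(self):
        out = evaluate_criteria(self.frame(n=2, ror_lo=50.0, prr=60.0, chi2=500.0))
        assert not out.loc[0, "ror_sig"] and not out.loc[0, "prr_sig"]

    def test_prr_boundary_inclusive(self):
        out = evaluate_criteria(self.frame(prr=2.0, chi2=4.0))
        assert out.loc[0, "prr_sig"]

    def test_symmetric_table_flags_nothing(self):
        res = screen([SYMMETRIC])
        assert not res.frame.loc[0, "all_four"]

    def test_all_four_is_conjunction(self):
        out = evaluate_criteria(self.frame(ic025=-0.1))
        assert out.loc[0, "ror_sig"] and not out.loc[0, "bcpnn_sig"]
        assert not out.loc[0, "all_four"]


class TestScreenInterface:
    def test_empty_input(self):
        res = screen([])
        assert len(res.frame) == 0 and len(res.signals) == 0

    def test_sorted_by_n_then_label(self):
        res = screen([ContingencyTable(5, 10, 10, 100, label="b"),
                      ContingencyTable(9, 6, 10, 100, label="a"),
                      ContingencyTable(5, 10, 10, 100, label="a")])
        assert list(res.frame["label"]) == ["a", "a", "b"]
        assert list(res.frame["n"]) == [9, 5, 5]

    def test_model_results_roundtrip(self, tmp_path):
        model = DisproportionalityScreen([HAND], ic_mode="fixed_offset")
        res = model.fit()
        assert res.model is model
        assert "signals" in res.summary()
        p = tmp_path / "out.csv"
        res.to_csv(p, paper_style=True)
        back = pd.read_csv(p)
        assert back.loc[0, "ror_2dp"] == pytest.approx(10.89)

    def test_injected_association_is_unique_signal(self):
        # one strongly associated label among nulls
        rng = np.random.default_rng(2)
        tables = [ContingencyTable(100, 900, 500, 49500, label="hit")]
        for i in range(30):
            a = int(rng.integers(5, 30))
            tables.append(ContingencyTable(a, 1000 - a, a * 50, 50000 - a * 50,
                                           label=f"null{i}"))
        res = screen(tables)
        assert list(res.signals["label"]) == ["hit"]
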