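"""Time-to-onset extraction, exclusion accounting and summaries."""

import numpy as np
import pytest

from faerspv.cohort import DrugQuery, match_cohort
from faerspv.onset import bin_label, compute_onsets, summarize_onsets
from faerspv.simulate import SimulationConfig
from faerspv.validation import onset_recovery

from conftest import make_quarter

QUERY = DrugQuery(generic_names=("erdafitinib",))


def quarter_with_dates(event_dt, start_dt, second_start=None):
    ther = [dict(primaryid="101", dsg_drug_seq="1", start_dt=start_dt)]
    if second_start is not None:
        ther.append(dict(primaryid="101", dsg_drug_seq="1", start_dt=second_start))
    return make_quarter(
        demo=[dict(primaryid="101", caseid="1", fda_dt="20200401",
                   event_dt=event_dt)],
        drug=[dict(primaryid="101", drug_seq="1", role_cod="PS",
                   drugname="ERDAFITINIB")],
        ther=ther)


def run_one(event_dt, start_dt, **kw):
    q = quarter_with_dates(event_dt, start_dt, **kw)
    return compute_onsets(q, match_cohort(q, QUERY))


@pytest.mark.parametrize("event,start,days", [
    ("20200224", "20200101", 54),
    ("20200101", "20200101", 0),     # same-day onset is valid
])
def test_calendar_arithmetic(event, start, days):
    records, excl = run_one(event, start)
    assert list(records["days"]) == [days]
    assert sum(excl.values()) == 0


@pytest.mark.parametrize("event,start,reason", [
    ("20200201", "20200301", "negative_interval"),
    ("20200224", "202001", "partial_start_date"),
    ("202002", "20200101", "partial_event_date"),
    ("", "20200101", "missing_event_date"),
    ("20200224", "", "missing_start_date"),
])
def test_exclusion_reasons(event, start, reason):
    records, excl = run_one(event, start)
    assert len(records) == 0
    assert excl[reason] == 1
    assert sum(excl.values()) == 1


def test_earliest_matched_start_is_used():
    records, _ = run_one("20200224", "20200201", second_start="20200101")
    assert list(records["days"]) == [54]


def test_retained_plus_excluded_equals_cohort():
    cfg = SimulationConfig(n_cases=2000, seed=17, exposure_prob=0.2)
    summary, exclusions, _drawn = onset_recovery(cfg)
    # cohort size = every exposed, non-deleted case
    from faerspv.dedup import deduplicate, restrict_quarter
    from faerspv.simulate import simulate
    from faerspv.cohort import cohort_ids
    from faerspv.validation import study_query

    quarter, _ = simulate(cfg)
    surviving, _ = deduplicate(quarter.demo, quarter.deleted_caseids)
    quarter = restrict_quarter(quarter, surviving)
    n_cohort = len(cohort_ids(match_cohort(quarter, study_query(cfg))))
    assert summary.n + sum(exclusions.values()) == n_cohort


class TestSummary:
    def test_three_point_summary(self):
        s = summarize_onsets([17, 54, 112])
        assert s.median_days == 54
        # quartiles by linear interpolation between order statistics
        assert s.q1_days == pytest.approx(35.5)
        assert s.q3_days == pytest.approx(83.0)

    def test_bins_and_percentages(self):
        s = summarize_onsets([0, 29, 30, 54, 360, 400])
        assert s.bins["0-29"] == 2
        assert s.bins["30-59"] == 2
        assert s.bins[">360"] == 2
        assert sum(s.bins.values()) == s.n
        assert abs(sum(s.bin_percentages().values()) - 100.0) < 0.05

    def test_bin_labels(self):
        assert bin_label(1) == "0-29"
        assert bin_label(12) == "330-359"
        assert bin_label(13) == ">360"

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize_onsets([])

    def test_shift_moves_quantiles_exactly(self):
        rng = np.random.default_rng(1)
        days = rng.integers(0, 300, size=200)
        s0, s1 = summarize_onsets(days), summarize_onsets(days + 17)
        assert s1.median_days == s0.median_days + 17
        assert s1.q1_days == s0.q1_days + 17
        assert s1.q3_days == s0.q3_days + 17


def test_lognormal_median_recovered():
    """Pipeline-recovered onset median within ~3 SE of the generated median.

    SE of the sample median of a log-normal(median m, sigma) is
    1 / (2 f(m) sqrt(n)) with f(m) = 1/(m sigma sqrt(2 pi)).
    """
    cfg = SimulationConfig(n_cases=6000, seed=29, exposure_prob=0.5,
                           duplicate_prob=0.0, deleted_prob=0.0)
    summary, _, drawn = onset_recovery(cfg)
    assert summary.n > 500
    m, sigma = cfg.onset_median_days, cfg.onset_sigma
    se = (m * sigma * np.sqrt(2 * np.pi)) / (2 * np.sqrt(summary.n))
    assert abs(summary.median_days - m) < 3 * se + 1.0  # +1 for day rounding
    # and the retained sample tracks the drawn ground truth
    assert abs(summary.median_days - np.median(drawn)) < 3 * se + 1.0
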