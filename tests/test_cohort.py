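"""Cohort matching, age conversion and the demographic summary."""

import numpy as np
import pytest

from faerspv.cohort import (
    DrugQuery,
    age_in_years,
    cohort_ids,
    match_cohort,
    summarize_cohort,
)
from faerspv.dedup import deduplicate, restrict_quarter
from faerspv.simulate import DEFAULT_DEMOGRAPHICS, SimulationConfig, simulate

from conftest import make_quarter

QUERY = DrugQuery(generic_names=("erdafitinib",), trade_names=("Balversa",))


def one_drug_quarter(drugname, role):
    return make_quarter(
        demo=[dict(primaryid="101", caseid="1", fda_dt="20200101")],
        drug=[dict(primaryid="101", drug_seq="1", role_cod=role, drugname=drugname)])


@pytest.mark.parametrize("drugname,role,expected", [
    ("BALVERSA 8MG", "PS", True),        # substring + role rule
    ("erdafitinib", "C", False),         # concomitant excluded by default
    ("Erdafitinib  (tablet)", "PS", True),   # whitespace/case normalisation
    ("SYNTH DRUG 01", "PS", False),
])
def test_match_rules(drugname, role, expected):
    ids = cohort_ids(match_cohort(one_drug_quarter(drugname, role), QUERY))
    assert (ids == {"101"}) is expected


def test_match_on_active_ingredient_field():
    q = make_quarter(
        demo=[dict(primaryid="101", caseid="1", fda_dt="20200101")],
        drug=[dict(primaryid="101", drug_seq="1", role_cod="PS",
                   drugname="UNKNOWN BRAND", prod_ai="ERDAFITINIB")])
    assert cohort_ids(match_cohort(q, QUERY)) == {"101"}


def test_match_monotone_in_name_list():
    q = one_drug_quarter("BALVERSA", "PS")
    small = DrugQuery(generic_names=("erdafitinib",))
    large = DrugQuery(generic_names=("erdafitinib",), trade_names=("balversa",))
    assert cohort_ids(match_cohort(q, small)) <= cohort_ids(match_cohort(q, large))


def test_empty_query_rejected():
    with pytest.raises(ValueError):
        DrugQuery(generic_names=("  ",))


def test_cohort_equals_generator_ground_truth():
    cfg = SimulationConfig(n_cases=2000, seed=21, duplicate_prob=0.2)
    quarter, truth = simulate(cfg)
    surviving, _ = deduplicate(quarter.demo, quarter.deleted_caseids)
    quarter = restrict_quarter(quarter, surviving)
    ids = cohort_ids(match_cohort(quarter, QUERY))
    expected = set(truth.loc[(truth["exposed"] == "1") & (truth["deleted"] == "0"),
                             "primaryid"])
    assert ids == expected


@pytest.mark.parametrize("value,unit,expected", [
    (66, "YR", 66.0),
    (6, "DEC", 60.0),
    (18, "MON", 1.5),
    (365.25, "DY", 1.0),
    (52.18, "WK", 1.0),
    (8766, "HR", 1.0),
    (-5, "YR", None),
    ("", "YR", None),
    (30, "", None),
    (30, "XX", None),
])
def test_age_in_years(value, unit, expected):
    got = age_in_years(value, unit)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


def test_single_report_summary():
    q = make_quarter(demo=[dict(primaryid="101", caseid="1", fda_dt="20200101",
                                sex="F", age="70", age_cod="YR")])
    s = summarize_cohort(q, {"101"})
    assert s.by_sex == {"female": 1}
    assert s.percentage("sex", "female") == 100.00
    assert s.percentage("sex", "male") == 0.0
    assert s.by_age_group == {">65": 1}
    assert s.by_outcome == {"other": 1}   # no outcome record
    assert s.by_year == {"2020": 1}


def test_outcome_precedence_most_serious_wins():
    q = make_quarter(
        demo=[dict(primaryid="101", caseid="1", fda_dt="20200101")],
        outc=[dict(primaryid="101", outc_cod="HO"),
              dict(primaryid="101", outc_cod="DE"),
              dict(primaryid="101", outc_cod="OT")])
    s = summarize_cohort(q, {"101"})
    assert s.by_outcome == {"death": 1}


def test_tally_groups_sum_to_total():
    cfg = SimulationConfig(n_cases=1500, seed=4)
    quarter, _ = simulate(cfg)
    surviving, _ = deduplicate(quarter.demo, quarter.deleted_caseids)
    quarter = restrict_quarter(quarter, surviving)
    ids = quarter.report_ids()
    s = summarize_cohort(quarter, ids)
    for tallies in s.groups().values():
        assert sum(tallies.values()) == s.n_total
        assert sum(s.percentage(g, c) for g, t in s.groups().items()
                   for c in t) > 0  # percentages materialise


def test_summary_recovers_generator_probabilities():
    """Tallies on 10,000 reports within 3 SD of the categorical expectations."""
    cfg = SimulationConfig(n_cases=10_000, seed=13, duplicate_prob=0.0,
                           deleted_prob=0.0)
    quarter, _ = simulate(cfg)
    s = summarize_cohort(quarter, quarter.report_ids())
    n = s.n_total
    checks = {
        ("sex", "male"): DEFAULT_DEMOGRAPHICS["sex"]["M"],
        ("sex", "female"): DEFAULT_DEMOGRAPHICS["sex"]["F"],
        ("age_group", ">65"): DEFAULT_DEMOGRAPHICS["age_group"][">65"],
        ("country", "US"): DEFAULT_DEMOGRAPHICS["country"]["US"],
        ("reporter", "consumer"): DEFAULT_DEMOGRAPHICS["occupation"]["CN"],
    }
    for (group, cat), p in checks.items():
        observed = s.groups()[group].get(cat, 0)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) < 3 * sd, (group, cat)
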