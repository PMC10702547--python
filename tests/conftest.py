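"""Shared fixtures: toy quarter builder and the seeded recovery experiment."""

from __future__ import annotations

import pandas as pd
import pytest

from faerspv.io import RawQuarter, SCHEMAS
from faerspv.simulate import SimulationConfig
from faerspv.validation import DEFAULT_INJECTIONS, parameter_recovery


def make_table(kind: str, rows: list[dict]) -> pd.DataFrame:
    cols = SCHEMAS[kind]
    data = [{c: str(r.get(c, "")) for c in cols} for r in rows]
    return pd.DataFrame(data, columns=cols, dtype=str) if data else \
        pd.DataFrame({c: pd.Series(dtype=str) for c in cols})


def make_quarter(demo=(), drug=(), reac=(), outc=(), ther=(), indi=(),
                 deleted=frozenset(), label="TEST") -> RawQuarter:
    """Build a quarter from lists of partial row dicts (missing fields empty)."""
    return RawQuarter(
        demo=make_table("demo", list(demo)), drug=make_table("drug", list(drug)),
        reac=make_table("reac", list(reac)), outc=make_table("outc", list(outc)),
        ther=make_table("ther", list(ther)), indi=make_table("indi", list(indi)),
        deleted_caseids=set(deleted), period_label=label)


@pytest.fixture
def toy_quarter():
    """Two reports: r1 (cohort drug, PS) with PT X, r2 with PT Y."""
    return make_quarter(
        demo=[dict(primaryid="101", caseid="1", fda_dt="20200110"),
              dict(primaryid="201", caseid="2", fda_dt="20200120")],
        drug=[dict(primaryid="101", drug_seq="1", role_cod="PS",
                   drugname="ERDAFITINIB"),
              dict(primaryid="201", drug_seq="1", role_cod="PS",
                   drugname="SYNTH DRUG 01")],
        reac=[dict(primaryid="101", pt="X"), dict(primaryid="201", pt="Y")])


@pytest.fixture(scope="session")
def recovery_report():
    """The 100-replicate injected-association recovery experiment.

    Session-scoped because it is by far the most expensive computation in the
    suite; several tests assert different properties of the same experiment.
    """
    return parameter_recovery(SimulationConfig(n_cases=10_000),
                              injections=DEFAULT_INJECTIONS, seeds=range(1, 101))
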