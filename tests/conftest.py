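import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from pvsignal.dates import PartialDate
from pvsignal.hierarchy import toy_hierarchy
from pvsignal.reports import (DrugEntry, ReactionEntry, ReportRecord,
                              ReportSet)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hierarchy():
    return toy_hierarchy()


def make_record(report_id="R1", case_id=None, case_version=1,
                receipt="2019-06-01", age=60.0, sex="female",
                outcomes=("hospitalization",), drugs=None, reactions=None):
    """Minimal valid report for fixtures; override what the test cares about."""
    if drugs is None:
        drugs = [DrugEntry("vemurafenib", "primary_suspect"),
                 DrugEntry("cobimetinib", "secondary_suspect")]
    if reactions is None:
        reactions = [ReactionEntry("rash")]
    return ReportRecord(
        report_id=report_id,
        case_id=case_id or report_id,
        case_version=case_version,
        receipt_date=PartialDate.parse(receipt) if receipt else None,
        age=age,
        sex=sex,
        country="US",
        outcomes=frozenset(outcomes),
        drugs=tuple(drugs),
        reactions=tuple(reactions),
    )


@pytest.fixture
def window_2018_2019():
    return (dt.date(2018, 1, 1), dt.date(2019, 12, 31))


def report_set(*records):
    rs = ReportSet(list(records))
    rs.log(action="fixture", n_records=len(records))
    return rs
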