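import datetime as dt
import itertools

import pytest
from hypothesis import given, strategies as st

from pvsignal.errors import ArgumentError, SchemaError, ValidationError
from pvsignal.reports import (FilterSpec, TSV_COLUMNS, deduplicate,
                              filter_reports, load_reports,
                              select_combination, write_tsv, DrugEntry,
                              ReactionEntry)

from conftest import make_record, report_set


# ---------------------------------------------------------------------------
# TSV loading

def _tsv_row(report_id, drug="vemurafenib", role="PS", pt="rash", **over):
    row = {c: "" for c in TSV_COLUMNS}
    row.update({
        "report_id": report_id, "case_id": f"case-{report_id}",
        "case_version": "1", "receipt_date": "2019-06-01", "age": "61",
        "sex": "F", "country": "US", "outcomes": "HO",
        "drug_name": drug, "drug_role": role, "pt_term": pt,
    })
    row.update(over)
    return row


def _write_tsv(path, rows):
    lines = ["\t".join(TSV_COLUMNS)]
    lines += ["\t".join(r[c] for c in TSV_COLUMNS) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def test_empty_tsv_loads_zero_records(tmp_path):
    path = _write_tsv(tmp_path / "empty.tsv", [])
    rs = load_reports(path, "tsv")
    assert len(rs) == 0 and rs.provenance[0]["n_records"] == 0


def test_three_well_formed_reports(tmp_path):
    rows = [_tsv_row(f"R{i}") for i in range(3)]
    rs = load_reports(_write_tsv(tmp_path / "in.tsv", rows), "tsv")
    assert len(rs) == 3
    assert len(rs.provenance) == 1


def test_one_row_per_link_collapses_to_one_record(tmp_path):
    rows = [
        _tsv_row("R1", drug="vemurafenib", role="PS", pt="rash"),
        _tsv_row("R1", drug="vemurafenib", role="PS", pt="pyrexia"),
        _tsv_row("R1", drug="cobimetinib", role="SS", pt="rash"),
        _tsv_row("R1", drug="cobimetinib", role="SS", pt="pyrexia"),
    ]
    rs = load_reports(_write_tsv(tmp_path / "in.tsv", rows), "tsv")
    (rec,) = rs.records
    assert {d.drug_name for d in rec.drugs} == {"vemurafenib", "cobimetinib"}
    assert rec.pt_terms == {"rash", "pyrexia"}


def test_missing_column_is_schema_error(tmp_path):
    cols = [c for c in TSV_COLUMNS if c != "case_id"]
    path = tmp_path / "bad.tsv"
    path.write_text("\t".join(cols) + "\n")
    with pytest.raises(SchemaError, match="case_id"):
        load_reports(path, "tsv")


def test_unknown_role_names_report(tmp_path):
    rows = [_tsv_row("R9", role="X")]
    with pytest.raises(ValidationError, match="R9"):
        load_reports(_write_tsv(tmp_path / "in.tsv", rows), "tsv")


def test_malformed_rows_counted_not_silently_dropped(tmp_path):
    rows = [_tsv_row("R1"), _tsv_row("", pt="rash"), _tsv_row("R2", pt="")]
    rs = load_reports(_write_tsv(tmp_path / "in.tsv", rows), "tsv")
    assert len(rs) == 1
    assert rs.provenance[0]["n_malformed_rows"] == 2


def test_partial_dates_preserved_as_partial(tmp_path):
    rows = [_tsv_row("R1", receipt_date="2018-03", onset_date="2018")]
    rs = load_reports(_write_tsv(tmp_path / "in.tsv", rows), "tsv")
    rec = rs.records[0]
    assert not rec.receipt_date.is_complete
    assert rec.reactions[0].onset_date.month is None


def test_term_normalization_collapses_spelling_variants(tmp_path):
    rows = [_tsv_row("R1", pt="Guillain–Barré  Syndrome")]
    rs = load_reports(_write_tsv(tmp_path / "in.tsv", rows), "tsv")
    assert rs.records[0].pt_terms == {"guillain-barre syndrome"}


def test_write_tsv_round_trips(tmp_path):
    original = report_set(
        make_record("R1", outcomes=("death", "other")),
        make_record("R2", age=None, receipt="2018-05",
                    reactions=[ReactionEntry("pyrexia")]),
    )
    path = tmp_path / "out.tsv"
    write_tsv(original, path)
    reloaded = load_reports(path, "tsv")
    assert [r.report_id for r in reloaded] == ["R1", "R2"]
    for a, b in zip(original, reloaded):
        assert a.outcomes == b.outcomes
        assert a.pt_terms == b.pt_terms
        assert a.age == b.age
        assert (a.receipt_date is None) == (b.receipt_date is None)


# ---------------------------------------------------------------------------
# FAERS ASCII loading

def _write_faers(tmp_path, drug_role="PS"):
    (tmp_path / "DEMO24Q1.txt").write_text(
        "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occr_country\n"
        "1001$500$1$20190215$61$YR$F$US\n"
        "1002$501$1$20190301$720$MON$M$FR\n"
    )
    (tmp_path / "DRUG24Q1.txt").write_text(
        "primaryid$caseid$drug_seq$role_cod$drugname$dose_amt$dose_unit$dechal$rechal\n"
        f"1001$500$1${drug_role}$Vemurafenib$960$MG$Y$U\n"
        "1001$500$2$SS$Cobimetinib$60$MG$Y$U\n"
        "1002$501$1$PS$Dabrafenib$$$U$U\n"
    )
    (tmp_path / "REAC24Q1.txt").write_text(
        "primaryid$caseid$pt\n1001$500$Rash\n1001$500$Pyrexia\n1002$501$Nausea\n"
    )
    (tmp_path / "OUTC24Q1.txt").write_text(
        "primaryid$caseid$outc_cod\n1001$500$HO\n1001$500$DE\n1002$501$OT\n"
    )
    (tmp_path / "THER24Q1.txt").write_text(
        "primaryid$caseid$dsg_drug_seq$start_dt$end_dt\n1001$500$1$20190201$\n"
    )
    return tmp_path


def test_faers_ascii_fixture_loads(tmp_path):
    rs = load_reports(_write_faers(tmp_path), "faers_ascii")
    rec = {r.report_id: r for r in rs}
    assert len(rs) == 2
    assert rec["1001"].is_serious and not rec["1002"].is_serious
    assert rec["1001"].pt_terms == {"rash", "pyrexia"}
    vem = next(d for d in rec["1001"].drugs if d.drug_name == "vemurafenib")
    assert vem.regimen_start.to_date() == dt.date(2019, 2, 1)
    assert vem.dechallenge == "positive"
    assert rec["1002"].age == pytest.approx(60.0)  # 720 months


def test_faers_ascii_unknown_role_is_validation_error(tmp_path):
    with pytest.raises(ValidationError, match="1001"):
        load_reports(_write_faers(tmp_path, drug_role="X"), "faers_ascii")


# ---------------------------------------------------------------------------
# Deduplication

def test_higher_case_version_survives():
    rs = report_set(
        make_record("R1", case_id="C1", case_version=1),
        make_record("R2", case_id="C1", case_version=2),
    )
    out = deduplicate(rs)
    assert [r.report_id for r in out] == ["R2"]


def test_deduplicate_is_idempotent_and_identity_on_clean_sets():
    rs = report_set(make_record("R1", case_id="C1"),
                    make_record("R2", case_id="C2"))
    once = deduplicate(rs)
    twice = deduplicate(once)
    assert once.records == rs.records
    assert twice.records == once.records


def test_dedup_tie_breaks_by_receipt_then_report_id():
    # 5 records over 3 cases; oracle = exhaustive sort by the stated key
    records = [
        make_record("A1", case_id="CA", case_version=1, receipt="2018-01-05"),
        make_record("A2", case_id="CA", case_version=2, receipt="2018-01-01"),
        make_record("B1", case_id="CB", case_version=1),
        make_record("C1", case_id="CC", case_version=3, receipt="2018-01"),
        make_record("C2", case_id="CC", case_version=3, receipt="2018-03"),
    ]

    def oracle(recs):
        survivors = {}
        for case in {r.case_id for r in recs}:
            group = [r for r in recs if r.case_id == case]
            group.sort(key=lambda r: (r.case_version,
                                      r.receipt_date.sort_key(),
                                      r.report_id))
            survivors[case] = group[-1].report_id
        return set(survivors.values())

    out = deduplicate(report_set(*records))
    assert {r.report_id for r in out} == oracle(records) == {"A2", "B1", "C2"}


@given(st.lists(
    st.tuples(st.integers(1, 3), st.integers(1, 4),
              st.sampled_from(["2018-01-01", "2018-03-01", "2018-03"])),
    min_size=1, max_size=12))
def test_dedup_idempotence_property(spec):
    records = [
        make_record(f"R{i}", case_id=f"C{case}", case_version=version,
                    receipt=receipt)
        for i, (case, version, receipt) in enumerate(spec)
    ]
    once = deduplicate(report_set(*records))
    assert deduplicate(once).records == once.records
    assert {r.case_id for r in once} == {r.case_id for r in records}


# ---------------------------------------------------------------------------
# Filtering

def test_no_active_criteria_is_identity():
    rs = report_set(make_record("R1"), make_record("R2"))
    assert filter_reports(rs, FilterSpec()).records == rs.records


def test_seriousness_filter_uses_outcome_definition():
    rs = report_set(
        make_record("R1", outcomes=("other",)),
        make_record("R2", outcomes=("life_threatening",)),
        make_record("R3", outcomes=("death", "other")),
    )
    out = filter_reports(rs, FilterSpec(serious_only=True))
    assert {r.report_id for r in out} == {"R2", "R3"}


def test_window_filter_counts_removals(window_2018_2019):
    records = (
        [make_record(f"R{i}", receipt="2017-06-01") for i in range(2)]
        + [make_record(f"S{i}", receipt="2019-06-01") for i in range(8)]
    )
    out = filter_reports(report_set(*records),
                         FilterSpec(window=window_2018_2019))
    assert len(out) == 8
    assert out.provenance[-1]["removed"]["window"] == 2


def test_window_start_after_end_is_argument_error():
    rs = report_set(make_record("R1"))
    with pytest.raises(ArgumentError):
        filter_reports(rs, FilterSpec(
            window=(dt.date(2019, 1, 1), dt.date(2018, 1, 1))))


def test_excluded_terms_remove_reactions_then_empty_records(hierarchy):
    rs = report_set(
        make_record("R1", reactions=[ReactionEntry("off-label use")]),
        make_record("R2", reactions=[ReactionEntry("off-label use"),
                                     ReactionEntry("rash")]),
    )
    out = filter_reports(rs, FilterSpec(excluded_terms=("Off-Label Use",)))
    assert {r.report_id for r in out} == {"R2"}
    assert out.records[0].pt_terms == {"rash"}


def test_excluded_category_resolves_through_hierarchy(hierarchy):
    rs = report_set(
        make_record("R1", reactions=[ReactionEntry("death")]),
        make_record("R2", reactions=[ReactionEntry("rash")]),
    )
    out = filter_reports(
        rs, FilterSpec(excluded_categories=(("fatal outcomes", "HLGT"),)),
        hierarchy=hierarchy)
    assert {r.report_id for r in out} == {"R2"}


def test_filter_conservation_and_order_independence(window_2018_2019):
    records = [
        make_record("R1", receipt="2017-01-01"),
        make_record("R2", outcomes=("other",)),
        make_record("R3", reactions=[ReactionEntry("off-label use")]),
        make_record("R4"),
        make_record("R5", receipt="2016-01-01", outcomes=("other",)),
    ]
    rs = report_set(*records)
    spec_full = FilterSpec(window=window_2018_2019, serious_only=True,
                           excluded_terms=("off-label use",))
    combined = filter_reports(rs, spec_full)
    removed = combined.provenance[-1]["removed"]
    assert len(rs) == len(combined) + sum(removed.values())

    # applying single-criterion filters in any order gives the same survivors
    singles = [FilterSpec(window=window_2018_2019),
               FilterSpec(serious_only=True),
               FilterSpec(excluded_terms=("off-label use",))]
    for perm in itertools.permutations(singles):
        cur = rs
        for f in perm:
            cur = filter_reports(cur, f)
        assert {r.report_id for r in cur} == {r.report_id for r in combined}


# ---------------------------------------------------------------------------
# Combination selection

@pytest.mark.parametrize("role_b, included", [
    ("secondary_suspect", True),
    ("concomitant", False),
])
def test_combination_requires_both_suspect_roles(role_b, included):
    rec = make_record("R1", drugs=[
        DrugEntry("vemurafenib", "primary_suspect"),
        DrugEntry("cobimetinib", role_b),
    ])
    out = select_combination(report_set(rec), "vemurafenib", "cobimetinib")
    assert (len(out) == 1) is included


def test_combination_selection_fixture_counts():
    def rec(i, roles):
        return make_record(f"R{i}", drugs=[
            DrugEntry("encorafenib", roles[0]),
            DrugEntry("binimetinib", roles[1]),
        ])

    rs = report_set(
        rec(1, ("primary_suspect", "secondary_suspect")),
        rec(2, ("secondary_suspect", "primary_suspect")),
        rec(3, ("primary_suspect", "primary_suspect")),
        rec(4, ("secondary_suspect", "secondary_suspect")),
        rec(5, ("primary_suspect", "concomitant")),
        rec(6, ("interacting", "secondary_suspect")),
    )
    out = select_combination(rs, "encorafenib", "binimetinib")
    assert {r.report_id for r in out} == {"R1", "R2", "R3", "R4"}
    # symmetric in the drug arguments
    swapped = select_combination(rs, "binimetinib", "encorafenib")
    assert swapped.records == out.records
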