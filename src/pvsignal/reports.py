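"""Spontaneous adverse-event report model: loading, validation, filtering.

Two input dialects are supported:

* a normalized TSV with one row per report x drug x reaction link,
  report-level fields repeated on every row; and
* the public FAERS quarterly ASCII layout — ``$``-delimited DEMO / DRUG /
  REAC / OUTC / THER (and optionally INDI) files keyed by ``primaryid``.

A report is *serious* when at least one of its outcomes is death,
life-threatening, hospitalization, or disability. Deduplication follows
the FAERS convention: one surviving record per case, the highest case
version winning, ties broken by latest receipt date and then report id.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._text import normalize_term
from .dates import PartialDate
from .errors import ArgumentError, SchemaError, ValidationError

# ---------------------------------------------------------------------------
# Coded vocabularies

ROLE_CODES = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interacting",
}
SUSPECT_ROLES = frozenset({"primary_suspect", "secondary_suspect"})

OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "OT": "other",
    # FAERS codes folded into 'other': congenital anomaly, required
    # intervention — neither appears in the seriousness definition used here.
    "CA": "other",
    "RI": "other",
}
SERIOUS_OUTCOMES = frozenset(
    {"death", "life_threatening", "hospitalization", "disability"}
)
_OUTCOME_TO_CODE = {
    "death": "DE", "life_threatening": "LT", "hospitalization": "HO",
    "disability": "DS", "other": "OT",
}

CHALLENGE_CODES = {
    "Y": "positive",
    "N": "negative",
    "D": "not_applicable",
    "U": "unreported",
    "": "unreported",
}
_CHALLENGE_TO_CODE = {v: k for k, v in CHALLENGE_CODES.items() if k}

SEXES = {"F": "female", "M": "male", "UNK": "unreported", "": "unreported"}


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True, slots=True)
class ReactionEntry:
    """One reported reaction (MedDRA preferred term) with optional onset."""

    pt_term: str
    onset_date: PartialDate | None = None


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug on a report, with its reporter-assigned causal role."""

    drug_name: str
    role: str
    dose_value: float | None = None
    dose_unit: str | None = None
    regimen_start: PartialDate | None = None
    regimen_end: PartialDate | None = None
    indication: str | None = None
    dechallenge: str = "unreported"
    rechallenge: str = "unreported"

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES.values():
            raise ValidationError(f"unknown drug role: {self.role!r}")
        if (
            self.regimen_start is not None
            and self.regimen_end is not None
            and self.regimen_start.is_complete
            and self.regimen_end.is_complete
            and self.regimen_end.to_date() < self.regimen_start.to_date()
        ):
            raise ValidationError(
                f"regimen end {self.regimen_end.isoformat()} precedes start"
            )


@dataclass(frozen=True, slots=True)
class ReportRecord:
    """One deduplicated safety report."""

    report_id: str
    case_id: str
    case_version: int
    receipt_date: PartialDate | None
    age: float | None
    sex: str
    country: str | None
    outcomes: frozenset[str]
    drugs: tuple[DrugEntry, ...]
    reactions: tuple[ReactionEntry, ...]

    def __post_init__(self) -> None:
        if self.case_version < 1:
            raise ValidationError(
                f"case_version must be >= 1 (report {self.report_id})"
            )
        if not self.drugs:
            raise ValidationError(f"report {self.report_id} has no drugs")
        if not self.reactions:
            raise ValidationError(f"report {self.report_id} has no reactions")
        bad = self.outcomes - set(_OUTCOME_TO_CODE)
        if bad:
            raise ValidationError(
                f"unknown outcome codes {sorted(bad)} (report {self.report_id})"
            )

    @property
    def is_serious(self) -> bool:
        return bool(self.outcomes & SERIOUS_OUTCOMES)

    @property
    def pt_terms(self) -> frozenset[str]:
        return frozenset(r.pt_term for r in self.reactions)

    def suspect_drugs(self) -> frozenset[str]:
        return frozenset(
            d.drug_name for d in self.drugs if d.role in SUSPECT_ROLES
        )


@dataclass
class ReportSet:
    """An ordered collection of reports plus an append-only provenance log."""

    records: list[ReportRecord] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def report_ids(self) -> set[str]:
        return {r.report_id for r in self.records}

    def log(self, **entry) -> None:
        self.provenance.append(entry)

    def derived(self, records: Iterable[ReportRecord], **entry) -> "ReportSet":
        """New ReportSet with inherited provenance plus one log entry."""
        out = ReportSet(list(records), list(self.provenance))
        out.log(**entry)
        return out


# ---------------------------------------------------------------------------
# TSV dialect

TSV_COLUMNS = [
    "report_id", "case_id", "case_version", "receipt_date", "age", "sex",
    "country", "outcomes", "drug_name", "drug_role", "dose_value",
    "dose_unit", "regimen_start", "regimen_end", "indication",
    "dechallenge", "rechallenge", "pt_term", "onset_date",
]


def _parse_outcomes(cell: str, report_id: str) -> frozenset[str]:
    out = set()
    for code in cell.split(";"):
        code = code.strip().upper()
        if not code:
            continue
        if code not in OUTCOME_CODES:
            raise ValidationError(
                f"unknown outcome code {code!r} in report {report_id}"
            )
        out.add(OUTCOME_CODES[code])
    return frozenset(out)


def _parse_float(cell: str) -> float | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        value = float(cell)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


def _load_tsv(path: Path) -> ReportSet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    malformed = 0
    order: list[str] = []
    header: dict[str, dict] = {}
    drugs: dict[str, dict[tuple, DrugEntry]] = {}
    reactions: dict[str, dict[str, ReactionEntry]] = {}

    for row in df.itertuples(index=False):
        rid = row.report_id.strip()
        pt = normalize_term(row.pt_term)
        if not rid or not row.case_id.strip() or not pt:
            malformed += 1
            continue
        role_code = row.drug_role.strip().upper()
        if role_code not in ROLE_CODES:
            raise ValidationError(
                f"unknown drug role code {row.drug_role!r} in report {rid}"
            )
        if rid not in header:
            order.append(rid)
            try:
                version = int(row.case_version) if row.case_version.strip() else 1
            except ValueError as exc:
                raise ValidationError(
                    f"non-integer case_version in report {rid}"
                ) from exc
            header[rid] = {
                "case_id": row.case_id.strip(),
                "case_version": version,
                "receipt_date": PartialDate.parse(row.receipt_date),
                "age": _parse_float(row.age),
                "sex": SEXES.get(row.sex.strip().upper(), "unreported"),
                "country": row.country.strip() or None,
                "outcomes": _parse_outcomes(row.outcomes, rid),
            }
            drugs[rid] = {}
            reactions[rid] = {}

        entry = DrugEntry(
            drug_name=normalize_term(row.drug_name),
            role=ROLE_CODES[role_code],
            dose_value=_parse_float(row.dose_value),
            dose_unit=row.dose_unit.strip().lower() or None,
            regimen_start=PartialDate.parse(row.regimen_start),
            regimen_end=PartialDate.parse(row.regimen_end),
            indication=row.indication.strip() or None,
            dechallenge=CHALLENGE_CODES.get(
                row.dechallenge.strip().upper(), "unreported"
            ),
            rechallenge=CHALLENGE_CODES.get(
                row.rechallenge.strip().upper(), "unreported"
            ),
        )
        key = (entry.drug_name, entry.role, entry.dose_value, entry.dose_unit)
        drugs[rid].setdefault(key, entry)
        if pt not in reactions[rid]:
            reactions[rid][pt] = ReactionEntry(pt, PartialDate.parse(row.onset_date))

    records = [
        ReportRecord(
            report_id=rid,
            drugs=tuple(drugs[rid].values()),
            reactions=tuple(reactions[rid].values()),
            **header[rid],
        )
        for rid in order
    ]
    rs = ReportSet(records)
    rs.log(action="load", dialect="tsv", source=str(path),
           n_records=len(records), n_malformed_rows=malformed)
    return rs


# ---------------------------------------------------------------------------
# FAERS quarterly ASCII dialect

_FAERS_AGE_FACTORS = {
    "YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25, "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0,
}


def _faers_file(directory: Path, prefix: str, required: bool = True) -> pd.DataFrame | None:
    hits = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.name.upper().startswith(prefix)
    )
    if not hits:
        if required:
            raise SchemaError(f"no {prefix}* file found in {directory}")
        return None
    df = pd.read_csv(hits[0], sep="$", dtype=str, keep_default_na=False,
                     engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "primaryid" not in df.columns:
        raise SchemaError(f"missing mandatory column(s): primaryid ({hits[0].name})")
    return df


def _faers_age(value: str, code: str) -> float | None:
    v = _parse_float(value)
    if v is None:
        return None
    factor = _FAERS_AGE_FACTORS.get(code.strip().upper(), 1.0)
    age = v * factor
    return age if age >= 0 else None


def _load_faers_ascii(path: Path) -> ReportSet:
    if not path.is_dir():
        raise SchemaError(f"faers_ascii path must be a directory: {path}")
    demo = _faers_file(path, "DEMO")
    drug = _faers_file(path, "DRUG")
    reac = _faers_file(path, "REAC")
    outc = _faers_file(path, "OUTC", required=False)
    ther = _faers_file(path, "THER", required=False)
    indi = _faers_file(path, "INDI", required=False)

    for name, frame, col in (("DEMO", demo, "caseid"), ("DRUG", drug, "drugname"),
                             ("REAC", reac, "pt")):
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column(s): {col} ({name})")

    outcomes: dict[str, set[str]] = {}
    if outc is not None and "outc_cod" in outc.columns:
        for row in outc.itertuples(index=False):
            code = row.outc_cod.strip().upper()
            if code in OUTCOME_CODES:
                outcomes.setdefault(row.primaryid, set()).add(OUTCOME_CODES[code])

    starts: dict[tuple[str, str], PartialDate] = {}
    ends: dict[tuple[str, str], PartialDate] = {}
    if ther is not None:
        seq_col = "dsg_drug_seq" if "dsg_drug_seq" in ther.columns else "drug_seq"
        for row in ther.itertuples(index=False):
            key = (row.primaryid, getattr(row, seq_col))
            if "start_dt" in ther.columns and row.start_dt.strip():
                starts.setdefault(key, PartialDate.parse(row.start_dt))
            if "end_dt" in ther.columns and row.end_dt.strip():
                ends.setdefault(key, PartialDate.parse(row.end_dt))

    indications: dict[tuple[str, str], str] = {}
    if indi is not None and "indi_pt" in indi.columns:
        seq_col = "indi_drug_seq" if "indi_drug_seq" in indi.columns else "drug_seq"
        for row in indi.itertuples(index=False):
            indications.setdefault(
                (row.primaryid, getattr(row, seq_col)),
                normalize_term(row.indi_pt),
            )

    drug_entries: dict[str, list[DrugEntry]] = {}
    for row in drug.itertuples(index=False):
        pid = row.primaryid
        role_code = getattr(row, "role_cod", "").strip().upper()
        if role_code not in ROLE_CODES:
            raise ValidationError(
                f"unknown drug role code {role_code!r} in report {pid}"
            )
        seq = getattr(row, "drug_seq", "")
        drug_entries.setdefault(pid, []).append(DrugEntry(
            drug_name=normalize_term(row.drugname),
            role=ROLE_CODES[role_code],
            dose_value=_parse_float(getattr(row, "dose_amt", "")),
            dose_unit=(getattr(row, "dose_unit", "").strip().lower() or None),
            regimen_start=starts.get((pid, seq)),
            regimen_end=ends.get((pid, seq)),
            indication=indications.get((pid, seq)),
            dechallenge=CHALLENGE_CODES.get(
                getattr(row, "dechal", "").strip().upper(), "unreported"),
            rechallenge=CHALLENGE_CODES.get(
                getattr(row, "rechal", "").strip().upper(), "unreported"),
        ))

    reaction_entries: dict[str, dict[str, ReactionEntry]] = {}
    for row in reac.itertuples(index=False):
        pt = normalize_term(row.pt)
        if not pt:
            continue
        bucket = reaction_entries.setdefault(row.primaryid, {})
        if pt not in bucket:
            onset = getattr(row, "event_dt", "").strip()
            bucket[pt] = ReactionEntry(
                pt, PartialDate.parse(onset) if onset else None
            )

    malformed = 0
    records = []
    for row in demo.itertuples(index=False):
        pid = row.primaryid.strip()
        if not pid or pid not in drug_entries or pid not in reaction_entries:
            malformed += 1
            continue
        version = getattr(row, "caseversion", "1").strip() or "1"
        receipt = getattr(row, "fda_dt", "").strip()
        records.append(ReportRecord(
            report_id=pid,
            case_id=row.caseid.strip(),
            case_version=int(version),
            receipt_date=PartialDate.parse(receipt) if receipt else None,
            age=_faers_age(getattr(row, "age", ""), getattr(row, "age_cod", "")),
            sex=SEXES.get(getattr(row, "sex", "").strip().upper(), "unreported"),
            country=getattr(row, "occr_country", "").strip() or None,
            outcomes=frozenset(outcomes.get(pid, set())),
            drugs=tuple(drug_entries[pid]),
            reactions=tuple(reaction_entries[pid].values()),
        ))
    rs = ReportSet(records)
    rs.log(action="load", dialect="faers_ascii", source=str(path),
           n_records=len(records), n_malformed_rows=malformed)
    return rs


def load_reports(path: str | Path, dialect: str = "tsv") -> ReportSet:
    """Load a report set from ``path`` in the given dialect.

    ``dialect`` is ``"tsv"`` (normalized one-row-per-link file) or
    ``"faers_ascii"`` (directory holding ``$``-delimited quarterly files).
    Malformed rows are counted in the provenance log, never silently
    dropped without trace; partial dates are preserved as partial.
    """
    path = Path(path)
    if not path.exists():
        raise ArgumentError(f"input path does not exist: {path}")
    if dialect == "tsv":
        return _load_tsv(path)
    if dialect == "faers_ascii":
        return _load_faers_ascii(path)
    raise ArgumentError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Writing the TSV dialect (round-trips through load_reports)

def write_tsv(rs: ReportSet, path: str | Path) -> None:
    """Write a ReportSet in the normalized TSV dialect (deterministic bytes)."""
    rows = []
    for rec in rs:
        common = {
            "report_id": rec.report_id,
            "case_id": rec.case_id,
            "case_version": rec.case_version,
            "receipt_date": rec.receipt_date.isoformat() if rec.receipt_date else "",
            "age": "" if rec.age is None else f"{rec.age:g}",
            "sex": {"female": "F", "male": "M"}.get(rec.sex, "UNK"),
            "country": rec.country or "",
            "outcomes": ";".join(sorted(_OUTCOME_TO_CODE[o] for o in rec.outcomes)),
        }
        for d in rec.drugs:
            for r in rec.reactions:
                rows.append({
                    **common,
                    "drug_name": d.drug_name,
                    "drug_role": {v: k for k, v in ROLE_CODES.items()}[d.role],
                    "dose_value": "" if d.dose_value is None else f"{d.dose_value:g}",
                    "dose_unit": d.dose_unit or "",
                    "regimen_start": d.regimen_start.isoformat() if d.regimen_start else "",
                    "regimen_end": d.regimen_end.isoformat() if d.regimen_end else "",
                    "indication": d.indication or "",
                    "dechallenge": _CHALLENGE_TO_CODE[d.dechallenge],
                    "rechallenge": _CHALLENGE_TO_CODE[d.rechallenge],
                    "pt_term": r.pt_term,
                    "onset_date": r.onset_date.isoformat() if r.onset_date else "",
                })
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Deduplication

def _dedup_key(rec: ReportRecord) -> tuple:
    receipt = rec.receipt_date.sort_key() if rec.receipt_date else (0, 0, 0)
    return (rec.case_version, receipt, rec.report_id)


def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep one record per case: highest case version, ties broken by
    latest receipt date, then lexicographically largest report id.

    Idempotent; original record order is preserved among survivors.
    """
    best: dict[str, ReportRecord] = {}
    for rec in rs:
        cur = best.get(rec.case_id)
        if cur is None or _dedup_key(rec) > _dedup_key(cur):
            best[rec.case_id] = rec
    keep = {id(rec) for rec in best.values()}
    survivors = [rec for rec in rs if id(rec) in keep]
    return rs.derived(
        survivors, action="deduplicate",
        n_removed=len(rs) - len(survivors), n_records=len(survivors),
    )


# ---------------------------------------------------------------------------
# Filtering

@dataclass(frozen=True)
class FilterSpec:
    """Criteria for :func:`filter_reports`; inactive criteria are ``None``/empty.

    ``excluded_terms`` are exact preferred terms (normalized before
    comparison). ``excluded_categories`` are ``(term, level)`` pairs resolved
    through a term hierarchy to the preferred terms beneath them.
    """

    window: tuple[dt.date, dt.date] | None = None
    serious_only: bool = False
    excluded_terms: Sequence[str] = ()
    excluded_categories: Sequence[tuple[str, str]] = ()


def filter_reports(rs: ReportSet, criteria: FilterSpec, hierarchy=None) -> ReportSet:
    """Apply all active criteria; a record survives iff it passes every one.

    Reactions matching excluded terms/categories are removed from surviving
    records; a record with no remaining reactions is dropped. Removal counts
    per criterion are appended to the provenance log. Records without a
    receipt date fail an active window criterion (their period is unknown).
    """
    if criteria.window is not None and criteria.window[0] > criteria.window[1]:
        raise ArgumentError("filter window start is after its end")

    excluded = {normalize_term(t) for t in criteria.excluded_terms}
    for term, level in criteria.excluded_categories:
        if hierarchy is None:
            raise ArgumentError(
                "excluded_categories requires a term hierarchy"
            )
        excluded |= hierarchy.descendant_pts(normalize_term(term), level)

    removed = {"window": 0, "seriousness": 0, "excluded_terms": 0}
    survivors: list[ReportRecord] = []
    for rec in rs:
        if criteria.window is not None:
            start, end = criteria.window
            if rec.receipt_date is None or not rec.receipt_date.in_window(start, end):
                removed["window"] += 1
                continue
        if criteria.serious_only and not rec.is_serious:
            removed["seriousness"] += 1
            continue
        if excluded:
            kept = tuple(r for r in rec.reactions if r.pt_term not in excluded)
            if not kept:
                removed["excluded_terms"] += 1
                continue
            if len(kept) != len(rec.reactions):
                rec = replace(rec, reactions=kept)
        survivors.append(rec)

    return rs.derived(
        survivors, action="filter", removed=removed, n_records=len(survivors),
    )


def select_combination(rs: ReportSet, drug_a: str, drug_b: str) -> ReportSet:
    """Reports naming both drugs with primary- or secondary-suspect roles."""
    a, b = normalize_term(drug_a), normalize_term(drug_b)
    survivors = [
        rec for rec in rs
        if {a, b} <= rec.suspect_drugs()
    ]
    return rs.derived(
        survivors, action="select_combination", drugs=sorted((a, b)),
        n_records=len(survivors),
    )
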