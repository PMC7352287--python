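"""2x2 contingency tables for drug-event pairs, crude and age-stratified.

Two analysis scopes are supported:

* ``full_database`` — case/non-case: the exposure group's reports versus
  every other report in the database (the exposure group is a subset of
  the background set);
* ``between_regimens`` — one drug combination's reports versus the other
  combinations' reports (disjoint sets).

Counting is always by distinct report: a report with several preferred
terms under the same analysis term contributes one to the cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

from ._text import normalize_term
from .errors import ArgumentError, TermLookupError
from .hierarchy import EventCounts, TermHierarchy
from .reports import ReportRecord, ReportSet

SCOPES = ("full_database", "between_regimens")


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Cells of the 2x2: exposed/unexposed x event/no-event."""

    n11: int  # exposed, with event
    n10: int  # exposed, without event
    n01: int  # unexposed, with event
    n00: int  # unexposed, without event

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ArgumentError("contingency cells must be nonnegative")
        if self.n == 0:
            raise ArgumentError("contingency table is empty")

    @property
    def n1_(self) -> int:
        """Exposed margin."""
        return self.n11 + self.n10

    @property
    def n_1(self) -> int:
        """Event margin."""
        return self.n11 + self.n01

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def swapped(self) -> "ContingencyTable":
        """Exposure groups exchanged."""
        return ContingencyTable(self.n01, self.n00, self.n11, self.n10)

    def cells(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n10, self.n01, self.n00)


@dataclass
class StratifiedTable:
    """Age-stratified 2x2 tables; strata are disjoint age intervals."""

    strata: list[tuple[str, ContingencyTable]]
    bins: tuple[float, ...]
    n_missing_age: int = 0
    skipped_strata: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.strata)

    def tables(self) -> list[ContingencyTable]:
        return [t for _, t in self.strata]

    def crude(self) -> ContingencyTable:
        """Cellwise sum over strata (the age-known crude table)."""
        cells = [0, 0, 0, 0]
        for _, t in self.strata:
            for i, c in enumerate(t.cells()):
                cells[i] += c
        return ContingencyTable(*cells)


# ---------------------------------------------------------------------------

def _event_pts(h: TermHierarchy, term: str, level: str) -> frozenset[str]:
    term = normalize_term(term)
    if not h.has_term(term, level):
        raise TermLookupError(f"unknown {level} term: {term!r}")
    return frozenset(h.descendant_pts(term, level))


def report_has_event(rec: ReportRecord, pts: frozenset[str]) -> bool:
    return not rec.pt_terms.isdisjoint(pts)


def _split_unexposed(cases: ReportSet, background: ReportSet,
                     scope: str) -> list[ReportRecord]:
    if scope not in SCOPES:
        raise ArgumentError(f"unknown scope: {scope!r}")
    if scope == "between_regimens":
        overlap = cases.report_ids() & background.report_ids()
        if overlap:
            raise ArgumentError(
                f"between-regimen scope requires disjoint sets; "
                f"{len(overlap)} overlapping report(s)"
            )
        return list(background)
    case_ids = cases.report_ids()
    missing = case_ids - background.report_ids()
    if missing:
        raise ArgumentError(
            f"full-database scope requires cases within background; "
            f"{len(missing)} case report(s) missing"
        )
    return [r for r in background if r.report_id not in case_ids]


def build_table(cases: ReportSet, background: ReportSet,
                event: tuple[str, str], h: TermHierarchy,
                scope: str = "between_regimens") -> ContingencyTable:
    """Build the 2x2 for one (exposure, event) pair by distinct-report counts.

    ``event`` is a ``(term, level)`` pair; a report carries the event when
    any of its preferred terms rolls up to ``term`` at ``level``.
    """
    if len(cases) == 0:
        raise ArgumentError("empty exposure group")
    term, level = event
    pts = _event_pts(h, term, level)
    unexposed = _split_unexposed(cases, background, scope)

    n11 = sum(1 for r in cases if report_has_event(r, pts))
    n01 = sum(1 for r in unexposed if report_has_event(r, pts))
    return ContingencyTable(n11, len(cases) - n11, n01, len(unexposed) - n01)


def build_tables(cases: ReportSet, background: ReportSet, level: str,
                 h: TermHierarchy, scope: str = "between_regimens",
                 terms: Iterable[str] | None = None,
                 ) -> dict[str, ContingencyTable]:
    """Build the 2x2 for every term at ``level`` in one pass over reports.

    Equivalent to calling :func:`build_table` per term, but each report's
    reactions are rolled up once. ``terms`` restricts the output (unknown
    terms raise); by default every level term observed in either group is
    returned.
    """
    if len(cases) == 0:
        raise ArgumentError("empty exposure group")
    unexposed = _split_unexposed(cases, background, scope)
    if terms is not None:
        terms = [normalize_term(t) for t in terms]
        for t in terms:
            if not h.has_term(t, level):
                raise TermLookupError(f"unknown {level} term: {t!r}")

    def tally(records) -> tuple[int, dict[str, int]]:
        counts: dict[str, int] = {}
        for rec in records:
            rolled = {h.map_pt(pt, level) for pt in rec.pt_terms}
            rolled.discard(None)
            for t in rolled:
                counts[t] = counts.get(t, 0) + 1
        return len(records), counts

    n_cases, case_counts = tally(list(cases))
    n_unexp, unexp_counts = tally(unexposed)
    if terms is None:
        terms = sorted(set(case_counts) | set(unexp_counts))
    return {
        t: ContingencyTable(
            case_counts.get(t, 0), n_cases - case_counts.get(t, 0),
            unexp_counts.get(t, 0), n_unexp - unexp_counts.get(t, 0),
        )
        for t in terms
    }


def stratify_by_age(cases: ReportSet, background: ReportSet,
                    event: tuple[str, str], h: TermHierarchy,
                    bins: tuple[float, ...],
                    scope: str = "between_regimens") -> StratifiedTable:
    """Age-stratified 2x2 tables over intervals ``[b0,b1), ..., [bk, inf)``.

    ``bins`` are strictly increasing cut-points; records with missing age
    are excluded from all strata and counted. Strata containing no records
    are skipped (and listed), so the remaining strata sum cellwise to the
    crude table over age-known records.
    """
    if not bins:
        raise ArgumentError("empty age bins")
    bins = tuple(float(b) for b in bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ArgumentError("age bins must be strictly increasing")
    if len(cases) == 0:
        raise ArgumentError("empty exposure group")
    term, level = event
    pts = _event_pts(h, term, level)
    unexposed = _split_unexposed(cases, background, scope)

    edges = bins + (math.inf,)
    labels = [
        f"[{lo:g},{hi:g})" if math.isfinite(hi) else f"[{lo:g},inf)"
        for lo, hi in zip(edges, edges[1:])
    ]

    def stratum_of(age: float) -> int | None:
        if age < edges[0]:
            return None
        for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
            if lo <= age < hi:
                return k
        return None

    n_missing = 0
    cells = [[0, 0, 0, 0] for _ in labels]
    for exposed, group in ((True, cases), (False, unexposed)):
        for rec in group:
            if rec.age is None:
                n_missing += 1
                continue
            k = stratum_of(rec.age)
            if k is None:
                n_missing += 1
                continue
            has = report_has_event(rec, pts)
            idx = (0 if has else 1) if exposed else (2 if has else 3)
            cells[k][idx] += 1

    strata: list[tuple[str, ContingencyTable]] = []
    skipped: list[str] = []
    for label, c in zip(labels, cells):
        if sum(c) == 0:
            skipped.append(label)
        else:
            strata.append((label, ContingencyTable(*c)))
    if not strata:
        warnings.warn("no records with usable age; stratified table is empty",
                      stacklevel=2)
    return StratifiedTable(strata, bins, n_missing, skipped)


def min_report_filter(counts: EventCounts, fraction: float) -> set[str]:
    """Terms reported at least ``ceil(fraction * group total)`` times in at
    least one exposure group.

    With the conventional fraction 0.005 and a group of 965 reports, the
    threshold is 5 reports.
    """
    if not 0 < fraction < 1:
        raise ArgumentError("fraction must be in (0, 1)")
    retained: set[str] = set()
    for group, total in counts.totals.items():
        threshold = math.ceil(fraction * total)
        for term, c in counts.counts.get(group, {}).items():
            if c >= threshold:
                retained.add(term)
    return retained
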