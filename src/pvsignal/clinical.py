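"""Clinical characterization of flagged adverse events.

Descriptive summaries of the reports behind a signal: dose category
relative to the recommended daily dose of the combination, time from the
earliest suspect-drug start to reaction onset, dechallenge/rechallenge
response, and outcome tabulations. Percentages are rounded half away from
zero, matching the printing convention of regulatory safety tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from ._text import normalize_term
from .errors import ArgumentError, UnitError
from .hierarchy import TermHierarchy
from .reports import DrugEntry, ReportRecord, ReportSet, SUSPECT_ROLES
from .contingency import _event_pts, report_has_event


# ---------------------------------------------------------------------------
# Dose categories

@dataclass(frozen=True)
class DoseRecommendation:
    """Recommended total daily dose for one drug."""

    drug_name: str
    value: float
    unit: str = "mg"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ArgumentError("recommended dose must be positive")


#: Recommended daily doses of the three BRAF+MEK inhibitor combinations.
DEFAULT_RECOMMENDATIONS: dict[str, DoseRecommendation] = {
    d.drug_name: d
    for d in (
        DoseRecommendation("vemurafenib", 960.0),
        DoseRecommendation("cobimetinib", 60.0),
        DoseRecommendation("dabrafenib", 150.0),
        DoseRecommendation("trametinib", 2.0),
        DoseRecommendation("encorafenib", 450.0),
        DoseRecommendation("binimetinib", 45.0),
    )
}

_UNIT_TO_MG = {"mg": 1.0, "g": 1000.0, "mcg": 0.001, "ug": 0.001}

DOSE_CATEGORIES = ("below", "at_recommended", "above", "unreported")


def _dose_in(entry: DrugEntry, unit: str) -> float | None:
    if entry.dose_value is None:
        return None
    entry_unit = (entry.dose_unit or unit).lower()
    if entry_unit == unit:
        return entry.dose_value
    if entry_unit in _UNIT_TO_MG and unit in _UNIT_TO_MG:
        return entry.dose_value * _UNIT_TO_MG[entry_unit] / _UNIT_TO_MG[unit]
    raise UnitError(
        f"cannot convert dose unit {entry_unit!r} to {unit!r} "
        f"for {entry.drug_name}"
    )


def dose_category(entries: Sequence[DrugEntry],
                  recs: Sequence[DoseRecommendation]) -> str:
    """Joint dose category of a drug combination.

    ``at_recommended`` when every drug is at its recommended dose;
    ``below`` when all are at or below with at least one strictly below;
    ``above`` when any is strictly above; ``unreported`` when any dose is
    missing.
    """
    if len(entries) != len(recs):
        raise ArgumentError("one recommendation per drug entry required")
    ratios = []
    for entry, rec in zip(entries, recs):
        dose = _dose_in(entry, rec.unit)
        if dose is None:
            return "unreported"
        ratios.append(dose / rec.value)
    if any(r > 1 + 1e-9 for r in ratios):
        return "above"
    if all(abs(r - 1) <= 1e-9 for r in ratios):
        return "at_recommended"
    return "below"


# ---------------------------------------------------------------------------
# Time to onset

def time_to_onset(report: ReportRecord, drugs: Sequence[str],
                  event: tuple[str, str], h: TermHierarchy) -> int | None:
    """Days from the earliest complete suspect-drug start to the earliest
    complete onset of a reaction matching ``event``.

    Same-day onset is 0. Partial dates and negative differences yield
    ``None`` — the interval is unknown, never fabricated.
    """
    names = {normalize_term(d) for d in drugs}
    pts = _event_pts(h, *event)
    starts = [
        d.regimen_start.to_date()
        for d in report.drugs
        if d.drug_name in names and d.role in SUSPECT_ROLES
        and d.regimen_start is not None and d.regimen_start.is_complete
    ]
    onsets = [
        r.onset_date.to_date()
        for r in report.reactions
        if r.pt_term in pts
        and r.onset_date is not None and r.onset_date.is_complete
    ]
    if not starts or not onsets:
        return None
    days = (min(onsets) - min(starts)).days
    return days if days >= 0 else None


@dataclass(frozen=True)
class OnsetSummary:
    """Median and interquartile range of time-to-onset, in days."""

    median: float
    q1: float
    q3: float
    n: int


def summarize_onset(values: Sequence[float]) -> OnsetSummary | None:
    """Median/quartiles by linear interpolation; ``None`` on empty input."""
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return OnsetSummary(float(med), float(q1), float(q3), len(vals))


# ---------------------------------------------------------------------------
# Outcome tabulation

@dataclass
class OutcomeTable:
    """Counts for one event group within one regimen's reports.

    Outcome categories are not mutually exclusive — a report may appear
    in several rows, so percentages can sum above 100.
    """

    n_reports: int
    outcomes: dict[str, int] = field(default_factory=dict)
    dechallenge_positive: int = 0
    dechallenge_assessed: int = 0
    rechallenge_positive: int = 0
    rechallenge_assessed: int = 0
    dose_categories: dict[str, int] = field(default_factory=dict)


def tabulate_outcomes(rs: ReportSet, event: tuple[str, str], h: TermHierarchy,
                      regimen: Sequence[str] | None = None,
                      recommendations: Mapping[str, DoseRecommendation]
                      = DEFAULT_RECOMMENDATIONS) -> OutcomeTable:
    """Tabulate outcomes, de/rechallenge and dose categories among the
    reports of ``rs`` (one regimen) that carry ``event``.

    De/rechallenge is assessed over reports where any suspect drug carries
    a positive or negative code (positive over assessed). Dose categories
    need ``regimen`` (the combination's drug names) with recommendations.
    """
    pts = _event_pts(h, *event)
    table = OutcomeTable(
        n_reports=0,
        outcomes={k: 0 for k in
                  ("death", "life_threatening", "hospitalization",
                   "disability", "other")},
        dose_categories={k: 0 for k in DOSE_CATEGORIES},
    )
    regimen_names = [normalize_term(d) for d in regimen] if regimen else None

    for rec in rs:
        if not report_has_event(rec, pts):
            continue
        table.n_reports += 1
        for out in rec.outcomes:
            table.outcomes[out] += 1

        suspects = [d for d in rec.drugs if d.role in SUSPECT_ROLES]
        dechal = {d.dechallenge for d in suspects}
        if "positive" in dechal:
            table.dechallenge_positive += 1
            table.dechallenge_assessed += 1
        elif "negative" in dechal:
            table.dechallenge_assessed += 1
        rechal = {d.rechallenge for d in suspects}
        if "positive" in rechal:
            table.rechallenge_positive += 1
            table.rechallenge_assessed += 1
        elif "negative" in rechal:
            table.rechallenge_assessed += 1

        if regimen_names:
            entries = []
            recs_ = []
            for name in regimen_names:
                entry = next((d for d in suspects if d.drug_name == name), None)
                if entry is None or name not in recommendations:
                    entries = []
                    break
                entries.append(entry)
                recs_.append(recommendations[name])
            category = dose_category(entries, recs_) if entries else "unreported"
            table.dose_categories[category] += 1
    return table


# ---------------------------------------------------------------------------
# Printed-percentage arithmetic

def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half away from zero.

    This is the convention behind printed percentages such as
    ``311/2345 -> 13.3`` and ``19/212 -> 9``.
    """
    if denominator <= 0:
        raise ArgumentError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ArgumentError("numerator must lie in [0, denominator]")
    q = Decimal(100 * numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))
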