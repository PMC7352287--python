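"""Seeded generator of FAERS-like spontaneous report sets with known truth.

The generator emulates the structure of serious-adverse-event reports for
three BRAF+MEK inhibitor combinations: per-regimen report volumes
(defaults 2,345 / 8,411 / 965), a background multinomial of reactions
over a PT->HLT->HLGT->SOC hierarchy, injected drug-event relative
reporting rates, regimen-specific age/sex distributions with
missingness, duplicate case versions, doses placed around the
recommended daily dose, therapy-start and onset dates with a log-normal
onset lag, seriousness outcomes, and dechallenge/rechallenge codes. A
pool of reports for unrelated drugs provides the full-database scope.

Everything is driven by one explicitly seeded random generator; a given
configuration reproduces identical output bytes.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .dates import PartialDate
from .errors import ArgumentError, IntegrityError
from .hierarchy import TermHierarchy
from .reports import DrugEntry, ReactionEntry, ReportRecord, ReportSet

BACKGROUND_GROUP = "__background__"

_CONCOMITANTS = ("paracetamol", "omeprazole", "metformin",
                 "levothyroxine", "amlodipine")
_BACKGROUND_DRUGS = ("nivolumab", "pembrolizumab", "ipilimumab",
                     "adalimumab", "methotrexate", "rivaroxaban")
_COUNTRIES = ("US", "FR", "DE", "JP", "GB", "IT", "AU")

#: Recommended daily doses used when placing dose values (mg).
_DOSES = {
    "vemurafenib": 960.0, "cobimetinib": 60.0,
    "dabrafenib": 150.0, "trametinib": 2.0,
    "encorafenib": 450.0, "binimetinib": 45.0,
}


@dataclass(frozen=True)
class InjectedPair:
    """Ground-truth association: the PT's reporting probability in the
    regimen's reports is the background probability times ``rr``."""

    regimen: str
    pt: str
    rr: float

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ArgumentError("relative reporting rate must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated report database."""

    regimen_sizes: Mapping[str, int] = field(default_factory=lambda: {
        "V+C": 2345, "D+T": 8411, "E+B": 965,
    })
    regimen_drugs: Mapping[str, tuple[str, str]] = field(default_factory=lambda: {
        "V+C": ("vemurafenib", "cobimetinib"),
        "D+T": ("dabrafenib", "trametinib"),
        "E+B": ("encorafenib", "binimetinib"),
    })
    background_size: int = 20000
    background_prob: float = 0.01
    injected: tuple[InjectedPair, ...] = ()
    age_dist: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "V+C": (58.8, 14.05), "D+T": (59.4, 16.0), "E+B": (62.93, 12.96),
        BACKGROUND_GROUP: (60.0, 17.0),
    })
    age_missing_rate: float = 0.15
    sex_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {  # (female, male, unreported)
            "V+C": (0.4726, 0.4709, 0.0565),
            "D+T": (0.4168, 0.4982, 0.0850),
            "E+B": (0.0686, 0.0743, 0.8571),
            BACKGROUND_GROUP: (0.50, 0.42, 0.08),
        })
    dose_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.10, 0.40)
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: {
        "death": 0.15, "life_threatening": 0.08, "hospitalization": 0.85,
        "disability": 0.03, "other": 0.35,
    })
    dechallenge_probs: tuple[float, float, float, float] = (0.35, 0.05, 0.10, 0.50)
    rechallenge_probs: tuple[float, float, float, float] = (0.05, 0.05, 0.10, 0.80)
    onset_lognorm: tuple[float, float] = (3.0, 0.9)  # (mu, sigma) of log-days
    partial_onset_rate: float = 0.05
    #: Nonspecific reaction given to reports whose Bernoulli draws produced
    #: no specific reaction (reports are never empty). Deliberately absent
    #: from the hierarchy, so it lands in the unmapped bucket at analysis
    #: and leaves every mapped term's count exactly binomial.
    filler_pt: str = "adverse event nos"
    window: tuple[dt.date, dt.date] = (dt.date(2018, 1, 1), dt.date(2019, 12, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (("dose", self.dose_probs),
                            ("dechallenge", self.dechallenge_probs),
                            ("rechallenge", self.rechallenge_probs)):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ArgumentError(f"{name} probabilities must sum to 1")
        if not 0 <= self.age_missing_rate <= 1:
            raise ArgumentError("age_missing_rate must be in [0, 1]")
        if any(n < 0 for n in self.regimen_sizes.values()):
            raise ArgumentError("regimen sizes must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated database, for recovery scoring."""

    injected: tuple[InjectedPair, ...]
    expected_n11: dict[tuple[str, str], float]
    regimens: tuple[str, ...]
    pts: tuple[str, ...]
    seed: int

    def injected_keys(self) -> set[tuple[str, str]]:
        return {(p.regimen, p.pt) for p in self.injected}

    def null_keys(self) -> set[tuple[str, str]]:
        return {
            (g, pt) for g in self.regimens for pt in self.pts
        } - self.injected_keys()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "regimens": list(self.regimens),
            "pts": list(self.pts),
            "injected": [
                {"regimen": p.regimen, "pt": p.pt, "rr": p.rr}
                for p in self.injected
            ],
            "expected_n11": {
                f"{g}\t{pt}": v for (g, pt), v in self.expected_n11.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            injected=tuple(InjectedPair(**p) for p in d["injected"]),
            expected_n11={
                tuple(k.split("\t")): v for k, v in d["expected_n11"].items()
            },
            regimens=tuple(d["regimens"]),
            pts=tuple(d["pts"]),
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# Generation

def _reaction_matrix(rng: np.random.Generator, n: int,
                     probs: np.ndarray) -> np.ndarray:
    """Independent Bernoulli reaction indicators; empty rows are handled by
    the caller with the nonspecific filler reaction."""
    return rng.random((n, probs.size)) < probs


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int) -> np.ndarray:
    ages = rng.normal(mean, sd, n)
    for _ in range(100):
        neg = ages < 0
        if not neg.any():
            break
        ages[neg] = rng.normal(mean, sd, int(neg.sum()))
    return np.maximum(ages, 0.0)


def _sample_dose(rng: np.random.Generator, category: str,
                 recommended: float) -> float | None:
    if category == "unreported":
        return None
    if category == "at":
        return recommended
    if category == "below":
        return round(float(rng.uniform(0.3, 0.95)) * recommended, 1)
    return round(float(rng.uniform(1.05, 1.5)) * recommended, 1)


def generate_reports(cfg: SimConfig,
                     h: TermHierarchy) -> tuple[ReportSet, SyntheticTruth]:
    """Generate one database: regimen reports plus a background pool.

    Each regimen report carries the combination's two drugs as primary and
    secondary suspects (order randomized) plus 0-3 concomitants;
    background reports carry one unrelated suspect drug. Injected pairs
    multiply the PT's background reporting probability by their relative
    rate (capped at 0.95).
    """
    rng = np.random.default_rng(cfg.seed)
    pts = tuple(sorted(h.pts()))
    if cfg.filler_pt in h.pts():
        raise ArgumentError(
            "filler_pt must not be a hierarchy term (it would bias that "
            "term's reporting rate)")
    base = np.full(len(pts), cfg.background_prob, dtype=float)
    pt_index = {pt: i for i, pt in enumerate(pts)}
    for pair in cfg.injected:
        if pair.pt not in pt_index:
            raise ArgumentError(f"injected PT {pair.pt!r} not in hierarchy")
        if pair.regimen not in cfg.regimen_sizes:
            raise ArgumentError(f"injected regimen {pair.regimen!r} unknown")

    window_start, window_end = cfg.window
    window_days = (window_end - window_start).days

    records: list[ReportRecord] = []
    expected: dict[tuple[str, str], float] = {}
    case_counter = 0
    groups = list(cfg.regimen_sizes) + [BACKGROUND_GROUP]

    for group in groups:
        n = (cfg.background_size if group == BACKGROUND_GROUP
             else cfg.regimen_sizes[group])
        if n == 0:
            continue
        probs = base.copy()
        if group != BACKGROUND_GROUP:
            for pair in cfg.injected:
                if pair.regimen == group:
                    probs[pt_index[pair.pt]] = min(
                        probs[pt_index[pair.pt]] * pair.rr, 0.95)
            for pt in pts:
                expected[(group, pt)] = float(n * probs[pt_index[pt]])
        hits = _reaction_matrix(rng, n, probs)

        ages = _truncated_normal(rng, *cfg.age_dist[group], n)
        age_missing = rng.random(n) < cfg.age_missing_rate
        sexes = rng.choice(
            ["female", "male", "unreported"], size=n, p=cfg.sex_probs[group])
        countries = rng.choice(_COUNTRIES, size=n)
        receipt_offsets = rng.integers(0, window_days + 1, n)
        start_offsets = rng.integers(0, window_days + 1, n)
        lags = np.maximum(
            np.rint(rng.lognormal(*cfg.onset_lognorm, n)), 0).astype(int)
        partial_onset = rng.random(n) < cfg.partial_onset_rate
        dose_cats = rng.choice(
            ["below", "at", "above", "unreported"], size=n, p=cfg.dose_probs)
        dechals = rng.choice(
            ["positive", "negative", "not_applicable", "unreported"],
            size=n, p=cfg.dechallenge_probs)
        rechals = rng.choice(
            ["positive", "negative", "not_applicable", "unreported"],
            size=n, p=cfg.rechallenge_probs)
        n_conc = rng.integers(0, 4, n)
        outcome_draws = {
            out: rng.random(n) < p for out, p in cfg.outcome_probs.items()
        }

        for i in range(n):
            case_counter += 1
            case_id = f"C{case_counter:07d}"
            start = window_start + dt.timedelta(days=int(start_offsets[i]))
            onset = start + dt.timedelta(days=int(lags[i]))
            if partial_onset[i]:
                onset_pd = PartialDate(onset.year, onset.month)
            else:
                onset_pd = PartialDate(onset.year, onset.month, onset.day)
            start_pd = PartialDate(start.year, start.month, start.day)
            receipt = window_start + dt.timedelta(days=int(receipt_offsets[i]))

            if group == BACKGROUND_GROUP:
                name = _BACKGROUND_DRUGS[case_counter % len(_BACKGROUND_DRUGS)]
                drugs = [DrugEntry(
                    drug_name=name, role="primary_suspect",
                    regimen_start=start_pd,
                    dechallenge=str(dechals[i]), rechallenge=str(rechals[i]),
                )]
            else:
                pair_names = list(cfg.regimen_drugs[group])
                if rng.random() < 0.5:
                    pair_names.reverse()
                drugs = []
                for role, name in zip(
                        ("primary_suspect", "secondary_suspect"), pair_names):
                    dose = _sample_dose(rng, str(dose_cats[i]),
                                        _DOSES.get(name, 100.0))
                    drugs.append(DrugEntry(
                        drug_name=name, role=role,
                        dose_value=dose, dose_unit="mg" if dose else None,
                        regimen_start=start_pd,
                        indication="melanoma",
                        dechallenge=str(dechals[i]),
                        rechallenge=str(rechals[i]),
                    ))
            for j in range(int(n_conc[i])):
                drugs.append(DrugEntry(
                    drug_name=_CONCOMITANTS[(case_counter + j) % len(_CONCOMITANTS)],
                    role="concomitant",
                ))

            reactions = tuple(
                ReactionEntry(pts[k], onset_pd)
                for k in np.flatnonzero(hits[i])
            ) or (ReactionEntry(cfg.filler_pt, onset_pd),)
            outcomes = {out for out in outcome_draws if outcome_draws[out][i]}
            if not outcomes & {"death", "life_threatening",
                               "hospitalization", "disability"}:
                outcomes.add("hospitalization")

            records.append(ReportRecord(
                report_id=f"{case_id}-1",
                case_id=case_id,
                case_version=1,
                receipt_date=PartialDate(receipt.year, receipt.month, receipt.day),
                age=None if age_missing[i] else round(float(ages[i]), 1),
                sex=str(sexes[i]),
                country=str(countries[i]),
                outcomes=frozenset(outcomes),
                drugs=tuple(drugs),
                reactions=reactions,
            ))

    rs = ReportSet(records)
    rs.log(action="simulate", seed=cfg.seed, n_records=len(records),
           groups={g: (cfg.background_size if g == BACKGROUND_GROUP
                       else cfg.regimen_sizes[g]) for g in groups})
    truth = SyntheticTruth(
        injected=tuple(cfg.injected),
        expected_n11=expected,
        regimens=tuple(cfg.regimen_sizes),
        pts=pts,
        seed=cfg.seed,
    )
    return rs, truth


def inject_duplicates(rs: ReportSet, rate: float, seed: int) -> ReportSet:
    """Re-emit a seeded sample of cases with an incremented case version
    and a perturbed receipt date, emulating follow-up submissions.

    The duplicated case ids are recorded in the provenance log so
    deduplication tests know the expected survivor count.
    """
    if not 0 <= rate < 1:
        raise ArgumentError("duplicate rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(len(rs)) < rate
    extras: list[ReportRecord] = []
    duplicated: list[str] = []
    for rec, hit in zip(rs, mask):
        if not hit:
            continue
        duplicated.append(rec.case_id)
        receipt = rec.receipt_date
        if receipt is not None and receipt.is_complete:
            bumped = receipt.to_date() + dt.timedelta(days=int(rng.integers(1, 31)))
            receipt = PartialDate(bumped.year, bumped.month, bumped.day)
        extras.append(replace(
            rec,
            report_id=f"{rec.case_id}-{rec.case_version + 1}",
            case_version=rec.case_version + 1,
            receipt_date=receipt,
        ))
    out = rs.derived(list(rs.records) + extras, action="inject_duplicates",
                     rate=rate, seed=seed, n_added=len(extras),
                     duplicated_cases=duplicated)
    return out


# ---------------------------------------------------------------------------
# Recovery scoring

@dataclass(frozen=True)
class RecoveryMetrics:
    """Signal recovery against the generator's ground truth."""

    sensitivity: float
    false_discovery_proportion: float
    n_injected: int
    n_flagged: int
    by_rr: dict[float, float]


def evaluate_recovery(signals: set[tuple[str, str]], truth: SyntheticTruth,
                      run_seed: int | None = None) -> RecoveryMetrics:
    """Score a flagged-signal set against the injected truth.

    ``signals`` are ``(regimen, pt)`` keys from the same run as ``truth``;
    pass ``run_seed`` to assert the provenance match.
    """
    if run_seed is not None and run_seed != truth.seed:
        raise IntegrityError(
            f"signals come from seed {run_seed}, truth from seed {truth.seed}"
        )
    injected = truth.injected_keys()
    hit = signals & injected
    false = signals - injected
    sens = len(hit) / len(injected) if injected else 0.0
    fdp = len(false) / len(signals) if signals else 0.0
    by_rr: dict[float, float] = {}
    for rr in sorted({p.rr for p in truth.injected}):
        keys = {(p.regimen, p.pt) for p in truth.injected if p.rr == rr}
        by_rr[rr] = len(signals & keys) / len(keys)
    return RecoveryMetrics(sens, fdp, len(injected), len(signals), by_rr)


# ---------------------------------------------------------------------------
# Programmatic hierarchies and special scenarios

def synthetic_hierarchy(n_pts: int) -> TermHierarchy:
    """A regular synthetic hierarchy with ``n_pts`` preferred terms
    (4 PTs per HLT, 4 HLTs per HLGT, 4 HLGTs per SOC)."""
    rows = [
        (f"pt {i:03d}", f"hlt {i // 4:03d}", f"hlgt {i // 16:03d}",
         f"soc {i // 64:03d}")
        for i in range(n_pts)
    ]
    return TermHierarchy(rows)


def generate_confounded(n_reports: int, common_or: float, seed: int,
                        h: TermHierarchy,
                        event_pt: str = "acute kidney injury",
                        filler_pt: str = "nausea",
                        ) -> tuple[ReportSet, ReportSet]:
    """Two regimens with an age-confounded event and a known common OR.

    The exposed regimen's patients are drawn older, the event's baseline
    reporting probability rises with age, and within every age stratum
    the exposed reporting odds are ``common_or`` times the comparator's.
    The crude ROR is therefore biased away from ``common_or`` while the
    age-adjusted estimator should recover it.
    """
    rng = np.random.default_rng(seed)
    n_arm = n_reports // 2
    base_young, base_old = 0.01, 0.06

    def build(group: str, drugs: tuple[str, str], p_old: float,
              or_mult: float) -> ReportSet:
        ages = np.where(rng.random(n_arm) < p_old,
                        _truncated_normal(rng, 70.0, 6.0, n_arm),
                        _truncated_normal(rng, 45.0, 6.0, n_arm))
        base = np.where(ages >= 60.0, base_old, base_young)
        odds = base / (1 - base) * or_mult
        p_event = odds / (1 + odds)
        has_event = rng.random(n_arm) < p_event
        records = []
        for i in range(n_arm):
            pts = (event_pt,) if has_event[i] else (filler_pt,)
            records.append(ReportRecord(
                report_id=f"{group}{i:06d}",
                case_id=f"{group}{i:06d}",
                case_version=1,
                receipt_date=PartialDate(2019, 6, 1),
                age=round(float(ages[i]), 1),
                sex="unreported",
                country=None,
                outcomes=frozenset({"hospitalization"}),
                drugs=(
                    DrugEntry(drugs[0], "primary_suspect"),
                    DrugEntry(drugs[1], "secondary_suspect"),
                ),
                reactions=tuple(ReactionEntry(pt) for pt in pts),
            ))
        rs = ReportSet(records)
        rs.log(action="simulate_confounded", group=group, seed=seed,
               common_or=common_or, n_records=len(records))
        return rs

    exposed = build("E", ("encorafenib", "binimetinib"), 0.8, common_or)
    comparator = build("K", ("dabrafenib", "trametinib"), 0.2, 1.0)
    return exposed, comparator
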