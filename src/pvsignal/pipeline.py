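"""End-to-end two-tier analysis: ingestion to signal and clinical tables.

Tier 1 screens each drug combination against the full database with the
BCPNN information component at high-level group terms, ranked by
posterior null probability and thresholded on the cumulative Bayesian
FDR. Tier 2 restricts to the tier-1 signals and their associated terms
and compares each combination against the other combinations with
reporting odds ratios (mid-p tests, Benjamini-Hochberg correction,
Mantel-Haenszel age adjustment), then confirms signals across hierarchy
levels. Flagged events are characterized clinically (doses, onset,
de/rechallenge, outcomes).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import clinical as clin
from .contingency import build_tables, min_report_filter, stratify_by_age
from .errors import ArgumentError
from .hierarchy import (LEVELS, TermHierarchy, associated_terms,
                        load_hierarchy, roll_up, toy_hierarchy)
from .reports import (FilterSpec, ReportSet, deduplicate, filter_reports,
                      load_reports, select_combination)
from .stats import (SignalResult, bayesian_fdr, bcpnn_ic,
                    bh_adjust, cross_level_confirm, crude_ror, ic_signal_set,
                    midp_value, mh_adjusted_ror)

DEFAULT_AGE_BINS = tuple(float(b) for b in range(0, 90, 10))

#: Term categories excluded from disproportionality analysis: fatal
#: outcomes reported as events, and neoplasm-related events (cancer
#: staging is unavailable in spontaneous reports, so these cannot be
#: interpreted).
DEFAULT_EXCLUDED_CATEGORIES: tuple[tuple[str, str], ...] = (
    ("fatal outcomes", "HLGT"),
    ("neoplasms benign malignant and unspecified (incl cysts and polyps)", "SOC"),
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    output_dir: str
    dialect: str = "tsv"
    hierarchy_path: str | None = None
    regimens: Mapping[str, tuple[str, str]] = field(default_factory=lambda: {
        "V+C": ("vemurafenib", "cobimetinib"),
        "D+T": ("dabrafenib", "trametinib"),
        "E+B": ("encorafenib", "binimetinib"),
    })
    window: tuple[dt.date, dt.date] | None = (
        dt.date(2018, 1, 1), dt.date(2019, 12, 31))
    serious_only: bool = True
    excluded_terms: tuple[str, ...] = ("off-label use",)
    excluded_categories: tuple[tuple[str, str], ...] = DEFAULT_EXCLUDED_CATEGORIES
    ic_level: str = "HLGT"
    ror_levels: tuple[str, ...] = ("HLGT", "PT")
    min_report_fraction: float = 0.005
    fdr_threshold: float = 0.05
    min_count: int = 3
    alpha: float = 0.05
    age_bins: tuple[float, ...] = DEFAULT_AGE_BINS
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.min_report_fraction, self.fdr_threshold, self.alpha):
            if not 0 < thr < 1:
                raise ArgumentError("thresholds must lie in (0, 1)")
        if not self.regimens:
            raise ArgumentError("at least one regimen pair is required")
        if self.window is not None and self.window[0] > self.window[1]:
            raise ArgumentError("analysis window is not well-ordered")
        for lv in (self.ic_level, *self.ror_levels):
            if lv not in LEVELS:
                raise ArgumentError(f"unknown hierarchy level: {lv!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "window" in raw and raw["window"] is not None:
            raw["window"] = tuple(
                v if isinstance(v, dt.date) else dt.date.fromisoformat(v)
                for v in raw["window"])
        if "regimens" in raw:
            raw["regimens"] = {k: tuple(v) for k, v in raw["regimens"].items()}
        for key in ("excluded_terms", "ror_levels", "age_bins"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "excluded_categories" in raw:
            raw["excluded_categories"] = tuple(
                tuple(pair) for pair in raw["excluded_categories"])
        return cls(**raw)

    def echo(self) -> dict:
        d = self.__dict__.copy()
        if d["window"]:
            d["window"] = [v.isoformat() for v in d["window"]]
        d["regimens"] = {k: list(v) for k, v in self.regimens.items()}
        for key in ("excluded_terms", "ror_levels", "age_bins"):
            d[key] = list(d[key])
        d["excluded_categories"] = [list(p) for p in d["excluded_categories"]]
        return d


def display_ror(value: float, offset: float = 0.1) -> float:
    """Display-layer transform for log-scale bar exports: a small constant
    added to avoid near-zero bars. Never used in inference."""
    return value + offset


@dataclass
class RunResult:
    """In-memory outcome of a pipeline run."""

    signals: list[SignalResult]
    tier1_signals: set[tuple[str, str]]   # (regimen, term) at ic_level
    manifest: dict
    output_dir: Path


# ---------------------------------------------------------------------------

def _load_and_clean(cfg: RunConfig, h: TermHierarchy) -> ReportSet:
    rs = load_reports(cfg.input_path, cfg.dialect)
    rs = deduplicate(rs)
    spec = FilterSpec(
        window=cfg.window,
        serious_only=cfg.serious_only,
        excluded_terms=cfg.excluded_terms,
        excluded_categories=cfg.excluded_categories,
    )
    return filter_reports(rs, spec, hierarchy=h)


def _tier1(cfg: RunConfig, h: TermHierarchy, full: ReportSet,
           regimens: Mapping[str, ReportSet]):
    """IC vs full database at ``cfg.ic_level`` with Bayesian FDR."""
    counts = None
    for g, sub in regimens.items():
        ec = roll_up(sub, h, cfg.ic_level, group=g)
        counts = ec if counts is None else counts.merge(ec)
    retained = min_report_filter(counts, cfg.min_report_fraction)

    items = []
    per_pair = {}
    for g, sub in regimens.items():
        if len(sub) == 0:
            continue
        tables = build_tables(sub, full, cfg.ic_level, h,
                              scope="full_database", terms=retained)
        for term, t in tables.items():
            if t.n_1 == 0 or t.n1_ == 0:
                continue
            per_pair[(g, term)] = t
            items.append(((g, term), bcpnn_ic(t), t.n11))
    if not items:
        return set(), [], per_pair
    ranked = bayesian_fdr(items)
    flagged = ic_signal_set(ranked, cfg.fdr_threshold, cfg.min_count)
    return flagged, ranked, per_pair


def _tier2_terms(cfg: RunConfig, h: TermHierarchy,
                 tier1_flagged: set[tuple[str, str]]) -> dict[str, set[tuple[str, str]]]:
    """Per-regimen (term, level) shortlist: tier-1 signals plus associated
    terms, restricted to the configured analysis levels."""
    out: dict[str, set[tuple[str, str]]] = {g: set() for g in cfg.regimens}
    for g, term in tier1_flagged:
        related = associated_terms(h, term, cfg.ic_level)
        related.add((term, cfg.ic_level))
        out[g] |= {(t, lv) for t, lv in related if lv in cfg.ror_levels}
    return out


def run_pipeline(cfg: RunConfig,
                 hierarchy: TermHierarchy | None = None) -> RunResult:
    """Execute the full two-tier analysis and write output files.

    Writes ``signals.tsv``, ``clinical.tsv``, ``ror_display.tsv`` (the
    display-only +0.1 transform for bar exports) and ``manifest.json``
    under ``cfg.output_dir``. Deterministic for a fixed config and input.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    h = hierarchy
    if h is None:
        h = (load_hierarchy(cfg.hierarchy_path)
             if cfg.hierarchy_path else toy_hierarchy())
    full = _load_and_clean(cfg, h)
    stages.append("ingest")

    regimens = {
        g: select_combination(full, a, b)
        for g, (a, b) in cfg.regimens.items()
    }
    regimens = {g: sub for g, sub in regimens.items() if len(sub) > 0}
    stages.append("select_combinations")

    tier1_flagged, ranked, tier1_tables = _tier1(cfg, h, full, regimens)
    fdr_by_key = {r.key: r for r in ranked}
    stages.append("tier1_ic")

    shortlist = _tier2_terms(cfg, h, tier1_flagged)
    regimen_ids = {g: sub.report_ids() for g, sub in regimens.items()}
    results: list[SignalResult] = []

    for g, sub in regimens.items():
        other_ids = set().union(
            *(ids for og, ids in regimen_ids.items() if og != g), set())
        others = ReportSet([r for r in full if r.report_id in other_ids],
                           list(full.provenance))
        comparison = f"{g} vs others"
        terms_by_level: dict[str, list[str]] = {}
        for term, lv in sorted(shortlist.get(g, ())):
            terms_by_level.setdefault(lv, []).append(term)

        level_signals: set[tuple[str, str]] = set()
        level_results: dict[tuple[str, str], SignalResult] = {}
        for lv, terms in terms_by_level.items():
            if len(others) == 0:
                continue
            # keep only terms present in at least one group at threshold
            counts = roll_up(sub, h, lv, group=g).merge(
                roll_up(others, h, lv, group="others"))
            retained = min_report_filter(counts, cfg.min_report_fraction)
            terms = [t for t in terms if t in retained]
            if not terms:
                continue
            tables = build_tables(sub, others, lv, h, terms=terms)
            pvals = bh_adjust([midp_value(t) for t in tables.values()])
            for (term, t), p_adj in zip(tables.items(), pvals):
                ror = crude_ror(t)
                ror.midp = midp_value(t)
                ror.p_adj = p_adj
                adj = None
                strat = stratify_by_age(sub, others, (term, lv), h,
                                        cfg.age_bins)
                if len(strat):
                    try:
                        adj = mh_adjusted_ror(strat)
                    except ArgumentError:
                        adj = None
                res = SignalResult(
                    term=term, level=lv, comparison=comparison, n11=t.n11,
                    ic=(fdr_by_key[(g, term)].ic
                        if (g, term) in fdr_by_key and lv == cfg.ic_level
                        else None),
                    bayes_fdr=(fdr_by_key[(g, term)].bayes_fdr
                               if (g, term) in fdr_by_key
                               and lv == cfg.ic_level else None),
                    ror=ror, adj_ror=adj,
                    ic_signal=(g, term) in tier1_flagged and lv == cfg.ic_level,
                    ror_signal=ror.estimate > 1 and p_adj < cfg.alpha,
                )
                level_results[(term, lv)] = res
                if res.ror_signal:
                    level_signals.add((term, lv))
        confirmed = cross_level_confirm(level_signals, h)
        for key, res in level_results.items():
            res.cross_level_confirmed = confirmed.get(key, False)
            results.append(res)
    stages.append("tier2_ror")

    clinical_rows = _clinical_profiles(cfg, h, regimens, results)
    stages.append("clinical")

    _write_signals_tsv(results, outdir / "signals.tsv")
    _write_display_tsv(results, outdir / "ror_display.tsv")
    _write_clinical_tsv(clinical_rows, outdir / "clinical.tsv")
    manifest = {
        "config": cfg.echo(),
        "seed": cfg.seed,
        "stages": stages,
        "pvsignal_version": _pkg_version("pvsignal"),
        "provenance": full.provenance,
        "n_reports_analyzed": len(full),
        "n_per_regimen": {g: len(sub) for g, sub in regimens.items()},
        "tier1_signals": sorted(map(list, tier1_flagged)),
        "n_tier2_results": len(results),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    stages.append("write_outputs")
    return RunResult(results, tier1_flagged, manifest, outdir)


# ---------------------------------------------------------------------------
# Clinical profiles and writers

def _clinical_profiles(cfg: RunConfig, h: TermHierarchy,
                       regimens: Mapping[str, ReportSet],
                       results: Sequence[SignalResult]) -> list[dict]:
    rows: list[dict] = []
    flagged = [(r.comparison.split(" vs ")[0], r.term, r.level)
               for r in results if r.ror_signal]
    for term, lv in sorted({(t, lv) for _, t, lv in flagged}):
        for g, sub in regimens.items():
            table = clin.tabulate_outcomes(sub, (term, lv), h,
                                           regimen=cfg.regimens[g])
            onsets = [
                clin.time_to_onset(rec, cfg.regimens[g], (term, lv), h)
                for rec in sub
            ]
            summary = clin.summarize_onset([v for v in onsets if v is not None])
            n = table.n_reports
            row = {
                "term": term, "level": lv, "regimen": g, "n_reports": n,
                **{f"outcome_{k}": v for k, v in table.outcomes.items()},
                "dechallenge_positive": table.dechallenge_positive,
                "dechallenge_assessed": table.dechallenge_assessed,
                "rechallenge_positive": table.rechallenge_positive,
                "rechallenge_assessed": table.rechallenge_assessed,
                **{f"dose_{k}": v for k, v in table.dose_categories.items()},
                "onset_median": summary.median if summary else "",
                "onset_q1": summary.q1 if summary else "",
                "onset_q3": summary.q3 if summary else "",
                "onset_n": summary.n if summary else 0,
            }
            rows.append(row)
    return rows


_SIGNAL_COLUMNS = [
    "term", "level", "comparison", "n11", "e_ic", "v_ic", "p_null",
    "bayes_fdr", "ror", "ci_low", "ci_high", "midp", "p_adj", "adj_ror",
    "adj_ci_low", "adj_ci_high", "ic_signal", "ror_signal",
    "cross_level_confirmed", "zero_cell_corrected",
]


def _fmt(x) -> str:
    if x is None or x == "":
        return ""
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_signals_tsv(results: Sequence[SignalResult], path: Path) -> None:
    lines = ["\t".join(_SIGNAL_COLUMNS)]
    for r in sorted(results, key=lambda r: (r.comparison, r.level, r.term)):
        row = [
            r.term, r.level, r.comparison, r.n11,
            r.ic.e_ic if r.ic else None, r.ic.v_ic if r.ic else None,
            r.ic.p_null if r.ic else None, r.bayes_fdr,
            r.ror.estimate if r.ror else None,
            r.ror.ci_low if r.ror else None,
            r.ror.ci_high if r.ror else None,
            r.ror.midp if r.ror else None,
            r.ror.p_adj if r.ror else None,
            r.adj_ror.estimate if r.adj_ror else None,
            r.adj_ror.ci_low if r.adj_ror else None,
            r.adj_ror.ci_high if r.adj_ror else None,
            r.ic_signal, r.ror_signal, r.cross_level_confirmed,
            r.ror.zero_cell_corrected if r.ror else None,
        ]
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _write_display_tsv(results: Sequence[SignalResult], path: Path) -> None:
    """Bar-export table; ROR shifted by the display constant, labelled."""
    lines = ["\t".join(["term", "level", "comparison",
                        "ror_plus_0.1_display_only"])]
    for r in sorted(results, key=lambda r: (r.comparison, r.level, r.term)):
        if r.ror is None:
            continue
        lines.append("\t".join([
            r.term, r.level, r.comparison, _fmt(display_ror(r.ror.estimate)),
        ]))
    path.write_text("\n".join(lines) + "\n")


def _write_clinical_tsv(rows: list[dict], path: Path) -> None:
    if not rows:
        path.write_text("term\tlevel\tregimen\tn_reports\n")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(_fmt(row[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def export_ror_barplot(results: Sequence[SignalResult], path: str | Path,
                       offset: float = 0.1) -> None:
    """Log-scale bar chart of displayed RORs (estimate + offset, labelled)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [(f"{r.term} [{r.comparison}]", display_ror(r.ror.estimate, offset))
            for r in results if r.ror is not None and r.ror_signal]
    if not rows:
        return
    labels, values = zip(*rows)
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(rows) + 1.5))
    ax.barh(range(len(rows)), values)
    ax.set_yticks(range(len(rows)), labels, fontsize=7)
    ax.set_xscale("log")
    ax.axvline(1.0, color="k", lw=0.8)
    ax.set_xlabel(f"ROR + {offset} (display constant)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
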