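"""MedDRA-style term hierarchy: PT -> HLT -> HLGT -> SOC.

The licensed MedDRA dictionary cannot be redistributed, so users supply
their own mapping as a four-column TSV (``pt``, ``hlt``, ``hlgt``,
``soc``; ``#`` comment lines ignored). A small toy hierarchy covering the
terms exercised in the documentation and tests ships with the package
(:func:`toy_hierarchy`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._text import normalize_term
from .errors import ArgumentError, IntegrityError, TermLookupError

LEVELS = ("PT", "HLT", "HLGT", "SOC")
_PARENT_INDEX = {"PT": 0, "HLT": 1, "HLGT": 2, "SOC": 3}


class TermHierarchy:
    """Immutable mapping of preferred terms to their parent chain."""

    def __init__(self, rows: Iterable[tuple[str, str, str, str]]):
        self._chain: dict[str, tuple[str, str, str]] = {}
        self._children: dict[tuple[str, str], set[str]] = {}
        self._levels: dict[str, set[str]] = {lv: set() for lv in LEVELS}
        for pt, hlt, hlgt, soc in rows:
            pt, hlt, hlgt, soc = map(normalize_term, (pt, hlt, hlgt, soc))
            if not all((pt, hlt, hlgt, soc)):
                raise IntegrityError(f"empty level in hierarchy row for pt {pt!r}")
            prev = self._chain.get(pt)
            if prev is not None and prev != (hlt, hlgt, soc):
                raise IntegrityError(
                    f"conflicting parentage for pt {pt!r}: {prev} vs {(hlt, hlgt, soc)}"
                )
            self._chain[pt] = (hlt, hlgt, soc)
            self._levels["PT"].add(pt)
            self._levels["HLT"].add(hlt)
            self._levels["HLGT"].add(hlgt)
            self._levels["SOC"].add(soc)
            self._children.setdefault(("HLT", hlt), set()).add(pt)
            self._children.setdefault(("HLGT", hlgt), set()).add(hlt)
            self._children.setdefault(("SOC", soc), set()).add(hlgt)

    # -- basic lookups --------------------------------------------------------

    def __len__(self) -> int:
        return len(self._chain)

    def pts(self) -> frozenset[str]:
        return frozenset(self._chain)

    def terms_at(self, level: str) -> frozenset[str]:
        self._check_level(level)
        return frozenset(self._levels[level])

    def has_term(self, term: str, level: str) -> bool:
        self._check_level(level)
        return normalize_term(term) in self._levels[level]

    def map_pt(self, pt: str, level: str) -> str | None:
        """Ancestor of ``pt`` at ``level``; None when the PT is unmapped."""
        self._check_level(level)
        pt = normalize_term(pt)
        if level == "PT":
            return pt if pt in self._chain else None
        chain = self._chain.get(pt)
        if chain is None:
            return None
        return chain[_PARENT_INDEX[level] - 1]

    # -- closures -------------------------------------------------------------

    def ancestors(self, term: str, level: str) -> set[tuple[str, str]]:
        term = normalize_term(term)
        self._require(term, level)
        out: set[tuple[str, str]] = set()
        if level == "PT":
            hlt, hlgt, soc = self._chain[term]
            out = {(hlt, "HLT"), (hlgt, "HLGT"), (soc, "SOC")}
        elif level in ("HLT", "HLGT"):
            upper = LEVELS[LEVELS.index(level) + 1:]
            for pt, chain in self._chain.items():
                if chain[_PARENT_INDEX[level] - 1] == term:
                    for lv in upper:
                        out.add((chain[_PARENT_INDEX[lv] - 1], lv))
        return out

    def descendants(self, term: str, level: str) -> set[tuple[str, str]]:
        term = normalize_term(term)
        self._require(term, level)
        out: set[tuple[str, str]] = set()
        frontier = [(term, level)]
        while frontier:
            t, lv = frontier.pop()
            for child in self._children.get((lv, t), ()):
                child_level = LEVELS[LEVELS.index(lv) - 1]
                out.add((child, child_level))
                if child_level != "PT":
                    frontier.append((child, child_level))
        return out

    def descendant_pts(self, term: str, level: str) -> set[str]:
        """All preferred terms at or below ``term``."""
        if level == "PT":
            self._require(normalize_term(term), level)
            return {normalize_term(term)}
        return {t for t, lv in self.descendants(term, level) if lv == "PT"}

    def _check_level(self, level: str) -> None:
        if level not in LEVELS:
            raise ArgumentError(f"unknown hierarchy level: {level!r}")

    def _require(self, term: str, level: str) -> None:
        self._check_level(level)
        if term not in self._levels[level]:
            raise TermLookupError(f"unknown {level} term: {term!r}")


def load_hierarchy(path: str | Path) -> TermHierarchy:
    """Load a hierarchy TSV with columns ``pt``, ``hlt``, ``hlgt``, ``soc``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("pt", "hlt", "hlgt", "soc") if c not in df.columns]
    if missing:
        raise IntegrityError(f"hierarchy file missing column(s): {', '.join(missing)}")
    return TermHierarchy(
        (row.pt, row.hlt, row.hlgt, row.soc) for row in df.itertuples(index=False)
    )


def toy_hierarchy() -> TermHierarchy:
    """The small bundled hierarchy used by tests, demos, and documentation."""
    ref = importlib.resources.files("pvsignal.data") / "toy_hierarchy.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_hierarchy(path)


def associated_terms(h: TermHierarchy, term: str, level: str) -> set[tuple[str, str]]:
    """Terms associated with ``term`` across levels: its ancestors plus the
    full set of descendants (intermediate levels included).

    Used for cross-level signal confirmation: a disproportionality finding
    at one granularity is corroborated when a related term at another
    granularity is also flagged.
    """
    return h.ancestors(term, level) | h.descendants(term, level)


# ---------------------------------------------------------------------------
# Roll-up counting

@dataclass
class EventCounts:
    """Distinct-report counts per (term, exposure group) at one level.

    A report contributes at most once to any (term, group) cell no matter
    how many of its preferred terms roll up to that term. Unmapped PTs are
    kept in a separate bucket, never silently dropped.
    """

    level: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    unmapped: dict[str, dict[str, int]] = field(default_factory=dict)

    def groups(self) -> list[str]:
        return list(self.totals)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for per_group in self.counts.values():
            out |= set(per_group)
        return out

    def count(self, term: str, group: str) -> int:
        return self.counts.get(group, {}).get(term, 0)

    def merge(self, other: "EventCounts") -> "EventCounts":
        if other.level != self.level:
            raise ArgumentError("cannot merge EventCounts at different levels")
        merged = EventCounts(self.level, dict(self.counts), dict(self.totals),
                             dict(self.unmapped))
        for g in other.totals:
            if g in merged.totals:
                raise ArgumentError(f"duplicate group {g!r} in merge")
            merged.counts[g] = dict(other.counts.get(g, {}))
            merged.totals[g] = other.totals[g]
            merged.unmapped[g] = dict(other.unmapped.get(g, {}))
        return merged


def roll_up(rs, h: TermHierarchy, level: str, group: str = "all") -> EventCounts:
    """Roll each report's reactions up to ``level`` and count distinct reports."""
    if level not in LEVELS:
        raise ArgumentError(f"unknown hierarchy level: {level!r}")
    counts: dict[str, int] = {}
    unmapped: dict[str, int] = {}
    for rec in rs:
        seen: set[str] = set()
        missed: set[str] = set()
        for pt in rec.pt_terms:
            target = h.map_pt(pt, level)
            if target is None:
                missed.add(pt)
            else:
                seen.add(target)
        for t in seen:
            counts[t] = counts.get(t, 0) + 1
        for pt in missed:
            unmapped[pt] = unmapped.get(pt, 0) + 1
    return EventCounts(level, {group: counts}, {group: len(rs)},
                       {group: unmapped})
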