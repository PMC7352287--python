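"""Disproportionality statistics for spontaneous-report signal detection.

Two complementary measures are implemented:

* the **information component** (IC) of the Bayesian confidence
  propagation neural network (BCPNN) — a shrunken base-2 log ratio of the
  observed to expected joint reporting probability of a drug-event pair,
  used against the full database, with signals ranked by the posterior
  probability of the null and thresholded on a cumulative Bayesian FDR;
* the **reporting odds ratio** (ROR) — the cross-product of the 2x2
  table, used between treatment subgroups, with Woolf confidence
  intervals, one-sided mid-p exact tests and Benjamini-Hochberg
  correction, plus a Mantel-Haenszel age-adjusted variant with
  Robins-Breslow-Greenland interval.

The BCPNN closed-form posterior moments follow the original formulation
with independent Dirichlet/Beta priors centred so that the prior
expectation of the IC is zero::

    E[IC]   = log2[ (n11+g11)(N+a)(N+b) / ((N+g)(n1.+a1)(n.1+b1)) ]
    V[IC]   = (1/ln 2)^2 * [ (N-n11+g-g11)/((n11+g11)(1+N+g))
                           + (N-n1.+a-a1)/((n1.+a1)(1+N+a))
                           + (N-n.1+b-b1)/((n.1+b1)(1+N+b)) ]
    g       = g11 (N+a)(N+b) / ((n1.+a1)(n.1+b1))

with defaults a1 = b1 = g11 = 1 and a = b = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable as _SMStrat
from statsmodels.stats.multitest import multipletests

from .contingency import ContingencyTable, StratifiedTable
from .errors import ArgumentError
from .hierarchy import TermHierarchy, associated_terms

_LN2 = math.log(2.0)
_Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# BCPNN information component

@dataclass(frozen=True)
class BcpnnPriors:
    """Prior constants of the BCPNN closed-form posterior."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ArgumentError("BCPNN priors must be strictly positive")

    def gamma(self, t: ContingencyTable) -> float:
        """Joint prior total, tuned so the prior IC expectation is zero."""
        return (self.gamma11 * (t.n + self.alpha) * (t.n + self.beta)
                / ((t.n1_ + self.alpha1) * (t.n_1 + self.beta1)))


@dataclass(frozen=True)
class ICResult:
    """Posterior moments of the information component."""

    e_ic: float   # posterior mean, base-2 log scale
    v_ic: float   # posterior variance
    p_null: float  # P(IC <= 0 | data), normal approximation

    @property
    def ic025(self) -> float:
        """Lower bound of the 95% credibility interval."""
        return self.e_ic - _Z95 * math.sqrt(self.v_ic)


def bcpnn_ic(t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()) -> ICResult:
    """Closed-form BCPNN posterior mean/variance of the IC for one table."""
    if t.n1_ == 0 or t.n_1 == 0:
        raise ArgumentError("undefined margin: n1. and n.1 must be positive")
    a1, b1 = priors.alpha1, priors.beta1
    a, b, g11 = priors.alpha, priors.beta, priors.gamma11
    n11, n1, n_1, n = t.n11, t.n1_, t.n_1, t.n
    g = priors.gamma(t)

    e_ic = math.log2(
        (n11 + g11) * (n + a) * (n + b) / ((n + g) * (n1 + a1) * (n_1 + b1))
    )
    v_ic = (1.0 / _LN2) ** 2 * (
        (n - n11 + g - g11) / ((n11 + g11) * (1 + n + g))
        + (n - n1 + a - a1) / ((n1 + a1) * (1 + n + a))
        + (n - n_1 + b - b1) / ((n_1 + b1) * (1 + n + b))
    )
    p_null = float(sps.norm.cdf(-e_ic / math.sqrt(v_ic)))
    return ICResult(e_ic, v_ic, p_null)


@dataclass(frozen=True)
class RankedIC:
    """One item of the Bayesian-FDR ranking."""

    key: Hashable
    ic: ICResult
    n11: int
    bayes_fdr: float


def bayesian_fdr(results: Sequence[tuple[Hashable, ICResult, int]]) -> list[RankedIC]:
    """Rank drug-event pairs by posterior null probability and attach the
    cumulative Bayesian FDR (running mean of ``p_null`` along the ranking).

    Ties in ``p_null`` are broken by ``n11`` descending, then by the
    string form of the key, so output order is deterministic.
    """
    if not results:
        raise ArgumentError("empty result list")
    ordered = sorted(results, key=lambda r: (r[1].p_null, -r[2], str(r[0])))
    out: list[RankedIC] = []
    running = 0.0
    for k, (key, ic, n11) in enumerate(ordered, start=1):
        running += ic.p_null
        out.append(RankedIC(key, ic, n11, running / k))
    return out


def ic_signal_set(ranked: Sequence[RankedIC], fdr_threshold: float = 0.05,
                  min_count: int = 3) -> set[Hashable]:
    """Keys flagged by the IC decision rule: positive posterior mean IC,
    at least ``min_count`` co-reports, and Bayesian FDR below threshold."""
    return {
        r.key for r in ranked
        if r.ic.e_ic > 0 and r.n11 >= min_count and r.bayes_fdr < fdr_threshold
    }


# ---------------------------------------------------------------------------
# Reporting odds ratio

@dataclass
class RORResult:
    """Reporting odds ratio with interval and (optionally) test results."""

    estimate: float
    ci_low: float
    ci_high: float
    method: str
    midp: float | None = None
    p_adj: float | None = None
    zero_cell_corrected: bool = False


def crude_ror(t: ContingencyTable) -> RORResult:
    """Crude ROR with Woolf (log-normal) 95% confidence interval.

    When any cell is zero, the Haldane-Anscombe correction (0.5 added to
    every cell) is applied to both estimate and interval and flagged.
    """
    zero_margins = sum(m == 0 for m in
                       (t.n1_, t.n01 + t.n00, t.n_1, t.n10 + t.n00))
    if zero_margins >= 2:
        raise ArgumentError("two or more empty margins; ROR undefined")
    cells = t.cells()
    corrected = any(c == 0 for c in cells)
    a, b, c, d = ((x + 0.5 for x in cells) if corrected else cells)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RORResult(
        estimate=est,
        ci_low=est * math.exp(-_Z95 * se),
        ci_high=est * math.exp(_Z95 * se),
        method="crude_woolf",
        zero_cell_corrected=corrected,
    )


def midp_value(t: ContingencyTable, alternative: str = "greater") -> float:
    """One-sided mid-p exact test for excess reporting.

    With margins fixed, the exposed-event cell follows a hypergeometric
    law; the mid-p counts all mass above the observed count plus half the
    mass at it. ``alternative="two-sided"`` doubles the smaller tail
    (capped at 1).
    """
    args = (t.n, t.n1_, t.n_1)
    pm = float(sps.hypergeom.pmf(t.n11, *args))
    upper = float(sps.hypergeom.sf(t.n11, *args)) + 0.5 * pm
    if alternative == "greater":
        return min(max(upper, np.nextafter(0, 1)), 1.0)
    if alternative == "two-sided":
        lower = float(sps.hypergeom.cdf(t.n11 - 1, *args)) + 0.5 * pm
        return min(max(2 * min(upper, lower), np.nextafter(0, 1)), 1.0)
    raise ArgumentError(f"unknown alternative: {alternative!r}")


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, aligned to input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ArgumentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def mh_adjusted_ror(s: StratifiedTable) -> RORResult:
    """Mantel-Haenszel common odds ratio across age strata with the
    Robins-Breslow-Greenland 95% interval.

    Strata with an empty total were already skipped at construction; the
    estimate is ``sum_k(a_k d_k / n_k) / sum_k(b_k c_k / n_k)``.
    """
    if len(s) == 0:
        raise ArgumentError("stratified table has no usable strata")
    denom = sum(t.n10 * t.n01 / t.n for t in s.tables())
    if denom == 0:
        raise ArgumentError(
            "Mantel-Haenszel denominator sum(b*c/n) is zero; estimate infinite"
        )
    arr = np.array([[[t.n11, t.n10], [t.n01, t.n00]] for t in s.tables()],
                   dtype=float)
    sm = _SMStrat(np.moveaxis(arr, 0, -1))
    est = float(sm.oddsratio_pooled)
    lo, hi = (float(x) for x in sm.oddsratio_pooled_confint(alpha=0.05))
    return RORResult(estimate=est, ci_low=lo, ci_high=hi,
                     method="mantel_haenszel_rbg")


def ror_signal_set(results: Mapping[Hashable, RORResult],
                   alpha: float = 0.05) -> set[Hashable]:
    """Keys flagged by the ROR decision rule: estimate above 1 and
    BH-adjusted mid-p below ``alpha``."""
    out = set()
    for key, r in results.items():
        if r.p_adj is None:
            raise ArgumentError(f"result {key!r} lacks an adjusted p-value")
        if r.estimate > 1 and r.p_adj < alpha:
            out.add(key)
    return out


# ---------------------------------------------------------------------------
# Cross-level confirmation

def cross_level_confirm(signals: set[tuple[str, str]],
                        h: TermHierarchy) -> dict[tuple[str, str], bool]:
    """Flag each ``(term, level)`` signal as confirmed when at least one
    associated term (ancestor or descendant) is also a signal within the
    same exposure comparison. Unconfirmed signals are retained, flagged
    ``False``."""
    out: dict[tuple[str, str], bool] = {}
    for term, level in signals:
        related = associated_terms(h, term, level)
        out[(term, level)] = any(pair in signals for pair in related)
    return out


# ---------------------------------------------------------------------------
# Combined per-pair record

@dataclass
class SignalResult:
    """Everything the pipeline knows about one (comparison, term) pair."""

    term: str
    level: str
    comparison: str
    n11: int
    ic: ICResult | None = None
    bayes_fdr: float | None = None
    ror: RORResult | None = None
    adj_ror: RORResult | None = None
    ic_signal: bool = False
    ror_signal: bool = False
    cross_level_confirmed: bool = False
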