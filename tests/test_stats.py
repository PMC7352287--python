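import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from pvsignal.contingency import ContingencyTable, StratifiedTable
from pvsignal.errors import ArgumentError
from pvsignal.hierarchy import TermHierarchy
from pvsignal.stats import (ICResult, bayesian_fdr, bcpnn_ic,
                            bh_adjust, cross_level_confirm, crude_ror,
                            ic_signal_set, midp_value, mh_adjusted_ror,
                            ror_signal_set, RORResult)


# ---------------------------------------------------------------------------
# BCPNN information component

def test_no_cooccurrence_gives_negative_ic_and_high_p_null():
    t = ContingencyTable(0, 1, 1, 99998)
    r = bcpnn_ic(t)
    assert r.e_ic < 0 and r.p_null > 0.5


def test_independence_shrinks_ic_to_zero():
    # n11 = n1. * n.1 / N exactly
    t = ContingencyTable(10, 990, 990, 98010)
    assert abs(bcpnn_ic(t).e_ic) < 0.05


def test_undefined_margin_is_error():
    with pytest.raises(ArgumentError):
        bcpnn_ic(ContingencyTable(0, 0, 5, 5))


def _mc_posterior_ic(t, seed, n=10**6):
    """Independent Monte-Carlo oracle: conjugate Beta posteriors of the
    joint and marginal reporting probabilities, IC sampled directly."""
    rng = np.random.default_rng(seed)
    a1 = b1 = g11 = 1.0
    a = b = 2.0
    g = g11 * (t.n + a) * (t.n + b) / ((t.n1_ + a1) * (t.n_1 + b1))
    p11 = rng.beta(t.n11 + g11, t.n - t.n11 + g - g11, n)
    p1 = rng.beta(t.n1_ + a1, t.n - t.n1_ + a - a1, n)
    p_1 = rng.beta(t.n_1 + b1, t.n - t.n_1 + b - b1, n)
    return float(np.mean(np.log2(p11 / (p1 * p_1))))


@pytest.mark.parametrize("cells", [
    (100, 900, 900, 98100),      # 10-fold overreporting
    (50, 1950, 400, 37600),
    (200, 4800, 2000, 93000),
])
def test_closed_form_matches_monte_carlo_posterior(cells):
    t = ContingencyTable(*cells)
    closed = bcpnn_ic(t).e_ic
    assert closed == pytest.approx(_mc_posterior_ic(t, seed=42), abs=0.02)


def test_p_null_is_half_at_zero_ic():
    r = ICResult(e_ic=0.0, v_ic=0.25,
                 p_null=float(sps.norm.cdf(0.0)))
    assert r.p_null == 0.5


# ---------------------------------------------------------------------------
# Bayesian FDR ranking

def _ic(p_null):
    return ICResult(e_ic=1.0, v_ic=1.0, p_null=p_null)


def test_single_item_fdr_is_its_p_null():
    (r,) = bayesian_fdr([("k", _ic(0.2), 5)])
    assert r.bayes_fdr == pytest.approx(0.2)


def test_running_mean_oracle():
    ranked = bayesian_fdr([
        ("a", _ic(0.5), 1), ("b", _ic(0.01), 2), ("c", _ic(0.03), 3),
    ])
    assert [r.key for r in ranked] == ["b", "c", "a"]
    assert [r.bayes_fdr for r in ranked] == pytest.approx(
        [0.01, 0.02, 0.18])


def test_constant_p_null_gives_constant_fdr():
    ranked = bayesian_fdr([(k, _ic(0.5), 1) for k in "abc"])
    assert all(r.bayes_fdr == pytest.approx(0.5) for r in ranked)


def test_fdr_is_monotone_along_ranking():
    rng = np.random.default_rng(5)
    items = [(i, _ic(float(p)), 1) for i, p in enumerate(rng.random(50))]
    ranked = bayesian_fdr(items)
    fdrs = [r.bayes_fdr for r in ranked]
    assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))


def test_ties_broken_by_n11_then_key():
    ranked = bayesian_fdr([
        ("z", _ic(0.1), 5), ("a", _ic(0.1), 5), ("m", _ic(0.1), 9),
    ])
    assert [r.key for r in ranked] == ["m", "a", "z"]


# ---------------------------------------------------------------------------
# IC decision rule

def test_ic_signal_rules():
    ranked = bayesian_fdr([
        ("count_fail", ICResult(1.2, 1.0, 0.001), 2),
        ("sign_fail", ICResult(-0.1, 1.0, 0.001), 50),
        ("ok", ICResult(0.8, 1.0, 0.002), 10),
        ("fdr_fail", ICResult(0.5, 1.0, 0.9), 10),
    ])
    assert ic_signal_set(ranked) == {"ok"}


def test_tightening_fdr_threshold_never_grows_signal_set():
    rng = np.random.default_rng(9)
    ranked = bayesian_fdr([
        (i, ICResult(float(rng.normal()), 1.0, float(p)), int(rng.integers(1, 20)))
        for i, p in enumerate(rng.random(40))
    ])
    prev = None
    for thr in (0.2, 0.1, 0.05, 0.01):
        cur = ic_signal_set(ranked, fdr_threshold=thr)
        if prev is not None:
            assert cur <= prev
        prev = cur


# ---------------------------------------------------------------------------
# Crude ROR

def test_gbs_ror_eb_vs_others():
    # oracle: (5/960) / (6/10750) = 9.3316...
    r = crude_ror(ContingencyTable(5, 960, 6, 10750))
    assert r.estimate == pytest.approx(9.33, abs=0.005)
    assert not r.zero_cell_corrected


def test_gbs_ror_dt_vs_others():
    # oracle: (4*3303)/(8407*7) = 0.2245...
    r = crude_ror(ContingencyTable(4, 8407, 7, 3303))
    assert r.estimate == pytest.approx(0.22, abs=0.005)


def test_all_ones_is_unity():
    assert crude_ror(ContingencyTable(1, 1, 1, 1)).estimate == 1.0


def test_zero_cell_triggers_haldane_correction():
    r = crude_ror(ContingencyTable(0, 10, 5, 85))
    assert r.zero_cell_corrected
    assert r.estimate == pytest.approx((0.5 * 85.5) / (10.5 * 5.5))
    assert r.ci_low < r.estimate < r.ci_high


def test_two_empty_margins_is_error():
    with pytest.raises(ArgumentError):
        crude_ror(ContingencyTable(0, 0, 0, 10))


def test_woolf_ci_brackets_estimate():
    r = crude_ror(ContingencyTable(20, 80, 10, 90))
    se = math.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
    assert r.ci_low == pytest.approx(r.estimate * math.exp(-1.959964 * se), rel=1e-5)


@given(st.tuples(st.integers(1, 30), st.integers(1, 30),
                 st.integers(1, 30), st.integers(1, 30)))
def test_swapping_exposure_inverts_ror(cells):
    t = ContingencyTable(*cells)
    prod = crude_ror(t).estimate * crude_ror(t.swapped()).estimate
    assert prod == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Mid-p

def test_midp_enumerated_two_by_two():
    # N=2, n1.=1, n.1=1: pmf over n11 is {0: 1/2, 1: 1/2}
    assert midp_value(ContingencyTable(0, 1, 1, 0)) == pytest.approx(0.75)


def test_midp_enumerated_all_ones():
    # N=4, n1.=n.1=2: pmf {0: 1/6, 1: 4/6, 2: 1/6}
    assert midp_value(ContingencyTable(1, 1, 1, 1)) == pytest.approx(0.5)


def test_midp_at_support_maximum_is_half_point_mass():
    t = ContingencyTable(2, 0, 0, 2)  # n11 at max of support
    hg = sps.hypergeom(4, 2, 2)
    assert midp_value(t) == pytest.approx(0.5 * hg.pmf(2))
    assert midp_value(t) <= 0.5


@given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                 st.integers(0, 12), st.integers(0, 13)))
def test_midp_no_larger_than_fisher_one_sided(cells):
    if sum(cells) == 0:
        cells = (1, 1, 1, 1)
    t = ContingencyTable(*cells)
    fisher = sps.fisher_exact([[t.n11, t.n10], [t.n01, t.n00]],
                              alternative="greater")[1]
    assert midp_value(t) <= fisher + 1e-12


def test_two_sided_midp_option():
    t = ContingencyTable(1, 1, 1, 1)
    assert midp_value(t, alternative="two-sided") == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def test_bh_single_p_unchanged():
    assert bh_adjust([0.03]) == [pytest.approx(0.03)]


def test_bh_hand_computed_step_up():
    assert bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])


def test_bh_all_ones_capped():
    assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]


def test_bh_rejects_out_of_range():
    for bad in ([0.0], [1.5], [-0.1]):
        with pytest.raises(ArgumentError):
            bh_adjust(bad)


def test_bh_aligned_to_input_order():
    p = [0.04, 0.01, 0.20]
    adj = bh_adjust(p)
    # oracle: sorted (0.01, 0.04, 0.20) -> (0.03, 0.06, 0.20), re-aligned
    assert adj == pytest.approx([0.06, 0.03, 0.20])


# ---------------------------------------------------------------------------
# Mantel-Haenszel

def _strat(*tables):
    return StratifiedTable([(str(i), t) for i, t in enumerate(tables)], (0.0,))


def test_single_stratum_collapses_to_crude():
    t = ContingencyTable(10, 90, 5, 95)
    assert mh_adjusted_ror(_strat(t)).estimate == pytest.approx(
        crude_ror(t).estimate)


def test_identical_strata_preserve_estimate():
    t = ContingencyTable(10, 90, 5, 95)
    assert mh_adjusted_ror(_strat(t, t)).estimate == pytest.approx(
        crude_ror(t).estimate)


def test_two_strata_closed_form_oracle():
    # sum(ad/n)/sum(bc/n) = (4.75 + 9) / (2.25 + 4) = 2.2
    s = _strat(ContingencyTable(10, 90, 5, 95),
               ContingencyTable(20, 80, 10, 90))
    r = mh_adjusted_ror(s)
    assert r.estimate == pytest.approx(2.2)
    assert r.ci_low < 2.2 < r.ci_high


def test_scaled_strata_equal_crude():
    t = ContingencyTable(10, 90, 5, 95)
    scaled = ContingencyTable(30, 270, 15, 285)
    assert mh_adjusted_ror(_strat(t, scaled)).estimate == pytest.approx(
        crude_ror(t).estimate)


def test_zero_denominator_is_error():
    s = _strat(ContingencyTable(5, 0, 0, 5))
    with pytest.raises(ArgumentError):
        mh_adjusted_ror(s)


# ---------------------------------------------------------------------------
# ROR decision rule and cross-level confirmation

def _ror(est, p_adj):
    return RORResult(estimate=est, ci_low=est / 2, ci_high=est * 2,
                     method="crude_woolf", midp=p_adj / 2, p_adj=p_adj)


def test_ror_signal_rules():
    results = {
        "in": _ror(3.3, 0.01),
        "direction_fail": _ror(0.9, 0.001),
        "threshold_fail": _ror(2.0, 0.06),
    }
    assert ror_signal_set(results) == {"in"}


def test_cross_level_confirmation(hierarchy):
    signals = {
        ("stevens-johnson syndrome", "PT"),
        ("epidermal and dermal conditions", "HLGT"),
        ("colitis", "PT"),
    }
    confirmed = cross_level_confirm(signals, hierarchy)
    assert confirmed[("stevens-johnson syndrome", "PT")]
    assert confirmed[("epidermal and dermal conditions", "HLGT")]
    assert not confirmed[("colitis", "PT")]  # isolated signal


def test_hlt_and_child_pt_confirm_each_other():
    toy = TermHierarchy([
        ("pt a", "hlt x", "hlgt x", "soc x"),
        ("pt b", "hlt x", "hlgt x", "soc x"),
    ])
    confirmed = cross_level_confirm({("hlt x", "HLT"), ("pt a", "PT")}, toy)
    assert confirmed == {("hlt x", "HLT"): True, ("pt a", "PT"): True}
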