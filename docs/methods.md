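# Methods

`pvsignal` implements a two-tier disproportionality analysis of
spontaneous adverse-event reports, as used to compare serious adverse
events (sAEs) across the three BRAF+MEK inhibitor combinations —
vemurafenib+cobimetinib (V+C), dabrafenib+trametinib (D+T) and
encorafenib+binimetinib (E+B) — against an FAERS-like report database.
This note records the model, the defaults, the numerical choices, and
what the synthetic data can and cannot show.

## Report model and filtering

A *report* is one deduplicated safety record: demographics, a set of
outcome codes, a list of drugs with reporter-assigned causal roles
(primary/secondary suspect, concomitant, interacting), and a list of
reactions coded as MedDRA-style preferred terms (PTs). A report is
**serious** iff its outcomes intersect {death, life-threatening,
hospitalization, disability}.

* **Deduplication** groups reports by case id and keeps the highest case
  version, breaking ties by latest receipt date, then lexicographically
  largest report id. This follows the convention for FAERS quarterly
  extracts, where follow-up submissions share a case id; the rule is
  deterministic and idempotent.
* **Period filter** applies to the receipt date (FAERS quarters are
  organized by receipt). The default window is 2018-01-01..2019-12-31.
  (The source cohort's own description is internally inconsistent —
  one passage says "through June 2019", another "to December 2019"; the
  package defaults to the December reading and exposes the window in
  configuration.)
* **Partial dates** (year or year-month) are kept as partial. They can
  satisfy a window filter under interval-overlap semantics (the date
  passes if any completion falls inside the window) but count as missing
  for day-level arithmetic such as time-to-onset. No component is ever
  imputed.
* **Term normalization** case-folds, strips accents, maps en/em dashes
  to hyphens and collapses whitespace, so "Guillain–Barré" and
  "guillain-barre" compare equal.
* **General-term exclusion**: administrative PTs (default list ships as
  an editable text file containing "off-label use") are removed from
  reports; a report left with no reactions is dropped and counted.
  Death-as-an-event and neoplasm-related terms are likewise excluded
  from disproportionality analysis (configured as hierarchy categories:
  the "fatal outcomes" HLGT and the neoplasms SOC), because staging and
  cause-of-death context is unavailable in spontaneous reports.
* **Combination attribution**: a report belongs to a drug combination
  iff both drugs appear with primary- or secondary-suspect roles.

Each filter logs its removal count; the provenance log satisfies
`|in| = |out| + Σ removals`.

## Term hierarchy

Analyses run at a chosen level of the PT → HLT → HLGT → SOC hierarchy.
MedDRA itself is licensed and cannot ship; users supply a four-column
TSV. A ~40-term toy hierarchy covering the terms used in the
documentation is bundled for tests and demos. Roll-up counts distinct
reports: a report with several PTs under one group term contributes one.
"Associated terms" of a term are its ancestor/descendant closure (not
siblings); this is the relation used for cross-level signal
confirmation.

## Tier 1 — information component vs the full database

For a 2×2 table with cells n11 (exposed, event), n10, n01, n00, margins
n1·, n·1 and total N, the BCPNN information component is
IC = log2 [ p11 / (p1· p·1) ], estimated with conjugate Beta/Dirichlet
priors. The closed-form posterior moments are

    E[IC] = log2[ (n11+γ11)(N+α)(N+β) / ((N+γ)(n1·+α1)(n·1+β1)) ]
    V[IC] = (1/ln 2)² [ (N−n11+γ−γ11)/((n11+γ11)(1+N+γ))
                      + (N−n1·+α−α1)/((n1·+α1)(1+N+α))
                      + (N−n·1+β−β1)/((n·1+β1)(1+N+β)) ]

with α1 = β1 = γ11 = 1, α = β = 2 and
γ = γ11 (N+α)(N+β) / ((n1·+α1)(n·1+β1)), chosen so the prior IC
expectation is 0. This is the original posterior-moment formulation,
not the later credibility-interval variant; the closed-form mean is an
approximation to the exact posterior mean of log2(p11/(p1·p·1)) whose
error is below 0.01–0.02 for n11 ≳ 50 and grows to ~0.04 for n11 ≤ 5
(the test suite checks it against a 10⁶-draw Monte-Carlo posterior on
moderate-count tables).

The posterior null probability is p_null = Φ(−E[IC]/√V[IC]) (normal
approximation). Pairs are ranked by p_null (ties: n11 descending, then
key), and the **Bayesian FDR** at rank k is the running mean
(Σ_{i≤k} p_null(i))/k — the posterior expected false-discovery
proportion if everything up to rank k is declared. The tier-1 decision
rule flags a pair iff E[IC] > 0, n11 ≥ 3, and Bayesian FDR < 0.05.

Tier-1 tables are built in the case/non-case (full-database) scope: the
exposure group's reports versus all other reports, with the exposure
group included in N. Terms must pass the **minimum-report filter**:
count ≥ ⌈0.005 × group total⌉ in at least one exposure group (5 reports
in a 965-report group).

## Tier 2 — reporting odds ratios between combinations

Terms shortlisted by tier 1 (signals plus their associated terms, at the
configured levels) are compared between combinations: one regimen's
reports versus the other regimens' reports, the rest of the database
excluded. The crude ROR is the cross-product (n11 n00)/(n10 n01) with
Woolf 95% CI exp(ln OR ± 1.96 √(1/n11+1/n10+1/n01+1/n00)). If any cell
is zero, the Haldane–Anscombe correction (0.5 to every cell) is applied
to estimate and CI and flagged in the output; a table with two empty
margins is undefined.

Inference uses the one-sided **mid-p** exact test toward excess
reporting: with margins fixed, X ~ Hypergeometric(N, n1·, n·1) and
p = P(X > n11) + ½ P(X = n11). One-sided matches the ROR > 1 decision
rule; a two-sided variant is available behind a flag. Mid-p values are
Benjamini–Hochberg adjusted within one family = all terms at one
hierarchy level for one exposure comparison after the minimum-report
filter (the narrowest defensible family; recorded in output metadata).
A pair is a tier-2 signal iff ROR > 1 and adjusted p < 0.05. Signals are
then **cross-level confirmed**: flagged true iff an associated term is
also a signal in the same comparison; unconfirmed signals are retained
but flagged false.

**Age adjustment** uses the Mantel–Haenszel common odds ratio over age
strata (default ten-year bins [0,10), …, [80,∞); reports with missing
age are excluded from the adjusted analysis only and counted), with the
Robins–Breslow–Greenland variance for the 95% CI. Strata with no
records are skipped and listed. Computation delegates to
`statsmodels.stats.contingency_tables.StratifiedTable`; tests verify the
estimate against the closed form Σ(a_k d_k/n_k) / Σ(b_k c_k/n_k) and
the single-stratum collapse to the crude OR.

The "+0.1" constant occasionally seen in log-scale bar charts of RORs is
implemented strictly as a display transform (`display_ror`), applied and
labelled only in the export layer, never in inference.

## Clinical characterization

For flagged events, per regimen:

* **Dose category** relative to the combination's recommended total
  daily dose (960/60 mg V+C, 150/2 mg D+T, 450/45 mg E+B):
  `at_recommended` iff both drugs at recommendation; `below` iff both ≤
  with one strictly below; `above` iff any strictly above; `unreported`
  iff any dose missing. Doses are interpreted as daily doses; g↔mg
  conversion is supported, other units raise.
* **Time to onset** = reaction onset minus the earliest complete
  suspect-drug start (same day = 0); negative or partial-date intervals
  are missing, never fabricated. Summaries are median and quartiles by
  linear interpolation (the common default; printed IQRs cannot
  disambiguate the convention).
* **Outcome tabulation** counts reports per outcome code over distinct
  reports carrying the event; categories are not mutually exclusive, so
  columns may sum above 100%. Dechallenge/rechallenge positives are
  tabulated over reports where any suspect drug carries a positive or
  negative code.
* **Percentages** are rounded half away from zero to the requested
  decimals (matching printed-table conventions such as 311/2345 → 13.3%
  and 19/212 → 9%).

## Synthetic data generator

`simulate.generate_reports` emits a seeded FAERS-like database: three
regimens at the study volumes (2,345 / 8,411 / 965 reports by default)
plus a 20,000-report background pool of unrelated drugs. Per report:
the regimen's two drugs as primary/secondary suspects (order
randomized) with 0–3 concomitants; reactions drawn per-PT Bernoulli
with background probability 0.01 (default), multiplied by the injected
relative reporting rate (RR) for injected (regimen, PT) pairs, capped
at 0.95; ages from the per-regimen normal distributions reported for
the cohort (means 58.8/59.4/62.9, SDs 14.1/16.0/13.0), truncated at 0,
with 15% missingness; sex mixes per regimen (including the
mostly-unreported third regimen); receipt dates uniform in the analysis
window; therapy start uniform with a log-normal onset lag (μ=3.0,
σ=0.9 log-days, ≈20-day median); doses placed below/at/above the
recommendation (25/25/10%, 40% unreported); outcome codes drawn
independently (death 15%, life-threatening 8%, hospitalization 85%,
disability 3%, other 35%) with hospitalization forced when no serious
code was drawn — every generated report is an sAE report by
construction; dechallenge/rechallenge codes drawn from fixed
categoricals. Values the source cohort does not state were fixed once
at these field-realistic levels.

A report whose Bernoulli draws produce no reaction receives a
nonspecific filler PT ("adverse event nos") that is deliberately not in
the hierarchy: it lands in the unmapped bucket at analysis, so reports
are never empty while every mapped term's count remains exactly
Binomial(n, p·RR) — the property the recovery tests rely on.
`inject_duplicates` re-emits a seeded sample of cases with incremented
versions and perturbed receipt dates to exercise deduplication. One
`numpy` generator seeded from the configuration drives everything; a
configuration reproduces identical output bytes.

What the generator does **not** model: reporting heterogeneity of real
spontaneous data (stimulated reporting, the Weber effect, notoriety
bias), drug-drug masking, correlated reaction co-occurrence, or
patient-level linkage across reports. Passing calibration on this
generator therefore shows the statistics are implemented correctly and
behave as designed under clean conditions, not that real-world FAERS
signals at these thresholds carry the same error rates.

## Seeded experiments

Three scenario runners (`pvsignal.experiments`) back both the test suite
and the acceptance script; each pushes generated data through the same
roll-up / contingency / decision-rule path as the pipeline:

* **Null calibration** — two regimens of 2,345 reports plus a
  15,000-report background, 200 candidate PTs in a regular synthetic
  hierarchy, all RR = 1, per-pair expected co-report count ≈ 35
  (background probability 0.015). Measured over 20 replicates: the
  fraction of the 400 (regimen, PT) pairs flagged by the IC rule, and
  the ROR rule's per-replicate false-discovery proportion (on null data,
  1 if anything is flagged, else 0; under the global null its expectation
  is roughly the BH level accumulated over the two comparison families,
  i.e. just under 0.1).
* **Power** — same conditions with background probability 0.002 and 8
  pairs injected at RR = 10 in one regimen (expected n11 ≈ 47);
  sensitivity of the conjunction of both rules over 20 replicates.
* **Adjustment recovery** — 50,000 reports in two arms; the exposed
  arm's patients are drawn mostly old (80% from N(70,6) vs 20%), the
  event's baseline reporting probability is 0.06 at age ≥ 60 vs 0.01
  below, and within every age the exposed reporting odds are 3× the
  comparator's. The crude ROR is confounded upward (≈ 7.4); the
  MH-adjusted estimate over ten-year strata should recover 3.0.

These problem sizes (desk scale) were chosen once as the smallest
configurations at which the binomial/normal error bounds quoted in the
tests have comfortable slack.

## Numerical choices and degenerate inputs

* Hypergeometric tail mass via `scipy.stats.hypergeom` (`sf`/`pmf`);
  mid-p values are clamped to (0, 1].
* Bayesian-FDR ranking ties broken by n11 descending then key string,
  for deterministic output.
* Zero-report exposure groups, empty age-bin lists, windows with
  start > end, fractions outside (0,1) and conflicting hierarchy
  parentage raise typed errors (`ArgumentError`, `IntegrityError`, …);
  the CLI maps configuration errors to exit code 2 and data errors to 3.
* An all-ages-missing stratification returns an empty stratified table
  with a warning rather than raising.
* Dose-category equality uses a 1e-9 relative tolerance.

## Known limitations

* The printed headline age-adjusted RORs and IC values of the source
  cohort are not reproducible from published margins (they require the
  raw report-level extract and unpublished age strata); the package
  reproduces the *methods*, validated against derived oracles and
  simulation, not those specific numbers.
* The FAERS ASCII reader covers the post-2012 quarterly layout only
  (no legacy LAERS), and no SMQ support is provided.
* p_null uses a normal approximation of the IC posterior; for very
  small n11 the approximation and the closed-form moments are both
  coarse (shrinkage keeps such pairs out of the signal set via the
  n11 ≥ 3 rule).
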