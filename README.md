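# pvsignal

Safety-signal detection for spontaneous adverse-event report databases,
built around the two-tier disproportionality workflow used to compare
serious adverse events (sAEs) across the three BRAF+MEK inhibitor
combinations — vemurafenib+cobimetinib (V+C), dabrafenib+trametinib
(D+T) and encorafenib+binimetinib (E+B) — in FAERS-style data.

It is aimed at pharmacovigilance analysts and methods researchers who
want the full pipeline — ingestion, deduplication, MedDRA-style term
roll-up, signal statistics, clinical characterization — as tested,
reusable Python, with a seeded synthetic-report generator so every
stage can be validated against known ground truth without access to a
real extract.

## The statistics

For a drug–event pair with 2×2 cells *n₁₁* (exposed with event), *n₁₀*,
*n₀₁*, *n₀₀*, margins *n₁.*, *n.₁* and total *N*:

* **Tier 1 — information component (BCPNN)** against the full database:
  IC = log₂[p₁₁/(p₁.p.₁)] with conjugate-prior shrinkage,
  E[IC] = log₂[(n₁₁+γ₁₁)(N+α)(N+β) / ((N+γ)(n₁.+α₁)(n.₁+β₁))]
  (defaults α₁=β₁=γ₁₁=1, α=β=2, γ tuned so the prior IC is 0).
  Pairs are ranked by the posterior null probability
  p_null = Φ(−E[IC]/√V[IC]) and thresholded on the cumulative
  **Bayesian FDR** (running mean of p_null). A signal needs E[IC] > 0,
  n₁₁ ≥ 3 and Bayesian FDR < 0.05.
* **Tier 2 — reporting odds ratio (ROR)** between combinations:
  ROR = (n₁₁n₀₀)/(n₁₀n₀₁) with Woolf 95% CI, one-sided **mid-p** exact
  tests (P(X > n₁₁) + ½P(X = n₁₁), X hypergeometric), and
  Benjamini–Hochberg correction within each comparison family; a signal
  needs ROR > 1 and adjusted p < 0.05, and is cross-level confirmed when
  an associated hierarchy term is also flagged.
* **Age adjustment** — Mantel–Haenszel common OR over ten-year age
  strata, Σ(aₖdₖ/nₖ)/Σ(bₖcₖ/nₖ), with the Robins–Breslow–Greenland CI.

Only terms with at least 0.5% of a group's reports (⌈0.005·n⌉, i.e. 5
reports in a 965-report group) enter the analysis. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a synthetic database (toy hierarchy, study-scale volumes:
2,345 / 8,411 / 965 regimen reports plus a 20,000-report background
pool, five injected associations), then run the full pipeline:

```bash
pvsignal simulate --out demo --seed 7
cat > demo/config.yaml <<EOF
input_path: demo/reports.tsv
output_dir: demo/run
EOF
pvsignal report --config demo/config.yaml
```

which prints

```
{"level": "info", "stage": "simulate", "message": "wrote 33291 reports to demo"}
{"output_dir": "demo/run", "stages": ["ingest", "select_combinations",
 "tier1_ic", "tier2_ror", "clinical", "write_outputs"], "n_results": 34}
```

`demo/run/signals.tsv` then contains one row per (comparison, term,
level). The rows flagged as ROR signals in this run:

```
comparison      term                                     level  n11  ror    95% CI        p_adj     adj_ror
V+C vs others   epidermal and dermal conditions          HLGT   400  2.08   1.83-2.37     1.0e-26   2.15
V+C vs others   rash                                     PT      87  3.45   2.58-4.60     3.0e-15   3.44
V+C vs others   stevens-johnson syndrome                 PT     186  7.04   5.55-8.93     9.8e-58   7.21
D+T vs others   body temperature conditions              HLGT   488  2.03   1.63-2.54     9.8e-12   1.99
D+T vs others   pyrexia                                  PT     313  3.83   2.67-5.49     1.1e-17   3.71
E+B vs others   gastrointestinal inflammatory conditions HLGT    27  3.08   2.00-4.74     4.4e-06   2.67
E+B vs others   colitis                                  PT      27  3.08   2.00-4.74     1.1e-05   2.67
E+B vs others   peripheral neuropathies                  HLGT   111  3.37   2.70-4.20     7.1e-22   3.29
E+B vs others   guillain-barre syndrome                  PT      76  10.21  7.46-13.96    2.4e-38   10.24
```

Every flagged term is one of the generator's five injected associations
(rash and Stevens–Johnson syndrome in V+C, pyrexia in D+T, colitis and
Guillain–Barré syndrome in E+B) or its parent group term, each
cross-level confirmed; `n11` is the number of exposed reports with the
event, `ror` the crude reporting odds ratio against the other two
combinations, and `adj_ror` its Mantel–Haenszel age-adjusted
counterpart. `demo/run/clinical.tsv` tabulates outcomes, dose
categories, de/rechallenge and time-to-onset for the flagged events,
and `demo/run/manifest.json` records the configuration, filter counts
and stage log. Re-running with the same seed and config reproduces the
outputs byte for byte.

The same workflow applies to real data: point `input_path` at a
normalized TSV (or a directory of FAERS quarterly ASCII files with
`dialect: faers_ascii`) and supply your licensed MedDRA mapping via
`hierarchy_path`.

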