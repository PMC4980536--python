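# targetprofiler

Druggability profiling of drug targets, built around the comparison of
**established targets** (proteins hit by at least one approved drug) with
**clinical-trial targets** (proteins so far hit only by drugs in phase 1–3
trials). The motivating case is the human kinome, where a small set of
approved kinase inhibitors coexists with a much larger clinical pipeline,
but every component is generic over target classes.

The package provides four analysis layers plus a synthetic-data generator:

1. **Sequence similarity with E-value classes** — an exact Smith–Waterman
   local aligner with affine gaps (BLOSUM62, gap open 11 / extend 1 by
   default) and Karlin–Altschul statistics: λ is the positive root of
   Σᵢⱼ pᵢ pⱼ exp(λ sᵢⱼ) = 1 and K comes from the classical lattice series,
   giving E = K·m·n·e^(−λS). Pairwise similarity is classified as
   *very similar* (E ≤ 0.001), *marginally similar* (0.001 < E ≤ 0.1) or
   *unsimilar* (E > 0.1), and a target's NS statistic counts similar
   proteins outside its own family. A reader for BLAST `-outfmt 6` tables
   is included for interoperability.
2. **System profiles** — the (NS, NP, NT) triple per target (similar
   proteins outside the family, affiliated signaling pathways, tissues of
   expression) with the systems-level druggability rules NS < 15, NP ≤ 3,
   NT ≤ 5; per-cohort compliance percentages, binned distributions,
   boxplot statistics with Tukey whiskers, and the median-trend check
   across development stages (established → phase 3 → phase 2 → phase 1).
3. **Promising-target rule** — a target similar to established targets in
   at least 3 of the 4 profiles (A sequence, B binding-domain fold,
   C physicochemical, D system) is "promising"; a retrospective evaluator
   parses free-text development-status strings (approved / positive
   phase 3 / negative-or-discontinued / unknown) and cross-tabulates
   outcomes, including the packaged 16-target phase 3 scorecard.
4. **Drug–target networks** — strictly bipartite interaction graphs with
   typed nodes and activation/inhibition edges; degree histograms, popular
   targets (degree above a threshold), multitarget drugs (degree ≥ 2),
   ICD disease-class subnetworks (e.g. C51–C58, malignant neoplasms of
   female genital organs), and Cytoscape-compatible export (SIF, GraphML,
   attribute tables).
5. **Synthetic data** — cohort generators with named count distributions
   (negative binomial by default, medians ascending through the clinical
   phases), mutation-derived protein families with controllable identity,
   and exact bipartite realization of prescribed degree sequences
   (Gale–Ryser feasibility check plus a deterministic greedy
   construction), including the canonical printed degree histograms
   (46 approved drugs × 25 targets; 13 drugs × 9 targets in the C51–C58
   subnetwork).

## Worked example

The packaged phase 3 scorecard lists 16 targets that satisfied the
≥3-of-4-profile rule, with their later development outcomes as free text.

```bash
targetprofiler druggability
```

prints

```text
status	count	pct	pct_printed	count_promising	count_not_promising
approved	5	31.25	31	5	0
positive_phase3	6	37.5	37	6	0
negative_or_discontinued	0	0.0	0	0	0
other	5	31.25	31	5	0
```

Reading: of the 16 predicted-promising targets, 5 (31% in truncated
display style) were approved and a further 6 (37%) reached positive
phase 3 results without approval; the remaining 5 had no reported outcome.
Status labels are exclusive with precedence approved > positive >
negative/discontinued, on whole-word keyword matches — a drug "filed for
approval" is not approved, and an approved row is never double-counted as
positive.

The same analysis is available as a library:

```python
from targetprofiler.druggability import evaluate_cohort
from targetprofiler.synthetic import table1_fixture

summary = evaluate_cohort(table1_fixture())
```

An end-to-end demo (synthetic cohorts, similarity classes, compliance
summaries, trend report, network statistics, exports, manifest):

```bash
targetprofiler run-all --out demo_out --seed 1
```

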