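# Methods

## Scope and model

The package compares the *system profiles* of established drug targets
with those of clinical-trial targets, and analyses the bipartite network
of drug–target interactions. A system profile is the count triple
(NS, NP, NT): proteins similar to the target but outside its biochemical
family, affiliated signaling pathways, and tissues of expression. The
systems-level druggability rules used throughout are

- NS < 15 (strict; fewer cross-family homologs → fewer off-target
  liabilities),
- NP ≤ 3 (inclusive; fewer pathway affiliations → fewer side effects),
- NT ≤ 5 (inclusive; narrower tissue expression → efficacy easier to
  achieve).

NS is strict and NP/NT inclusive because that is how the rule thresholds
are stated ("<15", "≤3", "≤5"); the boundary cases NS = 14, NP = 3,
NT = 5 are therefore all compliant and NS = 15 is not.

## Sequence similarity and E-values

Pairwise similarity is the maximum local-alignment score under BLOSUM62
with affine gap penalties (a gap of length L costs open + L·extend;
defaults 11 and 1). The aligner is an exact three-state Gotoh dynamic
program, including gap-switch transitions (an insertion directly
following a deletion pays a fresh opening), so its optimum coincides with
exhaustive enumeration over all local alignments — the equality is tested
against a brute-force oracle on short sequences and against an
independent mature implementation on longer ones. No heuristic seeding is
used: the cohorts involved are small enough for exact DP.

Scores map to expectations via the Karlin–Altschul model
E = K·m·n·e^(−λS) with m, n the raw sequence lengths (no edge-effect
correction; the sequences here are short and the classification
thresholds are coarse). λ is the unique positive root of
Σᵢⱼ pᵢ pⱼ e^(λ sᵢⱼ) = 1 (Brent's method, relative tolerance < 1e−12),
requiring a negative expected score and at least one positive score. K
uses the classical series for integer-lattice walks: with per-position
score distribution p(x), span δ = gcd of attainable scores, tilted drift
A = E[X e^(λX)], and

    σ = Σ_{k≥1} (1/k) [ P(S_k ≥ 0) + E(e^{λ S_k}; S_k < 0) ],

K = δ·e^(−2σ) / (A·(1 − e^(−λδ))). The series is evaluated by repeated
convolution of p; 80 terms is far beyond convergence (the terms decay
geometrically because the walk drifts downward). Background frequencies
default to the Robinson–Robinson composition, which reproduces the
standard ungapped BLOSUM62 values λ = 0.3176, K = 0.134. The gapped
scheme reuses the ungapped λ and K — a deliberate simplification (gapped
parameters would need large-scale simulation); it biases E-values
somewhat low, which is immaterial for three-way classification with
thresholds an order of magnitude apart.

Similarity levels partition (0, ∞): E ≤ 0.001 very similar,
0.001 < E ≤ 0.1 marginally similar, E > 0.1 unsimilar, boundaries
inclusive on the more-similar side. A target's similarity to the
established set is best-hit similarity (minimum E over the set). The NS
count uses an E-value criterion with cutoff 0.001 by default — the same
bound as the very-similar class, for internal consistency — exposed as a
parameter because an identity-based criterion is equally defensible.

## Cohort summaries and the median trend

Per cohort, compliance percentages are direct ratios; distributions are
binned with right-open integer bins whose edges place the rule thresholds
on boundaries (NS: 0–4, 5–9, 10–14, 15–19, 20+; NP: unit bins to 4 then
5+; NT: unit bins to 5 then 6+); boxplot statistics are the five-number
summary with Tukey 1.5×IQR whiskers (quartiles by linear interpolation,
numpy's default). "Median trend" checks the cohort medians of one
statistic in development order established → phase 3 → phase 2 → phase 1
for monotone nondecrease and reports the first violating adjacent pair —
the pathway count is the known example of a trend broken at the last
step. Targets absent from an annotation table count 0 with a logged
warning by default; the alternative policy (error) is explicit because
silently excluding targets would change the denominators of every
percentage.

Printed percentages truncate toward zero (31.25 → 31, 37.5 → 37),
matching the display style of the original tables; raw floats are kept
alongside.

## Promising-target rule and status parsing

A target is promising when at least 3 of the 4 profile-similarity flags
(A sequence, B binding-domain structural fold, C physicochemical,
D system) are true. B and C are consumed as given booleans from input
tables: their definitions live in the prior structural and
physicochemical analyses, and this package does not recompute them.

Status strings are classified by whole-word keyword rules applied
case-insensitively with precedence approved > positive >
negative/discontinued > other: "approved" (the word — deliberately not
"approval", so "filed for approval" or "in talks for approval" is not an
approved outcome), then "positive", then "discontinued" / "negative" /
"not approvable". The precedence means an approved target with earlier
positive results counts once, under approved; a positive trial later
discontinued still counts as positive phase 3. On the packaged 16-row
scorecard these rules give 5 approved + 6 positive + 5 unknown, which is
the partition the retrospective evaluation reports.

## Networks

Drug–target graphs are strictly bipartite networkx graphs; duplicate
(drug, target) pairs and dangling ids are construction errors. Degree is
the undirected edge count regardless of activation/inhibition mode.
Popular nodes use a strict threshold (degree > t), multitarget drugs
degree ≥ 2. ICD subnetworks keep every drug with at least one code whose
3-character category falls in the requested range (C54.1 matches
C51–C58) plus those drugs' targets; targets left without a retained drug
are dropped by default since the subnetwork view shows connected
entities (configurable). Exports: SIF (`drug TAB activates|inhibits TAB
target`), GraphML via networkx, and node/edge attribute TSVs.

## Synthetic data

The generators emulate the statistical structure of the original curated
datasets, which were never deposited:

- **Cohorts.** NS/NP/NT are i.i.d. draws from named count distributions;
  the default is negative binomial (mean/dispersion parameterisation,
  variance = μ + μ²/r), which captures the overdispersion of annotation
  counts. The presets place cohort medians in ascending order established
  → phase 3 → phase 2 → phase 1 (NS means 7/9/11/13, NP 2.2/2.6/3.2/3.8,
  NT 2.5/3.0/3.5/4.0, dispersions 5–6), so established-cohort compliance
  sits near 90% and decays through the phases — the qualitative pattern
  the analysis probes. Exact CDFs of the generating distributions are
  exposed, which is what makes parameter-recovery tests analytic
  (empirical compliance at n = 2000 within 3 binomial standard errors of
  the CDF at the threshold).
- **Families.** Each family descends from one random seed sequence by
  per-site point mutation at rate 1 − within-family identity; families
  are independent, so cross-family identity is the background
  coincidence rate Σ pᵢ² (1/20 for the default uniform alphabet, chosen
  to keep that oracle closed-form). Default length 60 keeps all-pairs
  exact alignment fast. What this does *not* emulate: real kinase domains
  share deep homology across families, domain architecture, and
  length variation — so passing tests demonstrate correct machinery, not
  biological conclusions about real proteomes.
- **Degree sequences.** Bipartite realization first checks the
  Gale–Ryser condition (and equal sums), naming the failing condition,
  then builds the graph greedily: drugs in descending-degree order, each
  connected to the targets of largest remaining capacity, ties broken by
  id. The construction is deterministic, so fixtures are reproducible;
  only the degree sequences of the canonical networks are published, not
  the actual wiring, so any realization is one member of the equivalence
  class — all degree-based statistics are invariant over it. The printed
  target-side histogram has no degree-8 class; it is transcribed
  literally, not "corrected".
- **Scorecard.** The 16-row development-status table is shipped verbatim
  as packaged TSV data.

## Pipeline and problem sizes

The demo pipeline simulates 40 targets per cohort and 3 families × 5
members of 60 residues, runs all stages in well under a minute on one
CPU, and writes a manifest listing every output; reruns under the same
seed are byte-identical. In the demo, each family's members are split
round-robin across development stages, reflecting that clinical-trial
kinases are homologs of established ones — which is why the demo's
similarity-level distribution is dominated by the very-similar class.
Statistical tests in the suite use n = 2000 cohorts (3-standard-error
tolerance) and 1,000 random graphs for the invariant checks.

## Known limitations

- Ungapped λ/K applied to gapped alignments (above).
- Effective lengths are raw lengths; no length correction.
- The headline cohort percentages of the original comparative study
  depended on unpublished target lists and live database snapshots
  (sequence, pathway and tissue annotations); they are represented here
  by the synthetic presets' qualitative pattern, not replayed
  numerically.
- `prediction_rates` reports observed fractions only; the historical
  50/25/10/4% per-phase identification rates cannot be re-derived
  without the original per-target flag data.
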