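"""System profiles (NS, NP, NT), druggability compliance rules, and cohort
summaries.

The system profile of a target is the triple of counts

- NS: human proteins similar to the target but outside its biochemical
  family,
- NP: signaling pathways the target is affiliated with,
- NT: tissues the target is expressed in.

The systems-level druggability rules hold that targets with NS < 15,
NP <= 3 and NT <= 5 are more likely to yield safe and efficacious drugs.
This module assembles profiles from annotation tables, applies the rules,
and summarises cohorts: compliance percentages, binned distributions, and
five-number boxplot statistics with Tukey whiskers, including the
median-trend comparison across development stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import (
    EvalueParams,
    SimilarityLevel,
    SimilarityThresholds,
    best_hit_evalue,
    classify_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "STATISTICS",
    "ProfileRuleConfig",
    "SystemProfile",
    "BoxplotStats",
    "CohortSummary",
    "TrendReport",
    "truncate_pct",
    "assemble_profile",
    "assemble_profiles",
    "summarize_cohort",
    "median_trend",
    "similarity_level_distribution",
    "plot_cohort_summaries",
]

#: The three system-profile statistics, in reporting order.
STATISTICS = ("NS", "NP", "NT")

#: Default histogram bin edges per statistic (right-open; last bin open-ended).
#: Rule thresholds fall on bin boundaries.
DEFAULT_BIN_EDGES: dict[str, Sequence[float]] = {
    "NS": (0, 5, 10, 15, 20, np.inf),
    "NP": (0, 1, 2, 3, 4, 5, np.inf),
    "NT": (0, 1, 2, 3, 4, 5, 6, np.inf),
}


@dataclass(frozen=True)
class ProfileRuleConfig:
    """Druggability compliance thresholds.

    NS is compared strictly (< ns_max_exclusive); NP and NT inclusively.
    """

    ns_max_exclusive: int = 15
    np_max_inclusive: int = 3
    nt_max_inclusive: int = 5

    def __post_init__(self) -> None:
        if min(self.ns_max_exclusive, self.np_max_inclusive,
               self.nt_max_inclusive) < 1:
            raise ValueError("rule thresholds must be positive integers")


@dataclass(frozen=True)
class SystemProfile:
    """NS/NP/NT counts for one target plus per-rule compliance flags."""

    target_id: str
    ns: int
    np: int
    nt: int
    compliant_ns: bool
    compliant_np: bool
    compliant_nt: bool

    def count(self, statistic: str) -> int:
        return {"NS": self.ns, "NP": self.np, "NT": self.nt}[statistic]


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number summary with Tukey 1.5*IQR whiskers and outliers."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class CohortSummary:
    """Compliance percentages and distribution summaries for one cohort."""

    cohort_label: str
    n: int
    pct_compliant_ns: float
    pct_compliant_np: float
    pct_compliant_nt: float
    binned_counts: Mapping[str, Mapping[str, int]]
    boxplot_stats: Mapping[str, BoxplotStats]

    def pct_compliant(self, statistic: str) -> float:
        return {"NS": self.pct_compliant_ns, "NP": self.pct_compliant_np,
                "NT": self.pct_compliant_nt}[statistic]


@dataclass(frozen=True)
class TrendReport:
    """Median sequence of one statistic across ordered cohorts."""

    statistic: str
    cohort_labels: tuple[str, ...]
    medians: tuple[float, ...]
    monotone_nondecreasing: bool
    first_violation: tuple[str, str] | None


def truncate_pct(x: float) -> int:
    """Truncate a percentage toward zero for report formatting (37.5 -> 37)."""
    return int(x)


def assemble_profile(
    target_id: str,
    ns_source: Mapping[str, int] | Callable[[str], int],
    pathway_table: pd.DataFrame,
    tissue_table: pd.DataFrame,
    rules: ProfileRuleConfig | None = None,
    missing_policy: str = "zero",
) -> SystemProfile:
    """Assemble one target's system profile from annotation tables.

    NP is the number of distinct pathway ids for the target in
    ``pathway_table`` (columns ``target_id``, ``pathway_id``); NT the number
    of distinct tissue labels in ``tissue_table`` (columns ``target_id``,
    ``tissue_label``).  Duplicated annotation rows count once.  NS comes
    from ``ns_source`` (a mapping or callable, typically backed by the
    similarity engine).

    A target absent from an annotation table is counted as 0 with a logged
    warning under the default ``missing_policy="zero"``; with ``"error"``
    it raises ``KeyError``.
    """
    if rules is None:
        rules = ProfileRuleConfig()
    ns = ns_source(target_id) if callable(ns_source) else ns_source[target_id]

    def _distinct(table: pd.DataFrame, value_col: str, what: str) -> int:
        sub = table.loc[table["target_id"] == target_id, value_col]
        if sub.empty:
            if missing_policy == "error":
                raise KeyError(f"target {target_id!r} absent from {what} table")
            logger.warning("target %s absent from %s table; counting 0",
                           target_id, what)
            return 0
        return int(sub.nunique())

    np_count = _distinct(pathway_table, "pathway_id", "pathway")
    nt_count = _distinct(tissue_table, "tissue_label", "tissue")
    return SystemProfile(
        target_id=target_id,
        ns=int(ns),
        np=np_count,
        nt=nt_count,
        compliant_ns=ns < rules.ns_max_exclusive,
        compliant_np=np_count <= rules.np_max_inclusive,
        compliant_nt=nt_count <= rules.nt_max_inclusive,
    )


def assemble_profiles(
    cohort: pd.DataFrame, rules: ProfileRuleConfig | None = None
) -> list[SystemProfile]:
    """Build profiles directly from a cohort table with NS/NP/NT columns."""
    if rules is None:
        rules = ProfileRuleConfig()
    return [
        SystemProfile(
            target_id=row.target_id,
            ns=int(row.NS), np=int(row.NP), nt=int(row.NT),
            compliant_ns=row.NS < rules.ns_max_exclusive,
            compliant_np=row.NP <= rules.np_max_inclusive,
            compliant_nt=row.NT <= rules.nt_max_inclusive,
        )
        for row in cohort.itertuples()
    ]


def _boxplot_stats(values: np.ndarray) -> BoxplotStats:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return BoxplotStats(
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(values.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )


def _bin_counts(values: np.ndarray, edges: Sequence[float]) -> dict[str, int]:
    """Right-open integer bins [e_k, e_{k+1}); the final bin may be open."""
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(hi):
            labels.append(f"{int(lo)}+")
        elif hi - lo == 1:
            labels.append(f"{int(lo)}")
        else:
            labels.append(f"{int(lo)}-{int(hi) - 1}")
    idx = np.digitize(values, edges[1:-1], right=False)
    counts = {lab: 0 for lab in labels}
    for i in idx:
        counts[labels[int(i)]] += 1
    return counts


def summarize_cohort(
    profiles: Sequence[SystemProfile],
    cohort_label: str,
    bin_edges: Mapping[str, Sequence[float]] | None = None,
) -> CohortSummary:
    """Summarise a cohort of system profiles.

    Percent compliance per rule, histogram counts over the configured bin
    edges (defaults put the rule thresholds on bin boundaries), and boxplot
    statistics per statistic.  Raises on an empty cohort.
    """
    if not profiles:
        raise ValueError("cannot summarise an empty cohort")
    if bin_edges is None:
        bin_edges = DEFAULT_BIN_EDGES
    n = len(profiles)
    values = {
        stat: np.array([p.count(stat) for p in profiles]) for stat in STATISTICS
    }
    return CohortSummary(
        cohort_label=cohort_label,
        n=n,
        pct_compliant_ns=100.0 * sum(p.compliant_ns for p in profiles) / n,
        pct_compliant_np=100.0 * sum(p.compliant_np for p in profiles) / n,
        pct_compliant_nt=100.0 * sum(p.compliant_nt for p in profiles) / n,
        binned_counts={
            stat: _bin_counts(values[stat], bin_edges[stat])
            for stat in STATISTICS
        },
        boxplot_stats={stat: _boxplot_stats(values[stat]) for stat in STATISTICS},
    )


def median_trend(
    summaries: Sequence[CohortSummary], statistic: str
) -> TrendReport:
    """Check the cohort medians of one statistic for an ascending trend.

    ``summaries`` must be in development order (established, phase 3,
    phase 2, phase 1).  Reports the median sequence, whether it is monotone
    nondecreasing, and the first violating adjacent pair if not.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of "
                         f"{STATISTICS}")
    if len(summaries) < 2:
        raise ValueError("median trend needs at least two cohorts")
    labels = tuple(s.cohort_label for s in summaries)
    medians = tuple(s.boxplot_stats[statistic].median for s in summaries)
    violation = None
    for (la, ma), (lb, mb) in zip(
        zip(labels, medians), zip(labels[1:], medians[1:])
    ):
        if mb < ma:
            violation = (la, lb)
            break
    return TrendReport(
        statistic=statistic,
        cohort_labels=labels,
        medians=medians,
        monotone_nondecreasing=violation is None,
        first_violation=violation,
    )


def similarity_level_distribution(
    clinical_targets: Mapping[str, Mapping[str, str]],
    established_sequences: Mapping[str, str],
    params: EvalueParams | None = None,
    thresholds: SimilarityThresholds | None = None,
) -> pd.DataFrame:
    """Per-phase fractions of clinical targets in each similarity level.

    ``clinical_targets`` maps phase label to {target_id: sequence}.  Each
    target's similarity to the established set is its best-hit E-value
    (minimum over the established sequences), classified into the three
    levels.  Phases with zero targets are omitted with a warning.  Returns
    a DataFrame indexed by phase with one column per level; rows sum to 1.
    """
    if not established_sequences:
        raise ValueError("established sequence set is empty")
    if params is None:
        params = EvalueParams()
    if thresholds is None:
        thresholds = SimilarityThresholds()
    rows = {}
    for phase, targets in clinical_targets.items():
        if not targets:
            warnings.warn(f"phase {phase!r} has no targets; omitted")
            continue
        counts = {level: 0 for level in SimilarityLevel}
        for tid, seq in targets.items():
            e = best_hit_evalue(seq, established_sequences, params)
            counts[classify_similarity(e, thresholds)] += 1
        total = len(targets)
        rows[phase] = {level.value: counts[level] / total
                       for level in SimilarityLevel}
    if not rows:
        raise ValueError("no phase had any targets")
    return pd.DataFrame.from_dict(rows, orient="index")[
        [level.value for level in SimilarityLevel]
    ]


def plot_cohort_summaries(
    summaries: Sequence[CohortSummary], path: str, statistic: str = "NS"
) -> None:
    """Export per-cohort histograms and boxplots of one statistic.

    Writes a two-panel figure: binned counts per cohort (grouped bars) and
    side-by-side boxplots drawn from the precomputed five-number summaries
    (Tukey whiskers, outliers as points).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if not summaries:
        raise ValueError("nothing to plot")
    fig, (ax_hist, ax_box) = plt.subplots(1, 2, figsize=(10, 4))
    labels = [s.cohort_label for s in summaries]
    bins = list(summaries[0].binned_counts[statistic])
    width = 0.8 / len(summaries)
    for i, s in enumerate(summaries):
        counts = [s.binned_counts[statistic].get(b, 0) for b in bins]
        ax_hist.bar([x + i * width for x in range(len(bins))], counts,
                    width=width, label=s.cohort_label)
    ax_hist.set_xticks([x + 0.4 for x in range(len(bins))], bins)
    ax_hist.set_xlabel(statistic)
    ax_hist.set_ylabel("targets")
    ax_hist.legend(fontsize="small")

    stats = []
    for s in summaries:
        b = s.boxplot_stats[statistic]
        stats.append({"med": b.median, "q1": b.q1, "q3": b.q3,
                      "whislo": b.whisker_low, "whishi": b.whisker_high,
                      "fliers": list(b.outliers), "label": s.cohort_label})
    ax_box.bxp(stats, showfliers=True)
    ax_box.set_ylabel(statistic)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
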