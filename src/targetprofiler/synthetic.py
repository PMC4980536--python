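"""Synthetic cohorts, sequence families, and bipartite interaction networks.

The comparative analysis this package implements was originally run on
curated target lists that were never deposited, so the generators here
emulate their statistical structure: development cohorts of targets
(established, phase 3/2/1 clinical trial, nonclinical) with controllable
discrete distributions of the three system-profile counts (NS, NP, NT),
protein families with controllable within-family identity, and bipartite
drug-target networks realizing prescribed degree sequences.

Two canonical fixtures are shipped: the degree sequences of the approved
drug-kinase network (46 drugs, 25 targets) and of its female-genital-organ
cancer clinical-trial subnetwork (13 drugs, 9 targets), both transcribed
from the printed degree histograms, and the 16-row development-status table
for the previously analysed phase 3 targets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .similarity import AMINO_ACIDS

__all__ = [
    "Distribution",
    "CohortSpec",
    "FamilySpec",
    "DegreeSequencePair",
    "COHORT_ORDER",
    "cohort_presets",
    "generate_cohort",
    "generate_cohorts",
    "generate_sequence_families",
    "annotation_tables",
    "realize_bipartite",
    "fig_approved_degrees",
    "fig_subnetwork_degrees",
    "table1_fixture",
    "write_fasta",
]

#: Development cohorts in the order used for trend comparisons.
COHORT_ORDER = ("established", "phase3", "phase2", "phase1", "nonclinical")


@dataclass(frozen=True)
class Distribution:
    """A named nonnegative-integer distribution for system-profile counts.

    Supported kinds:

    - ``nbinom``: negative binomial parameterised by ``mean`` and
      ``dispersion`` r (variance = mean + mean^2 / r).
    - ``poisson``: parameterised by ``mean``.
    - ``point``: degenerate at ``value``.
    """

    kind: str
    mean: float | None = None
    dispersion: float | None = None
    value: int | None = None

    def _frozen(self):
        if self.kind == "nbinom":
            if self.mean is None or self.dispersion is None:
                raise ValueError("nbinom requires mean and dispersion")
            if self.mean <= 0 or self.dispersion <= 0:
                raise ValueError("nbinom mean and dispersion must be positive")
            r = self.dispersion
            p = r / (r + self.mean)
            return stats.nbinom(r, p)
        if self.kind == "poisson":
            if self.mean is None or self.mean <= 0:
                raise ValueError("poisson requires positive mean")
            return stats.poisson(self.mean)
        if self.kind == "point":
            if self.value is None or self.value < 0:
                raise ValueError("point requires a nonnegative value")
            return None
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        frozen = self._frozen()
        if frozen is None:
            return np.full(n, self.value, dtype=int)
        return frozen.rvs(size=n, random_state=rng).astype(int)

    def cdf(self, k: int) -> float:
        """P(X <= k), exact from the generating distribution."""
        frozen = self._frozen()
        if frozen is None:
            return 1.0 if k >= self.value else 0.0
        return float(frozen.cdf(k))

    def median(self) -> float:
        frozen = self._frozen()
        if frozen is None:
            return float(self.value)
        return float(frozen.median())

    @classmethod
    def from_dict(cls, d: Mapping) -> "Distribution":
        return cls(**d)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic development cohort."""

    cohort_label: str
    n_targets: int
    ns_distribution: Distribution
    np_distribution: Distribution
    nt_distribution: Distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_label not in COHORT_ORDER:
            raise ValueError(
                f"cohort_label must be one of {COHORT_ORDER}, got "
                f"{self.cohort_label!r}"
            )
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        for dist in (self.ns_distribution, self.np_distribution,
                     self.nt_distribution):
            dist._frozen()  # validates parameters


@dataclass(frozen=True)
class FamilySpec:
    """Specification of synthetic protein families.

    Each family descends from one random seed sequence; members are derived
    by point mutation at per-site rate 1 - within_family_identity.  Distinct
    families are generated independently, so between-family identity is the
    background coincidence rate of the residue alphabet.
    """

    n_families: int = 3
    members_per_family: int = 5
    seed_length: int = 60
    within_family_identity: float = 0.9
    between_family_identity: float = 0.05
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.between_family_identity <= 1:
            raise ValueError("between_family_identity must be in [0, 1]")
        if not 0 <= self.within_family_identity <= 1:
            raise ValueError("within_family_identity must be in [0, 1]")
        if self.within_family_identity <= self.between_family_identity:
            raise ValueError(
                "within_family_identity must exceed between_family_identity"
            )
        if self.seed_length < 20:
            raise ValueError("seed_length must be >= 20 residues")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("family and member counts must be >= 1")


@dataclass(frozen=True)
class DegreeSequencePair:
    """Prescribed degree multisets for the two sides of a bipartite graph."""

    drug_degrees: tuple[int, ...]
    target_degrees: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.drug_degrees + self.target_degrees):
            raise ValueError("degrees must be positive integers")


# Cohort presets: negative-binomial NS/NP/NT with medians ascending from
# established through phase 3, 2, 1.  The nonclinical preset continues the
# trend.  Means are chosen so that established-cohort compliance with the
# druggability rules (NS < 15, NP <= 3, NT <= 5) sits near 90% and decays
# through the clinical phases, the qualitative pattern the analysis probes.
_PRESETS: dict[str, dict[str, Distribution]] = {
    "established": {
        "ns": Distribution("nbinom", mean=7.0, dispersion=5.0),
        "np": Distribution("nbinom", mean=2.2, dispersion=6.0),
        "nt": Distribution("nbinom", mean=2.5, dispersion=6.0),
    },
    "phase3": {
        "ns": Distribution("nbinom", mean=9.0, dispersion=5.0),
        "np": Distribution("nbinom", mean=2.6, dispersion=6.0),
        "nt": Distribution("nbinom", mean=3.0, dispersion=6.0),
    },
    "phase2": {
        "ns": Distribution("nbinom", mean=11.0, dispersion=5.0),
        "np": Distribution("nbinom", mean=3.2, dispersion=6.0),
        "nt": Distribution("nbinom", mean=3.5, dispersion=6.0),
    },
    "phase1": {
        "ns": Distribution("nbinom", mean=13.0, dispersion=5.0),
        "np": Distribution("nbinom", mean=3.8, dispersion=6.0),
        "nt": Distribution("nbinom", mean=4.0, dispersion=6.0),
    },
    "nonclinical": {
        "ns": Distribution("nbinom", mean=16.0, dispersion=5.0),
        "np": Distribution("nbinom", mean=4.5, dispersion=6.0),
        "nt": Distribution("nbinom", mean=5.0, dispersion=6.0),
    },
}


def cohort_presets(n_targets: int = 40, seed: int = 0) -> list[CohortSpec]:
    """Default cohort specs, one per development stage, medians ascending."""
    specs = []
    for i, label in enumerate(COHORT_ORDER):
        p = _PRESETS[label]
        specs.append(CohortSpec(
            cohort_label=label,
            n_targets=n_targets,
            ns_distribution=p["ns"],
            np_distribution=p["np"],
            nt_distribution=p["nt"],
            seed=seed + i,
        ))
    return specs


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort of target records with i.i.d. NS/NP/NT counts.

    Returns a DataFrame with columns ``target_id``, ``cohort``, ``family``,
    ``NS``, ``NP``, ``NT``; bit-reproducible under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_targets
    prefix = spec.cohort_label.upper()[:4]
    return pd.DataFrame({
        "target_id": [f"{prefix}_{i:04d}" for i in range(n)],
        "cohort": spec.cohort_label,
        "family": [f"FAM{rng.integers(0, max(2, n // 5)):03d}" for _ in range(n)],
        "NS": spec.ns_distribution.sample(rng, n),
        "NP": spec.np_distribution.sample(rng, n),
        "NT": spec.nt_distribution.sample(rng, n),
    })


def generate_cohorts(specs: Sequence[CohortSpec]) -> pd.DataFrame:
    """Concatenate :func:`generate_cohort` over several specs."""
    return pd.concat([generate_cohort(s) for s in specs], ignore_index=True)


def generate_sequence_families(
    spec: FamilySpec,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate protein families by point mutation from family seed sequences.

    Returns ``(sequences, family_map)`` where sequences maps member id to
    amino-acid string and family_map maps member id to family id.  Each
    member differs from its family seed at ~``1 - within_family_identity``
    of sites (mutated residues are drawn uniformly from the other letters).
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(spec.alphabet))
    k = len(letters)
    mut_rate = 1.0 - spec.within_family_identity
    sequences: dict[str, str] = {}
    family_map: dict[str, str] = {}
    for f in range(spec.n_families):
        fam = f"FAM{f:03d}"
        seed_seq = rng.integers(0, k, size=spec.seed_length)
        for m in range(spec.members_per_family):
            member = seed_seq.copy()
            mutate = rng.random(spec.seed_length) < mut_rate
            # replacement drawn from the other k-1 residues
            shift = rng.integers(1, k, size=spec.seed_length)
            member[mutate] = (member[mutate] + shift[mutate]) % k
            sid = f"{fam}_M{m:02d}"
            sequences[sid] = "".join(letters[member])
            family_map[sid] = fam
    return sequences, family_map


def annotation_tables(
    cohort: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand per-target NP/NT counts into pathway and tissue annotation rows.

    Pathway ids are drawn without replacement per target from a shared pool
    (so pathways are reused across targets, as in real pathway databases);
    tissues likewise.  Round-trips with the distinct-count semantics of
    profile assembly: each target's distinct pathway count equals its NP.
    """
    rng = np.random.default_rng(seed)
    n_pathways = max(20, int(cohort["NP"].max()) + 1)
    n_tissues = max(30, int(cohort["NT"].max()) + 1)
    path_rows, tissue_rows = [], []
    for row in cohort.itertuples():
        for p in rng.choice(n_pathways, size=int(row.NP), replace=False):
            path_rows.append({"target_id": row.target_id,
                              "pathway_id": f"path{p:04d}"})
        for t in rng.choice(n_tissues, size=int(row.NT), replace=False):
            tissue_rows.append({"target_id": row.target_id,
                                "tissue_label": f"tissue{t:03d}"})
    pathways = pd.DataFrame(path_rows, columns=["target_id", "pathway_id"])
    tissues = pd.DataFrame(tissue_rows, columns=["target_id", "tissue_label"])
    return pathways, tissues


def _gale_ryser_check(drug_degrees: Sequence[int],
                      target_degrees: Sequence[int]) -> None:
    """Raise ValueError naming the violated realizability condition."""
    sa, sb = sum(drug_degrees), sum(target_degrees)
    if sa != sb:
        raise ValueError(
            f"degree sums differ: drug side {sa} != target side {sb}"
        )
    a = sorted(drug_degrees, reverse=True)
    b = list(target_degrees)
    for k in range(1, len(a) + 1):
        lhs = sum(a[:k])
        rhs = sum(min(d, k) for d in b)
        if lhs > rhs:
            raise ValueError(
                f"Gale-Ryser condition fails at k={k}: "
                f"sum of top {k} drug degrees ({lhs}) exceeds "
                f"sum(min(target degree, {k})) = {rhs}"
            )


def realize_bipartite(
    degseq: DegreeSequencePair,
    drug_prefix: str = "drug",
    target_prefix: str = "target",
) -> nx.Graph:
    """Construct a bipartite graph realizing the prescribed degree multisets.

    Greedy Havel-Hakimi-style construction with deterministic ordering:
    nodes are labelled in descending-degree then lexicographic order, and
    each drug is connected to the targets of largest remaining capacity
    (ties broken by id).  Succeeds whenever the Gale-Ryser condition holds;
    infeasible inputs raise ``ValueError`` naming the failing condition.

    The returned graph carries ``bipartite`` node attributes (``"drug"`` /
    ``"target"``) and exactly reproduces the input degree multisets.
    """
    _gale_ryser_check(degseq.drug_degrees, degseq.target_degrees)
    drugs = sorted(degseq.drug_degrees, reverse=True)
    targets = sorted(degseq.target_degrees, reverse=True)
    g = nx.Graph()
    drug_ids = [f"{drug_prefix}{i + 1:03d}" for i in range(len(drugs))]
    target_ids = [f"{target_prefix}{i + 1:03d}" for i in range(len(targets))]
    for did, d in zip(drug_ids, drugs):
        g.add_node(did, bipartite="drug", degree_target=d)
    for tid, d in zip(target_ids, targets):
        g.add_node(tid, bipartite="target", degree_target=d)
    remaining = dict(zip(target_ids, targets))
    for did, d in zip(drug_ids, drugs):
        # targets by remaining capacity descending, then id ascending
        order = sorted(remaining, key=lambda t: (-remaining[t], t))
        chosen = [t for t in order if remaining[t] > 0][:d]
        if len(chosen) < d:  # pragma: no cover - excluded by Gale-Ryser
            raise ValueError("greedy realization ran out of capacity")
        for t in chosen:
            g.add_edge(did, t, mode="inhibition")
            remaining[t] -= 1
    assert all(v == 0 for v in remaining.values())
    return g


def fig_approved_degrees() -> DegreeSequencePair:
    """Degree sequences of the approved drug-kinase network.

    Drug side: one drug of degree 5, four of degree 3, ten of degree 2 and
    thirty-one of degree 1 (46 drugs).  Target side: single targets at
    degrees 10, 9, 7, 6, 5 and 4, three at degree 3, two at degree 2 and
    fourteen at degree 1 (25 targets; the printed histogram has no degree-8
    class and is transcribed literally).
    """
    drug = (5,) + (3,) * 4 + (2,) * 10 + (1,) * 31
    target = (10, 9, 7, 6, 5, 4) + (3,) * 3 + (2,) * 2 + (1,) * 14
    return DegreeSequencePair(drug, target)


def fig_subnetwork_degrees() -> DegreeSequencePair:
    """Degree sequences of the female-genital-organ cancer (C51-C58)
    clinical-trial subnetwork: 3 drugs of degree 2 and 10 of degree 1;
    targets at degrees 5, 3 and 2 plus six of degree 1 (13 drugs, 9 targets).
    """
    drug = (2,) * 3 + (1,) * 10
    target = (5, 3, 2) + (1,) * 6
    return DegreeSequencePair(drug, target)


def table1_fixture() -> pd.DataFrame:
    """The 16-row development-status table for the previously analysed
    phase 3 targets, shipped as packaged data.

    Columns: ``target`` (with the phase 3 drug in parentheses),
    ``target_name`` (short name), ``combination`` (e.g. ``"A,C,D"``),
    ``disease``, ``status`` (free-text latest development status; empty
    where no outcome had been reported).
    """
    ref = importlib.resources.files("targetprofiler.data") / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.insert(1, "target_name", df["target"].str.split(" (", regex=False).str[0])
    return df


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences as uncompressed FASTA (60-column wrapping)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=sid, description="")
               for sid, seq in sequences.items()]
    seqio_write(records, str(path), "fasta")
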