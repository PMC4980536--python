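"""Local-alignment similarity engine with Karlin-Altschul E-value statistics.

Pairwise protein similarity is scored by an exact Smith-Waterman dynamic
program with affine gap penalties, and alignment scores are converted to
expectation values (E-values) under the Karlin-Altschul model

    E = K * m * n * exp(-lambda * S)

where ``S`` is the raw alignment score, ``m`` and ``n`` are the (effective)
query and subject lengths, and ``lambda``/``K`` are computed from the
substitution matrix and background residue frequencies.  E-values are then
binned into three similarity levels (very similar, marginally similar,
unsimilar), and per-target counts of similar proteins outside the target's
own family (the NS statistic) are derived.

A reader for the standard 12-column BLAST tabular format (``outfmt 6``) is
provided for interoperability with externally computed searches.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from math import exp, gcd
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

__all__ = [
    "AMINO_ACIDS",
    "ROBINSON_FREQUENCIES",
    "AlignmentResult",
    "EvalueParams",
    "SimilarityLevel",
    "SimilarityThresholds",
    "solve_lambda",
    "karlin_k",
    "smith_waterman",
    "evalue",
    "classify_similarity",
    "best_hit_evalue",
    "count_similarity_proteins",
    "read_blast_tabular",
    "write_blast_tabular",
]

#: The 20 standard amino acids, in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Robinson & Robinson background residue frequencies, the convention used
#: by BLAST for ungapped Karlin-Altschul statistics.
ROBINSON_FREQUENCIES: Mapping[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


class SimilarityLevel(str, Enum):
    """Three-way E-value classification of pairwise similarity."""

    VERY_SIMILAR = "very_similar"
    MARGINALLY_SIMILAR = "marginally_similar"
    UNSIMILAR = "unsimilar"


@dataclass(frozen=True)
class SimilarityThresholds:
    """E-value cutpoints separating the three similarity levels.

    Boundaries are inclusive on the smaller (more similar) class:
    E <= very_similar_max is very similar, very_similar_max < E <= marginal_max
    is marginally similar, and E > marginal_max is unsimilar.
    """

    very_similar_max: float = 1e-3
    marginal_max: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.very_similar_max < self.marginal_max:
            raise ValueError(
                "thresholds must satisfy 0 < very_similar_max < marginal_max, "
                f"got {self.very_similar_max} and {self.marginal_max}"
            )


@dataclass(frozen=True)
class AlignmentResult:
    """One scored pairwise comparison.

    Attributes
    ----------
    query_id, subject_id : str
        Sequence identifiers.
    score : float
        Maximum local-alignment score in substitution-matrix units.
    query_length, subject_length : int
        Effective lengths m and n entering the E-value.
    evalue : float
        Expected number of chance alignments with score >= ``score``.
    """

    query_id: str
    subject_id: str
    score: float
    query_length: int
    subject_length: int
    evalue: float


def _matrix_lookup(matrix) -> dict[tuple[str, str], float]:
    """Flatten a Biopython substitution matrix (or mapping) to a pair dict."""
    if isinstance(matrix, substitution_matrices.Array):
        return {
            (a, b): float(matrix[a, b])
            for a in matrix.alphabet
            for b in matrix.alphabet
        }
    return {k: float(v) for k, v in dict(matrix).items()}


@dataclass
class EvalueParams:
    """Scoring scheme plus the Karlin-Altschul parameters derived from it.

    ``lambda_`` solves sum_ij p_i p_j exp(lambda * s_ij) = 1 for the ungapped
    matrix; ``kappa`` is the Karlin-Altschul prefactor K computed by the
    lattice series method (see :func:`karlin_k`).  Both are computed on first
    access and cached.  Gap penalties follow the BLAST convention: a gap of
    length L costs ``gap_open + L * gap_extend``.
    """

    matrix: object = None
    gap_open: float = 11.0
    gap_extend: float = 1.0
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(ROBINSON_FREQUENCIES)
    )
    strict_residues: bool = True
    _lambda: float | None = field(default=None, repr=False)
    _kappa: float | None = field(default=None, repr=False)
    _pairs: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.matrix is None:
            self.matrix = substitution_matrices.load("BLOSUM62")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")

    @property
    def pair_scores(self) -> dict[tuple[str, str], float]:
        if self._pairs is None:
            self._pairs = _matrix_lookup(self.matrix)
        return self._pairs

    def score(self, a: str, b: str) -> float:
        try:
            return self.pair_scores[(a, b)]
        except KeyError:
            if self.strict_residues:
                raise ValueError(f"unknown residue pair ({a!r}, {b!r})") from None
            # lenient mode: unknown residues behave like X (if present) or
            # score the worst mismatch in the matrix
            pairs = self.pair_scores
            if ("X", "X") in pairs:
                xa = a if (a, "X") in pairs else "X"
                xb = b if ("X", b) in pairs else "X"
                return pairs[(xa, xb)]
            return min(pairs.values())

    @property
    def lambda_(self) -> float:
        if self._lambda is None:
            self._lambda = solve_lambda(self.matrix, self.background)
        return self._lambda

    @property
    def kappa(self) -> float:
        if self._kappa is None:
            self._kappa = karlin_k(self.matrix, self.background, self.lambda_)
        return self._kappa


def _score_distribution(matrix, background) -> dict[int, float]:
    """Distribution of the per-position score X = s(a, b), a,b ~ background.

    Scores must be integer-valued (they are for all NCBI matrices).
    Frequencies are renormalised over the residues present in both the
    matrix alphabet and the background table.
    """
    pairs = _matrix_lookup(matrix)
    letters = sorted({a for a, _ in pairs} & set(background))
    if not letters:
        raise ValueError("matrix alphabet and background share no residues")
    total = sum(background[a] for a in letters)
    dist: dict[int, float] = defaultdict(float)
    for a in letters:
        for b in letters:
            s = pairs[(a, b)]
            if s != int(s):
                raise ValueError("Karlin-Altschul statistics require integer scores")
            dist[int(s)] += background[a] * background[b] / total**2
    return dict(dist)


def solve_lambda(matrix, background: Mapping[str, float] | None = None) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0.

    The root exists and is unique when the expected per-position score is
    negative and at least one score is positive.  Found by Brent's method to
    relative tolerance below 1e-12.

    Raises
    ------
    ValueError
        If the scoring scheme admits no positive root (all scores positive,
        or nonnegative expected score).
    """
    if background is None:
        background = ROBINSON_FREQUENCIES
    dist = _score_distribution(matrix, background)
    mean = sum(s * p for s, p in dist.items())
    if max(dist) <= 0:
        raise ValueError("no positive scores: lambda is undefined")
    if mean >= 0:
        raise ValueError(
            f"expected per-position score must be negative (got {mean:.4f})"
        )

    def f(lam: float) -> float:
        return sum(p * exp(lam * s) for s, p in dist.items()) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise ValueError("failed to bracket lambda")
    return brentq(f, 1e-12, hi, xtol=1e-300, rtol=1e-14)


def karlin_k(
    matrix,
    background: Mapping[str, float] | None = None,
    lambda_: float | None = None,
    n_terms: int = 80,
) -> float:
    """Karlin-Altschul prefactor K for an integer-lattice scoring scheme.

    Uses the classical series for lattice random walks: with score
    distribution p(x), span delta = gcd of attainable scores, tilted drift
    A = E[X exp(lambda X)], and

        sigma = sum_{k>=1} (1/k) [ P(S_k >= 0) + E(exp(lambda S_k); S_k < 0) ]

    over partial sums S_k of the walk,

        K = delta * exp(-2 sigma) / (A * (1 - exp(-lambda * delta))).

    The series converges geometrically (negative drift); ``n_terms`` = 80
    is far past convergence for protein matrices.  For BLOSUM62 with
    Robinson-Robinson frequencies this reproduces the standard ungapped
    values lambda = 0.3176, K = 0.134.
    """
    if background is None:
        background = ROBINSON_FREQUENCIES
    if lambda_ is None:
        lambda_ = solve_lambda(matrix, background)
    dist = _score_distribution(matrix, background)
    delta = 0
    for s in dist:
        delta = gcd(delta, abs(s))
    lo, hi = min(dist), max(dist)
    base = np.zeros(hi - lo + 1)
    for s, p in dist.items():
        base[s - lo] = p
    A = sum(s * p * exp(lambda_ * s) for s, p in dist.items())

    sigma = 0.0
    cur = base.copy()
    cur_lo = lo
    for k in range(1, n_terms + 1):
        scores = np.arange(cur_lo, cur_lo + len(cur))
        neg = scores < 0
        term = cur[~neg].sum() + float(np.sum(cur[neg] * np.exp(lambda_ * scores[neg])))
        sigma += term / k
        cur = np.convolve(cur, base)
        cur_lo += lo
    return delta * exp(-2.0 * sigma) / (A * (1.0 - exp(-lambda_ * delta)))


def smith_waterman(query: str, subject: str, params: EvalueParams | None = None,
                   query_id: str = "query", subject_id: str = "subject"
                   ) -> AlignmentResult:
    """Exact Smith-Waterman local alignment score with affine gaps (Gotoh).

    A gap of length L costs ``gap_open + L * gap_extend`` (BLAST convention).
    Returns the maximum-scoring local alignment score (>= 0) together with
    its E-value under ``params``.

    Raises
    ------
    ValueError
        On empty sequences, or unknown residues when ``params.strict_residues``.
    """
    if params is None:
        params = EvalueParams()
    if not query or not subject:
        raise ValueError("sequences must be nonempty")
    score = _gotoh_score(query, subject, params)
    e = evalue(score, len(query), len(subject), params)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        query_length=len(query),
        subject_length=len(subject),
        evalue=e,
    )


def _gotoh_score(a: str, b: str, params: EvalueParams) -> float:
    """Affine-gap local alignment DP (Gotoh's three-state recurrence).

    States per cell: M (a_i aligned to b_j), X (gap in b, consuming a),
    Y (gap in a, consuming b).  Opening a gap from any other state costs
    ``gap_open + gap_extend``; continuing one costs ``gap_extend``.  A local
    alignment may start fresh at any cell (the 0 branch of M); gaps never
    end an optimal local alignment, so the best score is tracked on M.
    """
    open_cost = params.gap_open + params.gap_extend
    ext = params.gap_extend
    neg_inf = float("-inf")
    n = len(b)
    score_fn = params.score
    # validate residues up front so strict mode errors even on zero-score inputs
    for ch in set(a) | set(b):
        score_fn(ch, ch)

    prev_m = [0.0] * (n + 1)
    prev_x = [neg_inf] * (n + 1)
    prev_y = [neg_inf] * (n + 1)
    best = 0.0
    for i in range(1, len(a) + 1):
        ai = a[i - 1]
        cur_m = [0.0] * (n + 1)
        cur_x = [neg_inf] * (n + 1)
        cur_y = [neg_inf] * (n + 1)
        for j in range(1, n + 1):
            x = max(prev_m[j] - open_cost, prev_x[j] - ext, prev_y[j] - open_cost)
            y = max(cur_m[j - 1] - open_cost, cur_y[j - 1] - ext,
                    cur_x[j - 1] - open_cost)
            m = max(0.0, prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]) \
                + score_fn(ai, b[j - 1])
            m = max(0.0, m)
            cur_m[j] = m
            cur_x[j] = x
            cur_y[j] = y
            if m > best:
                best = m
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best


def evalue(score: float, m: int, n: int, params: EvalueParams) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("effective lengths must be >= 1")
    return params.kappa * m * n * math.exp(-params.lambda_ * score)


def classify_similarity(
    e: float, thresholds: SimilarityThresholds | None = None
) -> SimilarityLevel:
    """Map an E-value to one of the three similarity levels.

    The partition of (0, inf) is exhaustive and exclusive; boundaries are
    inclusive on the more-similar side (E = 0.001 is very similar).
    """
    if thresholds is None:
        thresholds = SimilarityThresholds()
    if not e > 0:
        raise ValueError(f"E-value must be positive, got {e}")
    if e <= thresholds.very_similar_max:
        return SimilarityLevel.VERY_SIMILAR
    if e <= thresholds.marginal_max:
        return SimilarityLevel.MARGINALLY_SIMILAR
    return SimilarityLevel.UNSIMILAR


def best_hit_evalue(
    query: str,
    subjects: Mapping[str, str],
    params: EvalueParams | None = None,
    exclude: Iterable[str] = (),
) -> float:
    """Minimum E-value of ``query`` against a set of subject sequences.

    Similarity of a target to a reference set (e.g. the established targets)
    is taken as best-hit similarity: the smallest E-value over the set.
    """
    if params is None:
        params = EvalueParams()
    excluded = set(exclude)
    best = math.inf
    for sid, seq in subjects.items():
        if sid in excluded:
            continue
        res = smith_waterman(query, seq, params, subject_id=sid)
        if res.evalue < best:
            best = res.evalue
    if best is math.inf:
        raise ValueError("no subject sequences to compare against")
    return best


def count_similarity_proteins(
    target_id: str,
    sequences: Mapping[str, str],
    family_map: Mapping[str, str],
    params: EvalueParams | None = None,
    ns_cutoff: float = 1e-3,
) -> int:
    """NS: number of proteins outside the target's family with E <= cutoff.

    ``sequences`` plays the role of the searched proteome; every entry must
    carry a family label in ``family_map``.  The target itself is excluded
    from the count, as are all members of its own family.
    """
    if params is None:
        params = EvalueParams()
    if target_id not in sequences:
        raise KeyError(f"target {target_id!r} not present in the sequence set")
    missing = [sid for sid in sequences if sid not in family_map]
    if missing:
        raise KeyError(f"sequences without family label: {missing[:5]}")
    query = sequences[target_id]
    target_family = family_map[target_id]
    ns = 0
    for sid, seq in sequences.items():
        if sid == target_id or family_map[sid] == target_family:
            continue
        res = smith_waterman(query, seq, params, target_id, sid)
        if res.evalue <= ns_cutoff:
            ns += 1
    return ns


_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Read 12-column BLAST tabular output (``-outfmt 6``).

    Returns a DataFrame with the standard column names; the E-value is
    column 11 (``evalue``).  Malformed rows raise a ``ValueError`` naming
    the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append({
                    "qseqid": parts[0],
                    "sseqid": parts[1],
                    "pident": float(parts[2]),
                    "length": int(parts[3]),
                    "mismatch": int(parts[4]),
                    "gapopen": int(parts[5]),
                    "qstart": int(parts[6]),
                    "qend": int(parts[7]),
                    "sstart": int(parts[8]),
                    "send": int(parts[9]),
                    "evalue": float(parts[10]),
                    "bitscore": float(parts[11]),
                })
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=_BLAST_COLUMNS)


def write_blast_tabular(df: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table in the 12-column tabular dialect (round-trips with
    :func:`read_blast_tabular`)."""
    df = df[_BLAST_COLUMNS]
    df.to_csv(path, sep="\t", header=False, index=False)


def validate_sequence(seq: str, alphabet: str = AMINO_ACIDS) -> str:
    """Uppercase and check a protein sequence against an alphabet."""
    seq = seq.upper()
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"unknown residue symbols: {sorted(bad)}")
    return seq
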