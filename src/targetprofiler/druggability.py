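"""The >=3-of-4-profile promising-target rule and retrospective evaluation.

A combinational druggability method labels a target "promising" when it is
similar to established drug targets in at least 3 of 4 profiles: sequence
(A), drug-binding-domain structural fold (B), physicochemical features (C)
and system profile (D).  Profiles B and C are defined by prior structural
and physicochemical analyses and enter here only as boolean flags read from
input tables.

The retrospective evaluation parses free-text development-status strings
(approved / positive phase 3 / negative or discontinued / unknown) and
cross-tabulates outcomes against the promising flag, reproducing the
16-target phase 3 scorecard.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .profiles import truncate_pct

__all__ = [
    "PROFILE_NAMES",
    "ProfileFlags",
    "StatusLabel",
    "is_promising",
    "parse_combination",
    "parse_status",
    "evaluate_cohort",
    "prediction_rates",
    "read_flags_table",
]

PROFILE_NAMES = ("A", "B", "C", "D")


class StatusLabel(str, Enum):
    """Mutually exclusive development-outcome labels, in precedence order."""

    APPROVED = "approved"
    POSITIVE_PHASE3 = "positive_phase3"
    NEGATIVE_OR_DISCONTINUED = "negative_or_discontinued"
    OTHER = "other"


@dataclass(frozen=True)
class ProfileFlags:
    """The four boolean profile-similarity indicators for one target."""

    target_id: str
    a: bool
    b: bool
    c: bool
    d: bool

    @property
    def n_similar(self) -> int:
        return sum((self.a, self.b, self.c, self.d))


def is_promising(flags: ProfileFlags) -> bool:
    """True iff the target is similar to established targets in at least
    3 of the 4 profiles."""
    return flags.n_similar >= 3


def parse_combination(combo: str, target_id: str = "") -> ProfileFlags:
    """Parse a profile-combination string like ``"A,C,D"`` into flags.

    Accepts comma/space/plus-separated letters from {A, B, C, D}, case
    insensitively; unknown letters raise ``ValueError``.
    """
    letters = {tok.upper() for tok in re.split(r"[,\s+]+", combo.strip()) if tok}
    unknown = letters - set(PROFILE_NAMES)
    if unknown:
        raise ValueError(f"unknown profile letters {sorted(unknown)} in {combo!r}")
    return ProfileFlags(
        target_id=target_id,
        a="A" in letters, b="B" in letters,
        c="C" in letters, d="D" in letters,
    )


# Whole-word keyword rules, applied case-insensitively in precedence order.
# "approved" deliberately does not match "approval" (a drug "filed for
# approval" has no approved outcome), and an approved row is never also
# counted as positive.
_APPROVED = re.compile(r"\bapproved\b", re.IGNORECASE)
_POSITIVE = re.compile(r"\bpositive\b", re.IGNORECASE)
_NEGATIVE = re.compile(
    r"\bdiscontinued\b|\bnegative\b|\bnot approvable\b", re.IGNORECASE
)


def parse_status(status: str) -> StatusLabel:
    """Classify a free-text development-status string.

    Total function: empty or unrecognised strings map to ``OTHER``.
    Precedence: approved > positive phase 3 > negative/discontinued.
    """
    text = status or ""
    if _APPROVED.search(text):
        return StatusLabel.APPROVED
    if _POSITIVE.search(text):
        return StatusLabel.POSITIVE_PHASE3
    if _NEGATIVE.search(text):
        return StatusLabel.NEGATIVE_OR_DISCONTINUED
    return StatusLabel.OTHER


def evaluate_cohort(rows: pd.DataFrame) -> pd.DataFrame:
    """Retrospective outcome evaluation of a promising-target scorecard.

    ``rows`` needs columns ``combination`` (profile letters) and ``status``
    (free text); a ``target`` or ``target_name`` column is carried through
    if present.  Returns a summary DataFrame with one row per status label:
    count, percentage of all rows (raw and truncated toward zero in the
    printed style), split by whether the >=3-of-4 rule fires.

    Raises on an empty table.
    """
    if rows.empty:
        raise ValueError("cannot evaluate an empty table")
    labels = rows["status"].map(parse_status)
    promising = rows["combination"].map(
        lambda c: is_promising(parse_combination(c))
    )
    n = len(rows)
    records = []
    for label in StatusLabel:
        mask = labels == label
        count = int(mask.sum())
        records.append({
            "status": label.value,
            "count": count,
            "pct": 100.0 * count / n,
            "pct_printed": truncate_pct(100.0 * count / n),
            "count_promising": int((mask & promising).sum()),
            "count_not_promising": int((mask & ~promising).sum()),
        })
    out = pd.DataFrame(records)
    assert out["count"].sum() == n  # labels partition the rows
    return out


def prediction_rates(
    targets: pd.DataFrame, phase_column: str = "phase"
) -> pd.Series:
    """Fraction of targets flagged promising, per clinical-phase cohort.

    ``targets`` needs the phase column plus either boolean columns
    ``A``/``B``/``C``/``D`` or a ``combination`` column.  Phases with zero
    targets are omitted with a warning; unknown phase labels raise.
    """
    known = {"established", "phase3", "phase2", "phase1", "nonclinical"}
    bad = set(targets[phase_column].unique()) - known
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    if set(PROFILE_NAMES) <= set(targets.columns):
        promising = targets[list(PROFILE_NAMES)].sum(axis=1) >= 3
    else:
        promising = targets["combination"].map(
            lambda c: is_promising(parse_combination(c))
        )
    rates = {}
    for phase, group in targets.groupby(phase_column, observed=True):
        if group.empty:  # pragma: no cover - groupby omits empty groups
            warnings.warn(f"phase {phase!r} has no targets; omitted")
            continue
        rates[phase] = float(promising[group.index].mean())
    return pd.Series(rates, name="fraction_promising")


def read_flags_table(path) -> pd.DataFrame:
    """Read a TSV of (target, combination, status) rows for evaluation.

    This is the file-backed provider for the B and C profile flags (and A
    and D when externally computed): their internal definitions live in the
    cited structural and physicochemical analyses, so they are consumed
    here as given booleans.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"combination", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df
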