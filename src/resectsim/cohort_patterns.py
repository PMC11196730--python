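"""Per-subject GE-decline patterns and cohort-level worst-deletion tables.

The sorted percolation list L is partitioned into strata S_n (all resections
of n parcels).  Step n -> n+1 is *stepwise* when no size-(n+1) resection is
as harmless as the most harmless size-n resection, i.e. the strata do not
interleave.  Subjects are classified from these flags; cohort tables tally
which parcel is each subject's single worst deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .formatting import format_percent
from .percolation_engine import PercolationRecord, ResectionSweep
from .resection_enumerator import ResectionSet

__all__ = [
    "StepwiseClassification",
    "WorstBySize",
    "classify_stepwise",
    "worst_by_size",
    "worst_frequency_table",
    "worst_membership_table",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("perfect", "partial", "non-step", "mixed")


@dataclass(frozen=True)
class StepwiseClassification:
    subject_id: str
    lobe: str
    #: stepwise flag for each step n -> n+1, keyed by n
    flags: dict[int, bool]
    category: str


@dataclass(frozen=True)
class WorstBySize:
    subject_id: str
    lobe: str
    #: size n -> record with minimal GE among S_n
    worst: dict[int, PercolationRecord]
    #: size n -> whether worst(n-1) is nested inside worst(n)
    contains_previous: dict[int, bool]

    @property
    def worst_s1(self) -> ResectionSet:
        return self.worst[1].resection

    def nesting_fraction(self) -> float:
        """Fraction of steps whose worst set contains the previous worst."""
        if not self.contains_previous:
            return float("nan")
        return sum(self.contains_previous.values()) / len(self.contains_previous)


def classify_stepwise(sweep: ResectionSweep) -> StepwiseClassification:
    """Classify one subject-lobe GE decline as perfect / partial / non-step / mixed.

    Step n -> n+1 is stepwise iff min GE over S_n is strictly greater than
    max GE over S_{n+1} (equal values count as mixed-in).  Categories:
    *perfect* — every step stepwise; *partial* — steps 1-2, 2-3, 3-4 stepwise
    but some later step not; *non-step* — no step stepwise; *mixed* —
    anything else.  With fewer than 4 strata the partial category is
    undefined and classification is restricted (with a warning) to
    perfect / non-step / mixed.
    """
    sizes = sweep.sizes()
    if not sizes:
        raise ValueError("empty sweep")
    k = max(sizes)
    flags: dict[int, bool] = {}
    for n in range(1, k):
        s_n = sweep.stratum(n)
        s_next = sweep.stratum(n + 1)
        if not s_n or not s_next:
            continue
        flags[n] = min(r.ge for r in s_n) > max(r.ge for r in s_next)
    if k < 4:
        logger.warning(
            "sweep %s/%s has max size %d < 4: partial-stepwise undefined",
            sweep.subject_id,
            sweep.lobe,
            k,
        )
    if flags and all(flags.values()):
        category = "perfect"
    elif flags and not any(flags.values()):
        category = "non-step"
    elif (
        k >= 4
        and all(flags.get(n, False) for n in (1, 2, 3))
        and not all(flags.get(n, False) for n in range(4, k))
    ):
        category = "partial"
    else:
        category = "mixed"
    return StepwiseClassification(
        subject_id=sweep.subject_id, lobe=sweep.lobe, flags=flags, category=category
    )


def worst_by_size(sweep: ResectionSweep) -> WorstBySize:
    """The minimal-GE resection of each size, with nesting flags.

    Ties are broken by lexicographic parcel tuple.  ``contains_previous[n]``
    records whether the worst size-(n-1) set is a subset of the worst size-n
    set — the "accumulation" structure of worst deletions.
    """
    if not sweep.records:
        raise ValueError("empty sweep")
    worst: dict[int, PercolationRecord] = {}
    for rec in sweep.records:
        n = rec.resection.size
        cur = worst.get(n)
        if (
            cur is None
            or rec.ge < cur.ge
            or (rec.ge == cur.ge and rec.resection.parcels < cur.resection.parcels)
        ):
            worst[n] = rec
    contains: dict[int, bool] = {}
    for n in sorted(worst):
        if n - 1 in worst:
            contains[n] = set(worst[n - 1].resection.parcels) <= set(
                worst[n].resection.parcels
            )
    return WorstBySize(
        subject_id=sweep.subject_id,
        lobe=sweep.lobe,
        worst=dict(sorted(worst.items())),
        contains_previous=contains,
    )


def worst_frequency_table(
    cohort: list[WorstBySize], lobe: str, min_fraction: float = 0.05
) -> pd.DataFrame:
    """Tally each parcel's frequency as a subject's worst single deletion.

    Rows are sorted by count descending (ties lexicographic); parcels below
    ``min_fraction`` of the cohort are collapsed into an ``"other"`` row.
    Columns: parcel, count, total, display (``"n/d; p%"``).
    """
    entries = [w for w in cohort if w.lobe == lobe]
    total = len(entries)
    counts: dict[str, int] = {}
    for w in entries:
        (p,) = w.worst_s1.parcels
        counts[p] = counts.get(p, 0) + 1
    threshold = min_fraction * total
    kept = {p: c for p, c in counts.items() if c >= threshold}
    other = sum(c for p, c in counts.items() if p not in kept)
    rows = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    if other:
        rows.append(("other", other))
    return pd.DataFrame(
        [
            {
                "parcel": p,
                "count": c,
                "total": total,
                "display": format_percent(c, total),
            }
            for p, c in rows
        ],
        columns=["parcel", "count", "total", "display"],
    )


def worst_membership_table(cohort: list[WorstBySize], lobe: str) -> pd.DataFrame:
    """Secondary tally: subjects in whose worst-by-size *sequence* each parcel
    appears anywhere (regardless of being the single worst deletion)."""
    entries = [w for w in cohort if w.lobe == lobe]
    total = len(entries)
    counts: dict[str, int] = {}
    for w in entries:
        seen = {p for rec in w.worst.values() for p in rec.resection.parcels}
        for p in seen:
            counts[p] = counts.get(p, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [
            {"parcel": p, "count": c, "total": total, "display": format_percent(c, total)}
            for p, c in rows
        ],
        columns=["parcel", "count", "total", "display"],
    )
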