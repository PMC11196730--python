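"""Lobe epicenters, early-arrival evidence, and connectotype assignment.

An *epicenter* is a parcel that either is the cohort's modal worst single
deletion in a lobe, or arrives in a subject's worst-deletion progression
earlier than physical proximity predicts.  Because resections must be
connected, a candidate at hop distance ``h`` from the worst single deletion
cannot co-occur with it in any worst set of fewer than ``h + 1`` parcels;
its *expected minimal arrival size* is therefore ``S_m = h + 1``.  The
observed arrival size ``S_r`` is the smallest n whose worst size-n set
contains the candidate, and ``D = S_r - S_m``; negative D (arrival before
the proximity bound) falsifies the hypothesis that the candidate matters
only through physical closeness to the worst deletion, and marks it an
epicenter in its own right.

A subject's *connectotype* in a lobe is the candidate epicenter that
dominates their worst-deletion pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .atlas_topology import AtlasTopology
from .cohort_patterns import WorstBySize

__all__ = [
    "EpicenterEvidence",
    "ConnectotypeAssignment",
    "lobe_epicenter",
    "epicenter_evidence",
    "assign_connectotypes",
    "UNASSIGNED",
]

#: Sentinel arrival size for candidates never seen in any worst set.
NEVER = math.inf
UNASSIGNED = "unassigned"

_BASES = ("worst-s1-is-epicenter", "adjacent-collapse", "earliest-arrival")


@dataclass(frozen=True)
class EpicenterEvidence:
    subject_id: str
    lobe: str
    candidate: str
    worst_s1: str
    s_r: float  # observed arrival size (NEVER if absent from all worst sets)
    s_m: float  # expected minimal size = hop distance + 1
    d: float | None  # s_r - s_m; None when s_r is the sentinel
    early: bool  # d < 0: arrival earlier than proximity allows


@dataclass(frozen=True)
class ConnectotypeAssignment:
    subject_id: str
    lobe: str
    label: str
    basis: str


def lobe_epicenter(
    frequency_table: pd.DataFrame, n_candidates: int = 2
) -> list[str]:
    """Top-frequency worst-S1 parcels of a lobe, the candidate epicenters.

    Takes a table from :func:`resectsim.cohort_patterns.worst_frequency_table`
    (the ``"other"`` catch-all row is ignored); ties are broken by
    lexicographic parcel ID.
    """
    if frequency_table.empty:
        raise ValueError("empty frequency table")
    rows = frequency_table[frequency_table["parcel"] != "other"]
    ordered = sorted(
        zip(rows["parcel"], rows["count"]), key=lambda kv: (-kv[1], kv[0])
    )
    return [p for p, _ in ordered[:n_candidates]]


def epicenter_evidence(
    wbs: WorstBySize, atlas: AtlasTopology, candidate: str
) -> EpicenterEvidence:
    """Arrival statistics of one candidate epicenter in one subject's
    worst-by-size sequence."""
    if candidate not in set(atlas.lobe_parcels(wbs.lobe)):
        raise ValueError(f"candidate {candidate!r} not in lobe {wbs.lobe!r}")
    (worst_s1,) = wbs.worst[1].resection.parcels
    s_r: float = NEVER
    for n in sorted(wbs.worst):
        if candidate in wbs.worst[n].resection.parcels:
            s_r = n
            break
    hop = atlas.hop_distance(wbs.lobe, worst_s1, candidate)
    s_m = hop + 1
    d = None if s_r is NEVER or not math.isfinite(s_m) else s_r - s_m
    early = d is not None and d < 0
    return EpicenterEvidence(
        subject_id=wbs.subject_id,
        lobe=wbs.lobe,
        candidate=candidate,
        worst_s1=worst_s1,
        s_r=s_r,
        s_m=s_m,
        d=d,
        early=early,
    )


def assign_connectotypes(
    cohort_worst: list[WorstBySize],
    atlas: AtlasTopology,
    candidates: list[str],
) -> list[ConnectotypeAssignment]:
    """Assign each subject-lobe to a candidate epicenter.

    Precedence per subject: (1) the worst single deletion itself, when it is
    a candidate; (2) a candidate adjacent to the worst single deletion that
    joins it in the worst size-2 set — the "adjacent collapse" of a
    borderline worst deletion onto a neighbouring epicenter; (3) the
    candidate with minimal D (earliest arrival relative to the proximity
    bound), ties by smaller S_r then lexicographic ID.  Subjects in whose
    worst sequence no candidate ever appears are labeled ``"unassigned"``.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    out: list[ConnectotypeAssignment] = []
    for wbs in cohort_worst:
        (worst_s1,) = wbs.worst[1].resection.parcels
        label, basis = None, None
        if worst_s1 in candidates:
            label, basis = worst_s1, _BASES[0]
        if label is None and 2 in wbs.worst:
            worst2 = set(wbs.worst[2].resection.parcels)
            adjacent = atlas.neighbors(worst_s1)
            for cand in sorted(candidates):
                if cand in adjacent and cand in worst2:
                    label, basis = cand, _BASES[1]
                    break
        if label is None:
            evid = [epicenter_evidence(wbs, atlas, c) for c in candidates]
            scored = [e for e in evid if e.d is not None]
            if scored:
                best = min(scored, key=lambda e: (e.d, e.s_r, e.candidate))
                label, basis = best.candidate, _BASES[2]
        if label is None:
            label, basis = UNASSIGNED, "no-candidate-observed"
        out.append(
            ConnectotypeAssignment(
                subject_id=wbs.subject_id, lobe=wbs.lobe, label=label, basis=basis
            )
        )
    return out
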