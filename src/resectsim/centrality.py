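"""PageRank hub centrality and its ability to predict worst deletions.

The recursion used here places the teleport weight on ``d``,

    PR(P_i) = d / n + (1 - d) * sum_{j -> i} PR(P_j) / outdegree(P_j),

so ``d`` is the probability of a uniform jump and ``1 - d`` the probability
of following a link — the transpose of the common damping convention.  With
the default ``d = 0.15`` the scores coincide with standard 0.85-damped
PageRank.  The connectome's undirected edges are treated as arc pairs;
out-degree is the unweighted arc count (a streamline-weighted transition
variant is available via ``weighted=True``).  Dangling nodes (isolates)
link uniformly to every node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_topology import AtlasTopology
from .cohort_patterns import WorstBySize
from .connectome_io import Connectome
from .formatting import format_percent
from .percolation_engine import ResectionSweep

__all__ = [
    "CentralityReport",
    "PredictionRates",
    "pagerank_scores",
    "rank_per_hemisphere",
    "centrality_report",
    "pr_prediction_rates",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class CentralityReport:
    subject_id: str
    damping: float
    scores: dict[str, float]
    #: parcel -> rank within its hemisphere (1 = highest PR)
    hemisphere_rank: dict[str, int]
    #: parcel -> rank over the whole graph (1 = highest PR)
    global_rank: dict[str, int]


@dataclass(frozen=True)
class PredictionRates:
    lobe: str
    n_subjects: int
    worst: int
    worst_or_neighbor: int
    top3: int

    @property
    def rate_worst(self) -> float:
        return self.worst / self.n_subjects

    @property
    def rate_worst_or_neighbor(self) -> float:
        return self.worst_or_neighbor / self.n_subjects

    @property
    def rate_top3(self) -> float:
        return self.top3 / self.n_subjects

    def as_row(self) -> dict[str, str]:
        return {
            "lobe": self.lobe,
            "worst": format_percent(self.worst, self.n_subjects),
            "worst_or_neighbor": format_percent(self.worst_or_neighbor, self.n_subjects),
            "top3": format_percent(self.top3, self.n_subjects),
        }


def pagerank_scores(
    c: Connectome,
    d: float = 0.15,
    tol: float = 1e-12,
    max_iter: int = 1000,
    weighted: bool = False,
) -> dict[str, float]:
    """Fixed point of the teleport-on-d PageRank recursion.

    Iterates to L1 change < ``tol``; raises :class:`ConvergenceError` with
    the residual if ``max_iter`` is reached first.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("damping d must be in [0, 1]")
    n = c.n_parcels
    w = c.weights
    adj = (w > 0).astype(float)
    trans_weights = w if weighted else adj
    outdeg = trans_weights.sum(axis=1)
    dangling = outdeg == 0
    safe_out = np.where(dangling, 1.0, outdeg)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        contrib = x / safe_out
        new = d / n + (1.0 - d) * (trans_weights.T @ np.where(dangling, 0.0, contrib))
        new += (1.0 - d) * x[dangling].sum() / n  # dangling mass spread uniformly
        resid = np.abs(new - x).sum()
        x = new
        if resid < tol:
            return {p: float(v) for p, v in zip(c.parcels, x)}
    raise ConvergenceError(f"PageRank did not converge: L1 residual {resid:.3e}")


def rank_per_hemisphere(scores: dict[str, float], atlas: AtlasTopology) -> dict[str, int]:
    """Rank parcels within each hemisphere, 1 = highest score.

    Ties broken by lexicographic parcel ID; midline nodes form their own
    group.  Missing scores are an error.
    """
    missing = [p for p in atlas.parcels if p not in scores]
    if missing:
        raise ValueError(f"scores missing for parcels {missing[:5]!r}...")
    ranks: dict[str, int] = {}
    for hemi in ("left", "right", "midline"):
        members = [p for p in atlas.parcels if atlas.hemisphere[p] == hemi]
        for i, p in enumerate(sorted(members, key=lambda q: (-scores[q], q)), start=1):
            ranks[p] = i
    return ranks


def _global_rank(scores: dict[str, float]) -> dict[str, int]:
    ordered = sorted(scores, key=lambda q: (-scores[q], q))
    return {p: i for i, p in enumerate(ordered, start=1)}


def centrality_report(
    c: Connectome, atlas: AtlasTopology, d: float = 0.15, **kwargs
) -> CentralityReport:
    scores = pagerank_scores(c, d=d, **kwargs)
    return CentralityReport(
        subject_id=c.subject_id,
        damping=d,
        scores=scores,
        hemisphere_rank=rank_per_hemisphere(scores, atlas),
        global_rank=_global_rank(scores),
    )


def _worst_singletons(sweep: ResectionSweep, k: int = 3) -> list[str]:
    """The k minimal-GE single deletions, worst first (ties lexicographic)."""
    singles = [(r.ge, r.resection.parcels[0]) for r in sweep.stratum(1)]
    singles.sort(key=lambda t: (t[0], t[1]))
    return [p for _, p in singles[:k]]


def pr_prediction_rates(
    sweeps: list[ResectionSweep],
    reports: dict[str, CentralityReport],
    atlas: AtlasTopology,
    lobe: str,
) -> PredictionRates:
    """Score how often the lobe's top-PR parcel predicts the worst deletion.

    Three nested criteria per subject: the top-PR parcel of the lobe (a)
    equals the worst single deletion, (b) equals it or borders it in the
    atlas adjacency, (c) is among the subject's 3 worst single deletions.
    """
    members = atlas.lobe_parcels(lobe)
    n_subjects = 0
    hits = [0, 0, 0]
    for sweep in (s for s in sweeps if s.lobe == lobe):
        if sweep.subject_id not in reports:
            raise ValueError(f"no centrality report for subject {sweep.subject_id!r}")
        scores = reports[sweep.subject_id].scores
        predicted = min(members, key=lambda p: (-scores[p], p))
        top3 = _worst_singletons(sweep, 3)
        worst = top3[0]
        n_subjects += 1
        crit_worst = predicted == worst
        crit_neighbor = crit_worst or predicted in atlas.neighbors(worst)
        crit_top3 = predicted in top3
        hits[0] += crit_worst
        hits[1] += crit_neighbor
        hits[2] += crit_top3
    if n_subjects == 0:
        raise ValueError(f"no sweeps for lobe {lobe!r}")
    return PredictionRates(
        lobe=lobe,
        n_subjects=n_subjects,
        worst=hits[0],
        worst_or_neighbor=hits[1],
        top3=hits[2],
    )


def prediction_table(rates: list[PredictionRates]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in rates])
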