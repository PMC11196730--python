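"""Enumeration of anatomically plausible resections.

A plausible resection is a *connected* set of resectable parcels inside one
lobe, of size 1..K (default K = 10).  Because distinct traversal orders of
the same parcel set describe the same surgery, enumeration is performed over
vertex *combinations* rather than traversal permutations, using the anchored
extension scheme: connected sets are grown from each anchor vertex in turn,
with vertices ordered before the anchor forbidden and an exclusion set
preventing the same set from being reached along two branches.  Each
connected induced vertex set is emitted exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .atlas_topology import AtlasTopology

__all__ = ["ResectionSet", "enumerate_resections", "count_resections", "EnumerationSizeWarning"]

logger = logging.getLogger(__name__)

DEFAULT_MAX_SIZE = 10
#: Warn before enumerations projected to exceed this many sets.
DEFAULT_SET_CAP = 2_000_000


class EnumerationSizeWarning(UserWarning):
    pass


@dataclass(frozen=True, order=True)
class ResectionSet:
    """A connected set of resectable parcels within one lobe."""

    lobe: str
    parcels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parcels", tuple(sorted(self.parcels)))

    @property
    def size(self) -> int:
        return len(self.parcels)


def _connected_sets(order: list[str], neighbors: dict[str, set[str]], max_size: int):
    """Yield every connected vertex set of size <= max_size exactly once.

    ``order`` fixes a total vertex order; sets are anchored at their minimal
    vertex, and extensions may only use vertices after the anchor.
    """
    rank = {v: i for i, v in enumerate(order)}
    for anchor in order:
        a_rank = rank[anchor]
        base_ext = sorted(
            (v for v in neighbors[anchor] if rank[v] > a_rank), key=rank.__getitem__
        )
        yield (anchor,)
        if max_size == 1:
            continue
        # stack entries: (current set, extension candidates in rank order,
        # forbidden set = subset + every vertex ever offered as a candidate
        # on this branch — the exclusion that makes each set reachable once)
        stack = [((anchor,), base_ext, frozenset({anchor, *base_ext}))]
        while stack:
            subset, ext, banned = stack.pop()
            for i, w in enumerate(ext):
                new_subset = subset + (w,)
                yield new_subset
                if len(new_subset) < max_size:
                    new_cands = sorted(
                        (
                            u
                            for u in neighbors[w]
                            if rank[u] > a_rank and u not in banned
                        ),
                        key=rank.__getitem__,
                    )
                    stack.append(
                        (new_subset, ext[i + 1 :] + new_cands, banned | set(new_cands))
                    )


def enumerate_resections(
    atlas: AtlasTopology,
    lobe: str,
    max_size: int = DEFAULT_MAX_SIZE,
    set_cap: int = DEFAULT_SET_CAP,
) -> list[ResectionSet]:
    """All distinct connected resection sets of ``lobe`` with size <= ``max_size``.

    Output order is deterministic: size ascending, then lexicographic parcel
    tuple.  A warning is logged when the enumeration exceeds ``set_cap`` sets.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    members = atlas.lobe_parcels(lobe)  # validates the lobe label
    member_set = set(members)
    neighbors = {p: set(atlas.neighbors(p)) & member_set for p in members}
    out = []
    for subset in _connected_sets(members, neighbors, max_size):
        out.append(ResectionSet(lobe=lobe, parcels=subset))
        if len(out) == set_cap + 1:
            logger.warning(
                "enumeration of lobe %r exceeds cap of %d sets", lobe, set_cap
            )
    out.sort(key=lambda rs: (rs.size, rs.parcels))
    return out


def count_resections(atlas: AtlasTopology, lobe: str, max_size: int = DEFAULT_MAX_SIZE) -> dict[int, int]:
    """Number of connected resection sets per size (dry-run projection)."""
    members = atlas.lobe_parcels(lobe)
    member_set = set(members)
    neighbors = {p: set(atlas.neighbors(p)) & member_set for p in members}
    counts: dict[int, int] = {}
    for subset in _connected_sets(members, neighbors, max_size):
        counts[len(subset)] = counts.get(len(subset), 0) + 1
    return dict(sorted(counts.items()))
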