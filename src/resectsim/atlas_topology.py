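"""Atlas topology: parcel identities, lobe partition, and physical adjacency.

The anatomical substrate on which virtual resections are defined is an
undirected graph ``G = (V, E)`` whose vertices are atlas parcels and whose
edges join parcels that share a physical border.  Resections are restricted
to connected sets of parcels inside a single lobe, so each lobe's induced
adjacency subgraph must itself be connected.

Lobe labels are hemisphere-qualified strings such as ``"frontal/left"``.
Non-cortical nodes (subcortical, cerebellar, brainstem) participate in
connectomes and efficiency computations but are flagged non-resectable and
carry no lobe label.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "AtlasTopology",
    "AtlasError",
    "load_atlas",
    "save_atlas",
    "UNREACHABLE",
]

SCHEMA_VERSION = 1

#: Sentinel hop distance for parcel pairs with no within-lobe path.
UNREACHABLE = math.inf

_HEMISPHERES = frozenset({"left", "right", "midline"})


class AtlasError(ValueError):
    """Raised when a topology file is malformed or violates an invariant."""


@dataclass(frozen=True)
class AtlasTopology:
    """Validated parcel set, lobe partition, and adjacency graph.

    Parameters
    ----------
    parcels
        Parcel IDs in canonical (file) order; unique.
    hemisphere
        Parcel ID -> ``"left" | "right" | "midline"``.
    lobe
        Parcel ID -> hemisphere-qualified lobe label, for resectable
        (cortical) parcels only.
    resectable
        Parcel ID -> whether the parcel may be part of a resection.
    adjacency
        Unordered parcel pairs sharing a physical border, stored as sorted
        2-tuples.
    """

    parcels: tuple[str, ...]
    hemisphere: Mapping[str, str]
    lobe: Mapping[str, str]
    resectable: Mapping[str, bool]
    adjacency: frozenset[tuple[str, str]]
    _neighbors: dict[str, frozenset[str]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        nbrs: dict[str, set[str]] = {p: set() for p in self.parcels}
        for a, b in self.adjacency:
            nbrs[a].add(b)
            nbrs[b].add(a)
        object.__setattr__(
            self, "_neighbors", {p: frozenset(s) for p, s in nbrs.items()}
        )

    # -- basic queries -----------------------------------------------------

    @property
    def lobes(self) -> tuple[str, ...]:
        """All lobe labels, sorted."""
        return tuple(sorted(set(self.lobe.values())))

    def neighbors(self, parcel: str) -> frozenset[str]:
        try:
            return self._neighbors[parcel]
        except KeyError:
            raise AtlasError(f"unknown parcel {parcel!r}") from None

    def lobe_parcels(self, lobe: str) -> list[str]:
        """Resectable parcels of ``lobe`` in lexicographic order."""
        if lobe not in set(self.lobe.values()):
            raise AtlasError(f"unknown lobe label {lobe!r}")
        return sorted(p for p, lb in self.lobe.items() if lb == lobe)

    def hop_distance(self, lobe: str, a: str, b: str) -> float:
        """Minimum number of adjacency hops between ``a`` and ``b`` within a lobe.

        Breadth-first shortest hop count over the lobe-restricted adjacency
        graph; 0 iff ``a == b``; :data:`UNREACHABLE` if no within-lobe path
        exists.
        """
        members = set(self.lobe_parcels(lobe))
        for p in (a, b):
            if p not in members:
                raise AtlasError(f"parcel {p!r} not in lobe {lobe!r}")
        if a == b:
            return 0
        seen = {a}
        queue = deque([(a, 0)])
        while queue:
            node, dist = queue.popleft()
            for nxt in self._neighbors[node]:
                if nxt not in members or nxt in seen:
                    continue
                if nxt == b:
                    return dist + 1
                seen.add(nxt)
                queue.append((nxt, dist + 1))
        return UNREACHABLE

    def whole_graph_hops(self) -> dict[tuple[str, str], float]:
        """All-pairs hop distances over the full adjacency graph.

        Used by the synthetic generator's distance-decay kernel.  Pairs with
        no path (e.g. opposite hemispheres when no callosal edges are
        modeled) map to :data:`UNREACHABLE`.
        """
        out: dict[tuple[str, str], float] = {}
        for src in self.parcels:
            dist = {src: 0}
            queue = deque([src])
            while queue:
                node = queue.popleft()
                for nxt in self._neighbors[node]:
                    if nxt not in dist:
                        dist[nxt] = dist[node] + 1
                        queue.append(nxt)
            for dst in self.parcels:
                out[(src, dst)] = dist.get(dst, UNREACHABLE)
        return out

    # -- validation --------------------------------------------------------

    def validate(self, require_connected_lobes: bool = True) -> None:
        """Check every structural invariant, raising :class:`AtlasError`."""
        if len(set(self.parcels)) != len(self.parcels):
            raise AtlasError("duplicate parcel IDs")
        known = set(self.parcels)
        for p in self.parcels:
            hemi = self.hemisphere.get(p)
            if hemi not in _HEMISPHERES:
                raise AtlasError(f"parcel {p!r} has invalid hemisphere {hemi!r}")
        for a, b in self.adjacency:
            if a == b:
                raise AtlasError(f"self-loop on parcel {a!r}")
            if a not in known or b not in known:
                raise AtlasError(f"adjacency references unknown parcel in {(a, b)!r}")
            if (a, b) != tuple(sorted((a, b))):
                raise AtlasError("adjacency pair not stored in sorted order")
        for p in self.parcels:
            if self.resectable.get(p, False):
                if p not in self.lobe:
                    raise AtlasError(f"resectable parcel {p!r} has no lobe label")
            elif p in self.lobe:
                raise AtlasError(f"non-resectable parcel {p!r} carries lobe label")
        if require_connected_lobes:
            for lb in self.lobes:
                members = self.lobe_parcels(lb)
                if not _is_connected(members, self._neighbors):
                    raise AtlasError(f"lobe {lb!r} not connected")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": SCHEMA_VERSION,
            "parcels": [
                {
                    "id": p,
                    "hemisphere": self.hemisphere[p],
                    "lobe": self.lobe.get(p),
                    "resectable": bool(self.resectable[p]),
                }
                for p in self.parcels
            ],
            "adjacency": [list(pair) for pair in sorted(self.adjacency)],
        }


def _is_connected(members: Iterable[str], neighbors: Mapping[str, frozenset[str]]) -> bool:
    members = set(members)
    if not members:
        return True
    start = next(iter(members))
    seen = {start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nxt in neighbors[node]:
            if nxt in members and nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return seen == members


def build_atlas(
    parcels: Iterable[dict],
    adjacency: Iterable[Iterable[str]],
    require_connected_lobes: bool = True,
) -> AtlasTopology:
    """Assemble and validate an :class:`AtlasTopology` from plain records."""
    ids: list[str] = []
    hemisphere: dict[str, str] = {}
    lobe: dict[str, str] = {}
    resectable: dict[str, bool] = {}
    for rec in parcels:
        pid = str(rec["id"])
        ids.append(pid)
        hemisphere[pid] = rec["hemisphere"]
        resectable[pid] = bool(rec.get("resectable", True))
        if rec.get("lobe") is not None:
            lobe[pid] = rec["lobe"]
    pairs = set()
    for edge in adjacency:
        a, b = (str(x) for x in edge)
        if a == b:
            raise AtlasError(f"self-loop on parcel {a!r}")
        pairs.add(tuple(sorted((a, b))))
    atlas = AtlasTopology(
        parcels=tuple(ids),
        hemisphere=hemisphere,
        lobe=lobe,
        resectable=resectable,
        adjacency=frozenset(pairs),
    )
    atlas.validate(require_connected_lobes=require_connected_lobes)
    return atlas


def load_atlas(path, require_connected_lobes: bool = True) -> AtlasTopology:
    """Load and validate a topology JSON file.

    The schema is ``{"version": 1, "parcels": [{"id", "hemisphere", "lobe",
    "resectable"}...], "adjacency": [[id, id]...]}``.  Duplicate edges listed
    in both orientations collapse to a single unordered pair.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AtlasError(f"cannot parse topology file {path}: {exc}") from exc
    for key in ("parcels", "adjacency"):
        if key not in doc:
            raise AtlasError(f"topology file missing key {key!r}")
    return build_atlas(
        doc["parcels"], doc["adjacency"], require_connected_lobes=require_connected_lobes
    )


def save_atlas(atlas: AtlasTopology, path) -> None:
    """Write the canonical JSON form (round-trips through :func:`load_atlas`)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(atlas.to_dict(), fh, indent=1, sort_keys=False)
        fh.write("\n")
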