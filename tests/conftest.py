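"""Shared fixtures: tiny hand-built atlases and synthetic subjects."""

from __future__ import annotations

import numpy as np
import pytest

from resectsim.atlas_topology import build_atlas
from resectsim.connectome_io import Connectome
from resectsim.synthetic_cohort import GridAtlasSpec, generate_atlas


def make_atlas(edges, lobe_members, hemisphere="left", extra_parcels=()):
    """Build a one-hemisphere test atlas from an edge list and a lobe map.

    ``lobe_members``: {lobe label -> iterable of parcel IDs}.  Parcels in
    ``extra_parcels`` are included as non-resectable nodes.
    """
    ids = sorted({p for e in edges for p in e} | {p for m in lobe_members.values() for p in m})
    lobe_of = {p: lb for lb, members in lobe_members.items() for p in members}
    parcels = [
        {"id": p, "hemisphere": hemisphere, "lobe": lobe_of.get(p), "resectable": p in lobe_of}
        for p in ids
    ]
    for p in extra_parcels:
        parcels.append({"id": p, "hemisphere": "midline", "lobe": None, "resectable": False})
    return build_atlas(parcels, edges)


@pytest.fixture
def triangle_atlas():
    """One lobe {a, b, c} with all three pairwise adjacencies."""
    return make_atlas([("a", "b"), ("b", "c"), ("a", "c")], {"tri/left": ["a", "b", "c"]})


@pytest.fixture
def chain_atlas():
    """One lobe a-b-c-d, a path."""
    return make_atlas(
        [("a", "b"), ("b", "c"), ("c", "d")], {"chain/left": ["a", "b", "c", "d"]}
    )


@pytest.fixture(scope="session")
def grid_atlas():
    """Default mirrored test atlas: 2 lobes x 3x3 grid per hemisphere."""
    return generate_atlas(GridAtlasSpec())


def connectome_from_edges(parcels, weighted_edges, subject_id="sub-test"):
    """Symmetric connectome from {(a, b): weight} on an ordered parcel list."""
    parcels = tuple(parcels)
    idx = {p: i for i, p in enumerate(parcels)}
    w = np.zeros((len(parcels), len(parcels)))
    for (a, b), wt in weighted_edges.items():
        w[idx[a], idx[b]] = wt
        w[idx[b], idx[a]] = wt
    return Connectome(subject_id=subject_id, parcels=parcels, weights=w)


@pytest.fixture
def triangle_connectome():
    return connectome_from_edges(
        "abc", {("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1}
    )
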