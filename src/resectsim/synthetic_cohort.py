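"""Synthetic atlases and connectome cohorts with planted ground truth.

Real structural connectomes come from diffusion tractography; here cohorts
are simulated so that every downstream stage (enumeration, percolation,
epicenter detection, connectotype assignment, centrality prediction) can be
validated against a known answer.

The generative model, per subject:

* each configured lobe's *connectotype* (planted epicenter parcel) is drawn
  from the configured mixing proportions;
* expected streamline count for parcel pair (i, j) is ``W * pi_ij`` with
  ``pi_ij ∝ exp(-lambda * hop_ij) * b_i * b_j``, where ``hop_ij`` is the
  adjacency hop distance, ``b = beta`` on the subject's epicenter parcels,
  ``sqrt(beta)`` on their adjacency neighbours (so worst deletions form
  spatially coherent, nested combinations) and 1 elsewhere, and ``W`` is the
  target total streamline count (default 300 000, the scale of a typical
  whole-brain tractogram);
* realized counts are Poisson draws of the expectation scaled by a subject
  level log-normal factor ``exp(N(0, sigma^2))`` (overdispersion across
  subjects), then symmetrized.

Reproducibility: all randomness flows from ``(seed, subject index)``
substreams, so cohorts are stable when ``n_subjects`` changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atlas_topology import AtlasTopology, build_atlas
from .connectome_io import Connectome
from .data.hcp import (
    GLASSER_AREAS,
    LOBE_ASSIGNMENT,
    LOBE_BORDERS,
    LOBE_NAMES,
    SUBCORTICAL,
)

__all__ = [
    "GridAtlasSpec",
    "CohortConfig",
    "generate_atlas",
    "generate_cohort",
    "GroundTruthManifest",
]

#: subject_id -> {lobe label -> planted epicenter parcel}
GroundTruthManifest = dict[str, dict[str, str]]


@dataclass(frozen=True)
class GridAtlasSpec:
    """A small mirrored atlas: per hemisphere, ``lobes`` lobes of an
    ``rows x cols`` grid of parcels with 4-neighbour grid adjacency."""

    lobes: int = 2
    rows: int = 3
    cols: int = 3
    lobe_names: tuple[str, ...] | None = None
    inter_lobe_edges: bool = True

    def names(self) -> tuple[str, ...]:
        if self.lobe_names is not None:
            if len(self.lobe_names) != self.lobes:
                raise ValueError("lobe_names length must equal lobes")
            return tuple(self.lobe_names)
        if self.lobes <= len(LOBE_NAMES):
            return LOBE_NAMES[: self.lobes]
        return tuple(f"lobe{i}" for i in range(self.lobes))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 20
    atlas_spec: GridAtlasSpec | str = field(default_factory=GridAtlasSpec)
    total_streamlines: float = 300_000.0
    decay: float = 0.5
    hub_boost: float = 2.0
    connectotype_mix: dict[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self, atlas: AtlasTopology) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if self.hub_boost < 1:
            raise ValueError("hub_boost must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lobe, mix in self.connectotype_mix.items():
            members = set(atlas.lobe_parcels(lobe))
            total = 0.0
            for parcel, prop in mix:
                if parcel not in members:
                    raise ValueError(f"epicenter {parcel!r} not in lobe {lobe!r}")
                if prop < 0:
                    raise ValueError("mixing proportions must be >= 0")
                total += prop
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"mixing proportions for {lobe!r} sum to {total}, not 1")


# ---------------------------------------------------------------------------
# atlas generation


def _grid_edges(ids: list[str], rows: int, cols: int) -> list[tuple[str, str]]:
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.append((ids[i], ids[i + 1]))
            if r + 1 < rows:
                edges.append((ids[i], ids[i + cols]))
    return edges


def _grid_atlas(spec: GridAtlasSpec) -> AtlasTopology:
    parcels: list[dict] = []
    adjacency: list[tuple[str, str]] = []
    names = spec.names()
    for hemi, h in (("left", "L"), ("right", "R")):
        prev_lobe_ids: list[str] | None = None
        for name in names:
            ids = [
                f"{h}_{name}_{r}{c}" for r in range(spec.rows) for c in range(spec.cols)
            ]
            for pid in ids:
                parcels.append(
                    {"id": pid, "hemisphere": hemi, "lobe": f"{name}/{hemi}", "resectable": True}
                )
            adjacency.extend(_grid_edges(ids, spec.rows, spec.cols))
            if spec.inter_lobe_edges and prev_lobe_ids is not None:
                adjacency.append((prev_lobe_ids[-1], ids[0]))
            prev_lobe_ids = ids
    return build_atlas(parcels, adjacency)


def _full_scale_atlas() -> AtlasTopology:
    """The 379-node full-scale atlas: 180 HCP cortical areas per hemisphere
    plus 19 non-resectable subcortical components, with a synthetic border
    graph (within-lobe lattice + inter-lobe links)."""
    parcels: list[dict] = []
    adjacency: list[tuple[str, str]] = []
    for hemi, h in (("left", "L"), ("right", "R")):
        for area in GLASSER_AREAS:
            parcels.append(
                {
                    "id": f"{h}_{area}",
                    "hemisphere": hemi,
                    "lobe": None,  # filled below from the assignment table
                    "resectable": True,
                }
            )
        first_of: dict[str, str] = {}
        for lobe_name in LOBE_NAMES:
            ids = [f"{h}_{a}" for a in LOBE_ASSIGNMENT[lobe_name]]
            first_of[lobe_name] = ids[0]
            label = f"{lobe_name}/{hemi}"
            for rec in parcels:
                if rec["id"] in ids:
                    rec["lobe"] = label
            # lattice: chain plus skip-one chords gives a connected, locally
            # clustered border graph within the lobe
            for i in range(len(ids) - 1):
                adjacency.append((ids[i], ids[i + 1]))
            for i in range(len(ids) - 2):
                adjacency.append((ids[i], ids[i + 2]))
        for la, lb in LOBE_BORDERS:
            adjacency.append((first_of[la], first_of[lb]))
    for name, hemi in SUBCORTICAL:
        parcels.append({"id": name, "hemisphere": hemi, "lobe": None, "resectable": False})
    return build_atlas(parcels, adjacency)


def generate_atlas(atlas_spec: GridAtlasSpec | str) -> AtlasTopology:
    """Build a validated atlas from a spec: a :class:`GridAtlasSpec` or the
    string ``"full-scale"``.  Deterministic for a fixed spec; the two
    hemispheres are mirrored."""
    if atlas_spec == "full-scale":
        return _full_scale_atlas()
    if isinstance(atlas_spec, GridAtlasSpec):
        return _grid_atlas(atlas_spec)
    raise ValueError(f"unrecognized atlas spec {atlas_spec!r}")


# ---------------------------------------------------------------------------
# cohort generation


def _hop_matrix(atlas: AtlasTopology, decay: float) -> np.ndarray:
    """Pairwise hop distances; pairs with no adjacency path are set one hop
    beyond the graph diameter so distant/contralateral connections exist but
    are maximally decayed."""
    n = len(atlas.parcels)
    hops = atlas.whole_graph_hops()
    mat = np.empty((n, n))
    for i, a in enumerate(atlas.parcels):
        for j, b in enumerate(atlas.parcels):
            mat[i, j] = hops[(a, b)]
    finite = mat[np.isfinite(mat)]
    fallback = (finite.max() + 1.0) if finite.size else 1.0
    mat[~np.isfinite(mat)] = fallback
    return mat


def generate_cohort(
    config: CohortConfig, atlas: AtlasTopology | None = None
) -> tuple[list[Connectome], GroundTruthManifest]:
    """Generate a cohort of synthetic connectomes plus its ground truth.

    Returns the subjects (IDs ``sub-000``, ``sub-001``, ...) and the manifest
    mapping each subject to its planted epicenter per configured lobe.
    """
    if atlas is None:
        atlas = generate_atlas(config.atlas_spec)
    config.validate(atlas)
    n = len(atlas.parcels)
    index = {p: i for i, p in enumerate(atlas.parcels)}
    hop = _hop_matrix(atlas, config.decay)
    base_kernel = np.exp(-config.decay * hop)
    np.fill_diagonal(base_kernel, 0.0)

    lobes = sorted(config.connectotype_mix)
    subjects: list[Connectome] = []
    manifest: GroundTruthManifest = {}
    for s in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, s])
        subject_id = f"sub-{s:03d}"
        boosts = np.ones(n)
        planted: dict[str, str] = {}
        for lobe in lobes:
            mix = config.connectotype_mix[lobe]
            probs = np.array([prop for _, prop in mix])
            choice = int(rng.choice(len(mix), p=probs / probs.sum()))
            epicenter = mix[choice][0]
            planted[lobe] = epicenter
            e = index[epicenter]
            boosts[e] = max(boosts[e], config.hub_boost)
            for nb in atlas.neighbors(epicenter):
                i = index[nb]
                boosts[i] = max(boosts[i], math.sqrt(config.hub_boost))
        pi = base_kernel * np.outer(boosts, boosts)
        pi_sum = np.triu(pi, 1).sum()
        expectation = config.total_streamlines * pi / pi_sum
        noise = math.exp(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 1.0
        upper = np.triu(rng.poisson(expectation * noise).astype(float), 1)
        weights = upper + upper.T
        subjects.append(
            Connectome(subject_id=subject_id, parcels=tuple(atlas.parcels), weights=weights)
        )
        manifest[subject_id] = planted
    return subjects, manifest
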