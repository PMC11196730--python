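"""Reading, validating and writing per-subject structural connectomes.

A connectome is a symmetric nonnegative matrix of streamline counts between
atlas parcels, stored as CSV with parcel-ID headers on both axes.  On ingest
the matrix is aligned to atlas parcel order; parcels absent from the file are
filled in as zero rows/columns (with a warning) so every connectome in a
cohort shares one node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_topology import AtlasTopology

__all__ = ["Connectome", "ConnectomeError", "read_connectome", "write_connectome"]

logger = logging.getLogger(__name__)

#: Relative tolerance above which input asymmetry is treated as an error.
ASYMMETRY_RTOL = 1e-6


class ConnectomeError(ValueError):
    """Raised for malformed connectivity matrices."""


@dataclass(frozen=True)
class Connectome:
    """One subject's structural connectivity graph.

    ``weights[i, j]`` is the streamline count between ``parcels[i]`` and
    ``parcels[j]``; symmetric, zero diagonal, entries >= 0.
    """

    subject_id: str
    parcels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError("weights must be a square matrix")
        if w.shape[0] != len(self.parcels):
            raise ConnectomeError("weight matrix does not match parcel list")
        if np.any(w < 0):
            raise ConnectomeError("negative streamline count")
        if not np.array_equal(w, w.T):
            raise ConnectomeError("weights must be exactly symmetric")
        if np.any(np.diagonal(w) != 0):
            raise ConnectomeError("diagonal must be zero")
        object.__setattr__(self, "weights", w)

    @property
    def n_parcels(self) -> int:
        return len(self.parcels)

    def index_of(self, parcel: str) -> int:
        try:
            return self.parcels.index(parcel)
        except ValueError:
            raise ConnectomeError(f"unknown parcel {parcel!r}") from None

    def total_streamlines(self) -> float:
        """Sum of weights over unordered parcel pairs."""
        return float(self.weights.sum() / 2.0)


def read_connectome(
    path,
    atlas: AtlasTopology,
    subject_id: str | None = None,
    strict_integer: bool = False,
) -> Connectome:
    """Read a CSV connectivity matrix and align it to atlas order.

    Row and column headers must be identical parcel-ID sets drawn from the
    atlas.  Mild numerical asymmetry (relative error <= 1e-6) is symmetrized
    by averaging; larger asymmetry is an error.  With ``strict_integer`` any
    non-integer entry is rejected rather than tolerated.
    """
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.shape[0] != frame.shape[1]:
        raise ConnectomeError(f"non-square matrix {frame.shape} in {path}")
    if list(frame.index) != list(frame.columns):
        if set(frame.index) != set(frame.columns):
            raise ConnectomeError("row and column parcel IDs differ")
        frame = frame.loc[:, list(frame.index)]
    unknown = set(frame.index) - set(atlas.parcels)
    if unknown:
        raise ConnectomeError(f"unknown parcel IDs: {sorted(unknown)!r}")

    values = frame.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ConnectomeError("negative streamline count")
    scale = max(np.abs(values).max(), 1.0)
    if np.abs(values - values.T).max() > ASYMMETRY_RTOL * scale:
        raise ConnectomeError("matrix asymmetric beyond tolerance")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    if strict_integer and not np.array_equal(values, np.rint(values)):
        raise ConnectomeError("non-integer streamline counts with strict_integer=True")

    missing = [p for p in atlas.parcels if p not in set(frame.index)]
    if missing:
        logger.warning(
            "connectome %s missing %d atlas parcels; filled with zeros", path, len(missing)
        )
    n = len(atlas.parcels)
    full = np.zeros((n, n), dtype=float)
    pos = {p: i for i, p in enumerate(atlas.parcels)}
    idx = np.array([pos[p] for p in frame.index])
    full[np.ix_(idx, idx)] = values

    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    return Connectome(subject_id=subject_id, parcels=tuple(atlas.parcels), weights=full)


def write_connectome(c: Connectome, path) -> None:
    """Write CSV that round-trips bit-identically through :func:`read_connectome`.

    Integer-valued matrices (the common case for streamline counts) are
    written as integers to keep fixtures diff-able.
    """
    w = c.weights
    if np.array_equal(w, np.rint(w)):
        frame = pd.DataFrame(w.astype(np.int64), index=c.parcels, columns=c.parcels)
    else:
        frame = pd.DataFrame(w, index=c.parcels, columns=c.parcels)
    frame.to_csv(path)
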