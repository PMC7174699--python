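"""Weighted efficiency metrics for structural connectomes.

A structural connectome is a weighted, symmetric, zero-diagonal matrix whose
entry ``C[i, j]`` carries volume-normalized streamline counts between
gray-matter parcels ``i`` and ``j``.  Communication efficiency is measured by
global efficiency

    E(G)  = 1 / (n (n - 1)) * sum_{i != j} 1 / d(i, j)
    GE(G) = E(G) / E(G_ideal)

where ``d(i, j)`` is the weighted shortest-path length between parcels.
Stronger connections are shorter: a present edge of weight ``w`` has length
``w_max / w``, i.e. the reciprocal mapping after normalizing all weights by
the matrix maximum.  Under this convention every edge length is >= 1, the
ideal network (every possible edge present at the maximum weight) has all
pairwise distances equal to 1 and hence ``E(G_ideal) = 1``, and GE lies in
[0, 1] with GE = 1 exactly for a uniform complete graph.  Unreachable pairs
contribute ``1 / inf = 0``, so disconnected (e.g. lesioned) networks are
valid inputs, never errors.

Local efficiency of a node is the efficiency of the subgraph induced by its
neighbors (the node itself excluded); it is 0 for nodes with fewer than two
neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path


class ConnectomeError(ValueError):
    """Raised when a connectivity matrix violates its invariants."""


class MetricError(ValueError):
    """Raised when an efficiency metric is undefined for the input."""


@dataclass(frozen=True)
class Connectome:
    """A weighted, symmetric, zero-diagonal region-by-region network.

    Parameters
    ----------
    weights
        ``(n, n)`` nonnegative symmetric matrix with zero diagonal.
    region_ids
        Region identifier for each row/column.  Identifiers survive node
        deletion (rows are removed, ids are not reindexed), so a lesioned
        connectome remains traceable to the parent atlas.
    atlas_ref
        Free-form identifier of the parcellation the regions belong to.
    """

    weights: np.ndarray
    region_ids: tuple[int, ...]
    atlas_ref: str = ""
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be square, got shape {w.shape}")
        ids = tuple(int(r) for r in self.region_ids)
        if len(ids) != w.shape[0]:
            raise ConnectomeError(
                f"{len(ids)} region_ids for a {w.shape[0]}-row matrix"
            )
        if len(set(ids)) != len(ids):
            raise ConnectomeError("region_ids contain duplicates")
        if np.any(w < 0):
            raise ConnectomeError("negative edge weights are not allowed")
        if not np.allclose(w, w.T, rtol=0.0, atol=1e-12):
            raise ConnectomeError("weight matrix is not symmetric")
        if np.any(np.diagonal(w) != 0):
            raise ConnectomeError("diagonal must be zero (no self-connections)")
        w = np.ascontiguousarray((w + w.T) / 2.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_ids", ids)
        object.__setattr__(self, "_index", {r: i for i, r in enumerate(ids)})

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: int) -> int:
        try:
            return self._index[int(region_id)]
        except KeyError:
            raise KeyError(f"region id {region_id} not in connectome") from None

    @property
    def max_weight(self) -> float:
        return float(self.weights.max()) if self.n else 0.0


@dataclass(frozen=True)
class EfficiencyResult:
    """Raw, ideal, and normalized global efficiency of one network."""

    raw_efficiency: float
    ideal_efficiency: float
    global_efficiency: float


def _length_matrix(weights: np.ndarray, norm_weight: float) -> np.ndarray:
    """Map weights to lengths: length = norm_weight / weight, 0 = absent."""
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, norm_weight / np.maximum(weights, 1e-300), 0.0)
    return lengths


def _pairwise_distances(weights: np.ndarray, norm_weight: float) -> np.ndarray:
    lengths = _length_matrix(weights, norm_weight)
    dist = _csgraph_shortest_path(lengths, method="D", directed=False)
    return dist


def _raw_efficiency(weights: np.ndarray, norm_weight: float) -> float:
    """E(G) = mean over ordered pairs i != j of 1/d(i, j); 1/inf = 0."""
    n = weights.shape[0]
    if n < 2:
        raise MetricError("efficiency is undefined for fewer than 2 nodes")
    if norm_weight <= 0:  # edgeless network: every pair unreachable
        return 0.0
    dist = _pairwise_distances(weights, norm_weight)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def path_lengths(conn: Connectome, norm_weight: float | None = None) -> np.ndarray:
    """All-pairs weighted shortest-path lengths.

    Edge length is ``norm_weight / weight`` (``norm_weight`` defaults to the
    connectome's maximum weight), so the strongest edge has length 1.
    Unreachable pairs are ``+inf``; the diagonal is 0.
    """
    if norm_weight is None:
        norm_weight = conn.max_weight
    if conn.n == 0:
        return np.zeros((0, 0))
    if norm_weight <= 0:
        dist = np.full((conn.n, conn.n), np.inf)
        np.fill_diagonal(dist, 0.0)
        return dist
    return _pairwise_distances(conn.weights, norm_weight)


def global_efficiency(
    conn: Connectome, norm_weight: float | None = None
) -> EfficiencyResult:
    """Global efficiency GE = E(G) / E(G_ideal) of a connectome.

    ``norm_weight`` overrides the weight used for the reciprocal length
    mapping and for the ideal network; lesion analysis passes the *intact*
    network's maximum here so that efficiency loss reflects lost
    communication rather than renormalization.  The ideal network places
    every possible edge at ``norm_weight``, so all its distances are 1 and
    ``E(G_ideal) = 1``.
    """
    if conn.n < 2:
        raise MetricError("global efficiency is undefined for fewer than 2 nodes")
    if norm_weight is None:
        norm_weight = conn.max_weight
    raw = _raw_efficiency(conn.weights, norm_weight)
    ideal = 1.0
    return EfficiencyResult(raw, ideal, raw / ideal)


def local_efficiency(conn: Connectome, node: int) -> float:
    """Efficiency of the subgraph induced by a node's neighbors.

    Measures fault tolerance: how well the node's neighbors communicate when
    the node itself is removed.  Returns 0 for nodes with fewer than two
    neighbors.  Normalization uses the induced subgraph's own maximum weight,
    keeping the result in [0, 1].
    """
    i = conn.index_of(node)
    neighbors = np.flatnonzero(conn.weights[i] > 0)
    if neighbors.size < 2:
        return 0.0
    sub = conn.weights[np.ix_(neighbors, neighbors)]
    return _raw_efficiency(sub, float(sub.max()))


def binarize(conn: Connectome) -> Connectome:
    """Replace every present edge with unit weight (binary topology)."""
    return Connectome(
        (conn.weights > 0).astype(float), conn.region_ids, conn.atlas_ref
    )
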