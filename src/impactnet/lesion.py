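"""In-silico lesion simulation: exhaustive node-deletion sweeps and rankings.

A lesion removes a set of regions and all their connections from a
connectome.  The importance of the deleted set for network communication is
the normalized change in global efficiency

    dGE = (GE_intact - GE_lesioned) / GE_intact

so 1 means total disconnection and negative values are possible (removing an
isolated node raises average efficiency).  The lesioned network's efficiency
uses its own node count in the 1/(n(n-1)) prefactor but the intact network's
maximum weight for the length normalization, so dGE measures lost
communication, not rescaling.

A sweep enumerates every k-subset of regions (k = 1, 2 or 3) in
lexicographic order.  Per-region importance is the region's own dGE for
single deletions; for pairs and triples each combination is ranked by dGE
(rank 1 = largest drop), given a reverse-rank weight w(r) = C(n,k) - r + 1,
and a region's score is the sum of the weights of the combinations
containing it divided by its appearance count C(n-1, k-1) — 128 per region
for pairs and 8128 for triples on a 129-region atlas.  Alternative weight
strategies (1/r, top-m indicator) are available but non-default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .netcore import Connectome, MetricError, _raw_efficiency, global_efficiency

#: sweeps above this region count at k = 3 must opt in explicitly
LARGE_SWEEP_NODE_LIMIT = 60


class LesionError(ValueError):
    """Raised for invalid deletion requests or malformed sweeps."""


@dataclass(frozen=True)
class LesionOutcome:
    """Efficiency change caused by deleting one node set."""

    deleted: tuple[int, ...]
    ge_intact: float
    ge_lesioned: float
    delta_ge: float


@dataclass(frozen=True)
class DeletionSweep:
    """All C(n, k) k-subset deletion outcomes for one connectome."""

    k: int
    region_ids: tuple[int, ...]
    outcomes: tuple[LesionOutcome, ...]
    subject_id: str = ""

    def __post_init__(self):
        n = len(self.region_ids)
        expected = math.comb(n, self.k)
        if len(self.outcomes) != expected:
            raise LesionError(
                f"sweep has {len(self.outcomes)} outcomes, expected C({n},{self.k})={expected}"
            )


@dataclass(frozen=True)
class NodeImportance:
    """Per-region importance scores with a 1..n ranking (1 = most important).

    Ranks are nonincreasing in score; ties are broken by ascending region id.
    """

    region_ids: tuple[int, ...]
    scores: np.ndarray
    ranks: np.ndarray
    provenance: str

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        ranks = np.asarray(self.ranks, dtype=int)
        n = len(self.region_ids)
        if scores.shape != (n,) or ranks.shape != (n,):
            raise LesionError("scores/ranks must have one entry per region")
        if sorted(ranks) != list(range(1, n + 1)):
            raise LesionError("ranks must be a permutation of 1..n")
        scores.setflags(write=False)
        ranks.setflags(write=False)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "ranks", ranks)
        object.__setattr__(self, "region_ids", tuple(int(r) for r in self.region_ids))

    @classmethod
    def from_scores(
        cls, region_ids: Sequence[int], scores: Sequence[float], provenance: str
    ) -> "NodeImportance":
        region_ids = tuple(int(r) for r in region_ids)
        scores = np.asarray(scores, dtype=float)
        order = np.lexsort((region_ids, -scores))  # score desc, id asc
        ranks = np.empty(len(region_ids), dtype=int)
        ranks[order] = np.arange(1, len(region_ids) + 1)
        return cls(region_ids, scores, ranks, provenance)

    def top(self, m: int) -> list[int]:
        """Region ids with rank <= m, in rank order."""
        order = np.argsort(self.ranks)
        return [self.region_ids[i] for i in order[:m]]

    def score_of(self, region_id: int) -> float:
        return float(self.scores[self.region_ids.index(int(region_id))])


def subset_count(n: int, k: int) -> int:
    """Number of distinct k-subsets of n regions, C(n, k)."""
    if not 1 <= k < n:
        raise LesionError(f"need 1 <= k < n, got n={n}, k={k}")
    return math.comb(n, k)


def appearance_count(n: int, k: int) -> int:
    """How often each region appears across all k-subsets: C(n-1, k-1)."""
    if not 1 <= k < n:
        raise LesionError(f"need 1 <= k < n, got n={n}, k={k}")
    return math.comb(n - 1, k - 1)


def delete_nodes(conn: Connectome, nodes: Sequence[int]) -> Connectome:
    """Remove regions and all their connections; surviving ids are preserved."""
    nodes = set(int(v) for v in nodes)
    unknown = nodes - set(conn.region_ids)
    if unknown:
        raise LesionError(f"unknown region ids: {sorted(unknown)}")
    if len(nodes) >= conn.n:
        raise LesionError("cannot delete every region")
    keep = [i for i, r in enumerate(conn.region_ids) if r not in nodes]
    sub = conn.weights[np.ix_(keep, keep)]
    return Connectome(sub, tuple(conn.region_ids[i] for i in keep), conn.atlas_ref)


def delta_ge(
    conn: Connectome,
    nodes: Sequence[int],
    *,
    ge_intact: float | None = None,
    norm_weight: float | None = None,
) -> LesionOutcome:
    """Normalized global-efficiency change caused by deleting ``nodes``.

    ``ge_intact`` and ``norm_weight`` (the intact maximum weight) may be
    passed to amortize the intact computation across a sweep.
    """
    nodes = tuple(sorted(set(int(v) for v in nodes)))
    if not nodes:
        raise LesionError("at least one region must be deleted")
    if norm_weight is None:
        norm_weight = conn.max_weight
    if ge_intact is None:
        ge_intact = global_efficiency(conn, norm_weight).global_efficiency
    if ge_intact <= 0:
        raise MetricError("dGE undefined: intact global efficiency is 0")
    lesioned = delete_nodes(conn, nodes)
    ge_les = _raw_efficiency(lesioned.weights, norm_weight)
    return LesionOutcome(nodes, ge_intact, ge_les, (ge_intact - ge_les) / ge_intact)


def sweep(
    conn: Connectome, k: int, *, subject_id: str = "", allow_large: bool = False
) -> DeletionSweep:
    """Exhaustive deletion sweep over all C(n, k) k-subsets, k in {1, 2, 3}.

    Subsets are enumerated in lexicographic region-id order, so the sweep is
    fully deterministic.  Triple deletions on networks larger than
    ``LARGE_SWEEP_NODE_LIMIT`` regions must set ``allow_large=True`` (the
    full 129-region triple sweep is ~350k efficiency evaluations).
    """
    if k not in (1, 2, 3):
        raise LesionError(f"k must be 1, 2 or 3, got {k}")
    if k >= conn.n:
        raise LesionError(f"k={k} must be smaller than the region count {conn.n}")
    if k == 3 and conn.n > LARGE_SWEEP_NODE_LIMIT and not allow_large:
        raise LesionError(
            f"triple sweep over {conn.n} > {LARGE_SWEEP_NODE_LIMIT} regions is "
            "expensive; pass allow_large=True (CLI: --allow-large) to proceed"
        )
    norm = conn.max_weight
    gi = global_efficiency(conn, norm).global_efficiency
    if gi <= 0:
        raise MetricError("dGE undefined: intact global efficiency is 0")
    w = conn.weights
    ids = conn.region_ids
    n = conn.n
    all_idx = np.arange(n)
    outcomes = []
    for subset in combinations(range(n), k):
        keep = np.delete(all_idx, subset)
        ge_les = _raw_efficiency(w[np.ix_(keep, keep)], norm)
        deleted = tuple(ids[i] for i in subset)
        outcomes.append(LesionOutcome(deleted, gi, ge_les, (gi - ge_les) / gi))
    return DeletionSweep(k, ids, tuple(outcomes), subject_id)


# ---------------------------------------------------------------------------
# rank aggregation

def _weight_linear(rank: int, total: int) -> float:
    return float(total - rank + 1)


def _weight_inverse(rank: int, total: int) -> float:
    return 1.0 / rank


def _weight_top_decile(rank: int, total: int) -> float:
    return 1.0 if rank <= max(1, total // 10) else 0.0


WEIGHT_STRATEGIES: dict[str, Callable[[int, int], float]] = {
    "linear": _weight_linear,
    "inverse_rank": _weight_inverse,
    "top_decile": _weight_top_decile,
}


def aggregate_importance(
    sweep_: DeletionSweep, strategy: str = "linear"
) -> NodeImportance:
    """Collapse a deletion sweep into per-region importance scores.

    For k = 1 a region's score is simply its own dGE.  For k in {2, 3}
    combinations are ranked by dGE (rank 1 = largest drop, ties broken by
    lexicographic subset order), weighted by ``strategy`` (default: reverse
    rank, w(r) = C(n,k) - r + 1), and each region's score is its summed
    combination weight normalized by its appearance count C(n-1, k-1).
    """
    if not sweep_.outcomes:
        raise LesionError("empty sweep")
    ids = sweep_.region_ids
    if sweep_.k == 1:
        by_id = {o.deleted[0]: o.delta_ge for o in sweep_.outcomes}
        scores = [by_id[r] for r in ids]
        return NodeImportance.from_scores(ids, scores, "single")
    try:
        weight_fn = WEIGHT_STRATEGIES[strategy]
    except KeyError:
        raise LesionError(
            f"unknown weight strategy {strategy!r}; choose from {sorted(WEIGHT_STRATEGIES)}"
        ) from None
    total = len(sweep_.outcomes)
    ordered = sorted(sweep_.outcomes, key=lambda o: (-o.delta_ge, o.deleted))
    appearances = appearance_count(len(ids), sweep_.k)
    acc = {r: 0.0 for r in ids}
    for rank, outcome in enumerate(ordered, start=1):
        wgt = weight_fn(rank, total)
        for r in outcome.deleted:
            acc[r] += wgt
    scores = [acc[r] / appearances for r in ids]
    provenance = {2: "pair_aggregate", 3: "triple_aggregate"}[sweep_.k]
    return NodeImportance.from_scores(ids, scores, provenance)


def cohort_importance(
    sweeps: Sequence[DeletionSweep], strategy: str = "linear"
) -> NodeImportance:
    """Cohort-average importance across subjects sharing one atlas.

    For k = 1 the per-region score is the mean dGE across subjects; for
    k > 1 it is the mean of the per-subject aggregate scores.
    """
    if not sweeps:
        raise LesionError("no sweeps given")
    k = sweeps[0].k
    ids = sweeps[0].region_ids
    for s in sweeps[1:]:
        if s.k != k:
            raise LesionError("sweeps mix different deletion sizes k")
        if s.region_ids != ids:
            raise LesionError("sweeps cover different region sets")
    per_subject = [aggregate_importance(s, strategy) for s in sweeps]
    scores = np.mean([imp.scores for imp in per_subject], axis=0)
    return NodeImportance.from_scores(ids, scores, "cohort_average")


# ---------------------------------------------------------------------------
# tabular IO

def sweep_to_frame(sweep_: DeletionSweep) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "deleted": [",".join(map(str, o.deleted)) for o in sweep_.outcomes],
            "ge_intact": [o.ge_intact for o in sweep_.outcomes],
            "ge_lesioned": [o.ge_lesioned for o in sweep_.outcomes],
            "delta_ge": [o.delta_ge for o in sweep_.outcomes],
        }
    )


def frame_to_sweep(
    frame: pd.DataFrame, region_ids: Sequence[int], subject_id: str = ""
) -> DeletionSweep:
    outcomes = tuple(
        LesionOutcome(
            tuple(int(v) for v in str(row.deleted).split(",")),
            float(row.ge_intact),
            float(row.ge_lesioned),
            float(row.delta_ge),
        )
        for row in frame.itertuples()
    )
    k = len(outcomes[0].deleted)
    return DeletionSweep(k, tuple(int(r) for r in region_ids), outcomes, subject_id)


def importance_to_frame(imp: NodeImportance) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": imp.region_ids,
            "score": imp.scores,
            "rank": imp.ranks,
            "provenance": imp.provenance,
        }
    )


def frame_to_importance(frame: pd.DataFrame) -> NodeImportance:
    provenance = str(frame["provenance"].iloc[0]) if "provenance" in frame else ""
    return NodeImportance(
        tuple(int(r) for r in frame["region_id"]),
        frame["score"].to_numpy(dtype=float),
        frame["rank"].to_numpy(dtype=int),
        provenance,
    )
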