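"""Strain-side analytics for reconstructed head impacts.

Each impact case carries four peak kinematic scalars, a per-region maximum
principal strain vector (rMPS: the 95th percentile of element strain within
a parcel) and a whole-brain 95th-percentile strain (MPS95).  This module
ranks regions by strain in concussive impacts, runs per-region two-sample
rank-sum tests with Bonferroni correction, and correlates strain-based
region rankings against network-importance rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lesion import NodeImportance

CONCUSSION = "concussion"
NO_CONCUSSION = "no_concussion"

KINEMATIC_FIELDS = ("peak_lin_vel", "peak_ang_vel", "peak_lin_acc", "peak_ang_acc")


class StrainError(ValueError):
    """Raised for invalid impact data or undefined strain statistics."""


@dataclass(frozen=True)
class ImpactCase:
    """One reconstructed head impact and its injury outcome.

    Kinematics: peak linear velocity (m/s), peak angular velocity (rad/s),
    peak linear acceleration (g), peak angular acceleration (rad/s^2).
    Strain fields are dimensionless (strain).
    """

    case_id: str
    outcome: str
    peak_lin_vel: float
    peak_ang_vel: float
    peak_lin_acc: float
    peak_ang_acc: float
    rmps: np.ndarray
    mps95: float

    def __post_init__(self):
        if self.outcome not in (CONCUSSION, NO_CONCUSSION):
            raise StrainError(f"unknown outcome label {self.outcome!r}")
        rmps = np.asarray(self.rmps, dtype=float)
        if rmps.ndim != 1:
            raise StrainError("rmps must be a 1-D per-region vector")
        if np.any(rmps < 0) or self.mps95 < 0:
            raise StrainError("strains must be nonnegative")
        rmps.setflags(write=False)
        object.__setattr__(self, "rmps", rmps)

    @property
    def is_concussive(self) -> bool:
        return self.outcome == CONCUSSION


@dataclass(frozen=True)
class RegionTestResult:
    """Per-region concussive vs non-concussive rank-sum comparison."""

    region_id: int
    statistic: float
    p_value: float
    significant_bonferroni: bool


def percentile95(values: Sequence[float], method: str = "linear") -> float:
    """95th percentile with linear interpolation between closest ranks.

    The interpolation scheme is configurable via ``method`` (any numpy
    percentile method) because finite-element post-processors differ.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise StrainError("percentile of an empty sample is undefined")
    return float(np.percentile(values, 95, method=method))


def rank_by_strain(
    cases: Sequence[ImpactCase],
    region_ids: Sequence[int] | None = None,
    stat: str = "mean",
) -> NodeImportance:
    """Rank regions by their rMPS across concussive impacts only.

    ``stat`` selects mean (default) or median over the concussive cases.
    Non-concussive cases never influence the ranking.
    """
    concussive = [c for c in cases if c.is_concussive]
    if not concussive:
        raise StrainError("strain ranking needs at least one concussive case")
    mat = np.vstack([c.rmps for c in concussive])
    if stat == "mean":
        scores = mat.mean(axis=0)
    elif stat == "median":
        scores = np.median(mat, axis=0)
    else:
        raise StrainError(f"stat must be 'mean' or 'median', got {stat!r}")
    if region_ids is None:
        region_ids = range(mat.shape[1])
    return NodeImportance.from_scores(region_ids, scores, f"strain_{stat}")


def ranksum_test(
    x: Sequence[float], y: Sequence[float], exact_cutoff: int = 8
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic, p).

    Uses the exact null distribution of the Mann-Whitney statistic when the
    smaller group has at most ``exact_cutoff`` observations and there are no
    ties, and a tie-corrected normal approximation with continuity
    correction otherwise.  The returned statistic is the rank sum of ``x``
    (midranks for ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StrainError("rank-sum test needs two nonempty samples")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:nx].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if min(nx, ny) <= exact_cutoff and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return w, float(res.pvalue)
    n = nx + ny
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation tied: no evidence either way
        return w, 1.0
    dev = w - mu
    dev -= 0.5 * np.sign(dev)  # continuity correction toward the null
    p = 2.0 * stats.norm.sf(abs(dev) / np.sqrt(var))
    return w, float(min(p, 1.0))


def regional_tests(
    cases: Sequence[ImpactCase],
    alpha: float = 0.05,
    bonferroni_n: int | None = None,
    region_ids: Sequence[int] | None = None,
) -> list[RegionTestResult]:
    """Concussive vs non-concussive rank-sum test for every region's rMPS.

    ``bonferroni_n`` is the number of comparisons used for the corrected
    threshold ``alpha / bonferroni_n``; it defaults to the region count.
    """
    conc = [c for c in cases if c.is_concussive]
    nonc = [c for c in cases if not c.is_concussive]
    if not conc or not nonc:
        raise StrainError("regional tests need both outcome groups nonempty")
    conc_mat = np.vstack([c.rmps for c in conc])
    nonc_mat = np.vstack([c.rmps for c in nonc])
    n_regions = conc_mat.shape[1]
    if bonferroni_n is None:
        bonferroni_n = n_regions
    if region_ids is None:
        region_ids = range(n_regions)
    threshold = alpha / bonferroni_n
    results = []
    for j, rid in zip(range(n_regions), region_ids):
        statistic, p = ranksum_test(conc_mat[:, j], nonc_mat[:, j])
        results.append(RegionTestResult(int(rid), statistic, p, p < threshold))
    return results


def kinematic_tests(cases: Sequence[ImpactCase]) -> dict[str, tuple[float, float]]:
    """Uncorrected rank-sum tests for the four kinematic peaks and MPS95."""
    conc = [c for c in cases if c.is_concussive]
    nonc = [c for c in cases if not c.is_concussive]
    if not conc or not nonc:
        raise StrainError("kinematic tests need both outcome groups nonempty")
    out = {}
    for name in KINEMATIC_FIELDS + ("mps95",):
        xs = [getattr(c, name) for c in conc]
        ys = [getattr(c, name) for c in nonc]
        out[name] = ranksum_test(xs, ys)
    return out


def ranking_correlation(
    a: NodeImportance, b: NodeImportance, use: str = "scores"
) -> tuple[float, float]:
    """Pearson correlation between two region-importance profiles.

    ``use='scores'`` (default) correlates the raw score vectors;
    ``use='ranks'`` correlates the rank vectors (a Spearman-style view of the
    same question).  Returns (rho, two-sided p from the t transform).
    """
    if a.region_ids != b.region_ids:
        raise StrainError("rankings cover different region sets")
    if use == "scores":
        va, vb = a.scores, b.scores
    elif use == "ranks":
        va, vb = a.ranks.astype(float), b.ranks.astype(float)
    else:
        raise StrainError(f"use must be 'scores' or 'ranks', got {use!r}")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise StrainError("correlation undefined: a score vector has zero variance")
    res = stats.pearsonr(va, vb)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# tabular IO

def impacts_to_frame(cases: Sequence[ImpactCase]) -> pd.DataFrame:
    n_regions = cases[0].rmps.size
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "outcome": c.outcome,
            **{f: getattr(c, f) for f in KINEMATIC_FIELDS},
            "mps95": c.mps95,
        }
        row.update({f"rmps_{j}": c.rmps[j] for j in range(n_regions)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_impacts(frame: pd.DataFrame) -> list[ImpactCase]:
    rmps_cols = sorted(
        (c for c in frame.columns if c.startswith("rmps_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return [
        ImpactCase(
            case_id=str(row["case_id"]),
            outcome=str(row["outcome"]),
            peak_lin_vel=float(row["peak_lin_vel"]),
            peak_ang_vel=float(row["peak_ang_vel"]),
            peak_lin_acc=float(row["peak_lin_acc"]),
            peak_ang_acc=float(row["peak_ang_acc"]),
            rmps=row[rmps_cols].to_numpy(dtype=float),
            mps95=float(row["mps95"]),
        )
        for _, row in frame.iterrows()
    ]
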