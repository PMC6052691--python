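"""Pairwise community dissimilarity and temporal stability.

Two complementary views of community change: Bray-Curtis weights OTUs by
abundance (community *structure*), Jaccard uses presence/absence only
(community *membership*). Within-reactor dissimilarities over a monthly time
series measure temporal stability — the lower the mean, the more stable the
community.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import CountTable, DistanceMatrix, SampleMetadata
from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "bray_curtis",
    "jaccard_dissimilarity",
    "distance_matrix",
    "temporal_stability",
    "StabilitySummary",
]

METRICS = ("bray_curtis", "jaccard")


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundances must be non-negative")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]."""
    x, y = _pair(x, y)
    denom = float((x + y).sum())
    if denom == 0.0:
        raise UndefinedStatisticError(
            "Bray-Curtis undefined between two empty communities"
        )
    return float(np.abs(x - y).sum() / denom)


def jaccard_dissimilarity(x, y) -> float:
    """Jaccard dissimilarity on presence/absence: 1 - |A&B| / |A|B|."""
    x, y = _pair(x, y)
    a = x > 0
    b = y > 0
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise UndefinedStatisticError(
            "Jaccard undefined between two empty communities"
        )
    return float(1.0 - np.count_nonzero(a & b) / union)


def distance_matrix(table: CountTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """All pairwise sample dissimilarities of a count table."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    totals = table.counts.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        raise ValidationError(
            f"all-zero sample(s): {[table.sample_ids[i] for i in empty]}"
        )
    if metric == "bray_curtis":
        condensed = pdist(table.counts.astype(float), metric="braycurtis")
    else:
        condensed = pdist(table.counts > 0, metric="jaccard")
    return DistanceMatrix(list(table.sample_ids), squareform(condensed), metric=metric)


@dataclass
class StabilitySummary:
    """Within-group dissimilarity summary; lower mean means more stable."""

    group: str
    scheme: str
    metric: str
    n_pairs: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float


def _pairs_for(order: list[int], scheme: str) -> list[tuple[int, int]]:
    if scheme == "consecutive":
        return list(zip(order, order[1:]))
    return list(itertools.combinations(order, 2))


def temporal_stability(
    table: CountTable,
    metadata: SampleMetadata,
    metric: str = "bray_curtis",
    scheme: str = "all_pairs",
    group_by: str = "reactor",
    cluster_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Within-group community dissimilarity over a time series.

    Parameters
    ----------
    scheme : {"all_pairs", "consecutive"}
        ``all_pairs`` pools every within-group sample pair (k samples give
        k(k-1)/2 pairs); ``consecutive`` uses only month-to-month pairs
        (k-1 pairs) after ordering by timepoint.
    group_by : {"reactor", "cluster"}
        Grouping key; ``cluster`` requires ``cluster_labels`` (a Series
        mapping sample_id to a cluster label, e.g. from
        :func:`corescope.community_stats.assign_clusters`).

    Returns one row per group with mean, sd, pair count and a normal-theory
    95% CI of the pooled dissimilarities. Groups with fewer than 2 samples
    are skipped with a warning.
    """
    if scheme not in ("all_pairs", "consecutive"):
        raise ValueError(f"unknown scheme {scheme!r}")
    dm = distance_matrix(table, metric=metric)
    meta = metadata.table
    if group_by == "reactor":
        groups = meta.loc[[s for s in table.sample_ids], "reactor"]
    elif group_by == "cluster":
        if cluster_labels is None:
            raise ValidationError("group_by='cluster' requires cluster_labels")
        groups = cluster_labels.loc[[s for s in table.sample_ids]]
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    timepoints = meta.loc[[s for s in table.sample_ids], "timepoint"]
    index_of = {s: i for i, s in enumerate(dm.sample_ids)}
    rows = []
    for group in pd.unique(groups):
        members = [s for s, g in zip(table.sample_ids, groups) if g == group]
        if len(members) < 2:
            warnings.warn(
                f"group {group!r} has {len(members)} sample(s); skipped",
                stacklevel=2,
            )
            continue
        members = sorted(members, key=lambda s: (int(timepoints[s]), s))
        order = [index_of[s] for s in members]
        dists = np.array([dm.values[i, j] for i, j in _pairs_for(order, scheme)])
        mean = float(dists.mean())
        sd = float(dists.std(ddof=1)) if len(dists) > 1 else 0.0
        half = 1.96 * sd / np.sqrt(len(dists)) if len(dists) > 1 else 0.0
        rows.append(
            StabilitySummary(
                group=str(group), scheme=scheme, metric=metric,
                n_pairs=len(dists), mean=mean, sd=sd,
                ci95_low=mean - half, ci95_high=mean + half,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
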