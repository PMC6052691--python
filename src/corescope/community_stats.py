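"""Distance-based group statistics and nonparametric tests.

ANOSIM (analysis of similarities) asks whether between-group dissimilarities
exceed within-group ones on ranks: R = (mean between-group rank - mean
within-group rank) / (M/2) with M = n(n-1)/2 pairwise distances, so R is 1
under perfect separation, about 0 under none, and its significance comes from
whole-sample label permutations (add-one p estimator, never exactly 0).

NMDS, hierarchical cluster assignment, Kruskal-Wallis, Wilcoxon signed rank
and Spearman correlation matrices round out the statistics used to compare
diversity and stability between community clusters and to relate abundances
to physicochemical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import DistanceMatrix
from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "AnosimResult",
    "NmdsResult",
    "anosim",
    "nmds_embed",
    "assign_clusters",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "spearman_matrix",
]


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.R <= 1.0 + 1e-9:
            raise ValidationError(f"ANOSIM R out of range: {self.R}")


def _labels_vector(dm: DistanceMatrix, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        missing = [s for s in dm.sample_ids if s not in labels.index]
        if missing:
            raise ValidationError(f"labels missing for samples: {missing[:5]}")
        vec = labels.loc[dm.sample_ids].to_numpy()
    elif isinstance(labels, Mapping):
        vec = np.array([labels[s] for s in dm.sample_ids])
    else:
        vec = np.asarray(labels)
        if vec.shape != (dm.n_samples,):
            raise ValidationError("labels must align with the distance matrix")
    return vec


def anosim(
    dm: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Rank-based permutation test of group separation on a distance matrix.

    ``labels`` may be a Series indexed by sample id, a mapping, or a vector
    aligned with ``dm.sample_ids``. Every group needs at least 2 samples.
    The p-value is one-sided (between > within) with the add-one estimator
    p = (1 + #{permuted R >= observed R}) / (1 + n_permutations).
    """
    vec = _labels_vector(dm, labels)
    codes, counts = np.unique(vec, return_counts=True)
    if len(codes) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        singleton = codes[counts.argmin()]
        raise ValidationError(f"group {singleton!r} has fewer than 2 samples")
    n = dm.n_samples
    iu0, iu1 = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.values[iu0, iu1])  # mid-ranks for ties
    m = ranks.size
    denom = m / 2.0

    code_of = {c: i for i, c in enumerate(codes)}
    int_labels = np.array([code_of[v] for v in vec])

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu0] == lab[iu1]
        return float(
            (ranks[~within].mean() - ranks[within].mean()) / denom
        )

    r_obs = r_stat(int_labels)

    rng = np.random.default_rng(seed)
    # vectorised permutations: (n_permutations, n) label matrix
    perm = np.argsort(rng.random((n_permutations, n)), axis=1)
    lab_perm = int_labels[perm]
    within = lab_perm[:, iu0] == lab_perm[:, iu1]
    n_within = within.sum(axis=1).astype(float)
    sum_within = (ranks * within).sum(axis=1)
    total = ranks.sum()
    mean_within = sum_within / n_within
    mean_between = (total - sum_within) / (m - n_within)
    r_perm = (mean_between - mean_within) / denom
    p = (1.0 + int(np.count_nonzero(r_perm >= r_obs))) / (1.0 + n_permutations)
    return AnosimResult(R=r_obs, p=float(p), n_permutations=n_permutations, seed=seed)


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    r2: float
    seed: int | None
    converged: bool


def nmds_embed(
    dm: DistanceMatrix,
    dims: int = 2,
    seed: int | None = None,
    n_starts: int = 4,
    max_iter: int = 1000,
) -> NmdsResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Kruskal stress-1 minimisation (isotonic regression) from ``n_starts``
    random initialisations; the best configuration is returned. ``r2`` is
    the squared Pearson correlation between ordination distances and the
    original dissimilarities — one reasonable goodness-of-fit summary, not
    the only one in use.
    """
    from sklearn.manifold import MDS

    if dims < 1:
        raise ValidationError("dims must be >= 1")
    if dims >= dm.n_samples:
        raise ValidationError(
            f"dims={dims} must be below the number of samples ({dm.n_samples})"
        )
    model = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        eps=1e-9,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(dm.values)
    ord_dist = pdist(coords)
    orig = dm.condensed()
    if np.ptp(ord_dist) == 0 or np.ptp(orig) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(ord_dist, orig)[0, 1] ** 2)
    stress = float(model.stress_)
    return NmdsResult(
        coordinates=pd.DataFrame(
            coords,
            index=pd.Index(dm.sample_ids, name="sample_id"),
            columns=[f"NMDS{i + 1}" for i in range(dims)],
        ),
        stress=stress,
        r2=r2,
        seed=seed,
        converged=bool(np.isfinite(stress)),
    )


def assign_clusters(
    dm: DistanceMatrix, k: int, linkage: str = "average"
) -> pd.Series:
    """Cut an agglomerative tree of the distance matrix into k clusters.

    Deterministic given the matrix; labels are integers 1..k and are only
    meaningful up to relabelling.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if not 1 <= k <= dm.n_samples:
        raise ValidationError(f"k={k} out of range [1, {dm.n_samples}]")
    tree = hierarchy.linkage(dm.condensed(), method=linkage)
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=pd.Index(dm.sample_ids, name="sample_id"),
                     name="cluster")


@dataclass
class KruskalResult:
    H: float
    p: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis rank test with mid-rank tie correction.

    p comes from the chi-square approximation with (#groups - 1) degrees of
    freedom. All-identical data (H = 0) returns p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("Kruskal-Wallis groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValidationError("Kruskal-Wallis needs at least 3 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # scipy refuses all-identical input
        return KruskalResult(H=0.0, p=1.0)
    h, p = stats.kruskal(*arrays)
    return KruskalResult(H=float(h), p=float(p))


@dataclass
class WilcoxonResult:
    W: float
    p: float
    n_used: int


def wilcoxon_signed_rank(x, y, continuity: bool = True) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped before ranking; W is the sum of the ranks of
    positive differences; p uses the normal approximation, by default with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-D vectors")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedStatisticError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=continuity,
        alternative="two-sided", method="approx",
    )
    return WilcoxonResult(W=w_pos, p=float(res.pvalue), n_used=int(d.size))


def spearman_matrix(
    params: pd.DataFrame,
    features: pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman rank correlations between covariates and features.

    One row per (parameter, feature) cell with rho, two-sided p, the number
    of complete pairs used (missing values are pairwise-deleted) and a
    significance flag at ``alpha``. Cells with fewer than 3 complete pairs or
    a constant vector are flagged undefined (NaN rho). ``adjust=True``
    applies Benjamini-Hochberg across the defined cells; the default is the
    unadjusted per-cell p.
    """
    common = params.index.intersection(features.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 shared samples")
    params = params.loc[common]
    features = features.loc[common]
    rows = []
    for pcol in params.columns:
        for fcol in features.columns:
            pv = params[pcol].astype(float)
            fv = features[fcol].astype(float)
            mask = pv.notna() & fv.notna()
            n = int(mask.sum())
            if n < 3 or pv[mask].nunique() == 1 or fv[mask].nunique() == 1:
                rows.append(
                    {"parameter": pcol, "feature": fcol, "n": n,
                     "rho": float("nan"), "p": float("nan"), "defined": False}
                )
                continue
            rho, p = stats.spearmanr(pv[mask], fv[mask])
            rows.append(
                {"parameter": pcol, "feature": fcol, "n": n,
                 "rho": float(rho), "p": float(p), "defined": True}
            )
    out = pd.DataFrame(rows)
    pcol_name = "p"
    if adjust:
        defined = out["defined"]
        adjusted = np.full(len(out), np.nan)
        if defined.any():
            adjusted[defined.to_numpy()] = stats.false_discovery_control(
                out.loc[defined, "p"].to_numpy(), method="bh"
            )
        out["p_adjusted"] = adjusted
        pcol_name = "p_adjusted"
    out["significant"] = out[pcol_name] <= alpha
    out.loc[~out["defined"], "significant"] = False
    return out
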