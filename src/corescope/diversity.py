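"""Alpha diversity: observed richness, inverse Simpson, evenness, rarefaction.

All indices are meant to be computed on a fixed-depth subsampled table so they
are comparable across samples; :func:`diversity_table` refuses unequal sample
totals unless explicitly overridden.

Estimator notes
---------------
Two inverse Simpson forms are provided. The maximum-likelihood form
``1 / sum(p_i^2)`` is bounded by the observed richness S, so the evenness
ratio ``invsimpson_mle / S`` lies in (0, 1] and equals 1 exactly for a
uniform community. The finite-sample unbiased form ``N(N-1) / sum(n_i(n_i-1))``
(the default index, matching common 16S practice) can exceed S on small
samples — e.g. counts (5, 5) give 2.25 > 2 — so evenness always uses the MLE
form to keep its documented 0-to-1 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import CountTable
from .errors import UndefinedStatisticError, ValidationError
from .normalize import to_relative

__all__ = [
    "richness_sobs",
    "inverse_simpson",
    "evenness_invsimpson",
    "diversity_table",
    "rarefaction_curve",
    "rank_abundance",
]


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValidationError("expected a 1-D count vector")
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError("counts must be integers")
    arr = arr.astype(np.int64)
    if arr.size and arr.min() < 0:
        raise ValidationError("counts must be non-negative")
    return arr


def richness_sobs(counts) -> int:
    """Observed richness: number of OTUs with at least one read."""
    return int(np.count_nonzero(_as_counts(counts)))


def inverse_simpson(counts, mode: str = "unbiased") -> float:
    """Inverse Simpson diversity of one sample.

    mode="mle": 1 / sum(p_i^2).  mode="unbiased": N(N-1) / sum(n_i(n_i-1)),
    undefined (raises) when every present OTU is a singleton.
    """
    n = _as_counts(counts)
    total = int(n.sum())
    if mode == "mle":
        if total < 1:
            raise UndefinedStatisticError("inverse Simpson needs at least one read")
        p = n / total
        return float(1.0 / np.sum(p * p))
    if mode == "unbiased":
        if total < 2:
            raise UndefinedStatisticError(
                "unbiased inverse Simpson needs at least two reads"
            )
        denom = float(np.sum(n * (n - 1.0)))
        if denom == 0.0:
            raise UndefinedStatisticError(
                "unbiased inverse Simpson undefined: all OTUs are singletons"
            )
        return float(total * (total - 1.0) / denom)
    raise ValueError(f"unknown inverse Simpson mode {mode!r}")


def evenness_invsimpson(counts) -> float:
    """Inverse-Simpson evenness: invsimpson(mle) / sobs, in (0, 1].

    1 means a perfectly even community (all present OTUs equally abundant);
    values near 0 indicate one or a few dominant OTUs among many singlets.
    """
    sobs = richness_sobs(counts)
    if sobs == 0:
        raise UndefinedStatisticError("evenness undefined for an empty sample")
    return inverse_simpson(counts, mode="mle") / sobs


def diversity_table(
    table: CountTable, mode: str = "unbiased", allow_unequal_depth: bool = False
) -> pd.DataFrame:
    """Per-sample sobs / invsimpson / evenness summary.

    Expects a fixed-depth (subsampled) table; refuses unequal sample totals
    unless ``allow_unequal_depth`` is set. Samples where the unbiased index is
    undefined (all singletons) get NaN in the invsimpson column.
    """
    totals = table.sample_totals()
    if not allow_unequal_depth and totals.nunique() > 1:
        raise ValidationError(
            "sample totals differ; subsample first or pass allow_unequal_depth=True"
        )
    rows = []
    for sid, counts in zip(table.sample_ids, table.counts):
        sobs = richness_sobs(counts)
        try:
            inv = inverse_simpson(counts, mode=mode)
        except UndefinedStatisticError:
            inv = float("nan")
        even = evenness_invsimpson(counts) if sobs else float("nan")
        rows.append(
            {"sample_id": sid, "sobs": sobs, "invsimpson": inv,
             "evenness": even, "depth": int(totals[sid])}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _analytic_expected_richness(n: np.ndarray, depth: int) -> float:
    # E[S_d] = sum_j 1 - C(N - n_j, d) / C(N, d), via log-gamma for stability
    total = int(n.sum())
    present = n[n > 0].astype(float)
    rest = total - present  # N - n_j
    log_cn = gammaln(total + 1) - gammaln(depth + 1) - gammaln(total - depth + 1)
    with np.errstate(invalid="ignore"):
        log_c = gammaln(rest + 1) - gammaln(depth + 1) - gammaln(rest - depth + 1)
    prob_absent = np.where(rest >= depth, np.exp(log_c - log_cn), 0.0)
    return float(np.sum(1.0 - prob_absent))


def rarefaction_curve(
    counts,
    depths,
    method: str = "analytic",
    reps: int = 100,
    seed: int | None = None,
) -> pd.Series:
    """Expected richness at each subsampling depth for one sample.

    analytic: exact hypergeometric expectation
    E[S_d] = sum_j [1 - C(N - n_j, d) / C(N, d)].
    resample: mean observed richness over ``reps`` random subsamples without
    replacement. Either way the curve is non-decreasing in depth and reaches
    the observed richness exactly at the full depth N.
    """
    n = _as_counts(counts)
    total = int(n.sum())
    depths = [int(d) for d in depths]
    if any(d < 1 or d > total for d in depths):
        raise ValidationError(f"depths must lie in [1, {total}]")
    if method == "analytic":
        values = [_analytic_expected_richness(n, d) for d in depths]
    elif method == "resample":
        rng = np.random.default_rng(seed)
        values = []
        for d in depths:
            sobs_reps = [
                richness_sobs(rng.multivariate_hypergeometric(n, d))
                for _ in range(reps)
            ]
            values.append(float(np.mean(sobs_reps)))
    else:
        raise ValueError(f"unknown rarefaction method {method!r}")
    return pd.Series(values, index=pd.Index(depths, name="depth"), name="expected_sobs")


def rank_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample descending relative-abundance curves.

    Returns a long DataFrame (sample_id, rank, otu_id, relative_abundance)
    covering present OTUs only; ties are broken by OTU id so output is
    deterministic. After subsampling to depth d the smallest nonzero
    relative abundance is exactly 1/d — the detection limit of the assay.
    """
    rel = to_relative(table)
    frames = []
    for sid in table.sample_ids:
        row = rel.loc[sid]
        row = row[row > 0]
        ordered = row.sort_index().sort_values(ascending=False, kind="stable")
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "rank": np.arange(1, len(ordered) + 1),
                    "otu_id": ordered.index,
                    "relative_abundance": ordered.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def detection_limit(depth: int) -> float:
    """Smallest nonzero relative abundance observable at a subsampling depth."""
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    return 1.0 / depth
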