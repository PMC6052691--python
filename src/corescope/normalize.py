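"""Bring raw count tables to the analysis state.

Three steps, applied in this order throughout the pipeline:

1. drop OTUs supported by fewer than ``min_total`` reads study-wide
   (singleton removal by default);
2. subsample every sample to a fixed depth without replacement
   (multivariate hypergeometric), dropping samples below depth, so all
   downstream detection and diversity comparisons are depth-controlled;
3. convert to relative abundances only where an operation needs proportions.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SubsampleConfig", "filter_low_count_otus", "subsample", "to_relative"]


@dataclass(frozen=True)
class SubsampleConfig:
    """Fixed-depth subsampling parameters.

    depth
        Reads to draw per sample (e.g. 11,550 for bacterial 16S assays,
        2,070 for archaeal ones in the study design this package targets).
    seed
        Global seed; each sample gets an independent substream derived from
        ``(seed, crc32(sample_id))`` so removing or reordering samples never
        changes the draws of the others.
    drop_below_depth
        Drop samples whose total is below depth (the alternative is an error).
    """

    depth: int
    seed: int = 0
    drop_below_depth: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError(f"subsampling depth must be >= 1, got {self.depth}")


def filter_low_count_otus(table: CountTable, min_total: int = 2) -> CountTable:
    """Remove OTUs with fewer than ``min_total`` reads summed over all samples.

    The default 2 keeps only OTUs represented by more than one sequence,
    discarding study-wide singletons. Samples are never removed.
    """
    if min_total < 1:
        raise ValidationError(f"min_total must be >= 1, got {min_total}")
    keep = table.counts.sum(axis=0) >= min_total
    return CountTable(
        sample_ids=list(table.sample_ids),
        otu_ids=[o for o, k in zip(table.otu_ids, keep) if k],
        counts=table.counts[:, keep],
        domain=table.domain,
        label=table.label,
    )


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])


def subsample(table: CountTable, cfg: SubsampleConfig) -> CountTable:
    """Subsample each sample to ``cfg.depth`` reads without replacement.

    Each retained sample is one independent multivariate-hypergeometric draw
    from its own reads, so subsampled counts never exceed the originals and
    every output sample sums exactly to depth. A sample whose total equals
    depth is returned unchanged.
    """
    totals = table.counts.sum(axis=1)
    below = totals < cfg.depth
    if below.all():
        raise ValidationError(
            f"all {table.n_samples} samples are below depth {cfg.depth}"
        )
    if below.any():
        dropped = [s for s, b in zip(table.sample_ids, below) if b]
        if not cfg.drop_below_depth:
            raise ValidationError(
                f"{len(dropped)} samples below depth {cfg.depth}: {dropped}"
            )
        logger.warning(
            "dropping %d/%d samples below depth %d: %s",
            len(dropped), table.n_samples, cfg.depth, ", ".join(dropped),
        )
    keep_idx = np.flatnonzero(~below)
    out = np.empty((len(keep_idx), table.n_otus), dtype=np.int64)
    for row, i in enumerate(keep_idx):
        counts = table.counts[i]
        if totals[i] == cfg.depth:  # exhaustive draw
            out[row] = counts
            continue
        rng = _sample_rng(cfg.seed, table.sample_ids[i])
        out[row] = rng.multivariate_hypergeometric(counts, cfg.depth)
    return CountTable(
        sample_ids=[table.sample_ids[i] for i in keep_idx],
        otu_ids=list(table.otu_ids),
        counts=out,
        domain=table.domain,
        label=table.label,
    )


def to_relative(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances p_ij = n_ij / N_i as a float DataFrame.

    Rows (samples) sum to 1 within 1e-12. A zero-total sample is an error
    naming the sample; drop or re-subsample first.
    """
    totals = table.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"zero-total sample(s): {[table.sample_ids[i] for i in zero]}"
        )
    rel = table.counts / totals[:, None]
    return pd.DataFrame(
        rel, index=pd.Index(table.sample_ids, name="sample_id"),
        columns=table.otu_ids,
    )
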