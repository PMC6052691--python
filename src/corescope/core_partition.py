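"""Occurrence-based core / transient / intermediate OTU partitioning.

The central procedure: within a chosen sample scope, each detected OTU's
occurrence is the fraction of scope samples where it carries at least
``detection_min_count`` reads. OTUs occurring in *more than* 80% of samples
(strictly) form the core; OTUs present in *less than* 20% (strictly, but in
at least one sample) are transient; everything else — including exact
boundary values — is intermediate. Occurrence should be computed on a
fixed-depth subsampled table so detection is depth-controlled.

System-specific cores (e.g. a wastewater-treatment-plant core) are obtained
by re-running the partition with scope set to that system's samples — the
occurrence denominator changes, not the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import CountTable
from .errors import ValidationError
from .normalize import to_relative

__all__ = [
    "PartitionThresholds",
    "PartitionResult",
    "AbundanceShare",
    "CoreOverlap",
    "occurrence_fractions",
    "partition_otus",
    "subset_table",
    "abundance_share",
    "mean_nonzero_abundance",
    "occurrence_abundance_summary",
    "core_overlap",
]

LABELS = ("core", "intermediate", "transient")


@dataclass(frozen=True)
class PartitionThresholds:
    """Occurrence thresholds; both comparisons are strict.

    core_min_occurrence
        Core iff occurrence > this (default 0.80: "more than 80% of samples").
    transient_max_occurrence
        Transient iff 0 < occurrence < this (default 0.20).
    detection_min_count
        Reads required to count an OTU as present in a sample (default 1).
    """

    core_min_occurrence: float = 0.80
    transient_max_occurrence: float = 0.20
    detection_min_count: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.transient_max_occurrence < self.core_min_occurrence <= 1.0):
            raise ValidationError(
                "need 0 <= transient_max_occurrence < core_min_occurrence <= 1, got "
                f"{self.transient_max_occurrence} / {self.core_min_occurrence}"
            )
        if self.detection_min_count < 1:
            raise ValidationError("detection_min_count must be >= 1")


@dataclass
class PartitionResult:
    """Outcome of one core/transient partition run.

    ``assignment`` covers exactly the OTUs detected in the scope (an OTU never
    seen in the scope has no assignment there); ``universe`` records the full
    OTU set of the source table so two partitions can be compared safely.
    """

    scope: list[str]
    occurrence: pd.Series
    assignment: pd.Series
    thresholds: PartitionThresholds
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        # completeness & disjointness are structural for a Series, but the
        # label set and occurrence consistency are asserted on every run
        bad = set(self.assignment.unique()) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown partition labels: {bad}")
        if not self.assignment.index.equals(self.occurrence.index):
            raise ValidationError("assignment and occurrence must share an index")

    def otus(self, label: str) -> list[str]:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return list(self.assignment.index[self.assignment == label])

    @property
    def core_otus(self) -> list[str]:
        return self.otus("core")

    @property
    def transient_otus(self) -> list[str]:
        return self.otus("transient")

    @property
    def intermediate_otus(self) -> list[str]:
        return self.otus("intermediate")

    def counts(self) -> dict[str, int]:
        return {label: int((self.assignment == label).sum()) for label in LABELS}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"occurrence": self.occurrence, "assignment": self.assignment}
        ).rename_axis("otu_id")


def _resolve_scope(table: CountTable, scope: Sequence[str] | None) -> list[str]:
    if scope is None:
        return list(table.sample_ids)
    scope = list(scope)
    if not scope:
        raise ValidationError("scope must be non-empty")
    unknown = set(scope) - set(table.sample_ids)
    if unknown:
        raise ValidationError(f"scope samples not in table: {sorted(unknown)}")
    return scope


def occurrence_fractions(
    table: CountTable,
    scope: Sequence[str] | None = None,
    detection_min_count: int = 1,
) -> pd.Series:
    """Fraction of scope samples where each OTU is detected.

    Detection means count >= detection_min_count. OTUs absent from every
    scope sample get 0. Scope defaults to all samples.
    """
    scope = _resolve_scope(table, scope)
    idx = [table.sample_index(s) for s in scope]
    detected = table.counts[idx] >= detection_min_count
    frac = detected.sum(axis=0) / len(scope)
    return pd.Series(frac, index=pd.Index(table.otu_ids, name="otu_id"),
                     name="occurrence")


def partition_otus(
    table: CountTable,
    scope: Sequence[str] | None = None,
    thresholds: PartitionThresholds = PartitionThresholds(),
) -> PartitionResult:
    """Classify every OTU detected in the scope as core/transient/intermediate.

    Strict comparisons: occurrence > core_min is core, 0 < occurrence <
    transient_max is transient, everything else (boundary values included)
    is intermediate. OTUs with zero occurrence in the scope are excluded
    from the partition universe.
    """
    scope = _resolve_scope(table, scope)
    occ = occurrence_fractions(table, scope, thresholds.detection_min_count)
    occ = occ[occ > 0]
    labels = np.where(
        occ.to_numpy() > thresholds.core_min_occurrence,
        "core",
        np.where(
            occ.to_numpy() < thresholds.transient_max_occurrence,
            "transient",
            "intermediate",
        ),
    )
    assignment = pd.Series(labels, index=occ.index, name="assignment")
    return PartitionResult(
        scope=scope,
        occurrence=occ,
        assignment=assignment,
        thresholds=thresholds,
        universe=tuple(table.otu_ids),
    )


def subset_table(table: CountTable, otu_set: Iterable[str]) -> CountTable:
    """Restrict a table to a set of OTUs (counts untouched, samples kept).

    An empty set yields a zero-column table (allowed; downstream shares are 0).
    """
    otu_set = list(dict.fromkeys(otu_set))  # preserve order, drop dups
    unknown = set(otu_set) - set(table.otu_ids)
    if unknown:
        raise ValidationError(f"unknown OTU id(s): {sorted(unknown)[:5]}")
    pos = {o: i for i, o in enumerate(table.otu_ids)}
    idx = [pos[o] for o in otu_set]
    return CountTable(
        sample_ids=list(table.sample_ids),
        otu_ids=otu_set,
        counts=table.counts[:, idx] if idx else
        np.zeros((table.n_samples, 0), dtype=np.int64),
        domain=table.domain,
        label=table.label,
    )


@dataclass
class AbundanceShare:
    """Per-sample read share of an OTU set, with its mean +/- sd over a scope."""

    per_sample: pd.Series
    mean: float
    sd: float

    def as_percent(self) -> str:
        return f"{100 * self.mean:.1f}% ± {100 * self.sd:.1f}"


def abundance_share(
    table: CountTable,
    otu_set: Iterable[str],
    scope: Sequence[str] | None = None,
) -> AbundanceShare:
    """Fraction of each scope sample's reads carried by ``otu_set``."""
    scope = _resolve_scope(table, scope)
    otu_set = set(otu_set)
    unknown = otu_set - set(table.otu_ids)
    if unknown:
        raise ValidationError(f"unknown OTU id(s): {sorted(unknown)[:5]}")
    idx = [table.sample_index(s) for s in scope]
    totals = table.counts[idx].sum(axis=1)
    zero = [scope[i] for i in np.flatnonzero(totals == 0)]
    if zero:
        raise ValidationError(f"zero-total sample(s): {zero}")
    cols = [i for i, o in enumerate(table.otu_ids) if o in otu_set]
    in_set = table.counts[np.ix_(idx, cols)].sum(axis=1) if cols else np.zeros(len(idx))
    share = pd.Series(in_set / totals, index=scope, name="share")
    return AbundanceShare(
        per_sample=share,
        mean=float(share.mean()),
        sd=float(share.std(ddof=1)) if len(share) > 1 else 0.0,
    )


def mean_nonzero_abundance(table: CountTable) -> pd.Series:
    """Average relative abundance of each OTU over the samples where present.

    Samples with zero reads of the OTU are excluded from its average (they do
    not dilute it); an OTU absent from every sample is NaN (undefined), never 0.
    """
    rel = to_relative(table).to_numpy()
    present = table.counts > 0
    n_present = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(
            n_present > 0,
            (rel * present).sum(axis=0) / np.maximum(n_present, 1),
            np.nan,
        )
    return pd.Series(means, index=pd.Index(table.otu_ids, name="otu_id"),
                     name="mean_nonzero_abundance")


def occurrence_abundance_summary(
    table: CountTable, partition: PartitionResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrence-versus-abundance table plus the occurrence histogram.

    Returns ``(rows, histogram)``: one row per OTU detected in the scope
    (occurrence fraction, mean nonzero relative abundance, assignment), and a
    histogram over integer sample counts 1..|scope| whose ``percent_of_otus``
    densities sum to 100.
    """
    unknown = set(partition.scope) - set(table.sample_ids)
    if unknown:
        raise ValidationError(f"partition scope not in table: {sorted(unknown)}")
    scoped = table.select_samples(partition.scope)
    mean_abund = mean_nonzero_abundance(scoped)
    otus = list(partition.assignment.index)
    rows = pd.DataFrame(
        {
            "occurrence": partition.occurrence.loc[otus],
            "n_samples_present": (
                partition.occurrence.loc[otus] * len(partition.scope)
            ).round().astype(int),
            "mean_nonzero_abundance": mean_abund.loc[otus],
            "assignment": partition.assignment.loc[otus],
        }
    ).rename_axis("otu_id")
    n_scope = len(partition.scope)
    bins = np.arange(1, n_scope + 1)
    counts = (
        rows["n_samples_present"].value_counts().reindex(bins, fill_value=0)
    )
    hist = pd.DataFrame(
        {
            "n_samples": bins,
            "n_otus": counts.to_numpy(),
            "percent_of_otus": 100.0 * counts.to_numpy() / len(rows),
        }
    )
    return rows, hist


@dataclass
class CoreOverlap:
    """Overlap between two core sets (symmetric)."""

    shared: list[str]
    n_a: int
    n_b: int
    n_shared: int
    n_union: int
    jaccard: float


def core_overlap(a: PartitionResult, b: PartitionResult) -> CoreOverlap:
    """Compare the core sets of two partitions over the same OTU universe."""
    if set(a.universe) != set(b.universe):
        raise ValidationError(
            "partitions were built from different OTU universes"
        )
    core_a = set(a.core_otus)
    core_b = set(b.core_otus)
    shared = core_a & core_b
    union = core_a | core_b
    return CoreOverlap(
        shared=sorted(shared),
        n_a=len(core_a),
        n_b=len(core_b),
        n_shared=len(shared),
        n_union=len(union),
        jaccard=len(shared) / len(union) if union else float("nan"),
    )
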