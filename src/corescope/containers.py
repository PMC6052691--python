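"""Shared in-memory containers used throughout the pipeline.

The universal currency is the :class:`CountTable`: a samples x OTUs matrix of
non-negative integer read counts, kept as integers end-to-end (subsampling
semantics require exact counts; conversion to relative abundances is an
explicit, separate step in :mod:`corescope.normalize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Reactor categories of the study design this package targets: farm digesters,
#: bio-waste digesters, municipal-solid-waste digesters and anaerobic digesters
#: located at wastewater treatment plants.
CATEGORIES = ("farm", "bio-waste", "MSW", "WWTP-AD")

#: Reactor roles: fed digester, post-digester, storage tank.
REACTOR_ROLES = ("Fd", "Pd", "St")

#: Taxonomic ranks carried by a TaxonomyTable, highest first.
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_DOMAINS = ("bacteria", "archaea")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass
class CountTable:
    """OTU read counts for a set of samples.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per matrix row.
    otu_ids : sequence of str
        Unique OTU identifiers, one per matrix column.
    counts : array-like of int, shape (n_samples, n_otus)
        Non-negative integer read counts.
    domain : {"bacteria", "archaea"}
        Which amplicon assay the table came from.
    label : str
        Free-text OTU-definition tag (e.g. the 97%-identity label "0.03").
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    domain: str = "bacteria"
    label: str = "0.03"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (samples x OTUs)")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts = counts
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if self.domain not in _DOMAINS:
            raise ValidationError(
                f"domain must be one of {_DOMAINS}, got {self.domain!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> pd.Series:
        """Total reads per sample."""
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids, name="total")

    def otu_totals(self) -> pd.Series:
        """Total reads per OTU across all samples."""
        return pd.Series(self.counts.sum(axis=0), index=self.otu_ids, name="total")

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """One sample's count vector (copy)."""
        return self.counts[self.sample_index(sample_id)].copy()

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """Restrict to the given samples, preserving the requested order."""
        idx = [self.sample_index(s) for s in sample_ids]
        return CountTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            otu_ids=list(self.otu_ids),
            counts=self.counts[idx],
            domain=self.domain,
            label=self.label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.otu_ids,
        )

    def equals(self, other: "CountTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and self.domain == other.domain
            and self.label == other.label
        )


@dataclass
class TaxonomyTable:
    """SILVA-style ranked lineages for OTUs.

    ``lineages`` maps each OTU id to a list of ``(taxon, confidence)`` pairs
    ordered from domain downward; trailing ranks may be absent, and a
    confidence may be None when the file carried none.
    """

    lineages: dict[str, list[tuple[str, float | None]]]

    def __post_init__(self) -> None:
        for otu, lineage in self.lineages.items():
            if len(lineage) > len(TAXONOMY_RANKS):
                raise ValidationError(
                    f"{otu}: lineage has {len(lineage)} ranks, "
                    f"more than the {len(TAXONOMY_RANKS)} supported"
                )
            for taxon, conf in lineage:
                if conf is not None and not (0.0 <= conf <= 100.0):
                    raise ValidationError(
                        f"{otu}: confidence {conf} for {taxon!r} outside [0, 100]"
                    )

    def rank(self, otu_id: str, rank: str) -> str | None:
        """Taxon name at ``rank`` for an OTU, or None if unassigned."""
        i = TAXONOMY_RANKS.index(rank)
        lineage = self.lineages.get(otu_id, [])
        return lineage[i][0] if i < len(lineage) else None

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        for otu, lineage in self.lineages.items():
            row: dict[str, object] = {}
            for rank, (taxon, conf) in zip(TAXONOMY_RANKS, lineage):
                row[rank] = taxon
                row[f"{rank}_confidence"] = conf
            rows[otu] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "otu_id"
        return df


_METADATA_REQUIRED = ("reactor", "unit", "category", "timepoint")
_PHYSCHEM = ("pH", "temperature", "TIC", "NH4N", "TS", "VS", "total_VFA")


@dataclass
class SampleMetadata:
    """Per-sample study design and physicochemical covariates.

    Backed by a DataFrame indexed by sample_id with columns ``reactor``,
    ``unit``, ``category``, ``reactor_role`` (optional), ``timepoint`` and any
    of the physicochemical covariates (pH, temperature, TIC, NH4N, TS, VS,
    total_VFA). Missing covariates are NaN, never zero.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise ValidationError("metadata needs a sample_id column/index")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
        missing = [c for c in _METADATA_REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        df = df.copy()
        df["category"] = [_normalise_category(c) for c in df["category"]]
        if "reactor_role" in df.columns:
            for r in df["reactor_role"].dropna():
                if r not in REACTOR_ROLES:
                    raise ValidationError(
                        f"unknown reactor_role {r!r}; allowed: {REACTOR_ROLES}"
                    )
        df["timepoint"] = df["timepoint"].astype(int)
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def for_samples(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())

    def samples_where(self, **criteria: object) -> list[str]:
        """Sample ids matching all column==value criteria (e.g. category="farm")."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            mask &= self.table[col] == val
        return list(self.table.index[mask])

    def covariates(self) -> pd.DataFrame:
        """The physicochemical covariate columns present, NaN where missing."""
        cols = [c for c in _PHYSCHEM if c in self.table.columns]
        return self.table[cols].astype(float)


def _normalise_category(value: object) -> str:
    """Map a category string onto the canonical enum, case-insensitively."""
    text = str(value).strip()
    for cat in CATEGORIES:
        if text.lower() == cat.lower():
            return cat
    raise ValidationError(
        f"unknown category {text!r}; allowed values: {', '.join(CATEGORIES)}"
    )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities in [0, 1] with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        vals = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if vals.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {vals.shape} does not match {n} samples"
            )
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-9):
            raise ValidationError("distance matrix diagonal is not zero")
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValidationError("distances must lie in [0, 1]")
        # enforce exact symmetry / zero diagonal for downstream numerics
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        self.values = vals
        _check_unique(self.sample_ids, "sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]

    def between(self, a: str, b: str) -> float:
        ia = self.sample_ids.index(a)
        ib = self.sample_ids.index(b)
        return float(self.values[ia, ib])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
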