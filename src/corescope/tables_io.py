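"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats
-----------------
* mothur "shared" count tables: tab-delimited, header ``label Group numOtus
  OTU...``, one row per sample;
* plain TSV count tables (first column ``sample_id``);
* taxonomy TSV with SILVA-style ``Rank(confidence);`` lineage strings;
* sample metadata CSV;
* PHYLIP square / lower-triangle distance matrices and TSV distance tables.

All parsers validate as they read and raise :class:`~corescope.errors.ParseError`
(naming the line) or :class:`~corescope.errors.ValidationError`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CountTable,
    DistanceMatrix,
    SampleMetadata,
    TaxonomyTable,
)
from .errors import ParseError, ValidationError

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "validate_dataset",
    "ValidationReport",
]


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def _parse_int(token: str, path: Path, lineno: int) -> int:
    try:
        value = int(token)
    except ValueError:
        raise ValidationError(
            f"{path}:{lineno}: non-integer count {token!r}"
        ) from None
    if value < 0:
        raise ValidationError(f"{path}:{lineno}: negative count {value}")
    return value


def read_count_table(
    path: str | Path, format: str = "shared", domain: str = "bacteria"
) -> CountTable:
    """Read an OTU count table.

    Parameters
    ----------
    path : path
        File to read.
    format : {"shared", "tsv"}
        ``shared``: mothur layout with leading label/Group/numOtus columns.
        ``tsv``: plain table whose first column is the sample id.
    domain : {"bacteria", "archaea"}
        Domain tag to attach to the table.
    """
    path = Path(path)
    if format not in ("shared", "tsv"):
        raise ValueError(f"unknown count-table format {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")

    if format == "shared":
        if len(header) < 3 or header[:3] != ["label", "Group", "numOtus"]:
            raise ParseError(
                f"{path}:1: shared header must start with 'label\\tGroup\\tnumOtus'"
            )
        otu_ids = header[3:]
        label = None
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(lines[1:], start=2):
            fields = line.split("\t")
            if len(fields) != 3 + len(otu_ids):
                raise ParseError(
                    f"{path}:{lineno}: expected {3 + len(otu_ids)} fields, "
                    f"got {len(fields)}"
                )
            num_otus = _parse_int(fields[2], path, lineno)
            if num_otus != len(otu_ids):
                raise ParseError(
                    f"{path}:{lineno}: numOtus={num_otus} inconsistent with "
                    f"{len(otu_ids)} OTU columns"
                )
            label = label or fields[0]
            sample_ids.append(fields[1])
            rows.append([_parse_int(t, path, lineno) for t in fields[3:]])
        counts = np.array(rows, dtype=np.int64).reshape(len(sample_ids), len(otu_ids))
        return CountTable(sample_ids, otu_ids, counts, domain=domain,
                          label=label or "0.03")

    # plain TSV: first column sample_id
    otu_ids = header[1:]
    sample_ids = []
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 1 + len(otu_ids):
            raise ParseError(
                f"{path}:{lineno}: expected {1 + len(otu_ids)} fields, "
                f"got {len(fields)}"
            )
        sample_ids.append(fields[0])
        rows.append([_parse_int(t, path, lineno) for t in fields[1:]])
    counts = np.array(rows, dtype=np.int64).reshape(len(sample_ids), len(otu_ids))
    return CountTable(sample_ids, otu_ids, counts, domain=domain)


def write_count_table(table: CountTable, path: str | Path,
                      format: str = "shared") -> None:
    """Write a count table in shared or plain-TSV layout (round-trip safe)."""
    path = Path(path)
    if format not in ("shared", "tsv"):
        raise ValueError(f"unknown count-table format {format!r}")
    with open(path, "w") as fh:
        if format == "shared":
            fh.write("\t".join(["label", "Group", "numOtus", *table.otu_ids]) + "\n")
            for sid, row in zip(table.sample_ids, table.counts):
                fh.write(
                    "\t".join(
                        [table.label, sid, str(table.n_otus),
                         *(str(int(c)) for c in row)]
                    )
                    + "\n"
                )
        else:
            fh.write("\t".join(["sample_id", *table.otu_ids]) + "\n")
            for sid, row in zip(table.sample_ids, table.counts):
                fh.write("\t".join([sid, *(str(int(c)) for c in row)]) + "\n")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def _parse_lineage(text: str) -> list[tuple[str, float | None]]:
    lineage: list[tuple[str, float | None]] = []
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if part.endswith(")") and "(" in part:
            name, conf_text = part[:-1].rsplit("(", 1)
            try:
                conf: float | None = float(conf_text)
            except ValueError:
                name, conf = part, None
        else:
            name, conf = part, None
        lineage.append((name.strip(), conf))
    return lineage


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV: otu_id <tab> semicolon-delimited lineage.

    Lineage entries may carry a bootstrap confidence as ``Taxon(97)``; a
    header line starting with ``OTU`` or ``otu_id`` is skipped.
    """
    path = Path(path)
    lineages: dict[str, list[tuple[str, float | None]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("otu", "otu_id"):
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected otu_id<TAB>lineage")
            otu_id = fields[0]
            if otu_id in lineages:
                raise ValidationError(f"{path}:{lineno}: duplicate OTU id {otu_id!r}")
            lineages[otu_id] = _parse_lineage(fields[1])
    return TaxonomyTable(lineages)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample metadata CSV.

    Required columns: sample_id, reactor, unit, category, timepoint.
    Category values are normalised case-insensitively onto the canonical
    enum (farm, bio-waste, MSW, WWTP-AD). Empty physicochemical cells are
    read as missing (NaN), never as zero.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def write_distance_matrix(
    dm: DistanceMatrix, path: str | Path, format: str = "phylip_square"
) -> None:
    """Write a distance matrix as PHYLIP square, PHYLIP lower-triangle or TSV."""
    path = Path(path)
    if format not in ("phylip_square", "phylip_lower", "tsv"):
        raise ValueError(f"unknown distance format {format!r}")
    # DistanceMatrix construction already enforces symmetry/zero diagonal.
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("\t".join(["sample_id", *dm.sample_ids]) + "\n")
            for sid, row in zip(dm.sample_ids, dm.values):
                fh.write("\t".join([sid, *(f"{v:.10f}" for v in row)]) + "\n")
            return
        fh.write(f"{dm.n_samples}\n")
        for i, (sid, row) in enumerate(zip(dm.sample_ids, dm.values)):
            vals = row[:i] if format == "phylip_lower" else row
            fields = [sid, *(f"{v:.10f}" for v in vals)]
            fh.write("\t".join(fields).rstrip("\t") + "\n")


def read_distance_matrix(
    path: str | Path, format: str = "phylip_square", metric: str = "bray_curtis"
) -> DistanceMatrix:
    path = Path(path)
    if format not in ("phylip_square", "phylip_lower", "tsv"):
        raise ValueError(f"unknown distance format {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if format == "tsv":
        header = lines[0].split("\t")[1:]
        ids = []
        rows = []
        for line in lines[1:]:
            fields = line.split("\t")
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
        if ids != header:
            raise ParseError(f"{path}: row and column sample ids disagree")
        return DistanceMatrix(ids, np.array(rows), metric=metric)
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"{path}:1: expected sample count on first line") from None
    if len(lines) != n + 1:
        raise ParseError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    ids = []
    values = np.zeros((n, n))
    for i, line in enumerate(lines[1:], start=0):
        fields = line.split("\t")
        ids.append(fields[0])
        vals = [float(v) for v in fields[1:]]
        if format == "phylip_square":
            if len(vals) != n:
                raise ParseError(f"{path}:{i + 2}: expected {n} distances")
            values[i, :] = vals
        else:
            if len(vals) != i:
                raise ParseError(f"{path}:{i + 2}: expected {i} distances")
            values[i, :i] = vals
            values[:i, i] = vals
    return DistanceMatrix(ids, values, metric=metric)


# ---------------------------------------------------------------------------
# dataset validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only cross-check of a count table against its metadata."""

    samples_missing_metadata: list[str] = field(default_factory=list)
    metadata_without_samples: list[str] = field(default_factory=list)
    zero_total_samples: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.samples_missing_metadata
            or self.metadata_without_samples
            or self.zero_total_samples
        )

    def summary(self) -> str:
        if self.ok:
            return "ok"
        parts = []
        if self.samples_missing_metadata:
            parts.append(f"samples missing metadata: {self.samples_missing_metadata}")
        if self.metadata_without_samples:
            parts.append(f"metadata without samples: {self.metadata_without_samples}")
        if self.zero_total_samples:
            parts.append(f"zero-total samples: {self.zero_total_samples}")
        return "; ".join(parts)


def validate_dataset(table: CountTable, metadata: SampleMetadata) -> ValidationReport:
    """Cross-check a count table against metadata; never raises."""
    table_ids = set(table.sample_ids)
    meta_ids = set(metadata.sample_ids)
    totals = table.sample_totals()
    return ValidationReport(
        samples_missing_metadata=sorted(table_ids - meta_ids),
        metadata_without_samples=sorted(meta_ids - table_ids),
        zero_total_samples=sorted(totals.index[totals == 0]),
    )
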