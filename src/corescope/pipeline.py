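"""End-to-end orchestration: normalize -> diversity -> distances -> partition
-> stability -> statistics, from a single flat config, with a JSON manifest.

Stage order is fixed; every artifact is a plain-text table or JSON file in the
output directory, and a rerun with the same config and seed reproduces the
numeric outputs byte for byte (no timestamps or timing-dependent values).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountTable, SampleMetadata, CATEGORIES
from .core_partition import (
    PartitionThresholds,
    abundance_share,
    occurrence_abundance_summary,
    partition_otus,
)
from .dissimilarity import distance_matrix, temporal_stability
from .diversity import diversity_table
from .errors import CorescopeError, ValidationError
from .normalize import SubsampleConfig, filter_low_count_otus, subsample
from .community_stats import anosim, nmds_embed
from .tables_io import (
    read_count_table,
    read_metadata,
    validate_dataset,
    write_count_table,
    write_distance_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "parse_scope",
           "read_config_file"]

_SYSTEM_CATEGORIES = {"AD": ["farm", "bio-waste", "MSW"], "WWTP": ["WWTP-AD"]}


class PipelineError(CorescopeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; exactly one of count_table / synth_preset."""

    count_table: str | None = None
    count_format: str = "shared"
    metadata: str | None = None
    synth_preset: str | None = None
    domain: str = "bacteria"
    depth: int = 11550
    min_total: int = 2
    core_min: float = 0.80
    transient_max: float = 0.20
    detection_min_count: int = 1
    scopes: tuple[str, ...] = ("all",)
    metrics: tuple[str, ...] = ("bray_curtis", "jaccard")
    stability_scheme: str = "all_pairs"
    group_by: str = "reactor"
    anosim_labels: str = "category"
    permutations: int = 999
    nmds_dims: int = 2
    nmds_starts: int = 4
    seed: int = 0
    outdir: str = "corescope_out"

    def __post_init__(self) -> None:
        have_files = self.count_table is not None
        have_synth = self.synth_preset is not None
        if have_files == have_synth:
            raise ValidationError(
                "set exactly one of count_table or synth_preset"
            )
        if have_files and self.metadata is None:
            raise ValidationError("count_table input requires metadata")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")


def parse_scope(expr: str, metadata: SampleMetadata,
                sample_ids: Sequence[str]) -> list[str]:
    """Resolve a scope expression to sample ids present in the table.

    Accepted forms: ``all``, ``category:<farm|bio-waste|MSW|WWTP-AD>``,
    ``unit:<U-x>``, ``reactor:<acronym>``, ``system:<AD|WWTP>`` (AD pools
    every non-WWTP category).
    """
    available = [s for s in sample_ids if s in set(metadata.sample_ids)]
    if expr == "all":
        return list(sample_ids)
    if ":" not in expr:
        raise ValidationError(f"bad scope expression {expr!r}")
    kind, value = expr.split(":", 1)
    if kind == "system":
        cats = _SYSTEM_CATEGORIES.get(value)
        if cats is None:
            raise ValidationError(f"unknown system {value!r} (AD or WWTP)")
        chosen = {
            s for c in cats for s in metadata.samples_where(category=c)
        }
    elif kind in ("category", "unit", "reactor"):
        if kind == "category" and value not in CATEGORIES:
            raise ValidationError(f"unknown category {value!r}")
        chosen = set(metadata.samples_where(**{kind: value}))
    else:
        raise ValidationError(f"bad scope kind {kind!r}")
    scope = [s for s in available if s in chosen]
    if not scope:
        raise ValidationError(f"scope {expr!r} matches no samples")
    return scope


def read_config_file(path: str | Path) -> PipelineConfig:
    """Parse a flat key=value config file ('#' starts a comment)."""
    values: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected key=value")
        key, raw = (t.strip() for t in line.split("=", 1))
        values[key] = raw
    return _config_from_strings(values)


def _config_from_strings(values: dict[str, object]) -> PipelineConfig:
    kwargs: dict[str, object] = {}
    ints = {"depth", "min_total", "detection_min_count", "permutations",
            "nmds_dims", "nmds_starts", "seed"}
    floats = {"core_min", "transient_max"}
    tuples = {"scopes", "metrics"}
    for key, raw in values.items():
        if key in ints:
            kwargs[key] = int(raw)  # type: ignore[arg-type]
        elif key in floats:
            kwargs[key] = float(raw)  # type: ignore[arg-type]
        elif key in tuples:
            kwargs[key] = tuple(t.strip() for t in str(raw).split(",") if t.strip())
        else:
            kwargs[key] = raw
    return PipelineConfig(**kwargs)  # type: ignore[arg-type]


def _scope_tag(expr: str) -> str:
    return expr.replace(":", "_").replace("/", "_")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written as JSON).

    Artifacts written to ``config.outdir``: the subsampled shared table,
    per-sample diversity TSV, one distance matrix per metric, per-scope
    partition / abundance-share / occurrence-abundance TSVs, the stability
    summary TSV, NMDS coordinates and a JSON of ANOSIM/NMDS statistics, plus
    ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "artifacts": [],
        "complete": False,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    stage = "load"
    try:
        if config.synth_preset is not None:
            from .synthetic_data import SyntheticSpec, generate_dataset, small_spec

            # generate above the target depth so subsampling after the
            # low-count filter still reaches it for every sample
            raw_depth = round(1.2 * config.depth)
            if config.synth_preset == "default":
                spec = SyntheticSpec(seed=config.seed, depth=raw_depth)
            elif config.synth_preset == "small":
                spec = small_spec(seed=config.seed, depth=raw_depth)
            else:
                raise ValidationError(
                    f"unknown synth preset {config.synth_preset!r}"
                )
            table, metadata, _truth = generate_dataset(spec)
        else:
            table = read_count_table(
                config.count_table, format=config.count_format,
                domain=config.domain,
            )
            metadata = read_metadata(config.metadata)
        manifest["stages"][stage] = {
            "samples": table.n_samples, "otus": table.n_otus,
        }

        stage = "validate"
        report = validate_dataset(table, metadata)
        manifest["stages"][stage] = {"ok": report.ok, "summary": report.summary()}
        if report.samples_missing_metadata:
            raise ValidationError(
                "samples missing metadata: "
                f"{report.samples_missing_metadata[:5]}"
            )

        stage = "filter"
        filtered = filter_low_count_otus(table, min_total=config.min_total)
        manifest["stages"][stage] = {
            "otus_in": table.n_otus, "otus_out": filtered.n_otus,
        }

        stage = "subsample"
        sub = subsample(
            filtered,
            SubsampleConfig(depth=config.depth, seed=config.seed),
        )
        manifest["stages"][stage] = {
            "depth": config.depth,
            "samples_in": filtered.n_samples,
            "samples_out": sub.n_samples,
            "samples_dropped": filtered.n_samples - sub.n_samples,
        }
        shared_path = outdir / "subsampled.shared"
        write_count_table(sub, shared_path, format="shared")
        manifest["artifacts"].append(shared_path.name)

        stage = "diversity"
        div = diversity_table(sub)
        div_path = outdir / "diversity.tsv"
        div.to_csv(div_path, sep="\t", float_format="%.6f")
        manifest["stages"][stage] = {"samples": len(div)}
        manifest["artifacts"].append(div_path.name)

        stage = "distance"
        dms = {}
        for metric in config.metrics:
            dm = distance_matrix(sub, metric=metric)
            dm_path = outdir / f"{metric}.phylip"
            write_distance_matrix(dm, dm_path, format="phylip_square")
            manifest["artifacts"].append(dm_path.name)
            dms[metric] = dm
        manifest["stages"][stage] = {"metrics": list(config.metrics)}

        stage = "partition"
        thresholds = PartitionThresholds(
            core_min_occurrence=config.core_min,
            transient_max_occurrence=config.transient_max,
            detection_min_count=config.detection_min_count,
        )
        share_rows = []
        partition_counts = {}
        for expr in config.scopes:
            scope = parse_scope(expr, metadata, sub.sample_ids)
            part = partition_otus(sub, scope=scope, thresholds=thresholds)
            tag = _scope_tag(expr)
            part_path = outdir / f"partition_{tag}.tsv"
            part.to_dataframe().to_csv(part_path, sep="\t", float_format="%.6f")
            manifest["artifacts"].append(part_path.name)
            rows, hist = occurrence_abundance_summary(sub, part)
            oa_path = outdir / f"occurrence_abundance_{tag}.tsv"
            rows.to_csv(oa_path, sep="\t", float_format="%.6g")
            manifest["artifacts"].append(oa_path.name)
            for label in ("core", "intermediate", "transient"):
                share = abundance_share(sub, part.otus(label), scope)
                share_rows.append(
                    {"scope": expr, "partition": label,
                     "n_otus": part.counts()[label],
                     "mean_share": share.mean, "sd_share": share.sd}
                )
            partition_counts[expr] = part.counts()
        shares_path = outdir / "abundance_shares.tsv"
        pd.DataFrame(share_rows).to_csv(shares_path, sep="\t", index=False,
                                        float_format="%.6f")
        manifest["artifacts"].append(shares_path.name)
        manifest["stages"][stage] = {"scopes": partition_counts}

        stage = "stability"
        stab_frames = []
        for metric in config.metrics:
            stab = temporal_stability(
                sub, metadata, metric=metric,
                scheme=config.stability_scheme, group_by=config.group_by,
            )
            stab_frames.append(stab)
        stab_path = outdir / "stability.tsv"
        pd.concat(stab_frames, ignore_index=True).to_csv(
            stab_path, sep="\t", index=False, float_format="%.6f"
        )
        manifest["artifacts"].append(stab_path.name)
        manifest["stages"][stage] = {
            "groups": int(len(stab_frames[0])) if stab_frames else 0,
        }

        stage = "stats"
        labels = metadata.table.loc[sub.sample_ids, config.anosim_labels]
        stats_out: dict = {}
        first_metric = config.metrics[0]
        res = anosim(dms[first_metric], labels,
                     n_permutations=config.permutations, seed=config.seed)
        stats_out["anosim"] = {
            "metric": first_metric, "labels": config.anosim_labels,
            "R": res.R, "p": res.p, "n_permutations": res.n_permutations,
        }
        nmds = nmds_embed(dms[first_metric], dims=config.nmds_dims,
                          seed=config.seed, n_starts=config.nmds_starts)
        nmds_path = outdir / "nmds.tsv"
        nmds.coordinates.to_csv(nmds_path, sep="\t", float_format="%.6f")
        manifest["artifacts"].append(nmds_path.name)
        stats_out["nmds"] = {"stress": nmds.stress, "r2": nmds.r2,
                             "dims": config.nmds_dims}
        stats_path = outdir / "stats.json"
        stats_path.write_text(json.dumps(stats_out, indent=2, sort_keys=True))
        manifest["artifacts"].append(stats_path.name)
        manifest["stages"][stage] = {"anosim_R": res.R, "anosim_p": res.p}

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
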