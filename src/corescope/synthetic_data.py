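"""Synthetic longitudinal multi-reactor OTU tables with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
small set of core OTUs carrying most of the reads in every sample of their
digestion system, a large pool of transient OTUs that flicker in and out of
single samples at low abundance, and an intermediate tier present in only
some reactors. Two digestion systems (agricultural/bio-waste "AD" versus
wastewater-treatment-plant "WWTP") draw their cores from mostly disjoint OTU
pools with a configurable shared fraction.

Generative model, per sample:

1. each reactor owns a fixed base composition: its system's core profile
   (log-normal weights, jittered per reactor, scaled to ``target_core_share``)
   plus the intermediate OTUs planted in that reactor (scaled to the
   remaining non-transient mass);
2. a latent log-abundance deviation follows a stationary AR(1) across the
   monthly series (autocorrelation ``temporal_autocorrelation``, stationary
   sd ``drift_sd``);
3. transient OTUs enter each sample independently with probability
   ``transient_occurrence_rate`` and split ``target_transient_share`` of the
   sample's mass;
4. the sample composition is a Dirichlet draw around that month's expected
   profile (total concentration ``overdispersion``), and counts are one
   multinomial draw at ``depth``.

Identical spec + seed reproduce the dataset bit for bit. Abundance floors
(``min_core_abundance``, ``min_intermediate_abundance``) keep every planted
core/intermediate OTU above the detection limit of the configured depth, so
planted labels are recoverable by occurrence partitioning — the feature the
generator exists to test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountTable, SampleMetadata
from .core_partition import PartitionResult, abundance_share
from .errors import ValidationError

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "RecoveryReport",
    "generate_dataset",
    "recovery_report",
    "small_spec",
]

#: category -> digestion system
_SYSTEM_OF = {"farm": "AD", "bio-waste": "AD", "MSW": "AD", "WWTP-AD": "WWTP"}
_ACRONYM = {"farm": "FM", "bio-waste": "BW", "MSW": "MS", "WWTP-AD": "WW"}


def _default_categories() -> dict[str, int]:
    # 20 reactors in 4 categories across two systems, as in the monitored design
    return {"farm": 8, "bio-waste": 6, "MSW": 2, "WWTP-AD": 4}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design and generative parameters (defaults = the emulated design)."""

    n_reactors: int = 20
    n_timepoints: int = 12
    category_sizes: dict[str, int] = field(default_factory=_default_categories)
    n_otus: int = 6000
    core_fraction: float = 0.025
    transient_fraction: float = 0.84
    target_core_share: float = 0.70
    target_transient_share: float = 0.035
    shared_core_between_systems: float = 0.1
    transient_occurrence_rate: float = 0.02
    depth: int = 11550
    overdispersion: float = 4000.0
    temporal_autocorrelation: float = 0.5
    drift_sd: float = 0.3
    min_core_abundance: float = 0.002
    min_intermediate_abundance: float = 6e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "core_fraction", "transient_fraction", "target_core_share",
            "target_transient_share", "shared_core_between_systems",
            "transient_occurrence_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.core_fraction + self.transient_fraction > 1.0:
            raise ValidationError("core_fraction + transient_fraction > 1")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if not 0.0 <= self.temporal_autocorrelation < 1.0 + 1e-12:
            raise ValidationError("temporal_autocorrelation must be in [0, 1]")
        if sum(self.category_sizes.values()) != self.n_reactors:
            raise ValidationError(
                f"category sizes {self.category_sizes} do not sum to "
                f"{self.n_reactors} reactors"
            )
        unknown = set(self.category_sizes) - set(_SYSTEM_OF)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
        if self.target_core_share > 0 and self.n_core == 0:
            raise ValidationError(
                "target_core_share > 0 with zero core OTUs is infeasible"
            )
        if self.target_core_share + self.target_transient_share > 1.0:
            raise ValidationError("core + transient shares exceed 1")

    # -- derived counts --------------------------------------------------
    @property
    def n_core(self) -> int:
        return round(self.n_otus * self.core_fraction)

    @property
    def n_transient(self) -> int:
        return round(self.n_otus * self.transient_fraction)

    @property
    def n_intermediate(self) -> int:
        return self.n_otus - self.n_core - self.n_transient


def small_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A down-scaled spec for fast smoke tests (6 reactors, 400 OTUs)."""
    base = dict(
        n_reactors=6,
        n_timepoints=6,
        category_sizes={"farm": 2, "bio-waste": 2, "WWTP-AD": 2},
        n_otus=400,
        depth=2000,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@dataclass
class SyntheticTruth:
    """Planted per-OTU labels and per-sample bookkeeping for recovery tests."""

    labels: pd.Series  # otu_id -> core | intermediate | transient
    system: pd.Series  # otu_id -> AD | WWTP | both
    sample_system: pd.Series  # sample_id -> AD | WWTP
    realised_core_share: pd.Series  # per sample, share of its system's core reads
    spec: SyntheticSpec

    def core_otus(self, system: str | None = None) -> list[str]:
        mask = self.labels == "core"
        if system is not None:
            mask &= self.system.isin([system, "both"])
        return list(self.labels.index[mask])

    def transient_otus(self) -> list[str]:
        return list(self.labels.index[self.labels == "transient"])

    def samples_of_system(self, system: str) -> list[str]:
        return list(self.sample_system.index[self.sample_system == system])


def _core_profile(
    rng: np.random.Generator, n: int, share: float, floor: float
) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    if floor * n >= share:
        raise ValidationError(
            f"min_core_abundance {floor} infeasible for {n} core OTUs "
            f"sharing {share}"
        )
    raw = rng.lognormal(0.0, 1.0, n)
    return floor + raw / raw.sum() * (share - floor * n)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[CountTable, SampleMetadata, SyntheticTruth]:
    """Generate one longitudinal dataset with planted labels.

    Returns the count table (every sample summing exactly to ``spec.depth``),
    complete metadata with plausible physicochemical covariates (cosmetic:
    they never drive the counts), and the ground truth.
    """
    rng = np.random.default_rng(spec.seed)

    # ----- reactors & systems ------------------------------------------
    reactors: list[str] = []
    categories: list[str] = []
    counters: dict[str, int] = {}
    for cat, size in spec.category_sizes.items():
        for _ in range(size):
            counters[cat] = counters.get(cat, 0) + 1
            reactors.append(f"{_ACRONYM[cat]}{counters[cat]}")
            categories.append(cat)
    systems = [_SYSTEM_OF[c] for c in categories]
    present_systems = sorted(set(systems))
    reactors_of: dict[str, list[int]] = {
        s: [i for i, sy in enumerate(systems) if sy == s] for s in present_systems
    }

    # ----- OTU labels and system membership ----------------------------
    n_core, n_trans, n_int = spec.n_core, spec.n_transient, spec.n_intermediate
    width = len(str(spec.n_otus))
    otu_ids = [f"OTU_{i + 1:0{width}d}" for i in range(spec.n_otus)]
    labels = np.array(
        ["core"] * n_core + ["intermediate"] * n_int + ["transient"] * n_trans
    )
    otu_system = np.array(["both"] * spec.n_otus, dtype=object)

    core_idx = np.arange(n_core)
    core_members: dict[str, np.ndarray] = {}
    if len(present_systems) >= 2 and n_core:
        n_shared = round(spec.shared_core_between_systems * n_core)
        remaining = n_core - n_shared
        n_reactors_by = {s: len(reactors_of[s]) for s in present_systems}
        total_r = sum(n_reactors_by.values())
        specific: dict[str, int] = {}
        acc = 0
        for j, s in enumerate(present_systems):
            if j == len(present_systems) - 1:
                specific[s] = remaining - acc
            else:
                specific[s] = round(remaining * n_reactors_by[s] / total_r)
                acc += specific[s]
        cursor = n_shared
        for s in present_systems:
            own = core_idx[cursor:cursor + specific[s]]
            cursor += specific[s]
            otu_system[own] = s
            core_members[s] = np.concatenate([core_idx[:n_shared], own])
    else:
        for s in present_systems:
            core_members[s] = core_idx

    # ----- per-system core base profiles -------------------------------
    core_base: dict[str, np.ndarray] = {
        s: _core_profile(
            rng, len(core_members[s]), spec.target_core_share,
            spec.min_core_abundance,
        )
        for s in present_systems
    }

    # ----- intermediate placement & weights -----------------------------
    int_idx = np.arange(n_core, n_core + n_int)
    int_weight = rng.lognormal(0.0, 0.8, n_int)
    # presence[r] -> indices (into int block) of intermediates planted in reactor r
    present_in: list[list[int]] = [[] for _ in reactors]
    for s in present_systems:
        r_ids = reactors_of[s]
        lo = max(1, math.ceil(0.3 * len(r_ids)))
        hi = max(lo, math.floor(0.6 * len(r_ids)))
        for j in range(n_int):
            n_pres = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(len(r_ids), size=n_pres, replace=False)
            for c in chosen:
                present_in[r_ids[c]].append(j)

    int_mass = 1.0 - spec.target_core_share - spec.target_transient_share

    # ----- reactor base profiles (support + probabilities) --------------
    reactor_support: list[np.ndarray] = []
    reactor_profile: list[np.ndarray] = []
    for r, s in enumerate(systems):
        members = core_members[s]
        core_p = core_base[s] * rng.lognormal(0.0, 0.3, len(members))
        if core_p.size:
            core_p *= spec.target_core_share / core_p.sum()
        ints = np.array(sorted(present_in[r]), dtype=int)
        if ints.size and int_mass > 0:
            floor = spec.min_intermediate_abundance
            w = int_weight[ints] * rng.lognormal(0.0, 0.3, ints.size)
            if floor * ints.size >= int_mass:
                # floors saturate the intermediate mass: spread it evenly
                int_p = np.full(ints.size, int_mass / ints.size)
            else:
                int_p = floor + w / w.sum() * (int_mass - floor * ints.size)
        else:
            int_p = np.zeros(0)
        support = np.concatenate([members, int_idx[ints] if ints.size else []]).astype(int)
        profile = np.concatenate([core_p, int_p])
        if profile.sum() <= 0:
            raise ValidationError("reactor profile has no mass; spec infeasible")
        reactor_support.append(support)
        reactor_profile.append(profile)

    # ----- samples ------------------------------------------------------
    trans_idx = np.arange(n_core + n_int, spec.n_otus)
    phi = spec.temporal_autocorrelation
    innov_sd = spec.drift_sd * math.sqrt(max(0.0, 1.0 - phi * phi))

    sample_ids: list[str] = []
    meta_rows: list[dict[str, object]] = []
    counts = np.zeros((spec.n_reactors * spec.n_timepoints, spec.n_otus),
                      dtype=np.int64)
    sample_system: list[str] = []
    row = 0
    for r, (acr, cat, sy) in enumerate(zip(reactors, categories, systems)):
        support = reactor_support[r]
        base = reactor_profile[r]
        x = rng.normal(0.0, spec.drift_sd, base.size)  # stationary start
        unit = f"U-{r // 2 + 1}"
        ph_lo, ph_hi = (7.05, 7.25) if sy == "WWTP" else (7.5, 8.0)
        for t in range(1, spec.n_timepoints + 1):
            if t > 1:
                x = phi * x + rng.normal(0.0, innov_sd, base.size)
            latent = base * np.exp(x)
            present_trans = trans_idx[
                rng.random(n_trans) < spec.transient_occurrence_rate
            ]
            t_share = spec.target_transient_share if present_trans.size else 0.0
            latent = latent / latent.sum() * (1.0 - t_share)
            if present_trans.size:
                tw = rng.lognormal(0.0, 1.0, present_trans.size)
                tw = tw / tw.sum() * t_share
                mean_vec = np.concatenate([latent, tw])
                sup = np.concatenate([support, present_trans])
            else:
                mean_vec = latent
                sup = support
            alpha = spec.overdispersion * mean_vec
            comp = rng.standard_gamma(alpha)
            total = comp.sum()
            comp = mean_vec if total <= 0 else comp / total
            draw = rng.multinomial(spec.depth, comp / comp.sum())
            counts[row, sup] = draw

            sid = f"{acr}_M{t:02d}"
            sample_ids.append(sid)
            sample_system.append(sy)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "reactor": acr,
                    "unit": unit,
                    "category": cat,
                    "reactor_role": "Fd",
                    "timepoint": t,
                    "pH": round(float(rng.uniform(ph_lo, ph_hi)), 2),
                    "temperature": round(float(rng.uniform(37.0, 41.0)), 1),
                    "TIC": round(float(rng.uniform(5.0, 30.0)), 1),
                    "NH4N": round(float(rng.uniform(0.5, 5.0)), 2),
                    "TS": round(float(rng.uniform(2.0, 12.0)), 1),
                    "VS": round(float(rng.uniform(50.0, 80.0)), 1),
                    "total_VFA": round(float(rng.uniform(50.0, 3000.0)), 0),
                }
            )
            row += 1

    table = CountTable(sample_ids, otu_ids, counts, domain="bacteria")
    metadata = SampleMetadata(pd.DataFrame(meta_rows))

    # realised per-sample share of reads in the sample's own system core
    label_s = pd.Series(labels, index=otu_ids, name="label")
    system_s = pd.Series(otu_system, index=otu_ids, name="system")
    sample_sys = pd.Series(sample_system, index=sample_ids, name="system")
    share = np.empty(len(sample_ids))
    col_core: dict[str, np.ndarray] = {
        s: np.isin(np.arange(spec.n_otus), core_members[s]) for s in present_systems
    }
    totals = counts.sum(axis=1)
    for i, sy in enumerate(sample_system):
        share[i] = counts[i, col_core[sy]].sum() / totals[i] if totals[i] else 0.0
    truth = SyntheticTruth(
        labels=label_s,
        system=system_s,
        sample_system=sample_sys,
        realised_core_share=pd.Series(share, index=sample_ids, name="core_share"),
        spec=spec,
    )
    return table, metadata, truth


@dataclass
class RecoveryReport:
    """How well a partition recovered the planted labels.

    Precision/recall are computed over the partition universe (OTUs detected
    in the scope): an OTU never observed in a scope is excluded from that
    scope's partition by definition and cannot be recovered by any
    occurrence rule. Precision is NaN (flagged) when nothing was recovered.
    """

    precision: dict[str, float]
    recall: dict[str, float]
    n_planted: dict[str, int]
    n_recovered: dict[str, int]
    estimated_core_share: float | None = None
    core_share_error: float | None = None


def recovery_report(
    truth: SyntheticTruth,
    partition: PartitionResult,
    table: CountTable | None = None,
    system: str | None = None,
) -> RecoveryReport:
    """Score a partition against the planted truth.

    ``system`` restricts the planted core to OTUs belonging to that system
    (or both), matching a partition whose scope was that system's samples.
    With ``table`` given, the recovered core's mean abundance share over the
    partition scope is compared against the planted target.
    """
    if set(partition.universe) != set(truth.labels.index):
        raise ValidationError("partition and truth use different OTU universes")
    universe = set(partition.assignment.index)
    planted = {
        "core": set(truth.core_otus(system)) & universe,
        "transient": set(truth.transient_otus()) & universe,
    }
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    n_rec: dict[str, int] = {}
    for label in ("core", "transient"):
        recovered = set(partition.otus(label))
        n_rec[label] = len(recovered)
        hit = len(recovered & planted[label])
        precision[label] = hit / len(recovered) if recovered else float("nan")
        recall[label] = hit / len(planted[label]) if planted[label] else float("nan")
    est = err = None
    if table is not None:
        est = abundance_share(table, partition.core_otus, partition.scope).mean
        err = abs(est - truth.spec.target_core_share)
    return RecoveryReport(
        precision=precision,
        recall=recall,
        n_planted={k: len(v) for k, v in planted.items()},
        n_recovered=n_rec,
        estimated_core_share=est,
        core_share_error=err,
    )
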