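# corescope

Occurrence-based core/transient microbiome analysis for longitudinal OTU
count tables.

## The problem

Full-scale anaerobic-digestion (AD) reactors — farm digesters, bio-waste and
municipal-solid-waste plants, and digesters at wastewater treatment plants
(WWTP-ADs) — host thousands of bacterial and archaeal OTUs, but most of that
diversity is fleeting. When the same reactors are sampled monthly for a
year, a small set of broadly distributed OTUs carries most of the reads in
every sample, while the bulk of the OTU inventory appears in only one or two
samples at trace abundance. Separating those tiers, and asking whether
different digestion systems run on different cores, is the analysis this
package packages up: for microbial ecologists working with replicated
time-series amplicon surveys of engineered (or natural) ecosystems.

## The method

Given a samples × OTUs count matrix, each sample subsampled without
replacement to a fixed depth *d* (so detection is depth-controlled), the
occurrence of OTU *j* within a sample scope *S* is

    occ_j = #{ i in S : n_ij >= c } / |S|          (detection threshold c = 1)

and OTUs are partitioned by two strict thresholds:

* **core**: occ_j > 0.80 (present in more than 80% of scope samples),
* **transient**: 0 < occ_j < 0.20,
* **intermediate**: everything else (boundary values included).

System-specific cores are obtained by re-running the partition with the
scope restricted to that system's samples — the denominator changes, not the
thresholds. Each partition is accounted for by its per-sample read share
Σ_{j∈set} n_ij / N_i, and per-OTU average abundance is taken only over the
samples where the OTU is present.

Around the partition sit the standard instruments: observed richness
(sobs), inverse Simpson diversity 1/Σp² (plus the finite-sample form
N(N−1)/Σn(n−1)), inverse-Simpson evenness, analytic hypergeometric
rarefaction, Bray–Curtis (structure) and Jaccard (membership)
dissimilarities, within-reactor temporal stability, ANOSIM with seeded
permutations, non-metric multidimensional scaling, Kruskal–Wallis, Wilcoxon
signed-rank and Spearman correlation matrices.

A synthetic Dirichlet-multinomial generator
(`corescope.synthetic_data`) plants core/intermediate/transient labels
across two digestion systems with AR(1) monthly drift, so every stage of
the pipeline can be validated against known ground truth.

## Worked example

```python
from corescope.synthetic_data import SyntheticSpec, generate_dataset
from corescope.core_partition import partition_otus, abundance_share

table, metadata, truth = generate_dataset(SyntheticSpec(seed=1))
scope = truth.samples_of_system("AD")          # agricultural & bio-waste reactors
part = partition_otus(table, scope=scope)
for label, n in part.counts().items():
    share = abundance_share(table, part.otus(label), scope)
    print(f"{label:>12}: {n:5d} OTUs  read share {share.as_percent()}")
```

prints

```
        core:   123 OTUs  read share 70.1% ± 1.1
intermediate:   810 OTUs  read share 26.4% ± 1.1
   transient:  4676 OTUs  read share 3.5% ± 0.3
```

i.e. on the default synthetic design (20 reactors × 12 months, 6,000 OTUs,
depth 11,550) roughly 2% of detected OTUs form the core yet carry ~70% of
the reads in the agricultural/bio-waste system, while ~84% of OTUs are
transient and together account for ~3.5% — the size structure the package
is built to measure. The same calls with `scope =
truth.samples_of_system("WWTP")` yield that system's own, largely disjoint,
core.

The command line mirrors the library:

```sh
corescope synth --preset default --seed 1 --out data/
corescope core data/counts.shared out/ad_core --metadata data/metadata.csv --scope system:AD
corescope run --config run.cfg        # full pipeline with manifest
```

## Documentation

`docs/methods.md` describes the statistical model behind the synthetic
generator, the estimator variants and numerical choices, and the known
limitations of validating against synthetic data.
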