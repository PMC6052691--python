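# Methods

## Analysis model

The pipeline treats an amplicon survey as a samples × OTUs matrix of
non-negative integer read counts plus per-sample metadata (reactor, biogas
unit, category, monthly timepoint, physicochemical covariates). Counts stay
integers end-to-end; relative abundances are derived explicitly and never
silently. The fixed stage order is:

1. **Low-count filtering.** OTUs with fewer than `min_total` (default 2)
   reads summed over all samples are removed — only OTUs represented by
   more than one sequence survive. Samples are never removed here.
2. **Fixed-depth subsampling.** Every sample is one multivariate-
   hypergeometric draw (without replacement) of `depth` reads from its own
   counts; samples below depth are dropped with a logged count, never
   padded. Defaults are 11,550 reads for bacterial assays and 2,070 for
   archaeal ones, the depths the package's defaults are organised around.
   All detection-sensitive statistics downstream (occurrence, richness,
   Jaccard membership) are computed on the subsampled table; computing them
   on raw tables requires an explicit override. The smallest observable
   relative abundance after subsampling is 1/depth (≈ 0.0087% at 11,550).
3. **Diversity.** Observed richness (`sobs`), inverse Simpson and
   inverse-Simpson evenness per sample; analytic or resampled rarefaction
   curves; rank–abundance curves.
4. **Dissimilarity.** Bray–Curtis on counts (structure) and Jaccard on
   presence/absence (membership); within-reactor temporal stability as the
   mean pairwise dissimilarity under an `all_pairs` (default) or
   `consecutive` month-pair scheme.
5. **Partitioning.** Occurrence-based core/transient/intermediate
   assignment per scope (see below), read-share accounting per partition,
   occurrence–abundance summaries, core overlap between scopes.
6. **Statistics.** ANOSIM, NMDS, agglomerative cluster assignment,
   Kruskal–Wallis, Wilcoxon signed-rank, Spearman matrices.

## Partition semantics

Occurrence is the fraction of scope samples where an OTU has at least
`detection_min_count` (default 1) reads. Both thresholds are strict:
occurrence > 0.80 is core, 0 < occurrence < 0.20 is transient, and exact
boundary values land in intermediate, so ties are deterministic. OTUs never
detected inside a scope are excluded from that scope's partition universe —
an OTU cannot be "transient in" samples it never occurs in. System-specific
cores recompute occurrence within the restricted scope rather than
re-thresholding global occurrence. Raising the core threshold can only
shrink the core (monotonicity), and the three partitions' per-sample read
shares always sum to 1; both properties are asserted in the test suite.

Dissimilarities on partition subsets (core-only, transient-only tables) use
the subset counts without renormalisation, so numerators and denominators
remain interpretable as read overlap; callers can renormalise explicitly
via `to_relative` when proportions within the subset are wanted.

## Estimator variants

Two inverse Simpson forms are provided. The finite-sample form
N(N−1)/Σnᵢ(nᵢ−1) is the default diversity index (it matches common 16S
calculator behaviour) but can exceed the observed richness on small
samples — counts (5, 5) give 2.25 against a richness of 2 — which would
push an evenness ratio above 1. Evenness therefore always uses the
maximum-likelihood form 1/Σpᵢ², keeping the documented 0-to-1 scale with
equality exactly at uniformity. The finite-sample form is undefined on
all-singleton samples and raises rather than returning a number (NaN is
used only in tabular output, flagged as such).

ANOSIM uses the rank statistic R = (r̄_between − r̄_within)/(M/2) with
M = n(n−1)/2 pairwise distances and mid-ranks for ties, which pins R to 1
under perfect separation and 0 in expectation under none. Permutations are
whole-sample label shuffles from a seeded generator, vectorised, and the
p-value uses the add-one estimator (1 + #{R_perm ≥ R_obs})/(1 + B) so p is
never exactly zero. For six samples in two groups of three the permutation
p reproduces the exact enumeration over all 20 assignments; the statistic
is also cross-checked against an independent implementation in the tests.

NMDS is Kruskal stress-1 minimisation (isotonic regression) from multiple
random starts; the reported R² is the squared Pearson correlation between
ordination distances and input dissimilarities — one defensible summary
among several in circulation, and labelled as such. Cluster assignment on a
distance matrix (average- or complete-linkage agglomeration cut at k) is a
reproducible stand-in for clusters usually drawn by eye on ordinations;
ANOSIM validates a chosen k post hoc.

Wilcoxon signed-rank drops zero differences before ranking, reports the sum
of positive-difference ranks, and takes its two-sided p from the normal
approximation with continuity correction. Kruskal–Wallis and Spearman use
mid-rank tie corrections; Spearman cells with fewer than 3 complete pairs
or a constant vector are flagged undefined, and Benjamini–Hochberg
adjustment across cells is available but off by default.

## Synthetic data generator

`synthetic_data.generate_dataset` emulates the study design the analysis
assumes: 20 reactors sampled monthly for a year in four categories (farm,
bio-waste, MSW, WWTP-AD) forming two digestion systems, 6,000 OTUs of which
2.5% are core (a configurable 10% of them shared between the systems'
otherwise disjoint core pools), 84% transient, and the remainder
intermediate. Default mass targets: core 0.70 of each sample's reads,
transient 0.035, intermediate the rest.

Mechanics, per reactor and sample:

* **Core.** Each system's core profile is log-normal (σ = 1) with a
  per-OTU abundance floor (`min_core_abundance`, default 0.002) and is
  rescaled to the core mass target; each reactor applies log-normal jitter
  (σ = 0.3). The floor guarantees every planted core OTU an expected
  ≥ 10 reads at depth 5,000, i.e. near-certain detection per sample even
  under compositional noise, which is what makes the planted labels
  recoverable by an occurrence rule.
* **Intermediate.** Each intermediate OTU is planted in 30–60% of each
  system's reactors, with weights log-normal (σ = 0.8) and floor
  `min_intermediate_abundance` (6 × 10⁻⁴). The band keeps realised
  occurrence comfortably between the transient and core thresholds.
* **Transient.** Each transient OTU enters each sample independently with
  probability `transient_occurrence_rate` (0.02); the present ones split
  the transient mass log-normally. Expected occurrence ≈ 2% per scope, far
  below the 20% threshold.
* **Temporal drift.** A stationary AR(1) on log abundance
  (autocorrelation φ, stationary sd `drift_sd` = 0.3, innovation sd
  `drift_sd`·√(1−φ²)) moves each reactor's latent profile between months.
  At φ = 0 consecutive-pair and all-pairs dissimilarity agree; as φ → 1
  the latent profile freezes and consecutive dissimilarity falls to the
  replicate-noise floor set by the Dirichlet draw — not to zero, because
  sampling noise remains.
* **Noise and counts.** The sample composition is Dirichlet around the
  month's expected profile with total concentration `overdispersion`
  (default 4,000, chosen so replicate samples of one reactor sit at
  Bray–Curtis ≈ 0.2–0.3, a realistic within-reactor spread); counts are a
  single multinomial draw at `depth`. Every sample sums to depth exactly,
  and identical spec + seed reproduces the dataset bit for bit.

Physicochemical covariates (pH slightly below neutral in WWTP digesters,
7.5–8.0 elsewhere; temperature, TIC, NH₄–N, TS, VS, VFA in plausible
mesophilic ranges) are cosmetic: they never drive the counts, so covariate
correlations against this generator are null by construction.

**Recovery scoring.** `recovery_report` computes precision and recall of
the planted core and transient sets over the partition universe — OTUs
detected at least once in the scope. OTUs the scope never saw are excluded
by the partition semantics above and no occurrence rule could label them;
including them would turn the score into a raw detection measure rather
than a measure of the partitioning rule. Precision of an empty recovered
set is flagged undefined, not zero.

**What passing tests do not show.** The generator draws clean
Dirichlet-multinomial noise around smooth profiles: no chimeras, primer
bias, copy-number variation, batch effects, irregular sampling, reactor
restarts, or covariate-driven community shifts. Recovery at ≥ 0.95
precision/recall on this model demonstrates that the partitioning machinery
is correct and well-calibrated at realistic depths and design sizes — not
that real surveys, with their messier detection processes, will achieve the
same operating characteristics.

## Numerical choices

* Analytic rarefaction evaluates E[S_d] = Σⱼ[1 − C(N−nⱼ, d)/C(N, d)] via
  log-gamma differences for stability at large N.
* Subsampling derives one independent random substream per sample from
  (seed, CRC32(sample id)), so dropping or reordering samples never
  perturbs the other samples' draws.
* Rank–abundance ties are broken by OTU id; partition boundary ties go to
  intermediate; cluster labels are deterministic given the matrix.
* Distance matrices are validated symmetric within 1e-9, then symmetrised
  exactly; round-trips through PHYLIP/TSV formats are equal within 1e-9.
* All simulation entry points take explicit integer seeds; nothing reads
  the global random state.

## Problem sizes used in validation

The default test suite runs on down-scaled designs (6 reactors × 6 months,
400 OTUs, depth ≈ 2,000) for speed, with the full default design
(20 × 12, 6,000 OTUs) exercised in the partition-algebra and recovery
checks at depth 5,000 and in the acceptance script at depth 11,550. These
sizes are the package's own validation choices; all generators scale to
larger designs unchanged.

## Known limitations

* Occurrence thresholds are step functions; OTUs hovering near a threshold
  flip assignment under resampling. The thresholds are configurable but no
  uncertainty is attached to an individual OTU's label.
* The unbiased inverse Simpson estimator is undefined for all-singleton
  samples; such samples appear as NaN in diversity tables.
* NMDS is a local optimiser; multiple starts mitigate but do not eliminate
  local minima, and stress comparisons across dimensionalities use the best
  start found.
* ANOSIM assumes exchangeability of samples under the null; with strong
  within-reactor autocorrelation, treating monthly samples as independent
  replicates inflates significance, as it does in any design of this shape.
* The Spearman module reports unadjusted p-values by default; with many
  covariate × feature cells, enable the Benjamini–Hochberg option.
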