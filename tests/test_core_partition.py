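import numpy as np
import pandas as pd
import pytest

from corescope.containers import CountTable
from corescope.core_partition import (
    PartitionThresholds,
    abundance_share,
    core_overlap,
    mean_nonzero_abundance,
    occurrence_abundance_summary,
    occurrence_fractions,
    partition_otus,
    subset_table,
)
from corescope.errors import ValidationError
from .conftest import random_table


class TestOccurrenceFractions:
    def test_always_present(self):
        counts = np.ones((12, 1), dtype=int)
        table = CountTable([f"S{i}" for i in range(12)], ["a"], counts)
        assert occurrence_fractions(table).iloc[0] == 1.0

    def test_present_once_in_twelve(self):
        counts = np.zeros((12, 1), dtype=int)
        counts[3, 0] = 5
        table = CountTable([f"S{i}" for i in range(12)], ["a"], counts)
        assert occurrence_fractions(table).iloc[0] == pytest.approx(1 / 12)

    def test_detection_threshold(self):
        counts = np.ones((6, 1), dtype=int)
        table = CountTable([f"S{i}" for i in range(6)], ["a"], counts)
        occ = occurrence_fractions(table, detection_min_count=2)
        assert occ.iloc[0] == 0.0

    def test_empty_scope_is_error(self, toy_table):
        with pytest.raises(ValidationError):
            occurrence_fractions(toy_table, scope=[])


def _occurrence_table(occurrences, n_samples=10):
    """Build a table whose OTU j is present in exactly occurrences[j] samples."""
    counts = np.zeros((n_samples, len(occurrences)), dtype=int)
    for j, k in enumerate(occurrences):
        counts[:k, j] = j + 1
    return CountTable([f"S{i}" for i in range(n_samples)],
                      [f"o{j}" for j in range(len(occurrences))], counts)


class TestPartitionOtus:
    def test_full_occurrence_is_core(self):
        part = partition_otus(_occurrence_table([10]))
        assert part.assignment.iloc[0] == "core"

    def test_exact_boundary_is_intermediate(self):
        # occurrence exactly 0.80 and exactly 0.20: strict comparisons
        part = partition_otus(_occurrence_table([8, 2, 9, 1]))
        assert part.assignment.loc["o0"] == "intermediate"
        assert part.assignment.loc["o1"] == "intermediate"
        assert part.assignment.loc["o2"] == "core"
        assert part.assignment.loc["o3"] == "transient"

    def test_zero_occurrence_excluded_from_universe(self):
        part = partition_otus(_occurrence_table([0, 5]))
        assert "o0" not in part.assignment.index
        assert set(part.universe) == {"o0", "o1"}

    def test_matches_bruteforce_reclassification(self):
        rng = np.random.default_rng(17)
        table = random_table(rng, n_samples=12, n_otus=50, high=4)
        thresholds = PartitionThresholds(0.8, 0.2, 1)
        part = partition_otus(table, thresholds=thresholds)
        for j, otu in enumerate(table.otu_ids):
            occ = np.count_nonzero(table.counts[:, j] >= 1) / 12
            if occ == 0:
                assert otu not in part.assignment.index
                continue
            if occ > 0.8:
                expected = "core"
            elif occ < 0.2:
                expected = "transient"
            else:
                expected = "intermediate"
            assert part.assignment.loc[otu] == expected
            assert part.occurrence.loc[otu] == pytest.approx(occ)

    def test_partition_complete_and_disjoint(self):
        rng = np.random.default_rng(23)
        table = random_table(rng, n_samples=15, n_otus=80, high=3)
        part = partition_otus(table)
        detected = {o for j, o in enumerate(table.otu_ids)
                    if (table.counts[:, j] > 0).any()}
        assert set(part.assignment.index) == detected
        assert sum(part.counts().values()) == len(detected)

    def test_core_monotone_in_threshold(self):
        rng = np.random.default_rng(29)
        table = random_table(rng, n_samples=20, n_otus=60, high=2)
        previous = None
        for core_min in (0.5, 0.6, 0.7, 0.8, 0.9, 0.95):
            core = set(partition_otus(
                table, thresholds=PartitionThresholds(core_min, 0.2, 1)
            ).core_otus)
            if previous is not None:
                assert core <= previous
            previous = core


class TestSubsetTable:
    def test_full_set_identity(self, toy_table):
        out = subset_table(toy_table, toy_table.otu_ids)
        assert out.equals(toy_table)

    def test_empty_set_allowed(self, toy_table):
        out = subset_table(toy_table, [])
        assert out.n_otus == 0
        assert out.sample_ids == toy_table.sample_ids

    def test_unknown_otu_is_error(self, toy_table):
        with pytest.raises(ValidationError):
            subset_table(toy_table, ["nope"])

    def test_consistent_with_abundance_share(self):
        rng = np.random.default_rng(31)
        table = random_table(rng, n_samples=6, n_otus=20, high=10)
        part = partition_otus(table, thresholds=PartitionThresholds(0.6, 0.4, 1))
        core = part.core_otus
        sub = subset_table(table, core)
        share = abundance_share(table, core)
        manual = sub.counts.sum(axis=1) / table.counts.sum(axis=1)
        assert np.allclose(share.per_sample.to_numpy(), manual)


class TestAbundanceShare:
    def test_whole_sample(self):
        table = CountTable(["S1"], ["a", "b"], [[3, 7]])
        assert abundance_share(table, ["a", "b"]).per_sample.iloc[0] == 1.0

    def test_empty_set_is_zero(self, toy_table):
        assert abundance_share(toy_table, []).per_sample.eq(0).all()

    def test_direct_division(self):
        table = CountTable(["S1"], ["a", "b", "c"], [[70, 20, 10]])
        assert abundance_share(table, ["a"]).per_sample.iloc[0] == pytest.approx(0.7)

    def test_partition_shares_sum_to_one(self):
        rng = np.random.default_rng(37)
        table = random_table(rng, n_samples=10, n_otus=40, high=5)
        part = partition_otus(table)
        total = sum(
            abundance_share(table, part.otus(label)).per_sample
            for label in ("core", "intermediate", "transient")
        )
        assert np.allclose(total.to_numpy(), 1.0, atol=1e-12)


class TestMeanNonzeroAbundance:
    def test_excludes_absent_samples(self):
        # relative abundances of OTU a: 0.1, 0, 0.3 -> mean over present = 0.2
        table = CountTable(
            ["S1", "S2", "S3"], ["a", "b"],
            [[10, 90], [0, 50], [30, 70]],
        )
        out = mean_nonzero_abundance(table)
        assert out.loc["a"] == pytest.approx(0.2)

    def test_present_everywhere_equals_plain_mean(self):
        rng = np.random.default_rng(41)
        counts = rng.integers(1, 30, size=(5, 6))
        table = CountTable([f"S{i}" for i in range(5)],
                           [f"o{j}" for j in range(6)], counts)
        rel = counts / counts.sum(axis=1, keepdims=True)
        out = mean_nonzero_abundance(table)
        assert np.allclose(out.to_numpy(), rel.mean(axis=0))

    def test_absent_everywhere_flagged_nan(self):
        table = CountTable(["S1", "S2"], ["a", "gone"], [[3, 0], [2, 0]])
        assert np.isnan(mean_nonzero_abundance(table).loc["gone"])


class TestOccurrenceAbundanceSummary:
    def test_single_bin_when_all_ubiquitous(self):
        counts = np.ones((6, 3), dtype=int)
        table = CountTable([f"S{i}" for i in range(6)],
                           ["a", "b", "c"], counts)
        part = partition_otus(table)
        rows, hist = occurrence_abundance_summary(table, part)
        assert hist.loc[hist["n_samples"] == 6, "percent_of_otus"].iloc[0] == 100.0
        assert hist["percent_of_otus"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_rows_match_independent_recomputation(self):
        rng = np.random.default_rng(43)
        table = random_table(rng, n_samples=8, n_otus=10, high=6)
        part = partition_otus(table)
        rows, hist = occurrence_abundance_summary(table, part)
        rel = table.counts / table.counts.sum(axis=1, keepdims=True)
        for otu in rows.index:
            j = table.otu_ids.index(otu)
            present = table.counts[:, j] > 0
            assert rows.loc[otu, "occurrence"] == pytest.approx(present.mean())
            assert rows.loc[otu, "mean_nonzero_abundance"] == pytest.approx(
                rel[present, j].mean()
            )
        assert hist["percent_of_otus"].sum() == pytest.approx(100.0, abs=1e-9)


class TestCoreOverlap:
    def test_identical_partitions(self):
        table = _occurrence_table([10, 9, 1])
        part = partition_otus(table)
        overlap = core_overlap(part, part)
        assert overlap.n_shared == overlap.n_a == len(part.core_otus)
        assert overlap.jaccard == 1.0

    def test_disjoint_cores(self):
        # scope A: o0 core, o1 rare; scope B reversed
        counts = np.zeros((20, 2), dtype=int)
        counts[:10, 0] = 1   # o0 in all of scope A
        counts[10, 1] = 1    # o1 once in scope A... and core in scope B
        counts[10:, 1] = 1
        counts[0, 0] = 1
        table = CountTable([f"S{i}" for i in range(20)], ["o0", "o1"], counts)
        a = partition_otus(table, scope=[f"S{i}" for i in range(10)])
        b = partition_otus(table, scope=[f"S{i}" for i in range(10, 20)])
        overlap = core_overlap(a, b)
        assert overlap.n_shared == 0

    def test_universe_mismatch_is_error(self):
        t1 = _occurrence_table([10, 1])
        t2 = CountTable(t1.sample_ids, ["x", "y"], t1.counts)
        with pytest.raises(ValidationError, match="universe"):
            core_overlap(partition_otus(t1), partition_otus(t2))
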