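import itertools

import numpy as np
import pandas as pd
import pytest

from corescope.containers import DistanceMatrix
from corescope.community_stats import (
    anosim,
    assign_clusters,
    kruskal_wallis,
    nmds_embed,
    spearman_matrix,
    wilcoxon_signed_rank,
)
from corescope.errors import UndefinedStatisticError, ValidationError


# ---------------------------------------------------------------------------
# independent oracles (pure numpy, no scipy ranking)
# ---------------------------------------------------------------------------

def midranks(values):
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    r = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        r[i:j + 1] = (i + j) / 2.0 + 1.0
        i = j + 1
    out = np.empty(len(v))
    out[order] = r
    return out


def anosim_r_oracle(dm_values, labels):
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = midranks(dm_values[iu])
    within = np.array([labels[i] == labels[j] for i, j in zip(*iu)])
    m = ranks.size
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)


def random_dm(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m / m.max()


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # every between-group distance strictly above every within-group one
        n = 6
        labels = ["a"] * 3 + ["b"] * 3
        vals = np.full((n, n), 0.9)
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    vals[i, j] = 0.1
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], vals)
        res = anosim(dm, labels, n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_constant_distances_give_r_zero_p_one(self):
        n = 6
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], vals)
        res = anosim(dm, ["a"] * 3 + ["b"] * 3, n_permutations=99, seed=0)
        assert res.R == pytest.approx(0.0)
        assert res.p == 1.0

    def test_singleton_group_is_error(self):
        dm = DistanceMatrix(["a", "b", "c"], random_dm(np.random.default_rng(0), 3))
        with pytest.raises(ValidationError):
            anosim(dm, ["x", "x", "y"], n_permutations=9, seed=0)

    def test_r_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        vals = random_dm(rng, 6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = DistanceMatrix([f"s{i}" for i in range(6)], vals)
        res = anosim(dm, labels, n_permutations=9, seed=0)
        assert res.R == pytest.approx(anosim_r_oracle(vals, labels), abs=1e-12)

    def test_permutation_p_converges_to_exact_enumeration(self):
        """n=6, two groups of 3: permutation p approaches the exact p over
        all 20 distinct label assignments."""
        rng = np.random.default_rng(13)
        vals = random_dm(rng, 6)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], vals)
        obs_labels = np.array(["a", "a", "a", "b", "b", "b"])
        r_obs = anosim_r_oracle(vals, obs_labels)
        r_all = []
        for group_a in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(group_a)] = "a"
            r_all.append(anosim_r_oracle(vals, lab))
        p_exact = np.mean(np.array(r_all) >= r_obs - 1e-12)
        res = anosim(dm, obs_labels, n_permutations=20000, seed=3)
        assert res.p == pytest.approx(p_exact, abs=0.02)

    def test_matches_skbio_statistic(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(19)
        for _ in range(5):
            n = 10
            vals = random_dm(rng, n)
            labels = list("aaaaabbbbb")
            dm = DistanceMatrix([f"s{i}" for i in range(n)], vals)
            mine = anosim(dm, labels, n_permutations=9, seed=0).R
            ref = skbio.stats.distance.anosim(
                skbio.DistanceMatrix(vals), grouping=labels, permutations=0
            )["test statistic"]
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        vals = random_dm(rng, 8)
        labels = ["a"] * 4 + ["b"] * 4
        ids = [f"s{i}" for i in range(8)]
        r1 = anosim(DistanceMatrix(ids, vals), labels, 9, seed=0).R
        r2 = anosim(DistanceMatrix(ids, vals ** 2), labels, 9, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-12)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

class TestNmds:
    def test_planar_triangle_embeds_with_negligible_stress(self):
        vals = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        dm = DistanceMatrix(["a", "b", "c"], vals)
        res = nmds_embed(dm, dims=2, seed=0, n_starts=8)
        assert res.stress < 1e-6

    def test_same_seed_same_coordinates(self):
        rng = np.random.default_rng(29)
        dm = DistanceMatrix([f"s{i}" for i in range(7)], random_dm(rng, 7))
        a = nmds_embed(dm, dims=2, seed=5, n_starts=2)
        b = nmds_embed(dm, dims=2, seed=5, n_starts=2)
        assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())
        assert a.stress == b.stress

    def test_more_dimensions_never_hurt(self):
        rng = np.random.default_rng(31)
        for trial in range(3):
            dm = DistanceMatrix([f"s{i}" for i in range(8)], random_dm(rng, 8))
            s1 = nmds_embed(dm, dims=1, seed=trial, n_starts=6).stress
            s2 = nmds_embed(dm, dims=2, seed=trial, n_starts=6).stress
            assert s2 <= s1 + 1e-6

    def test_too_many_dims_is_error(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValidationError):
            nmds_embed(dm, dims=2)


class TestAssignClusters:
    def test_k_extremes(self):
        rng = np.random.default_rng(37)
        dm = DistanceMatrix([f"s{i}" for i in range(5)], random_dm(rng, 5))
        assert assign_clusters(dm, 1).nunique() == 1
        assert assign_clusters(dm, 5).nunique() == 5

    def test_two_separated_blocks_recovered(self):
        n = 10
        vals = np.full((n, n), 0.9)
        vals[:5, :5] = 0.1
        vals[5:, 5:] = 0.1
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], vals)
        labels = assign_clusters(dm, 2)
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert res.H == 0.0
        assert res.p == 1.0

    def test_hand_computed_value(self):
        # ranks 1..6, rank sums 6 and 15: H = 12/(6*7) * (12 + 75) - 21 = 27/7
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.H == pytest.approx(27 / 7)

    def test_tie_corrected_h_matches_formula_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            sizes = rng.integers(2, 5, size=3)
            groups = [list(rng.integers(0, 4, size=s)) for s in sizes]
            pooled = np.concatenate(groups).astype(float)
            if np.ptp(pooled) == 0:
                continue
            ranks = midranks(pooled)
            n = len(pooled)
            h = 0.0
            start = 0
            for g in groups:
                r = ranks[start:start + len(g)]
                h += r.sum() ** 2 / len(g)
                start += len(g)
            h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
            _, tie_counts = np.unique(pooled, return_counts=True)
            correction = 1 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
            h /= correction
            assert kruskal_wallis(groups).H == pytest.approx(h, abs=1e-9)

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2], []])


class TestWilcoxon:
    def test_all_positive_differences_maximal_w(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.W == 15.0

    def test_symmetric_differences_give_half_rank_sum(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])  # differences -1, +1, -1, +1
        res = wilcoxon_signed_rank(x, y)
        assert res.W == pytest.approx(res.n_used * (res.n_used + 1) / 4)

    def test_all_zero_differences_is_error(self):
        with pytest.raises(UndefinedStatisticError):
            wilcoxon_signed_rank([1, 2], [1, 2])

    def test_zero_differences_dropped_before_ranking(self):
        res = wilcoxon_signed_rank([5, 1, 2, 3], [5, 0, 0, 0])
        assert res.n_used == 3
        assert res.W == 6.0

    def test_approximate_p_close_to_exact_enumeration(self):
        """n=6 distinct pairs: the normal approximation with continuity
        correction tracks the exact sign-flip distribution."""
        x = np.array([3.1, 0.8, 2.4, 4.0, 1.5, 2.9])
        y = np.array([2.0, 1.5, 1.1, 2.2, 1.9, 1.2])
        d = x - y
        ranks = midranks(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        mu = total / 2.0
        t_all = [
            np.sum(ranks[np.array(signs, dtype=bool)])
            for signs in itertools.product([0, 1], repeat=6)
        ]
        p_exact = np.mean(np.abs(np.array(t_all) - mu) >= abs(w_obs - mu) - 1e-12)
        res = wilcoxon_signed_rank(x, y)
        assert res.W == pytest.approx(w_obs)
        assert res.p == pytest.approx(p_exact, abs=0.075)


class TestSpearmanMatrix:
    @staticmethod
    def _frames():
        idx = [f"S{i}" for i in range(8)]
        params = pd.DataFrame({
            "pH": np.arange(8.0),
            "TIC": [1.0, 3.0, 2.0, np.nan, 5.0, 4.0, 7.0, 6.0],
            "flat": [2.0] * 8,
        }, index=idx)
        features = pd.DataFrame({
            "up": np.arange(8.0) ** 2,
            "down": -np.arange(8.0),
        }, index=idx)
        return params, features

    def test_monotone_extremes(self):
        params, features = self._frames()
        out = spearman_matrix(params, features).set_index(["parameter", "feature"])
        assert out.loc[("pH", "up"), "rho"] == pytest.approx(1.0)
        assert out.loc[("pH", "down"), "rho"] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        params, features = self._frames()
        out = spearman_matrix(params, features).set_index(["parameter", "feature"])
        assert not out.loc[("flat", "up"), "defined"]
        assert not out.loc[("flat", "up"), "significant"]

    def test_missing_values_pairwise_deleted(self):
        params, features = self._frames()
        out = spearman_matrix(params, features).set_index(["parameter", "feature"])
        assert out.loc[("TIC", "up"), "n"] == 7

    def test_tied_data_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(10):
            a = rng.integers(0, 4, size=9).astype(float)
            b = rng.integers(0, 4, size=9).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            params = pd.DataFrame({"a": a}, index=range(9))
            features = pd.DataFrame({"b": b}, index=range(9))
            out = spearman_matrix(params, features)
            expected = np.corrcoef(midranks(a), midranks(b))[0, 1]
            assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_bh_adjustment_only_raises_pvalues(self):
        params, features = self._frames()
        raw = spearman_matrix(params, features)
        adj = spearman_matrix(params, features, adjust=True)
        mask = raw["defined"]
        assert (adj.loc[mask, "p_adjusted"].to_numpy()
                >= raw.loc[mask, "p"].to_numpy() - 1e-12).all()
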