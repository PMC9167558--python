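import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.spatial
import scipy.stats

from invashift.ordination_beta import (
    DistanceMatrix,
    pairwise_permanova,
    pcoa,
    permanova,
    permdisp,
)

from conftest import make_metadata


def euclidean_dm(X, ids=None):
    ids = ids or [f"s{i}" for i in range(len(X))]
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(X))
    return DistanceMatrix(ids, d)


class TestDistanceMatrix:
    def test_rejects_asymmetry(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], m)

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        dm = euclidean_dm(rng.normal(size=(4, 3)))
        dm.write_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.read_tsv(tmp_path / "d.tsv")
        assert back.sample_ids == dm.sample_ids
        assert np.allclose(back.values, dm.values)


class TestPcoa:
    def test_euclidean_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 3))
        dm = euclidean_dm(X)
        emb = pcoa(dm)
        d2 = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(emb.coordinates.to_numpy())
        )
        assert np.allclose(d2, dm.values, atol=1e-8)

    def test_all_zero_matrix(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        emb = pcoa(dm)
        assert np.allclose(emb.eigenvalues, 0.0, atol=1e-12)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(2)
        dm = euclidean_dm(rng.normal(size=(6, 4)))
        a = -0.5 * dm.values**2
        centered = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
        emb = pcoa(dm)
        assert emb.eigenvalues.sum() == pytest.approx(np.trace(centered), abs=1e-9)

    def test_negative_eigenvalues_reported_for_non_euclidean(self):
        # Sorensen-type dissimilarities are generally non-Euclidean
        d = np.array(
            [[0, 0.9, 0.1, 0.5], [0.9, 0, 0.9, 0.5], [0.1, 0.9, 0, 0.9], [0.5, 0.5, 0.9, 0]]
        )
        emb = pcoa(DistanceMatrix(list("abcd"), d))
        assert emb.eigenvalues.min() < 0
        assert emb.neg_coordinates.shape[1] >= 1


class TestPermanova:
    def test_univariate_equals_classical_anova(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.normal(size=15)
            labels = list(np.repeat(["a", "b", "c"], 5))
            dm = DistanceMatrix(
                [f"s{i}" for i in range(15)], np.abs(y[:, None] - y[None, :])
            )
            meta = make_metadata(dm.sample_ids, region=labels)
            res = permanova(dm, meta, ["region"], n_perm=9, seed=0)
            f_classic = scipy.stats.f_oneway(*[y[np.array(labels) == g] for g in "abc"])[0]
            assert res.table.loc["region", "F"] == pytest.approx(f_classic, abs=1e-8)

    def test_matches_skbio_one_way(self):
        import skbio.stats.distance as sksd

        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        X[:6] += 1.0
        dm = euclidean_dm(X)
        labels = ["a"] * 6 + ["b"] * 6
        meta = make_metadata(dm.sample_ids, region=labels)
        res = permanova(dm, meta, ["region"], n_perm=99, seed=0)
        sk = sksd.permanova(dm.to_skbio(), grouping=labels, permutations=99)
        assert res.table.loc["region", "F"] == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_exhaustive_enumeration_matches_brute_force(self):
        # n=6, two groups of 3: p over all 6! relabellings
        rng = np.random.default_rng(5)
        y = rng.normal(size=6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = DistanceMatrix([f"s{i}" for i in range(6)], np.abs(y[:, None] - y[None, :]))
        meta = make_metadata(dm.sample_ids, region=list(labels))
        res = permanova(dm, meta, ["region"], n_perm="exhaustive", seed=0)

        def f_stat(values):
            return scipy.stats.f_oneway(values[:3], values[3:])[0]

        f_obs = f_stat(y)
        count = sum(
            f_stat(y[np.array(perm)]) >= f_obs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        expected_p = (1 + count) / (1 + math.factorial(6))
        assert res.n_permutations == math.factorial(6)
        assert res.table.loc["region", "p"] == pytest.approx(expected_p, abs=1e-12)

    def test_sequential_ss_decomposition(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(24, 6))
        dm = euclidean_dm(X)
        region = list(np.repeat(["r1", "r2", "r3"], 8))
        season = list(np.tile(np.repeat(["spring", "autumn"], 4), 3))
        meta = make_metadata(dm.sample_ids, region=region, season=season)
        res = permanova(dm, meta, ["region", "season", "region:season"], n_perm=9, seed=0)
        t = res.table
        terms_ss = t.loc[["region", "season", "region:season", "Residual"], "SS"].sum()
        assert terms_ss == pytest.approx(t.loc["Total", "SS"], abs=1e-9)
        assert t.loc[["region", "season", "region:season", "Residual"], "R2"].sum() == (
            pytest.approx(1.0, abs=1e-9)
        )
        assert list(t.index[:3]) == ["region", "season", "region:season"]

    def test_aliased_term_rejected(self):
        rng = np.random.default_rng(7)
        dm = euclidean_dm(rng.normal(size=(8, 3)))
        labels = list(np.repeat(["a", "b"], 4))
        meta = make_metadata(dm.sample_ids, region=labels, season=None)
        meta.data["season"] = np.where(np.array(labels) == "a", "spring", "autumn")
        with pytest.raises(ValueError, match="aliased"):
            permanova(dm, meta, ["region", "season"], n_perm=9, seed=0)

    def test_p_value_floor_never_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 3))
        X[:5] += 50  # overwhelming separation
        dm = euclidean_dm(X)
        meta = make_metadata(dm.sample_ids, region=["a"] * 5 + ["b"] * 5)
        res = permanova(dm, meta, ["region"], n_perm=99, seed=0)
        # (1 + b) / (1 + m) floor: tied permutations (e.g. the full label
        # swap reproducing the partition) may raise p slightly above it
        assert res.table.loc["region", "p"] >= 1 / 100
        assert res.table.loc["region", "p"] < 0.05

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        dm = euclidean_dm(rng.normal(size=(12, 4)))
        meta = make_metadata(dm.sample_ids, region=list(np.repeat(["a", "b"], 6)))
        p1 = permanova(dm, meta, ["region"], n_perm=199, seed=5).table.loc["region", "p"]
        p2 = permanova(dm, meta, ["region"], n_perm=199, seed=5).table.loc["region", "p"]
        assert p1 == p2


class TestPairwisePermanova:
    def make_three_groups(self, sep=3.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(3 * n, 4))
        X[n : 2 * n] += sep
        X[2 * n :] += 2 * sep
        labels = list(np.repeat(["a", "b", "c"], n))
        return euclidean_dm(X), labels

    def test_two_levels_reduce_to_one_way(self):
        dm, labels = self.make_three_groups()
        keep = [s for s, l in zip(dm.sample_ids, labels) if l in ("a", "b")]
        sub = dm.submatrix(keep)
        meta = make_metadata(dm.sample_ids, region=labels)
        table = pairwise_permanova(sub, meta, "region", n_perm=99, seed=1)
        assert len(table) == 1
        one_way = permanova(sub, meta, ["region"], n_perm=99, seed=0)
        assert table.loc[0, "F"] == pytest.approx(one_way.table.loc["region", "F"], abs=1e-10)

    def test_three_levels_give_three_rows(self):
        dm, labels = self.make_three_groups()
        meta = make_metadata(dm.sample_ids, region=labels)
        table = pairwise_permanova(dm, meta, "region", n_perm=49, seed=1)
        assert len(table) == 3
        assert set(zip(table["level_a"], table["level_b"])) == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }

    def test_planted_separation_all_significant(self):
        dm, labels = self.make_three_groups(sep=5.0)
        meta = make_metadata(dm.sample_ids, region=labels)
        table = pairwise_permanova(dm, meta, "region", n_perm=999, seed=1)
        assert (table["p"] <= 0.05).all()

    def test_singleton_level_rejected(self):
        rng = np.random.default_rng(1)
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        meta = make_metadata(dm.sample_ids, region=["a", "a", "b", "b", "c"])
        with pytest.raises(ValueError, match="c"):
            pairwise_permanova(dm, meta, "region", n_perm=9, seed=0)


class TestPermdisp:
    def test_distances_match_direct_coordinates(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(14, 3))
        dm = euclidean_dm(X)
        labels = ["a"] * 7 + ["b"] * 7
        meta = make_metadata(dm.sample_ids, region=labels)
        res = permdisp(dm, meta, "region", n_perm=9, seed=0)
        for g in ("a", "b"):
            rows = np.array(labels) == g
            centroid = X[rows].mean(axis=0)
            direct = np.linalg.norm(X[rows] - centroid, axis=1)
            assert np.allclose(np.sort(res.distances[rows]), np.sort(direct), atol=1e-8)

    def test_scaled_group_dispersion_ratio(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(20, 3))
        A -= A.mean(axis=0)
        B = 2.0 * A + 10.0  # same shape, doubled dispersion, shifted
        dm = euclidean_dm(np.vstack([A, B]))
        labels = ["a"] * 20 + ["b"] * 20
        meta = make_metadata(dm.sample_ids, region=labels)
        res = permdisp(dm, meta, "region", n_perm=99, seed=0)
        ratio = res.group_means["b"] / res.group_means["a"]
        assert ratio == pytest.approx(2.0, abs=1e-8)

    def test_matches_skbio_centroid_statistic(self):
        import skbio.stats.distance as sksd

        rng = np.random.default_rng(12)
        X = rng.normal(size=(16, 4))
        X[8:] *= 2.5
        dm = euclidean_dm(X)
        labels = ["a"] * 8 + ["b"] * 8
        meta = make_metadata(dm.sample_ids, region=labels)
        res = permdisp(dm, meta, "region", n_perm=99, seed=0)
        sk = sksd.permdisp(dm.to_skbio(), grouping=labels, permutations=99, test="centroid")
        assert res.f_statistic == pytest.approx(sk["test statistic"], rel=1e-8)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(13)
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        meta = make_metadata(dm.sample_ids, region=["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="b"):
            permdisp(dm, meta, "region", n_perm=9, seed=0)

    def test_spatial_median_center_runs(self):
        rng = np.random.default_rng(14)
        dm = euclidean_dm(rng.normal(size=(12, 3)))
        meta = make_metadata(dm.sample_ids, region=["a"] * 6 + ["b"] * 6)
        res = permdisp(dm, meta, "region", n_perm=49, seed=0, center="spatial_median")
        assert np.all(res.distances >= 0)
        assert 0 < res.p_value <= 1
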