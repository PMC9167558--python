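import io
import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given, settings, strategies as st

from invashift.hill_diversity import (
    HillConfig,
    dissimilarity_matrix,
    hill_alpha,
    hill_beta_pair,
    hill_phylo_alpha,
    pairwise_dissimilarities,
)
from invashift.tables_io import PhyloTree, RelativeAbundanceTable


def tree_from(newick: str) -> PhyloTree:
    return PhyloTree(skbio.TreeNode.read(io.StringIO(newick), format="newick"))


def star_tree(n: int) -> PhyloTree:
    leaves = ",".join(f"L{i}:1" for i in range(n))
    return tree_from(f"({leaves});")


def random_simplex(rng, n, sparsity=0.0):
    p = rng.dirichlet(np.ones(n))
    if sparsity:
        mask = rng.random(n) < sparsity
        if mask.all():
            mask[rng.integers(n)] = False
        p[mask] = 0.0
        p /= p.sum()
    return p


class TestHillAlpha:
    def test_even_pair(self):
        p = np.array([0.5, 0.5])
        assert hill_alpha(p, 0) == 2
        assert hill_alpha(p, 1) == pytest.approx(2, abs=1e-12)

    def test_q1_matches_exp_shannon_formula(self):
        p = np.array([0.8, 0.2])
        expected = np.exp(-(0.8 * np.log(0.8) + 0.2 * np.log(0.2)))
        assert hill_alpha(p, 1) == pytest.approx(expected, abs=1e-14)

    def test_q0_counts_support_only(self):
        assert hill_alpha(np.array([0.7, 0.3, 0.0]), 0) == 2

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            hill_alpha(np.array([0.5, 0.2]), 1)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_nonincreasing_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = random_simplex(rng, 12, sparsity=0.3)
        values = [hill_alpha(p, q) for q in (0, 0.5, 1, 2)]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_q1_continuity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_simplex(rng, 10, sparsity=0.2)
            assert abs(hill_alpha(p, 1) - hill_alpha(p, 0.999)) < 1e-2 * hill_alpha(p, 1)


class TestHillPhyloAlpha:
    def test_star_tree_reduces_to_taxonomic(self):
        rng = np.random.default_rng(1)
        tree = star_tree(8)
        order = tree.leaf_names
        for q in (0, 0.5, 1, 2):
            for _ in range(10):
                p = random_simplex(rng, 8, sparsity=0.2)
                p = pd.Series(p, index=[f"L{i}" for i in range(8)])[order].to_numpy()
                assert hill_phylo_alpha(p, tree, q) == pytest.approx(
                    hill_alpha(p, q), abs=1e-10
                )

    def test_single_taxon_is_one(self):
        tree = tree_from("((A:1,B:1):1,C:2);")
        p = pd.Series({n: 0.0 for n in tree.leaf_names})
        p["A"] = 1.0
        assert hill_phylo_alpha(p.to_numpy(), tree, 1) == pytest.approx(1.0, abs=1e-12)

    def test_caterpillar_matches_hand_enumeration(self):
        # ((A:1,B:1):1,C:2); leaves A,B,C with p = (0.5, 0.3, 0.2)
        tree = tree_from("((A:1,B:1):1,C:2);")
        pv = {"A": 0.5, "B": 0.3, "C": 0.2}
        p = np.array([pv[n] for n in tree.leaf_names])
        # independent enumeration: (length, abundance) per branch
        branches = [(1.0, 0.5), (1.0, 0.3), (1.0, 0.8), (2.0, 0.2)]
        T = sum(l * a for l, a in branches)
        assert T == pytest.approx(2.0)
        for q in (0, 0.5, 2):
            expected = sum((l / T) * a**q for l, a in branches) ** (1 / (1 - q))
            assert hill_phylo_alpha(p, tree, q) == pytest.approx(expected, abs=1e-12)
        expected_q1 = np.exp(-sum((l / T) * a * np.log(a) for l, a in branches))
        assert hill_phylo_alpha(p, tree, 1) == pytest.approx(expected_q1, abs=1e-12)


class TestHillBetaPair:
    def test_sorensen_set_arithmetic(self):
        p1 = np.array([0.5, 0.5, 0.0])
        p2 = np.array([0.0, 0.5, 0.5])
        assert hill_beta_pair(p1, p2, 0) == pytest.approx(0.5)

    def test_identical_pairs_are_zero(self):
        rng = np.random.default_rng(5)
        for q in (0, 0.5, 1, 2):
            p = random_simplex(rng, 6)
            assert hill_beta_pair(p, p, q) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_are_one(self):
        p1 = np.array([0.6, 0.4, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 0.3, 0.7])
        for q in (0, 1):
            assert hill_beta_pair(p1, p2, q) == pytest.approx(1.0, abs=1e-9)
            tree = star_tree(4)
            assert hill_beta_pair(p1, p2, q, "phylogenetic", tree) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_pruned_phylo_beta_matches_explicit_shear(self):
        # the fast path masks full-tree branches; an explicitly sheared
        # subtree with recomputed mean depth is the independent oracle
        from invashift.hill_diversity import (
            BranchDecomposition,
            _beta_ratio,
            _beta_to_dissimilarity,
        )
        from invashift.synthetic_data import _random_tree

        tree = _random_tree([f"L{i}" for i in range(20)], seed=4)
        names = tree.leaf_names
        rng = np.random.default_rng(0)

        def shear_oracle(p1, p2, q):
            support = [n for n, a, b in zip(names, p1, p2) if a > 0 or b > 0]
            sub = tree.shear(support)
            dec = BranchDecomposition.from_tree(sub, support)
            keep = [names.index(n) for n in support]
            a1, a2 = dec.abundances(p1[keep]), dec.abundances(p2[keep])
            tbar = float(dec.lengths @ ((a1 + a2) / 2))
            beta = _beta_ratio(dec.lengths / tbar, a1, a2, q)
            return _beta_to_dissimilarity(beta, q, "sorensen")

        for _ in range(15):
            p1 = random_simplex(rng, 20, sparsity=0.6)
            p2 = random_simplex(rng, 20, sparsity=0.6)
            for q in (0, 0.5, 1, 2):
                fast = hill_beta_pair(p1, p2, q, "phylogenetic", tree)
                assert fast == pytest.approx(shear_oracle(p1, p2, q), abs=1e-12)

    def test_jaccard_variant_at_q0(self):
        p1 = np.array([0.5, 0.5, 0.0])
        p2 = np.array([0.0, 0.5, 0.5])
        # |union|=3, |intersection|=1 -> Jaccard dissimilarity 2/3
        assert hill_beta_pair(p1, p2, 0, variant="jaccard") == pytest.approx(2 / 3)

    def test_phylo_beta_zero_for_identical_and_symmetric(self):
        tree = tree_from("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        rng = np.random.default_rng(2)
        p1 = random_simplex(rng, 4)
        p2 = random_simplex(rng, 4)
        for q in (0, 1):
            assert hill_beta_pair(p1, p1, q, "phylogenetic", tree) == pytest.approx(0, abs=1e-9)
            d12 = hill_beta_pair(p1, p2, q, "phylogenetic", tree)
            d21 = hill_beta_pair(p2, p1, q, "phylogenetic", tree)
            assert d12 == pytest.approx(d21, abs=1e-12)
            assert 0 <= d12 <= 1


class TestDissimilarityMatrix:
    def make_rel(self, P, ids=None, cols=None):
        ids = ids or [f"s{i}" for i in range(P.shape[0])]
        cols = cols or [f"f{j}" for j in range(P.shape[1])]
        return RelativeAbundanceTable(pd.DataFrame(P, index=ids, columns=cols))

    def test_identical_samples_zero_matrix(self):
        P = np.tile([0.25, 0.25, 0.5], (3, 1))
        dm = dissimilarity_matrix(self.make_rel(P), HillConfig(q=1))
        assert np.allclose(dm.values, 0.0, atol=1e-9)

    @pytest.mark.parametrize("q", [0, 0.5, 1, 2])
    def test_matrix_matches_pairwise_calls(self, q):
        rng = np.random.default_rng(7)
        P = np.array([random_simplex(rng, 6, sparsity=0.3) for _ in range(5)])
        dm = dissimilarity_matrix(self.make_rel(P), HillConfig(q=q))
        for i, j in itertools.combinations(range(5), 2):
            assert dm.values[i, j] == pytest.approx(
                hill_beta_pair(P[i], P[j], q), abs=1e-9
            )

    def test_q0_equals_set_sorensen(self):
        rng = np.random.default_rng(9)
        P = np.array([random_simplex(rng, 10, sparsity=0.5) for _ in range(6)])
        dm = dissimilarity_matrix(self.make_rel(P), HillConfig(q=0))
        for i, j in itertools.combinations(range(6), 2):
            a, b = set(np.where(P[i] > 0)[0]), set(np.where(P[j] > 0)[0])
            expected = (len(a) + len(b) - 2 * len(a & b)) / (len(a) + len(b))
            assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_fast_paths_match_generic(self):
        rng = np.random.default_rng(11)
        P = np.array([random_simplex(rng, 8, sparsity=0.3) for _ in range(4)])
        for q in (0.0, 1.0):
            fast = pairwise_dissimilarities(P, q)
            for i, j in itertools.combinations(range(4), 2):
                assert fast[i, j] == pytest.approx(hill_beta_pair(P[i], P[j], q), abs=1e-9)

    def test_phylo_matrix_on_tree(self, small_sim):
        from invashift.tables_io import to_relative

        ids = small_sim.table.sample_ids[:5]
        rel = to_relative(small_sim.table.select_samples(ids))
        dm = dissimilarity_matrix(
            rel, HillConfig(q=1, facet="phylogenetic"), tree=small_sim.tree
        )
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(dm.values >= 0) and np.all(dm.values <= 1)

    def test_phylo_requires_asv_rank(self, small_sim):
        from invashift.tables_io import to_relative

        rel = to_relative(small_sim.table.select_samples(small_sim.table.sample_ids[:3]))
        with pytest.raises(ValueError, match="rank"):
            dissimilarity_matrix(
                rel,
                HillConfig(q=1, facet="phylogenetic", rank="Family"),
                tree=small_sim.tree,
                taxonomy=small_sim.taxonomy,
            )
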