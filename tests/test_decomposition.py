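from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import balanced_newick, block_alignment
from oracles import best_quartet_topology, min_split_imbalance

from hmmens.decomposition import (
    DecompositionParams,
    centroid_edge,
    decompose,
    estimate_guide_tree,
    leaf_labels,
    mean_pairwise_identity,
    pairwise_identity,
    split_on_edge,
    tree_from_newick,
)
from hmmens.io_formats import Alignment, Sequence
from hmmens.synthetic import sample_tree


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACD", "ACD", 1.0),
            ("ACFD", "ACED", 0.75),  # 3 matches over 4 mutually non-gap columns
            ("A---", "-CDE", 0.0),  # no shared non-gap column
            ("A-CD", "AW-D", 2 / 2),  # only mutually non-gap columns count
            ("XXXX", "XXXX", 0.0),  # ambiguity codes never match
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)
        assert pairwise_identity(b, a) == pytest.approx(expected)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACD", "AC")


class TestMeanPairwiseIdentity:
    def test_identical_rows(self):
        aln = Alignment([Sequence(f"s{i}", "ACDW") for i in range(3)])
        assert mean_pairwise_identity(aln) == 1.0

    def test_enumerated_pairs(self):
        # pair identities: (a,b)=1.0, (a,c)=0.5, (b,c)=0.5 -> mean 2/3
        aln = Alignment(
            [Sequence("a", "AC"), Sequence("b", "AC"), Sequence("c", "AW")]
        )
        assert mean_pairwise_identity(aln) == pytest.approx(2 / 3)

    def test_single_row_convention(self):
        assert mean_pairwise_identity(Alignment([Sequence("a", "ACD")])) == 1.0

    def test_sampled_estimate_is_seeded(self):
        aln = block_alignment(120, 30, seed=3, n_blocks=2)
        a = mean_pairwise_identity(aln, np.random.default_rng(5))
        b = mean_pairwise_identity(aln, np.random.default_rng(5))
        assert a == b
        exact = float(
            np.mean(
                [
                    pairwise_identity(x.residues, y.residues)
                    for x, y in itertools.combinations(aln.rows, 2)
                ]
            )
        )
        assert a == pytest.approx(exact, abs=0.05)


class TestCentroidEdge:
    def test_quartet_balanced_split(self):
        tree = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        head = centroid_edge(tree)
        below = {leaf.taxon.label for leaf in head.leaf_iter()}
        assert below in ({"a", "b"}, {"c", "d"})

    def test_two_leaf_tree(self):
        tree = tree_from_newick("(a:1,b:1);")
        head = centroid_edge(tree)
        assert {leaf.taxon.label for leaf in head.leaf_iter()} in ({"a"}, {"b"})

    def test_caterpillar_best_split(self):
        tree = tree_from_newick("(((a:1,b:1):1,c:1):1,(d:1,e:1):1);")
        head = centroid_edge(tree)
        below = {leaf.taxon.label for leaf in head.leaf_iter()}
        assert abs(len(below) - (5 - len(below))) == min_split_imbalance(tree)

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_exhaustive_minimization(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 31))
        tree = sample_tree(n, rng, height=0.5)
        head = centroid_edge(tree)
        below = {leaf.taxon.label for leaf in head.leaf_iter()}
        assert abs(len(below) - (n - len(below))) == min_split_imbalance(tree)

    def test_deterministic_tie_break(self):
        newick = "((a:1,b:1):1,(c:1,d:1):1);"
        picks = {
            frozenset(
                leaf.taxon.label
                for leaf in centroid_edge(tree_from_newick(newick)).leaf_iter()
            )
            for _ in range(5)
        }
        assert len(picks) == 1


class TestSplitOnEdge:
    def test_quartet_split(self):
        tree = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t1, t2 = split_on_edge(tree, centroid_edge(tree))
        assert {frozenset(leaf_labels(t1)), frozenset(leaf_labels(t2))} == {
            frozenset({"a", "b"}),
            frozenset({"c", "d"}),
        }

    def test_pendant_split_gives_single_leaf(self):
        tree = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        pendant = next(
            leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label == "a"
        )
        t1, t2 = split_on_edge(tree, pendant)
        sets = {frozenset(leaf_labels(t1)), frozenset(leaf_labels(t2))}
        assert frozenset({"a"}) in sets

    @pytest.mark.parametrize("trial", range(50))
    def test_leaf_sets_partition(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(3, 20))
        tree = sample_tree(n, rng, height=0.3)
        labels = leaf_labels(tree)
        t1, t2 = split_on_edge(tree, centroid_edge(tree))
        assert leaf_labels(t1) | leaf_labels(t2) == labels
        assert not (leaf_labels(t1) & leaf_labels(t2))


def _uniform_alignment(n: int, length: int = 20, seed: int = 0, prefix: str = "s"):
    return block_alignment(n, length, seed=seed, n_blocks=1, block_noise=0.0,
                           prefix=prefix)


class TestDecompose:
    def test_small_family_single_node(self):
        aln = _uniform_alignment(8)
        tree = estimate_guide_tree(aln)
        dec = decompose(aln, tree, DecompositionParams(), np.random.default_rng(0))
        assert dec.node_count == 1

    def test_balanced_forty_size_only(self):
        aln = _uniform_alignment(40)
        tree = tree_from_newick(balanced_newick(40))
        dec = decompose(
            aln,
            tree,
            DecompositionParams(max_size_pct=10, min_identity_pct=0),
            np.random.default_rng(0),
        )
        sizes = sorted(node.size for node in dec.nodes())
        assert dec.node_count == 7
        assert sizes == [10, 10, 10, 10, 20, 20, 40]

    def test_identity_stop_rule(self):
        # two homogeneous blocks of 20: halves stop under (X=50, Y=40)
        aln = block_alignment(40, 30, seed=1, n_blocks=2, block_noise=0.02)
        tree = tree_from_newick(balanced_newick(40))
        dec = decompose(
            aln,
            tree,
            DecompositionParams(max_size_pct=50, min_identity_pct=40),
            np.random.default_rng(0),
        )
        assert dec.node_count == 3
        child_sizes = sorted(c.size for c in dec.root.children)
        assert child_sizes == [20, 20]
        assert all(c.mean_identity >= 0.40 for c in dec.root.children)

    def test_leaf_mismatch_error(self):
        aln = _uniform_alignment(4)
        tree = tree_from_newick("((x:1,y:1):1,(z:1,w:1):1);")
        with pytest.raises(ValueError):
            decompose(aln, tree, DecompositionParams(), np.random.default_rng(0))

    def test_size_only_invariant_to_column_permutation(self):
        rng = np.random.default_rng(11)
        aln = block_alignment(32, 25, seed=2, n_blocks=2, block_noise=0.3)
        tree = tree_from_newick(balanced_newick(32))
        params = DecompositionParams(max_size_pct=25, min_identity_pct=0)
        base = decompose(aln, tree, params, np.random.default_rng(0))
        # permute residues within every column
        cols = np.array([list(r.residues) for r in aln.rows])
        for c in range(cols.shape[1]):
            cols[:, c] = cols[rng.permutation(cols.shape[0]), c]
        shuffled = Alignment(
            [
                Sequence(r.id, "".join(cols[i]))
                for i, r in enumerate(aln.rows)
            ]
        )
        permuted = decompose(shuffled, tree, params, np.random.default_rng(0))
        assert [n.taxon_ids for n in base.nodes()] == [
            n.taxon_ids for n in permuted.nodes()
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_x_and_y(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        tree = sample_tree(n, rng, height=0.12, labels=[f"s{i:03d}" for i in range(n)])
        from hmmens.synthetic import SimParams, evolve_family

        aln = evolve_family(tree, SimParams(seed=seed, tree_height=0.12), rng)

        def count(x, y):
            params = DecompositionParams(max_size_pct=x, min_identity_pct=y)
            return decompose(aln, tree, params, np.random.default_rng(0)).node_count

        assert count(25, 0) <= count(25, 40)  # lowering Y never adds nodes
        assert count(50, 40) <= count(25, 40)  # raising X never adds nodes

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_shape_invariants(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(12, 50))
        aln = _uniform_alignment(n, seed=seed)
        tree = sample_tree(n, rng, height=0.2, labels=aln.ids)
        params = DecompositionParams(max_size_pct=20, min_identity_pct=60)
        dec = decompose(aln, tree, params, np.random.default_rng(0))
        n_split = sum(1 for node in dec.nodes() if node.children)
        assert dec.node_count == 1 + 2 * n_split
        assert dec.node_count % 2 == 1
        for node in dec.nodes():
            if node.children:
                assert node.size > params.hard_floor
                a, b = node.children
                assert a.taxon_ids | b.taxon_ids == node.taxon_ids
                assert not (a.taxon_ids & b.taxon_ids)
        assert dec.root.taxon_ids == frozenset(aln.ids)


class TestEstimateGuideTree:
    def test_two_rows_single_edge(self):
        aln = Alignment([Sequence("a", "ACDW"), Sequence("b", "ACDD")])
        tree = estimate_guide_tree(aln)
        assert leaf_labels(tree) == {"a", "b"}

    def test_nj_recovers_additive_quartet(self):
        # sequences engineered so p-distances satisfy d(a,b)+d(c,d) smallest
        rows = {
            "a": "AAAAAAAAAACCCCC",
            "b": "AAAAAAAAAACCCCW",
            "c": "WWWWWWWWWWCCCCC",
            "d": "WWWWWWWWWWCCCCW",
        }
        aln = Alignment([Sequence(k, v) for k, v in rows.items()])
        dist = {
            (x, y): 1 - pairwise_identity(rows[x], rows[y])
            for x, y in itertools.combinations(rows, 2)
        }
        dist.update({(y, x): d for (x, y), d in dist.items()})
        expected_pair = best_quartet_topology(list(rows), dist)
        tree = estimate_guide_tree(aln)
        head = centroid_edge(tree)
        below = frozenset(leaf.taxon.label for leaf in head.leaf_iter())
        assert below == expected_pair or (frozenset(rows) - below) == expected_pair

    def test_identical_rows_deterministic(self):
        aln = Alignment([Sequence(f"s{i}", "ACDW") for i in range(5)])
        t1 = estimate_guide_tree(aln)
        t2 = estimate_guide_tree(aln)
        assert t1.as_string("newick") == t2.as_string("newick")
        for edge in t1.preorder_edge_iter():
            assert (edge.length or 0) >= 0  # negative NJ lengths clamped

    def test_external_tree_leaf_mismatch_error(self, tmp_path):
        aln = Alignment([Sequence("a", "ACD"), Sequence("b", "ACC")])
        p = tmp_path / "t.nwk"
        p.write_text("(a:1,zzz:1);")
        with pytest.raises(ValueError):
            estimate_guide_tree(aln, p)
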