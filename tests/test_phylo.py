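"""Distances, neighbor joining, bootstrap and consensus trees."""

import dendropy
import numpy as np
import pytest

from elkin.core import CoreAlignment
from elkin.phylo import (
    bootstrap_trees,
    consensus_supports,
    distance_matrix,
    extended_majority_consensus,
    neighbor_joining,
    patristic_matrix,
    score_distance,
    tree_bipartitions,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def random_additive_matrix(n, rng):
    """Distance matrix of a random binary tree with positive lengths."""
    taxa = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    a = dendropy.Node(taxon=ns.get_taxon("t0"))
    b = dendropy.Node(taxon=ns.get_taxon("t1"))
    tree.seed_node.add_child(a)
    tree.seed_node.add_child(b)
    a.edge.length = rng.uniform(0.1, 1.0)
    b.edge.length = rng.uniform(0.1, 1.0)
    for i in range(2, n):
        edges = [
            nd.edge
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        ]
        e = edges[rng.integers(len(edges))]
        child, parent = e.head_node, e.tail_node
        mid = dendropy.Node()
        split = rng.uniform(0.25, 0.75) * e.length
        parent.remove_child(child)
        parent.add_child(mid)
        mid.edge.length = e.length - split
        mid.add_child(child)
        child.edge.length = split
        leaf = dendropy.Node(taxon=ns.get_taxon(f"t{i}"))
        leaf.edge.length = rng.uniform(0.1, 1.0)
        mid.add_child(leaf)
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                ns.get_taxon(f"t{i}"), ns.get_taxon(f"t{j}")
            )
    return D, taxa


class TestScoreDistance:
    def test_identical_sequences_have_zero_distance(self):
        assert score_distance("ACDKLM", "ACDKLM") == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), 30))
            b = "".join(rng.choice(list(AA), 30))
            assert score_distance(a, b) == pytest.approx(
                score_distance(b, a)
            )

    def test_mutation_ladder_is_monotone(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list(AA), 80))
        ladder, cur = [], list(base)
        positions = rng.permutation(80)
        for k, p in enumerate(positions):
            cur[p] = AA[(AA.index(cur[p]) + 7) % 20]
            if k % 8 == 0:
                ladder.append("".join(cur))
        dists = [score_distance(base, s) for s in ladder]
        assert all(b > a for a, b in zip(dists, dists[1:]))

    def test_no_shared_columns_rejected(self):
        with pytest.raises(ValueError):
            score_distance("A-", "-C")


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        """Hand-built additive matrix: ((A:1,B:2):1,(C:3,D:4)) with the
        central edge of length 1."""
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        labels = ["A", "B", "C", "D"]
        tree = neighbor_joining(D, labels)
        assert np.allclose(patristic_matrix(tree, labels), D, atol=1e-9)
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}

    def test_three_taxa_unique_topology(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = neighbor_joining(D, ["x", "y", "z"])
        assert np.allclose(
            patristic_matrix(tree, ["x", "y", "z"]), D, atol=1e-9
        )

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            D, taxa = random_additive_matrix(n, rng)
            tree = neighbor_joining(D, taxa)
            assert np.allclose(patristic_matrix(tree, taxa), D, atol=1e-8)

    def test_taxon_permutation_preserves_topology(self):
        rng = np.random.default_rng(7)
        D, taxa = random_additive_matrix(8, rng)
        t1 = neighbor_joining(D, taxa)
        perm = list(rng.permutation(8))
        D2 = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(D2, [taxa[i] for i in perm])
        assert tree_bipartitions(t1) == tree_bipartitions(t2)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0, 1], [1, 0]], dtype=float),  # too few taxa
            np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0]], dtype=float),
            np.array([[0, -1, 2], [-1, 0, 3], [2, 3, 0]], dtype=float),
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            neighbor_joining(bad)


class TestBootstrap:
    def _clade_alignment(self):
        rng = np.random.default_rng(0)

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(len(s), k, replace=False):
                s[i] = AA[(AA.index(s[i]) + 1 + int(rng.integers(19))) % 20]
            return "".join(s)

        b1 = "".join(rng.choice(list(AA), 60))
        b2 = "".join(rng.choice(list(AA), 60))
        rows = [mutate(b1, 3) for _ in range(4)] + [
            mutate(b2, 3) for _ in range(4)
        ]
        return CoreAlignment([f"x{i}" for i in range(8)], rows)

    def test_replicate_count_and_determinism(self):
        aln = self._clade_alignment()
        t1 = bootstrap_trees(aln, 12, rng_seed=5)
        t2 = bootstrap_trees(aln, 12, rng_seed=5)
        assert len(t1) == 12
        for a, b in zip(t1, t2):
            assert tree_bipartitions(a) == tree_bipartitions(b)

    def test_separated_clades_get_high_support(self):
        aln = self._clade_alignment()
        trees = bootstrap_trees(aln, 100, rng_seed=1)
        sup = consensus_supports(trees)
        clade = frozenset(f"x{i}" for i in range(4, 8))
        assert sup.get(clade, 0.0) >= 95.0


class TestExtendedMajorityConsensus:
    def test_identical_inputs_return_that_topology_at_full_support(self):
        trees = [newick("((A,B),(C,D),E);") for _ in range(10)]
        cons = extended_majority_consensus(trees)
        assert tree_bipartitions(cons) == tree_bipartitions(trees[0])
        assert set(consensus_supports(trees).values()) == {100.0}

    def test_majority_bipartition_present_with_correct_support(self):
        trees = [newick("((A,B),(C,D),E);")] * 6 + [
            newick("((A,C),(B,D),E);")
        ] * 4
        sup = consensus_supports(trees)
        assert sup[frozenset({"C", "D"})] == 60.0
        assert sup[frozenset({"C", "D", "E"})] == 60.0
        assert frozenset({"B", "D"}) not in sup

    def test_compatible_minority_greedily_admitted(self):
        # {A,B}|rest at 40% is admitted greedily; {B,C}|rest at 35% is
        # incompatible with it and excluded.  Sides are normalised to
        # exclude the reference taxon A, so {A,B} keys as {C,D,E,F} and
        # {A,B,C} as {D,E,F}.
        t_ab = newick("(((A,B),C),(D,E),F);")  # {A,B}, {A,B,C}, {D,E}
        t_bc = newick("(((B,C),A),(D,F),E);")  # {B,C}, {A,B,C}, {D,F}
        t_other = newick("((A,F),(B,E),(C,D));")
        trees = [t_ab] * 8 + [t_bc] * 7 + [t_other] * 5
        sup = consensus_supports(trees)
        assert sup[frozenset({"D", "E", "F"})] == 75.0  # >50% rule
        assert sup[frozenset({"C", "D", "E", "F"})] == 40.0  # greedy
        assert frozenset({"B", "C"}) not in sup  # incompatible, excluded
        assert sup[frozenset({"D", "E"})] == 40.0

    def test_input_order_invariance_for_distinct_frequencies(self):
        trees = [newick("((A,B),(C,D),E);")] * 6 + [
            newick("((A,C),(B,D),E);")
        ] * 4
        rev = list(reversed(trees))
        assert tree_bipartitions(
            extended_majority_consensus(trees)
        ) == tree_bipartitions(extended_majority_consensus(rev))

    def test_mismatched_taxon_sets_rejected(self):
        with pytest.raises(ValueError):
            extended_majority_consensus(
                [newick("((A,B),C,D);"), newick("((A,B),C,E);")]
            )

    def test_agrees_with_reference_majority_rule(self):
        """>50% bipartitions match dendropy's majority-rule consensus."""
        rng = np.random.default_rng(3)
        tns = dendropy.TaxonNamespace([f"t{i}" for i in range(6)])
        trees = dendropy.TreeList(taxon_namespace=tns)
        for _ in range(9):
            trees.append(
                dendropy.simulate.treesim.birth_death_tree(
                    birth_rate=1.0,
                    death_rate=0.0,
                    num_extant_tips=6,
                    taxon_namespace=tns,
                    rng=__import__("random").Random(int(rng.integers(1 << 30))),
                )
            )
        for t in trees:
            for i, lf in enumerate(t.leaf_node_iter()):
                lf.taxon = tns[i]
        ref = trees.consensus(min_freq=0.5000001)
        ref_bips = tree_bipartitions(ref)
        ours = tree_bipartitions(extended_majority_consensus(list(trees)))
        assert ref_bips <= ours
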