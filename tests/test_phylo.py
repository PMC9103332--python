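"""Neighbor joining, bootstrap supports, rooting, collapsing, RF distance."""

import itertools

import dendropy
import numpy as np
import pytest

from crtkit.aligndist import DistanceMatrix, Msa, msa_to_distances
from crtkit.phylo import (
    Node,
    Tree,
    bipartitions,
    bootstrap_support,
    collapse_low_support,
    compare_topologies,
    neighbor_joining,
    random_tree,
    read_newick,
    root_by_outgroup,
    support_table,
    to_newick,
    tree_to_distance_matrix,
)
from crtkit import simulate


def dendropy_rf(t1: Tree, t2: Tree) -> int:
    """Independent Robinson–Foulds oracle via dendropy."""
    ns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=to_newick(t1, supports=False),
                           schema="newick", taxon_namespace=ns)
    d2 = dendropy.Tree.get(data=to_newick(t2, supports=False),
                           schema="newick", taxon_namespace=ns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0.0, 0.3, 0.5],
                                      [0.3, 0.0, 0.6],
                                      [0.5, 0.6, 0.0]]))
        t = neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in t.root.leaves()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_exact_on_additive_six_taxon_matrix(self, rng):
        true = random_tree(6, rng)
        dm = tree_to_distance_matrix(true)
        est = neighbor_joining(dm)
        assert compare_topologies(true, est) == 0
        np.testing.assert_allclose(
            tree_to_distance_matrix(est).d, dm.d, atol=1e-9
        )

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_additive_exactness_fuzz(self, n_leaves):
        for seed in range(10):
            rng = np.random.default_rng([n_leaves, seed])
            true = random_tree(n_leaves, rng)
            est = neighbor_joining(tree_to_distance_matrix(true))
            assert compare_topologies(true, est) == 0

    def test_taxon_order_equivariance(self, rng):
        true = random_tree(7, rng)
        dm = tree_to_distance_matrix(true)
        order = list(rng.permutation(len(dm.taxa)))
        dm_p = DistanceMatrix([dm.taxa[i] for i in order],
                              dm.d[np.ix_(order, order)])
        assert compare_topologies(neighbor_joining(dm),
                                  neighbor_joining(dm_p)) == 0

    def test_agrees_with_dendropy_nj_on_noisy_matrix(self, rng):
        true = random_tree(7, rng)
        msa, _ = simulate.evolve_family(true, 500, seed=17)
        dm = msa_to_distances(msa)
        ours = neighbor_joining(dm)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_dm_to_csv(dm), delimiter=",")
        theirs = read_newick(pdm.nj_tree().as_string(schema="newick"))
        assert compare_topologies(ours, theirs) == 0

    def test_nonfinite_matrix_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], d))

    def test_negative_lengths_clamped_with_raw_kept(self):
        # classic matrix producing a negative NJ branch estimate
        d = np.array(
            [[0.0, 0.1, 0.6, 0.6],
             [0.1, 0.0, 0.55, 0.55],
             [0.6, 0.55, 0.0, 0.1],
             [0.6, 0.55, 0.1, 0.0]])
        t = neighbor_joining(DistanceMatrix(list("abcd"), d))
        for node in t.root.walk():
            assert node.length >= 0
            if node.raw_length is not None and node.raw_length < 0:
                assert node.length == 0.0


def _dm_to_csv(dm: DistanceMatrix) -> "io.StringIO":
    import io

    lines = ["," + ",".join(dm.taxa)]
    for name, row in zip(dm.taxa, dm.d):
        lines.append(name + "," + ",".join(f"{x:.8f}" for x in row))
    return io.StringIO("\n".join(lines))


class TestBootstrap:
    @pytest.fixture()
    def family(self):
        rng = np.random.default_rng(5)
        tree = random_tree(6, rng)
        msa, _ = simulate.evolve_family(tree, 600, seed=5)
        return msa

    def test_single_replicate_supports_binary(self, family):
        t = bootstrap_support(family, n_reps=1, seed=1)
        sups = [n.support for n in bipartitions(t).values()]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_identical_supports(self, family):
        t1 = bootstrap_support(family, n_reps=30, seed=9)
        t2 = bootstrap_support(family, n_reps=30, seed=9)
        s1 = {k: n.support for k, n in bipartitions(t1).items()}
        s2 = {k: n.support for k, n in bipartitions(t2).items()}
        assert s1 == s2

    def test_supports_in_range_and_on_original_edges(self, family):
        t = bootstrap_support(family, n_reps=50, seed=2)
        base = neighbor_joining(msa_to_distances(family))
        assert set(bipartitions(t)) == set(bipartitions(base))
        assert all(0.0 <= n.support <= 100.0
                   for n in bipartitions(t).values())

    def test_uncontradicted_half_supported_clade_near_certain(self):
        # Five taxa; 50% of columns support (A,B), the rest are constant.
        informative = ["AACCC", "GGTTT"]
        constant = ["CCCCC", "EEEEE"]
        cols = informative * 20 + constant * 20
        rows = ["".join(c[i] for c in cols) for i in range(5)]
        msa = Msa(list("ABCDE"), rows)
        t = bootstrap_support(msa, n_reps=100, seed=3)
        # the (A,B) split is canonicalized to its complement side {C,D,E}
        ab = frozenset("CDE")
        support = {k: n.support for k, n in bipartitions(t).items()}[ab]
        assert support >= 99.0


class TestRooting:
    @pytest.fixture()
    def supported_tree(self):
        rng = np.random.default_rng(7)
        tree = random_tree(6, rng)
        msa, _ = simulate.evolve_family(tree, 500, seed=7)
        return bootstrap_support(msa, n_reps=20, seed=7)

    def test_outgroup_sister_is_everything_else(self, supported_tree):
        rooted = root_by_outgroup(supported_tree, "t3")
        left, right = rooted.root.children
        out = left if left.is_leaf and left.name == "t3" else right
        rest = right if out is left else left
        assert out.name == "t3"
        assert rest.leaf_names() == supported_tree.taxa - {"t3"}

    def test_rerooting_idempotent(self, supported_tree):
        once = root_by_outgroup(supported_tree, "t2")
        twice = root_by_outgroup(once, "t2")
        assert to_newick(once) == to_newick(twice)

    def test_bipartitions_preserved_by_rooting(self, supported_tree):
        rooted = root_by_outgroup(supported_tree, "t5")
        assert compare_topologies(rooted, supported_tree) == 0

    def test_supports_carried_over(self, supported_tree):
        rooted = root_by_outgroup(supported_tree, "t1")
        before = {k: n.support for k, n in bipartitions(supported_tree).items()}
        after = {k: n.support for k, n in bipartitions(rooted).items()}
        shared = set(before) & set(after)
        assert shared and all(before[k] == after[k] for k in shared)

    def test_unknown_taxon_rejected(self, supported_tree):
        with pytest.raises(ValueError, match="not a leaf"):
            root_by_outgroup(supported_tree, "nope")


def _tree_with_supports():
    """((a,b)60,(c,d)80,e); with branch lengths 0.1 everywhere."""
    ab = Node(children=[Node("a", 0.1), Node("b", 0.1)], length=0.1, support=60.0)
    cd = Node(children=[Node("c", 0.1), Node("d", 0.1)], length=0.1, support=80.0)
    return Tree(Node(children=[ab, cd, Node("e", 0.1)]))


class TestCollapse:
    def test_cutoff_zero_unchanged(self):
        t = _tree_with_supports()
        assert to_newick(collapse_low_support(t, 0)) == to_newick(t)

    def test_cutoff_above_hundred_gives_star(self):
        t = collapse_low_support(_tree_with_supports(), 101)
        assert all(c.is_leaf for c in t.root.children)
        assert len(t.root.children) == 5

    def test_mixed_supports_contract_exactly_one_edge(self):
        t = collapse_low_support(_tree_with_supports(), 70)
        assert len(bipartitions(t)) == 1
        (key,) = bipartitions(t)
        assert key == frozenset("cd")

    def test_leaf_set_preserved(self):
        t = _tree_with_supports()
        assert collapse_low_support(t, 101).taxa == t.taxa


class TestRobinsonFoulds:
    def test_self_distance_zero(self, rng):
        t = random_tree(8, rng)
        assert compare_topologies(t, t) == 0

    def test_two_quartet_resolutions(self):
        t1 = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = read_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert compare_topologies(t1, t2) == 2

    def test_leaf_set_mismatch_rejected(self, rng):
        t1 = random_tree(5, rng)
        t2 = random_tree(6, rng)
        with pytest.raises(ValueError, match="leaf sets"):
            compare_topologies(t1, t2)

    def test_matches_dendropy_oracle_on_random_pairs(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            t1, t2 = random_tree(7, rng), random_tree(7, rng)
            assert compare_topologies(t1, t2) == dendropy_rf(t1, t2)


class TestNewick:
    def test_round_trip_preserves_structure(self):
        t = _tree_with_supports()
        back = read_newick(to_newick(t))
        assert back.taxa == t.taxa
        assert compare_topologies(back, t) == 0
        sups = {k: n.support for k, n in bipartitions(back).items()}
        assert sups[frozenset("cd")] == 80.0

    def test_branch_length_precision(self):
        t = Tree(Node(children=[Node("a", 0.123456789),
                                Node("b", 1.0), Node("c", 1.0)]))
        assert "a:0.123457" in to_newick(t)

    def test_support_table_lists_internal_edges(self):
        table = support_table(_tree_with_supports())
        # the (a,b) split is canonicalized to its side excluding taxon "a"
        assert "c,d,e\t60" in table and "c,d\t80" in table
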