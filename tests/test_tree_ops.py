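import re
from itertools import combinations

import pytest

from bioutils import tree_ops as to
from bioutils.fixtures import make_tree
from bioutils.io_formats import parse_newick, write_tree


def token_length_sum(newick):
    return sum(float(t) for t in re.findall(r":([0-9.eE+-]+)", newick))


def two_deepest_subtree_depths(tree):
    """Max root-to-tip depth within each root subtree, two largest."""
    def max_depth(node):
        if node.is_leaf:
            return node.length
        return node.length + max(max_depth(c) for c in node.children)

    depths = sorted((max_depth(c) for c in tree.root.children), reverse=True)
    return depths[0], depths[1]


class TestTotalLength:
    def test_basic(self):
        assert to.total_length(parse_newick("(A:1,B:2):0;")) == 3.0

    def test_all_zero(self):
        assert to.total_length(parse_newick("(A:0,B:0);")) == 0.0

    def test_token_sum_oracle(self):
        fixture = make_tree(21, n_leaves=50)
        assert to.total_length(fixture.tree) == \
            pytest.approx(token_length_sum(fixture.newick))


class TestMidpoint:
    def test_two_leaf(self):
        out = to.midpoint_root(parse_newick("(A:1,B:3);"))
        assert dict(to.otu_depths(out)) == {"A": 2.0, "B": 2.0}

    def test_idempotent(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        once = to.midpoint_root(tree)
        twice = to.midpoint_root(once)
        assert to.distance_map(once) == pytest.approx(to.distance_map(twice))
        d1, d2 = two_deepest_subtree_depths(twice)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_single_leaf_error(self):
        with pytest.raises(to.TreeError):
            to.midpoint_root(parse_newick("A:1;"))

    @pytest.mark.parametrize("seed", range(10))
    def test_metamorphic(self, seed):
        tree = make_tree(seed, n_leaves=30).tree
        rooted = to.midpoint_root(tree)
        before = to.distance_map(tree)
        after = to.distance_map(rooted)
        for pair, d in before.items():
            assert abs(after[pair] - d) < 1e-9
        assert to.total_length(rooted) == pytest.approx(
            to.total_length(tree), abs=1e-9)
        d1, d2 = two_deepest_subtree_depths(rooted)
        assert abs(d1 - d2) < 1e-9

    def test_max_depth_is_half_diameter(self, random_tree):
        rooted = to.midpoint_root(random_tree)
        diameter = max(to.distance_map(random_tree).values())
        max_depth = max(d for _, d in to.otu_depths(rooted))
        assert max_depth == pytest.approx(diameter / 2, abs=1e-9)


class TestOutgroupReroot:
    def test_sister_clade(self):
        out = to.reroot_outgroup(parse_newick("(A:1,(B:1,C:1):1);"), "A")
        assert len(out.root.children) == 2
        sister = next(c for c in out.root.children if c.label != "A")
        assert sorted(to.PhyloTree(sister).leaf_names()) == ["B", "C"]

    def test_unknown_otu(self):
        with pytest.raises(to.TreeError, match="nope"):
            to.reroot_outgroup(parse_newick("(A:1,B:1);"), "nope")

    def test_idempotent_topology(self, random_tree):
        once = to.reroot_outgroup(random_tree, "L3")
        twice = to.reroot_outgroup(once, "L3")
        assert to.distance_map(once) == pytest.approx(to.distance_map(twice))
        for t in (once, twice):
            leaf_kids = [c for c in t.root.children if c.label == "L3"]
            assert len(leaf_kids) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_patristic_invariant(self, seed):
        tree = make_tree(seed + 100, n_leaves=30).tree
        otu = tree.leaf_names()[seed % 30]
        rerooted = to.reroot_outgroup(tree, otu)
        before = to.distance_map(tree)
        after = to.distance_map(rerooted)
        for pair, d in before.items():
            assert abs(after[pair] - d) < 1e-9


class TestDeleteOtus:
    def test_basic(self):
        out = to.delete_otus(parse_newick("((A:1,B:1):1,C:2);"), ["C"])
        assert out.leaf_names() == ["A", "B"]
        assert to.distance_map(out)[frozenset(("A", "B"))] == 2.0

    def test_drop_two(self, random_tree):
        out = to.delete_otus(random_tree, ["L1", "L5"])
        assert set(out.leaf_names()) == \
            set(random_tree.leaf_names()) - {"L1", "L5"}

    def test_unknown_otu(self):
        with pytest.raises(to.TreeError, match="Q"):
            to.delete_otus(parse_newick("(A:1,B:1,C:1);"), ["Q"])

    def test_too_few_left(self):
        with pytest.raises(to.TreeError, match="fewer than 2"):
            to.delete_otus(parse_newick("(A:1,B:1,C:1);"), ["A", "B"])

    @pytest.mark.parametrize("seed", range(5))
    def test_surviving_distances(self, seed):
        tree = make_tree(seed + 200, n_leaves=30).tree
        names = tree.leaf_names()
        doomed = names[seed::7][:4]
        out = to.delete_otus(tree, doomed)
        before = to.distance_map(tree)
        after = to.distance_map(out)
        for pair, d in after.items():
            assert abs(before[pair] - d) < 1e-9


class TestSubset:
    def test_all_leaves_identity(self, random_tree):
        out = to.subset(random_tree, random_tree.leaf_names())
        assert to.distance_map(out) == pytest.approx(
            to.distance_map(random_tree))

    def test_two_leaves_total_length(self, random_tree):
        names = random_tree.leaf_names()[:2]
        out = to.subset(random_tree, names)
        assert to.total_length(out) == pytest.approx(
            to.distance_map(random_tree)[frozenset(names)])

    def test_internal_node_clade(self):
        tree = parse_newick("((A:1,B:1)node1:1,(C:1,D:1)node2:1);")
        out = to.subset(tree, ["node2"])
        assert sorted(out.leaf_names()) == ["C", "D"]

    def test_unknown_target(self):
        with pytest.raises(to.TreeError):
            to.subset(parse_newick("(A:1,B:1);"), ["zz"])

    @pytest.mark.parametrize("seed", range(5))
    def test_kept_distances(self, seed):
        tree = make_tree(seed + 300, n_leaves=30).tree
        keep = tree.leaf_names()[: 5 + seed]
        out = to.subset(tree, keep)
        assert sorted(out.leaf_names()) == sorted(keep)
        before = to.distance_map(tree)
        after = to.distance_map(out)
        for pair, d in after.items():
            assert abs(before[pair] - d) < 1e-9


class TestCollapse:
    def test_identity_when_all_strong(self, tree5):
        out = to.collapse_low_support(tree5, 75)
        assert write_tree(out) == write_tree(tree5)

    def test_star_when_all_weak(self, tree5):
        out = to.collapse_low_support(tree5, 101)
        assert all(c.is_leaf for c in out.root.children)
        assert sorted(out.leaf_names()) == ["A", "B", "C", "D", "E"]

    def test_strict_less_than(self, tree5):
        out = to.collapse_low_support(tree5, 90)
        supports = [n.support for n in out.nodes()
                    if not n.is_leaf and n is not out.root
                    and n.support is not None]
        assert supports and all(s >= 90 for s in supports)

    def test_depths_preserved(self, tree5):
        before = dict(to.otu_depths(tree5))
        after = dict(to.otu_depths(to.collapse_low_support(tree5, 95)))
        assert after == pytest.approx(before)

    def test_unlabeled_warned_not_collapsed(self, capsys):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        out = to.collapse_low_support(tree, 99)
        assert "unlabeled" in capsys.readouterr().err
        assert any(not n.is_leaf and n is not out.root for n in out.nodes())

    @pytest.mark.parametrize("seed", range(5))
    def test_postconditions(self, seed):
        tree = make_tree(seed + 400, n_leaves=20,
                         support_range=(50, 100)).tree
        out = to.collapse_low_support(tree, 80)
        assert sorted(out.leaf_names()) == sorted(tree.leaf_names())
        for node in out.nodes():
            if node.is_leaf or node is out.root:
                continue
            assert node.support is None or node.support >= 80


class TestDistancesAndDepths:
    def test_two_leaf_distance(self):
        names, mat = to.pairwise_distances(parse_newick("(A:1,B:2);"))
        assert mat[0][1] == 3.0

    def test_zero_diagonal_symmetry(self, random_tree):
        names, mat = to.pairwise_distances(random_tree)
        for i in range(len(names)):
            assert mat[i][i] == 0.0
            for j in range(len(names)):
                assert mat[i][j] == mat[j][i]

    def test_lca_oracle(self, random_tree):
        depths = to._node_depths(random_tree)
        leaves = random_tree.leaves()
        names, mat = to.pairwise_distances(random_tree)
        index = {n: i for i, n in enumerate(names)}
        for a, b in combinations(leaves, 2):
            lca = to._lca(a, b)
            expected = depths[a] + depths[b] - 2 * depths[lca]
            assert mat[index[a.label]][index[b.label]] == \
                pytest.approx(expected)

    def test_depths_basic(self):
        rows = dict(to.otu_depths(parse_newick("(A:1,B:2):0;")))
        assert rows == {"A": 1.0, "B": 2.0}

    def test_depth_path_sum(self, random_tree):
        depths = dict(to.otu_depths(random_tree))
        for leaf in random_tree.leaves():
            total, node = 0.0, leaf
            while node is not None:
                total += node.length
                node = node.parent
            assert depths[leaf.label] == pytest.approx(total)


class TestAscii:
    def test_leaf_lines(self):
        art = to.ascii_render(parse_newick("(A:1,B:2);"))
        assert "A" in art and "B" in art
        assert len(art.splitlines()) >= 2

    def test_all_leaves_greppable(self, random_tree):
        art = to.ascii_render(random_tree)
        for name in random_tree.leaf_names():
            assert name in art

    def test_deterministic(self, random_tree):
        assert to.ascii_render(random_tree) == to.ascii_render(random_tree)


class TestSerializationClosure:
    @pytest.mark.parametrize("seed", range(3))
    def test_ops_emit_readable_newick(self, seed):
        tree = make_tree(seed + 500, n_leaves=12).tree
        outputs = [
            to.midpoint_root(tree),
            to.reroot_outgroup(tree, tree.leaf_names()[0]),
            to.delete_otus(tree, tree.leaf_names()[:2]),
            to.subset(tree, tree.leaf_names()[2:8]),
            to.collapse_low_support(tree, 85),
        ]
        for out in outputs:
            reread = parse_newick(write_tree(out))
            assert sorted(reread.leaf_names()) == sorted(out.leaf_names())
            assert to.distance_map(reread) == pytest.approx(
                to.distance_map(out))
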