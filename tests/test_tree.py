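"""Tree core: newick I/O, bipartitions, rooting, collapsing."""

import numpy as np
import pytest

from hotrecon.tree import (
    Bipartition,
    NewickParseError,
    TreeError,
    are_compatible,
    bipartition_set,
    collapse_low_support,
    parse_newick,
    prune_to_taxa,
    root_with_outgroup,
    serialize_newick,
)
from conftest import random_binary_tree


class TestParse:
    def test_supports_and_lengths(self, quartet):
        sups = sorted(
            n.support
            for n in quartet.postorder()
            if not n.is_leaf() and n is not quartet.root
        )
        assert sups == [95, 100]
        assert quartet.leaf_labels == {"A", "B", "C", "D"}

    def test_fractional_supports_rescaled(self):
        t = parse_newick("((A,B)0.95,(C,D)1.0);")
        sups = sorted(
            n.support for n in t.postorder() if not n.is_leaf() and n is not t.root
        )
        assert sups == [95, 100]

    def test_percent_scale_forced(self):
        # a lone "1" stays 1% when the caller says the file is in percent
        t = parse_newick("(((A,B)1,C),D);", support_scale="percent")
        sups = [n.support for n in t.postorder() if n.support is not None]
        assert sups == [1]

    def test_duplicate_leaf_named_in_error(self):
        with pytest.raises(NewickParseError, match="A"):
            parse_newick("((A,B),(A,C));")

    def test_unbalanced_parentheses_position(self):
        with pytest.raises(NewickParseError, match="[Uu]nbalanced"):
            parse_newick("((A,B),(C,D);")

    def test_non_numeric_internal_labels_kept_as_names(self):
        t = parse_newick("((A,B)cladeX,(C,D)77);")
        names = [n.label for n in t.postorder() if not n.is_leaf()]
        assert "cladeX" in names

    def test_comments_and_quotes_tolerated(self):
        t = parse_newick("(('A b':1[a comment],B:1)50,C:2);")
        assert "A b" in t.leaf_labels


class TestRoundTrip:
    def test_many_random_trees(self, rng):
        """parse(serialize(t)) is isomorphic to t (supports included)."""
        for _ in range(1000):
            n = int(rng.integers(2, 65))
            labels = [f"t{i}" for i in range(n)]
            t = random_binary_tree(labels, rng)
            for node in t.postorder():
                if node is not t.root and not node.is_leaf():
                    node.support = int(rng.integers(0, 101))
                node.length = float(np.round(rng.uniform(0.01, 2.0), 4))
            t.root.length = None
            back = parse_newick(serialize_newick(t))
            assert back.leaf_labels == t.leaf_labels
            assert back.isomorphic(t, check_support=True)

    def test_polytomy_round_trip(self):
        t = parse_newick("((A,B,C)88,D);")
        back = parse_newick(serialize_newick(t))
        assert back.isomorphic(t)
        polys = [n for n in back.postorder() if len(n.children) == 3]
        assert len(polys) == 1


class TestBipartitions:
    def test_quartet(self, quartet):
        bps = bipartition_set(quartet)
        assert [str(b) for b, _ in bps] == ["A,B|C,D"]
        assert bps[0][1] in (95, 100)

    def test_caterpillar(self):
        t = parse_newick("(((( A,B),C),D),E);".replace(" ", ""))
        assert [str(b) for b, _ in bipartition_set(t)] == [
            "A,B|C,D,E",
            "A,B,C|D,E",
        ]

    def test_star_is_empty(self):
        assert bipartition_set(parse_newick("(A,B,C);")) == []

    def test_count_matches_internal_edges(self, rng):
        """Binary tree on n leaves displays n-3 non-trivial splits."""
        for _ in range(50):
            n = int(rng.integers(4, 40))
            t = random_binary_tree([f"x{i}" for i in range(n)], rng)
            assert len(bipartition_set(t)) == n - 3

    def test_compatibility_matches_brute_force(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(300):
            def rand_bp():
                k = int(rng.integers(1, len(taxa)))
                side = set(rng.choice(taxa, k, replace=False))
                return Bipartition(side, set(taxa) - side)

            b1, b2 = rand_bp(), rand_bp()
            brute = any(
                not (s1 & s2)
                for s1 in (b1.side1, b1.side2)
                for s2 in (b2.side1, b2.side2)
            )
            assert are_compatible(b1, b2) == brute
            assert are_compatible(b2, b1) == are_compatible(b1, b2)
            assert are_compatible(b1, b1)

    def test_differing_taxa_rejected(self):
        with pytest.raises(TreeError):
            are_compatible(
                Bipartition("AB", "CD"), Bipartition("AB", "CE")
            )


class TestRooting:
    def test_outgroup_rerooting(self, caterpillar):
        rooted = root_with_outgroup(caterpillar, {"A", "B"})
        top = {frozenset(c.label for c in side.children) if not side.is_leaf() else None
               for side in rooted.root.children}
        clades = rooted.clades()
        sides = {clades[c] for c in rooted.root.children}
        assert frozenset({"A", "B"}) in sides

    def test_bipartitions_invariant_under_rerooting(self, rng):
        for _ in range(25):
            t = random_binary_tree([f"t{i}" for i in range(10)], rng)
            clades = t.clades()
            node = next(
                n
                for n in t.postorder()
                if n is not t.root and 2 <= len(clades[n]) <= 8
            )
            out = clades[node]
            r = root_with_outgroup(t, out)
            assert {b for b, _ in bipartition_set(r)} == {
                b for b, _ in bipartition_set(t)
            }

    def test_whole_tree_outgroup_rejected(self, quartet):
        with pytest.raises(TreeError):
            root_with_outgroup(quartet, {"A", "B", "C", "D"})

    def test_non_clade_outgroup_names_taxa(self, caterpillar):
        with pytest.raises(TreeError, match="A"):
            root_with_outgroup(caterpillar, {"A", "C"})


class TestCollapse:
    def test_all_strong_unchanged(self):
        t = parse_newick("(((A,B)100,C)100,(D,E)100);")
        assert collapse_low_support(t, 70).isomorphic(t)

    def test_weak_edge_collapsed(self):
        t = parse_newick("(((A,B)40,C)90,(D,E)85);")
        c = collapse_low_support(t, 70)
        assert c.leaf_labels == t.leaf_labels
        polys = [n for n in c.postorder() if len(n.children) == 3]
        assert len(polys) == 1

    def test_boundary_support_retained(self):
        t = parse_newick("(((A,B)70,C)90,(D,E)85);")
        assert collapse_low_support(t, 70).isomorphic(t)

    def test_unsupported_edges_never_collapsed(self):
        t = parse_newick("(((A,B),C)90,(D,E)85);")
        assert collapse_low_support(t, 70).isomorphic(t, check_support=False)

    def test_threshold_range_checked(self, quartet):
        with pytest.raises(TreeError):
            collapse_low_support(quartet, 101)

    def test_strong_edges_survive_random(self, rng):
        for _ in range(25):
            t = random_binary_tree([f"t{i}" for i in range(12)], rng)
            for node in t.postorder():
                if node is not t.root and not node.is_leaf():
                    node.support = int(rng.integers(0, 101))
            strong = {
                bp
                for bp, sup in bipartition_set(t)
                if sup is not None and sup >= 70
            }
            collapsed = collapse_low_support(t, 70)
            assert collapsed.leaf_labels == t.leaf_labels
            assert strong <= {bp for bp, _ in bipartition_set(collapsed)}


class TestPrune:
    def test_prune_keeps_induced_topology(self, caterpillar):
        p = prune_to_taxa(caterpillar, {"A", "B", "C", "E"})
        assert p.leaf_labels == {"A", "B", "C", "E"}
        assert [str(b) for b, _ in bipartition_set(p)] == ["A,B|C,E"]

    def test_missing_taxon_rejected(self, quartet):
        with pytest.raises(TreeError):
            prune_to_taxa(quartet, {"A", "Z"})
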