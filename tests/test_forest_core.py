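"""Forest data structure: Newick I/O, splits, equivalence, combinatorics."""

import math

import numpy as np
import pytest

from waldspace.forest_core import (
    Forest,
    Split,
    Topology,
    canonicalize,
    enumerate_topologies,
    forests_equivalent,
    leaf_distance_matrix,
    length_to_weight,
    length_weight_convert,
    nni_neighbors,
    parse_newick,
    split_matrix,
    tree_from_splits,
    weight_to_length,
    write_newick,
)
from waldspace.cli_fixtures import random_tree
from waldspace.two_state_model import character_pmf


class TestNewick:
    def test_parse_f1_structure(self):
        f = parse_newick("((1:0.1,2:0.1):0.3,3:0.1,(4:0.1,5:0.1):0.2);")
        assert f.n_leaves == 5
        assert len(f.edges()) == 7
        internal = sorted(f.edge_length(e) for e in f.edges()
                          if not f.split_of_edge(e).is_pendant)
        assert internal == [0.2, 0.3]

    def test_two_leaf_degree_two_suppression(self):
        f = parse_newick("(1:0.5,2:0.5);")
        (e,) = f.edges()
        assert f.edge_length(e) == pytest.approx(1.0)
        assert write_newick(f) == "(1:0.5,2:0.5);"

    def test_isolated_leaf_forest(self):
        f = parse_newick("1;\n2;\n3;")
        assert f.n_components == 3
        assert write_newick(f).splitlines() == ["1;", "2;", "3;"]

    @pytest.mark.parametrize("newick", [
        "((1:0.1,2:0.1):0.3,3:0.1,(4:0.1,5:0.1):0.2);",
        "(1:0.2,2:0.4,3:0.1);",
        "((1:0.1,2:0.1):inf,3:0.1,(4:0.1,5:0.1):0.2);",
    ])
    def test_round_trip(self, newick):
        f = parse_newick(newick)
        text = write_newick(f)
        again = parse_newick(text)
        assert write_newick(again) == text  # write . parse . write = write
        assert forests_equivalent(f, again)

    def test_random_tree_round_trips(self, rng):
        # serialization keeps 12 significant digits
        for _ in range(20):
            t = random_tree(6, rng=rng)
            assert forests_equivalent(t, parse_newick(write_newick(t)),
                                      tol=1e-9)

    def test_duplicate_label_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("(1:0.1,1:0.1,2:0.2);")

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("(1:-0.1,2:0.1,3:0.2);")

    def test_zero_pendant_rejected(self):
        with pytest.raises(ValueError, match="pendant"):
            parse_newick("((1:0.0,2:0.0):0.3,3:0.1,4:0.1);")

    def test_coincident_leaves_rejected(self):
        # a pair of leaves joined only by weight-zero edges is invalid
        import networkx as nx

        g = nx.Graph()
        g.add_edge(1, "a", length=0.0)
        g.add_edge(2, "a", length=0.0)
        g.add_edge(3, "a", length=0.1)
        with pytest.raises(ValueError, match="coincident leaves 1 and 2"):
            Forest(g, n_leaves=3, allow_zero_pendant=True)


class TestDistancesAndSplits:
    def test_f1_path_lengths(self):
        f = parse_newick("((1:0.1,2:0.1):0.1,3:0.1,(4:0.1,5:0.1):0.1);")
        d = leaf_distance_matrix(f)
        assert d[0, 1] == pytest.approx(0.2)
        assert d[0, 3] == pytest.approx(0.4)
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)

    def test_cross_component_infinite(self):
        f = parse_newick("(1:0.2,2:0.3);\n(3:0.1,4:0.4);")
        d = leaf_distance_matrix(f)
        assert math.isinf(d[0, 2]) and math.isinf(d[1, 3])
        assert d[0, 1] == pytest.approx(0.5)

    def test_pendant_split_matrix_three_leaf_star(self):
        f = parse_newick("(1:0.1,2:0.1,3:0.1);")
        e = next(e for e in f.edges() if 1 in e)
        sigma = split_matrix(f, e)
        expect = np.zeros((3, 3), dtype=int)
        expect[0, 1] = expect[1, 0] = expect[0, 2] = expect[2, 0] = 1
        assert np.array_equal(sigma, expect)

    def test_split_matrices_reconstruct_distances(self, caterpillar5):
        total = sum(caterpillar5.edge_length(e) * split_matrix(caterpillar5, e)
                    for e in caterpillar5.edges())
        assert np.allclose(total, leaf_distance_matrix(caterpillar5))

    def test_four_point_condition(self, rng):
        # tree metrics: for each leaf quartet the two largest of the three
        # pairings of sums must be equal
        for _ in range(10):
            t = random_tree(6, rng=rng)
            d = leaf_distance_matrix(t)
            from itertools import combinations
            for i, j, k, l in combinations(range(6), 4):
                sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l],
                               d[i, l] + d[j, k]])
                assert sums[2] - sums[1] < 1e-9


class TestCanonicalize:
    def test_zero_internal_edge_contraction(self):
        # a zero-length internal edge separating two degree-3 vertices is
        # removed, yielding a degree-4 vertex
        f = parse_newick("((1:0.1,2:0.1):0.0,3:0.1,4:0.1);",)
        c = canonicalize(f)
        assert len(c.edges()) == 4
        star = parse_newick("(1:0.1,2:0.1,3:0.1,4:0.1);")
        assert forests_equivalent(f, star)

    def test_infinite_pendant_edge_removal(self):
        # pendant edge at weight 1 removed; flanking edges merge with
        # lam_A + lam_B - lam_A lam_B, i.e. lengths add
        f = parse_newick("((1:0.2,2:0.3):0.25,3:inf,(4:0.1,5:0.4):0.15);")
        c = canonicalize(f)
        assert c.n_components == 2
        comps = {frozenset(v for v in comp if isinstance(v, int))
                 for comp in c.components()}
        assert frozenset({3}) in comps
        # merged internal edge has length 0.25 + 0.15
        merged = parse_newick("((1:0.2,2:0.3):0.4,(4:0.1,5:0.4));\n3;")
        assert forests_equivalent(f, merged)

    def test_idempotent(self, rng):
        for _ in range(10):
            t = random_tree(5, rng=rng)
            t.graph.edges[t.edge_order()[5]]["length"] = 0.0
            c1 = canonicalize(t)
            c2 = canonicalize(c1)
            assert forests_equivalent(c1, c2)

    def test_equivalence_matches_character_pmf_oracle(self, rng):
        # Markov-model oracle: forests are equivalent iff their induced
        # character distributions coincide
        cases = []
        f = parse_newick("((1:0.1,2:0.1):0.0,3:0.1,4:0.1);")
        cases.append((f, parse_newick("(1:0.1,2:0.1,3:0.1,4:0.1);")))
        g = parse_newick("((1:0.2,2:0.3):0.25,3:inf,(4:0.1,5:0.4):0.15);")
        cases.append((g, parse_newick("((1:0.2,2:0.3):0.4,(4:0.1,5:0.4));\n3;")))
        cases.append((random_tree(5, rng=rng), random_tree(5, rng=rng)))
        for a, b in cases:
            pmf_equal = np.allclose(character_pmf(a), character_pmf(b),
                                    atol=1e-12)
            assert forests_equivalent(a, b) == pmf_equal


class TestTopologyCombinatorics:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
    def test_enumeration_counts(self, n, count):
        topos = enumerate_topologies(n)
        assert len(topos) == count
        assert len({t.sort_key() for t in topos}) == count

    def test_resolved_split_counts(self):
        for topo in enumerate_topologies(5):
            assert topo.resolved
            assert len(topo.splits) == 7
            assert sum(s.is_pendant for s in topo.splits) == 5
            assert len(topo.internal_splits) == 2

    def test_nni_three_orthants_at_boundary(self):
        topo = enumerate_topologies(5)[0]
        s = next(iter(topo.internal_splits))
        n1, n2 = nni_neighbors(topo, s)
        keys = {topo.sort_key(), n1.sort_key(), n2.sort_key()}
        assert len(keys) == 3
        for nb in (n1, n2):
            assert nb.splits - topo.splits != set()
            assert len(nb.splits & topo.splits) == 6  # all but the contracted

    def test_nni_graph_connects_all_topologies(self):
        seen = set()
        start = enumerate_topologies(5)[0]
        frontier = [start]
        seen.add(start.sort_key())
        while frontier:
            topo = frontier.pop()
            for s in topo.internal_splits:
                for nb in nni_neighbors(topo, s):
                    if nb.sort_key() not in seen:
                        seen.add(nb.sort_key())
                        frontier.append(nb)
        assert len(seen) == 15

    def test_tree_from_splits_reconstructs(self, caterpillar5):
        topo = caterpillar5.topology()
        lengths = {caterpillar5.split_of_edge(e): caterpillar5.edge_length(e)
                   for e in caterpillar5.edges()}
        rebuilt = tree_from_splits(lengths)
        assert forests_equivalent(caterpillar5, rebuilt)


class TestLengthWeight:
    def test_limits(self):
        assert length_to_weight(0.0) == 0.0
        assert length_to_weight(math.inf) == 1.0
        assert weight_to_length(1.0) == math.inf
        assert length_to_weight(math.log(2)) == pytest.approx(0.5)

    def test_round_trip_grid(self):
        grid = np.linspace(0.0, 10.0, 100)
        back = [weight_to_length(length_to_weight(l)) for l in grid]
        assert np.allclose(back, grid, atol=1e-12)

    def test_direction_dispatch(self):
        assert length_weight_convert(math.log(2), "to_weight") == pytest.approx(0.5)
        assert length_weight_convert(0.5, "to_length") == pytest.approx(math.log(2))
        with pytest.raises(ValueError):
            length_weight_convert(1.5, "to_length")
        with pytest.raises(ValueError):
            length_weight_convert(-0.1, "to_weight")
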