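"""Quartet distances, bipartition congruence, Cailliez correction, MDS/NMDS."""

import itertools
import random

import dendropy
import numpy as np
import pytest

from colchain.simulate import perturb_tree_sample, sample_timetree
from colchain.treespace import (
    DistanceMatrix,
    TreeSpaceError,
    cailliez,
    classical_mds,
    congruence,
    is_euclidean,
    mean_distance_to_reference,
    nmds,
    pairwise_quartet_matrix,
    parse_tree,
    prune_to_common,
    quartet_distance,
)


def _random_binary_tree(n_leaves, seed):
    rng = random.Random(seed)
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
    return dendropy.simulate.treesim.pure_kingman_tree(tns, pop_size=1, rng=rng)


def _oracle_quartet_state(tree, quartet):
    """Induced 4-leaf topology read off the extracted subtree's structure.

    Independent of the path-distance method: extracts the induced subtree
    with dendropy and asks which pair forms a cherry (a node whose leaf set
    is exactly that pair).  Returns a frozenset pairing or None (star).
    """
    sub = tree.extract_tree_with_taxa_labels(list(quartet))
    cherries = []
    for node in sub.preorder_internal_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(leaves) == 2:
            cherries.append(leaves)
    for pair in map(frozenset, itertools.combinations(quartet, 2)):
        rest = frozenset(quartet) - pair
        if pair in cherries or rest in cherries:
            return frozenset({pair, rest})
    return None


def oracle_quartet_distance(tree_a, tree_b):
    labels = sorted(lf.taxon.label for lf in tree_a.leaf_node_iter())
    diff = 0
    for quartet in itertools.combinations(labels, 4):
        if _oracle_quartet_state(tree_a, quartet) != _oracle_quartet_state(tree_b, quartet):
            diff += 1
    return diff


class TestPruneToCommon:
    def test_identical_trees_unchanged(self):
        tns = dendropy.TaxonNamespace()
        t1 = parse_tree("((a,b),(c,d));", tns)
        t2 = parse_tree("((a,b),(c,d));", tns)
        pruned = prune_to_common([t1, t2])
        assert quartet_distance(pruned[0], t1) == 0
        assert quartet_distance(pruned[1], t2) == 0

    def test_pruned_topology_matches_induced_subtree(self):
        t5 = parse_tree("((((a:1,b:1):1,c:2):1,d:3):1,e:4);")
        t4 = parse_tree("(((a:1,b:1):1,c:2):1,d:3);")
        pruned = prune_to_common([t5, t4])
        # brute-force induced subtree of t5 on {a,b,c,d} is the caterpillar t4
        assert quartet_distance(pruned[0], pruned[1]) == 0
        # branch lengths along suppressed paths are summed
        leaf_d = next(lf for lf in pruned[0].leaf_node_iter() if lf.taxon.label == "d")
        assert leaf_d.edge.length == pytest.approx(3.0)

    def test_disjoint_leaf_sets_error(self):
        with pytest.raises(TreeSpaceError):
            prune_to_common([parse_tree("(a,(b,c));"), parse_tree("(x,(y,z));")])


class TestCongruence:
    def test_identical_binary_trees_fully_congruent(self):
        tree = _random_binary_tree(28, seed=1)
        newick = tree.as_string(schema="newick")
        result = congruence(parse_tree(newick), parse_tree(newick))
        assert result["a_in_b"]["incongruent_nodes"] == 0
        assert result["a_in_b"]["fraction_congruent"] == 1.0
        assert result["a_in_b"]["total_nodes"] == 25  # unrooted binary: n-3

    def test_single_nni_breaks_exactly_one_bipartition(self):
        # caterpillar vs its NNI neighbour: bipartition sets enumerated by
        # hand are {ab|cde, abc|de} vs {ac|bde, abc|de}
        a = parse_tree("((((a,b),c),d),e);")
        b = parse_tree("((((a,c),b),d),e);")
        result = congruence(a, b)
        assert result["shared_nodes"] == 1
        assert result["a_in_b"]["incongruent_nodes"] == 1
        assert result["b_in_a"]["incongruent_nodes"] == 1

    def test_star_tree_shares_nothing_with_binary(self):
        star = parse_tree("(a,b,c,d,e);")
        binary = parse_tree("(((a,b),c),(d,e));")
        result = congruence(star, binary)
        assert result["shared_nodes"] == 0
        assert result["a_in_b"]["total_nodes"] == 0

    def test_congruence_decreases_with_accumulating_nni(self):
        base = _random_binary_tree(20, seed=3)
        few = perturb_tree_sample(base, 8, 1, seed=5)
        many = perturb_tree_sample(base, 8, 8, seed=5)

        def mean_frac(sample):
            vals = []
            for t in sample:
                r = congruence(base, t)
                vals.append(r["a_in_b"]["fraction_congruent"])
            return np.mean(vals)

        assert mean_frac(few) > mean_frac(many)


class TestQuartetDistance:
    def test_identical_trees_distance_zero(self):
        t = _random_binary_tree(10, seed=2)
        s = t.as_string(schema="newick")
        assert quartet_distance(parse_tree(s), parse_tree(s)) == 0

    def test_two_resolved_four_leaf_topologies_differ_by_one(self):
        assert quartet_distance(parse_tree("((a,b),(c,d));"),
                                parse_tree("((a,c),(b,d));")) == 1

    def test_unresolved_policy(self):
        star = parse_tree("(a,b,c,d);")
        resolved = parse_tree("((a,b),(c,d));")
        assert quartet_distance(star, resolved, "differ") == 1
        assert quartet_distance(star, resolved, "ignore") == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_on_random_trees(self, seed):
        rng = random.Random(seed)
        n = rng.randint(6, 9)
        a = _random_binary_tree(n, seed=100 + seed)
        b = _random_binary_tree(n, seed=200 + seed)
        d = quartet_distance(a, b)
        assert d == oracle_quartet_distance(a, b)
        assert d == quartet_distance(b, a)  # symmetry
        assert 0 <= d <= len(list(itertools.combinations(range(n), 4)))

    def test_invariant_under_joint_leaf_relabelling(self):
        a = _random_binary_tree(8, seed=9)
        b = _random_binary_tree(8, seed=10)
        d1 = quartet_distance(a, b)
        mapping = {f"t{i}": f"x{(i * 3) % 8}" for i in range(8)}
        def relabel(t):
            s = t.as_string(schema="newick")
            for old, new in mapping.items():
                s = s.replace(old + ":", new + ":")
            return parse_tree(s)
        assert quartet_distance(relabel(a), relabel(b)) == d1

    def test_fewer_than_four_leaves_rejected(self):
        with pytest.raises(TreeSpaceError):
            quartet_distance(parse_tree("(a,(b,c));"), parse_tree("((a,b),c);"))


class TestPairwiseMatrix:
    def test_repeated_tree_gives_zero_matrix_and_duplicate_count(self):
        t = _random_binary_tree(8, seed=4)
        trees = [parse_tree(t.as_string(schema="newick")) for _ in range(5)]
        matrix, duplicates = pairwise_quartet_matrix(trees)
        assert np.all(matrix.values == 0)
        assert list(duplicates) == [5] * 5

    def test_entries_match_individual_calls_and_reference_mean(self):
        trees = [_random_binary_tree(8, seed=s) for s in (21, 22, 23)]
        trees = [parse_tree(t.as_string(schema="newick")) for t in trees]
        matrix, _ = pairwise_quartet_matrix(trees, labels=["x", "y", "ref"])
        for i, j in itertools.combinations(range(3), 2):
            assert matrix.values[i, j] == quartet_distance(trees[i], trees[j])
        expected = (matrix.values[0, 2] + matrix.values[1, 2]) / 2
        assert mean_distance_to_reference(matrix, "ref") == expected


class TestCailliez:
    def test_collinear_points_already_euclidean(self):
        D = DistanceMatrix(list("abc"), np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        corrected, c = cailliez(D)
        assert c == 0.0
        assert corrected.is_euclidean == "yes"
        assert np.array_equal(corrected.values, D.values)

    @pytest.mark.parametrize("seed", range(4))
    def test_constant_matches_spectral_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        V = rng.uniform(1, 2, size=(n, n))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        V[0, 1] = V[1, 0] = 6.0  # violate Euclidean embeddability
        assert not is_euclidean(V)
        D = DistanceMatrix([str(i) for i in range(n)], V)
        _, c = cailliez(D)

        def euclid(cc):  # oracle: eigenvalues of the double-centred matrix
            W = V + cc * (1 - np.eye(n))
            J = np.eye(n) - np.ones((n, n)) / n
            eig = np.linalg.eigvalsh(-0.5 * J @ (W**2) @ J)
            return eig.min() >= -1e-9 * max(1.0, eig.max())

        lo, hi = 0.0, 50.0
        for _ in range(60):  # bisection scan for the smallest Euclidean constant
            mid = (lo + hi) / 2
            lo, hi = (lo, mid) if euclid(mid) else (mid, hi)
        assert c == pytest.approx(hi, abs=1e-6)

    def test_correction_is_idempotent(self):
        V = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 3], [1, 1, 3, 0]], float)
        corrected, c = cailliez(DistanceMatrix(list("abcd"), V))
        assert c > 0
        _, c2 = cailliez(corrected)
        assert c2 == 0.0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(TreeSpaceError):
            DistanceMatrix(list("ab"), np.array([[0, 1], [2, 0]], float))


class TestClassicalMds:
    def test_recovers_planar_point_distances_exactly(self):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        V = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = classical_mds(DistanceMatrix([str(i) for i in range(5)], V), k=2)
        rec = np.sqrt(((emb.coordinates[:, None] - emb.coordinates[None]) ** 2).sum(-1))
        assert np.allclose(rec, V, atol=1e-10)

    def test_variance_fractions_bounded_and_non_increasing(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        V = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = classical_mds(DistanceMatrix([str(i) for i in range(6)], V), k=3)
        vf = emb.variance_explained
        assert vf.sum() <= 1 + 1e-12
        assert np.all(np.diff(vf) <= 1e-12)
        assert np.all((0 <= vf) & (vf <= 1))

    def test_collinear_points_have_negligible_second_axis(self):
        V = np.abs(np.subtract.outer([0.0, 1.0, 2.0, 3.5], [0.0, 1.0, 2.0, 3.5]))
        emb = classical_mds(DistanceMatrix(list("abcd"), V), k=1)
        assert emb.eigenvalues[1] == pytest.approx(0, abs=1e-9)

    def test_k_beyond_positive_spectrum_rejected(self):
        V = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        with pytest.raises(TreeSpaceError):
            classical_mds(DistanceMatrix(list("abc"), V), k=3)


@pytest.fixture(scope="module")
def planar():
    pts = np.random.default_rng(2).normal(size=(7, 2))
    V = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix([str(i) for i in range(7)], V)


class TestNmds:
    def test_rank_consistent_input_reaches_near_zero_stress(self, planar):
        emb = nmds(planar, k=2, seed=0, restarts=4)
        assert emb.stress < 1e-4

    def test_same_seed_same_embedding(self, planar):
        e1 = nmds(planar, k=2, seed=3, restarts=3)
        e2 = nmds(planar, k=2, seed=3, restarts=3)
        assert np.array_equal(e1.coordinates, e2.coordinates)
        assert e1.stress == e2.stress

    def test_stress_trace_never_increases(self, planar):
        emb = nmds(planar, k=2, seed=1, restarts=2)
        trace = np.array(emb.stress_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        assert 0 <= emb.stress <= 1
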