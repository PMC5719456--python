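import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from firetrace.align import Alignment
from firetrace.phylogeny import (neighbor_joining, p_distance_matrix,
                                 p_distance_pair, read_newick, rf_distance,
                                 write_newick)
from firetrace.simulate import random_tree


def path_distances(tree: TreeNode, labels) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix by summation along the tree."""
    tips = {t.name: t for t in tree.tips()}
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            d[i, j] = d[j, i] = tips[a].distance(tips[b])
    return DistanceMatrix(d, ids=list(labels))


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(records=[("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert p_distance_matrix(aln)["a", "b"] == 0.0

    def test_one_difference_in_four(self):
        aln = Alignment(records=[("a", "ACGT"), ("b", "ACGA")])
        assert p_distance_matrix(aln)["a", "b"] == 0.25

    def test_pairwise_deletion_of_gaps_and_ns(self):
        # gap and N columns drop for the pair; remaining 4 sites agree
        diffs, comparable = p_distance_pair("AC-GTN", "ACCGTA")
        assert (diffs, comparable) == (0, 4)

    def test_matches_bruteforce_column_counter(self, rng):
        alphabet = list("ACGT-N")
        for _ in range(50):
            n = int(rng.integers(10, 60))
            a = "".join(rng.choice(alphabet, size=n))
            b = "".join(rng.choice(alphabet, size=n))
            diffs = comparable = 0
            for x, y in zip(a, b):
                if x in "ACGT" and y in "ACGT":
                    comparable += 1
                    diffs += x != y
            if comparable == 0:
                with pytest.raises(ValueError):
                    p_distance_pair and p_distance_matrix(
                        Alignment(records=[("a", a), ("b", b)]))
            else:
                assert p_distance_pair(a, b) == (diffs, comparable)

    def test_zero_comparable_sites_names_pair(self):
        aln = Alignment(records=[("left", "AC--"), ("right", "--GT"), ("c", "ACGT")])
        with pytest.raises(ValueError, match="'left'.*'right'"):
            p_distance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]]),
                           ids=["A", "B", "C"])
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["C"] == pytest.approx((0.4 + 0.5 - 0.3) / 2)

    def test_additive_four_taxon_recovery(self):
        # distances generated by path summation on ((A:1,B:2):1,(C:3,D:4)),
        # scaled into the p-distance range
        gen = read_newick("((A:1,B:2):1,(C:3,D:4):1);")
        for node in gen.traverse():
            if node.length is not None:
                node.length /= 20.0
        labels = ["A", "B", "C", "D"]
        dm = path_distances(gen, labels)
        tree = neighbor_joining(dm)
        assert rf_distance(tree, gen) == 0
        recovered = path_distances(tree, labels)
        assert np.allclose(recovered.data, dm.data, atol=1e-12)

    def test_consistency_on_random_additive_inputs(self):
        for seed in range(12):
            n = 4 + seed % 5  # 4..8 taxa
            gen = random_tree(n, rng_seed=seed, branch_length=0.06)
            labels = sorted(t.name for t in gen.tips())
            dm = path_distances(gen, labels)
            tree = neighbor_joining(dm)
            assert rf_distance(tree, gen) == 0
            recovered = path_distances(tree, labels)
            assert np.abs(recovered.data - dm.data).max() < 1e-9

    def test_agrees_with_reference_nj_topology(self, rng):
        # independent cross-check against scikit-bio's NJ on noisy distances
        from skbio.tree import nj as skbio_nj

        n = 7
        gen = random_tree(n, rng_seed=99, branch_length=0.08)
        labels = sorted(t.name for t in gen.tips())
        d = path_distances(gen, labels).data.copy()
        noise = rng.normal(0, 0.002, size=d.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dm = DistanceMatrix(np.abs(d + noise), ids=labels)
        assert rf_distance(neighbor_joining(dm), skbio_nj(dm)) == 0

    def test_invalid_matrices_rejected(self):
        class FakeDM:
            ids = ["a", "b", "c"]
            data = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])

        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(FakeDM())

        class NegDM:
            ids = ["a", "b", "c"]
            data = np.array([[0, -1, 2], [-1, 0, 3], [2, 3, 0]])

        with pytest.raises(ValueError, match="non-negative"):
            neighbor_joining(NegDM())

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)

    def test_branch_lengths_never_negative(self, rng):
        # matrices violating additivity can produce negative two-point
        # estimates; they must be clamped with the pair total preserved
        for seed in range(5):
            r = np.random.default_rng(seed)
            d = r.uniform(0.01, 0.4, size=(6, 6))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = neighbor_joining(DistanceMatrix(d, ids=list("ABCDEF")))
            for node in tree.traverse(include_self=False):
                assert node.length >= 0


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies by stepwise leaf insertion (15 for n=5)."""
    base = TreeNode.read(
        iter([f"({labels[0]}:1,{labels[1]}:1,{labels[2]}:1);"]))
    trees = [base]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            edges = [n for n in t.traverse(include_self=False)]
            for k in range(len(edges)):
                t2 = t.copy()
                edges2 = [n for n in t2.traverse(include_self=False)]
                target = edges2[k]
                parent = target.parent
                newint = TreeNode(length=1.0)
                parent.remove(target)
                target.length = 1.0
                newint.append(target)
                newint.append(TreeNode(name=label, length=1.0))
                parent.append(newint)
                nxt.append(t2)
        trees = nxt
    return trees


def least_squares_fit(topology: TreeNode, dm: DistanceMatrix) -> float:
    """OLS branch lengths for a fixed topology; returns the residual SS."""
    edges = [n for n in topology.traverse(include_self=False)]
    labels = list(dm.ids)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    tips = {t.name: t for t in topology.tips()}
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        a, b = tips[labels[i]], tips[labels[j]]
        ancestors_a = [a] + list(a.ancestors())
        ancestors_b = [b] + list(b.ancestors())
        onpath = set(map(id, ancestors_a)) ^ set(map(id, ancestors_b))
        for col, e in enumerate(edges):
            if id(e) in onpath:
                A[row, col] = 1.0
        y[row] = dm[labels[i], labels[j]]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


class TestNJvsLeastSquaresOracle:
    def test_nj_finds_least_squares_topology_five_taxa(self):
        labels = list("ABCDE")
        topologies = enumerate_unrooted_topologies(labels)
        assert len(topologies) == 15
        for seed in range(5):
            gen = random_tree(5, rng_seed=seed + 300, branch_length=0.07,
                              prefix="")
            for i, tip in enumerate(sorted(gen.tips(), key=lambda t: t.name)):
                tip.name = labels[i]
            dm = path_distances(gen, labels)
            fits = [least_squares_fit(t, dm) for t in topologies]
            best = topologies[int(np.argmin(fits))]
            assert rf_distance(neighbor_joining(dm), best) == 0


class TestNewick:
    def test_three_leaf_form(self):
        dm = DistanceMatrix(np.array([[0, .3, .4], [.3, 0, .5], [.4, .5, 0]]),
                            ids=["A", "B", "C"])
        text = write_newick(neighbor_joining(dm))
        assert text.strip().startswith("(") and text.strip().endswith(";")
        assert "A:0.1" in text

    def test_round_trip_preserves_topology_and_lengths(self):
        for seed in range(5):
            tree = random_tree(6, rng_seed=seed)
            back = read_newick(write_newick(tree))
            assert rf_distance(tree, back) == 0
            orig = sorted((t.name, round(t.length, 6)) for t in tree.tips())
            got = sorted((t.name, round(t.length, 6)) for t in back.tips())
            assert orig == got

    def test_six_significant_digits(self):
        tree = read_newick("(A:0.123456789,B:0.2,C:0.3);")
        assert "0.123457" in write_newick(tree)

    def test_labels_with_spaces_quoted(self):
        tree = read_newick("('my leaf':0.1,B:0.2,C:0.3);")
        text = write_newick(tree)
        assert "'my leaf'" in text
        back = read_newick(text)
        assert {t.name for t in back.tips()} == {"my leaf", "B", "C"}

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            read_newick("(A:0.1,B:0.2")

    def test_rf_distance_detects_topology_change(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        assert rf_distance(t1, t2) > 0
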