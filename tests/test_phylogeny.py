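"""Distances, neighbor joining, Newick I/O, subtree extraction."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from evorate.errors import (
    LabelMismatchError,
    QueryOutsideSubtreeError,
    TooFewHomologuesError,
)
from evorate.phylogeny import (
    DISTANCE_CAP,
    DistanceMatrix,
    build_nj,
    extract_subtree,
    jukes_cantor_distance,
    pairwise_distances,
    poisson_distance,
    read_newick,
    tree_to_newick,
    validate_tree_against_alignment,
    write_newick,
)
from evorate.simulate import random_tree

from conftest import make_alignment


def path_distance_matrix(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[frozenset((a.label, b.label))] = pdm.distance(a, b)
    return out


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=tree_to_newick(t1), schema="newick", taxon_namespace=ns)
    b = dendropy.Tree.get(data=tree_to_newick(t2), schema="newick", taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b, is_bipartitions_updated=True) == 0


class TestDistanceCorrections:
    def test_identical_sequences_zero(self):
        aln = make_alignment({"a": "MKLVMKLV", "b": "MKLVMKLV"}, "a")
        D = pairwise_distances(aln)
        assert D.value("a", "b") == 0.0

    def test_jukes_cantor_closed_form(self):
        # p = 0.3 -> -(3/4) ln(1 - 0.4) = 0.383119...
        assert jukes_cantor_distance(0.3) == pytest.approx(
            -0.75 * math.log(0.6), abs=1e-12
        )
        aln = make_alignment(
            {"a": "ACGTACGTAC", "b": "ACGTACGGTA"[:7] + "TAC"}, "a", "nucleotide"
        )
        # craft exactly 3 mismatches over 10 shared columns
        aln = make_alignment(
            {"a": "ACGTACGTAC", "b": "ACGTACGCGA"}, "a", "nucleotide"
        )
        D = pairwise_distances(aln)
        assert D.value("a", "b") == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)

    def test_poisson_cap(self):
        p_sat = 1.0 - math.exp(-DISTANCE_CAP)
        assert poisson_distance(p_sat) == DISTANCE_CAP
        assert poisson_distance(0.9999999) == DISTANCE_CAP

    def test_monotone_in_p(self):
        ps = np.linspace(0.0, 0.7, 30)
        dp = [poisson_distance(p) for p in ps]
        dj = [jukes_cantor_distance(p) for p in ps]
        assert all(x < y for x, y in zip(dp, dp[1:]))
        assert all(x < y for x, y in zip(dj, dj[1:]))

    def test_gaps_excluded_pairwise(self):
        # b/c share only 4 columns, 1 mismatch -> p = 0.25
        aln = make_alignment(
            {"a": "MKLVWDES", "b": "MKLV--ES", "c": "MKIV--ES"}, "a"
        )
        D = pairwise_distances(aln)
        assert D.value("b", "c") == pytest.approx(-math.log(1 - 1 / 6), abs=1e-12)

    def test_no_shared_columns_gets_cap(self):
        aln = make_alignment({"a": "MKLV----", "b": "----WDES"}, "a")
        D = pairwise_distances(aln)
        assert D.value("a", "b") == DISTANCE_CAP


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        D = DistanceMatrix(("A", "B"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = build_nj(D)
        dists = path_distance_matrix(tree)
        assert dists[frozenset(("A", "B"))] == pytest.approx(3.0)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.5)

    def test_three_taxa_hand_computed(self):
        # AB:2 AC:4 BC:4 -> branch lengths A:1, B:1, C:3 around one hub
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = build_nj(DistanceMatrix(("A", "B", "C"), d))
        dists = path_distance_matrix(tree)
        assert dists[frozenset(("A", "B"))] == pytest.approx(2.0)
        assert dists[frozenset(("A", "C"))] == pytest.approx(4.0)
        assert dists[frozenset(("B", "C"))] == pytest.approx(4.0)

    def test_four_taxon_additive_recovered_exactly(self):
        # tree ((A:1,B:2):1,C:3,D:4): additive distances
        names = ("A", "B", "C", "D")
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = build_nj(DistanceMatrix(names, d))
        dists = path_distance_matrix(tree)
        for i, a in enumerate(names):
            for j in range(i + 1, 4):
                assert dists[frozenset((a, names[j]))] == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_negative_branch_lengths_clamped(self):
        d = np.array(
            [[0, 0.1, 0.4, 0.5], [0.1, 0, 0.45, 0.55], [0.4, 0.45, 0, 0.05], [0.5, 0.55, 0.05, 0]]
        )
        tree = build_nj(DistanceMatrix(("A", "B", "C", "D"), d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_additive_matrices_from_random_trees(self, seed):
        """NJ on exactly additive matrices reproduces the generating
        topology (cross-checked against dendropy's independent NJ)."""
        true_tree = random_tree(7, scale=0.3, seed=seed)
        taxa = sorted(lf.taxon.label for lf in true_tree.leaf_node_iter())
        dists = path_distance_matrix(true_tree)
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = dists[frozenset((taxa[i], taxa[j]))]
        mine = build_nj(DistanceMatrix(tuple(taxa), d))
        assert same_topology(mine, true_tree)
        # independent oracle: dendropy's own NJ implementation
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_csv_of(taxa, d), delimiter=","
        )
        oracle = pdm.nj_tree()
        assert same_topology(mine, oracle)


def _csv_of(taxa, d):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(taxa) + "\n")
    for i, t in enumerate(taxa):
        buf.write(t + "," + ",".join(f"{x:.10f}" for x in d[i]) + "\n")
    buf.seek(0)
    return buf


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1.0,B:1.0);\n")
        tree = read_newick(p)
        out = tmp_path / "o.nwk"
        write_newick(tree, out)
        tree2 = read_newick(out)
        assert same_topology(tree, tree2)
        assert path_distance_matrix(tree) == path_distance_matrix(tree2)

    def test_quoted_labels_with_spaces(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("('taxon one':1.0,'taxon two':2.0);\n")
        tree = read_newick(p)
        labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        assert labels == {"taxon one", "taxon two"}

    def test_label_mismatch_detected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,(B:1,Z:1):0.5);\n")
        tree = read_newick(p)
        aln = make_alignment({"A": "MK", "B": "ML", "C": "MI"}, "A")
        with pytest.raises(LabelMismatchError):
            validate_tree_against_alignment(tree, aln)


class TestExtractSubtree:
    def _setup(self):
        tree = read_newick_str("((q:1,a:1):1,((b:1,c:1):1,(d:1,(e:1,f:1):1):1):1);")
        rows = {
            "q": "MKLVWD",
            "a": "MKIVWD",
            "b": "MRLVWD",
            "c": "MRLVW-",
            "d": "MKLVF-",
            "e": "MKLVY-",
            "f": "MKLVY-",
        }
        return tree, make_alignment(rows, "q")

    def test_full_leaf_set_is_identity(self):
        tree, aln = self._setup()
        sub, sub_aln = extract_subtree(tree, aln.ids, aln)
        assert {lf.taxon.label for lf in sub.leaf_node_iter()} == set(aln.ids)
        assert sub_aln.n_sites == aln.n_sites

    def test_small_clade_rejected(self):
        tree, aln = self._setup()
        with pytest.raises(TooFewHomologuesError):
            extract_subtree(tree, ["q", "a"], aln)

    def test_query_outside_clade_rejected(self):
        tree, aln = self._setup()
        with pytest.raises(QueryOutsideSubtreeError):
            extract_subtree(tree, ["b", "c", "d", "e", "f"], aln)

    def test_non_clade_rejected(self):
        tree, aln = self._setup()
        with pytest.raises(LabelMismatchError):
            extract_subtree(tree, ["q", "a", "b", "d", "e"], aln)

    def test_all_gap_columns_dropped(self):
        # clade {b..f} minus query is invalid; use a 6-leaf clade with query
        tree = read_newick_str(
            "(((q:1,a:1):1,((b:1,c:1):1,(d:1,(e:1,f:1):1):1):1):1,(x:1,y:1):1);"
        )
        rows = {
            "q": "MKLVW-",
            "a": "MKIVW-",
            "b": "MRLVW-",
            "c": "MRLVW-",
            "d": "MKLVF-",
            "e": "MKLVY-",
            "f": "MKLVY-",
            "x": "MKLVYD",
            "y": "MKLVYD",
        }
        aln = make_alignment(rows, "q")
        clade = ["q", "a", "b", "c", "d", "e", "f"]
        sub, sub_aln = extract_subtree(tree, clade, aln)
        assert {lf.taxon.label for lf in sub.leaf_node_iter()} == set(clade)
        assert sub_aln.n_sites == 5  # last column all-gap within the clade
        # branch lengths preserved: q-a path is still 2
        assert path_distance_matrix(sub)[frozenset(("q", "a"))] == pytest.approx(2.0)


def read_newick_str(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
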