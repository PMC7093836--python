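import io
import itertools

import dendropy
import numpy as np
import pytest

from satlib.datasets import clade_assignments
from satlib.libstats import clade_distance_test
from satlib.phylo import (
    DistanceMatrix,
    monophyly_check,
    nj_tree,
    pairwise_distance_matrix,
)
from satlib.seqcore import p_distance


def _tree_path_matrix(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = pdm.distance(taxa[a], taxa[b])
    return DistanceMatrix(tuple(labels), m)


def _rf_zero(tree, newick_true):
    tns = tree.taxon_namespace
    true = dendropy.Tree.get(data=newick_true, schema="newick",
                             taxon_namespace=tns)
    tree.encode_bipartitions()
    true.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(tree, true) == 0


class TestDistanceMatrix:
    def test_identical_sequences_give_zero(self):
        dm = pairwise_distance_matrix({"a": "ACGT", "b": "ACGT"})
        assert dm.get("a", "b") == 0.0

    def test_entries_match_per_pair_oracle(self):
        rng = np.random.default_rng(4)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 100))
                for i in range(5)}
        dm = pairwise_distance_matrix(seqs, metric="p")
        for a, b in itertools.combinations(seqs, 2):
            assert dm.get(a, b) == pytest.approx(p_distance(seqs[a], seqs[b]))

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            pairwise_distance_matrix({"a": "ACGT", "b": "ACG"})

    def test_k2p_metric_at_least_p(self):
        rng = np.random.default_rng(8)
        base = rng.choice(list("ACGT"), 200)
        seqs = {}
        for i in range(4):  # ~10% divergence from a shared ancestor
            arr = base.copy()
            pos = rng.choice(200, size=20, replace=False)
            arr[pos] = [rng.choice([b for b in "ACGT" if b != arr[p]])
                        for p in pos]
            seqs[f"s{i}"] = "".join(arr)
        dp = pairwise_distance_matrix(seqs, metric="p")
        dk = pairwise_distance_matrix(seqs, metric="k2p")
        assert (dk.values >= dp.values - 1e-12).all()

    def test_tsv_round_trip(self, tmp_path):
        dm = pairwise_distance_matrix({"a": "ACGT", "b": "ACGA", "c": "TCGA"})
        path = tmp_path / "dm.tsv"
        dm.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values)


def _ls_best_quartet_topology(dm):
    """Least-squares fit of all three unrooted 4-leaf topologies; returns
    the winning split as a frozenset pair. Independent NJ oracle."""
    a, b, c, d = dm.labels
    best = None
    for pair in [(a, b), (a, c), (a, d)]:
        rest = [x for x in dm.labels if x not in pair]
        # path matrix for topology (pair | rest): 5 branches
        leaves = [pair[0], pair[1], rest[0], rest[1]]
        rows, targets = [], []
        for i in range(4):
            for j in range(i + 1, 4):
                x, y = leaves[i], leaves[j]
                row = [0.0] * 5  # e_x for 4 leaves + internal edge
                row[i] = row[j] = 1.0
                same_side = ({x, y} == set(pair)) or ({x, y} == set(rest))
                if not same_side:
                    row[4] = 1.0
                rows.append(row)
                targets.append(dm.get(x, y))
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(targets),
                                       rcond=None)
        sse = float(res[0]) if len(res) else 0.0
        if best is None or sse < best[0]:
            best = (sse, frozenset((frozenset(pair), frozenset(rest))))
    return best[1]


def _tree_quartet_split(tree):
    tree2 = tree.clone(depth=1)
    tree2.encode_bipartitions()
    labels = {l.taxon.label for l in tree2.leaf_node_iter()}
    for edge in tree2.preorder_edge_iter():
        leaves = {l.taxon.label for l in edge.head_node.leaf_iter()}
        if len(leaves) == 2 and len(labels - leaves) == 2:
            return frozenset((frozenset(leaves), frozenset(labels - leaves)))
    return None


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        dm = DistanceMatrix(("a", "b", "c"),
                            np.array([[0, 0.2, 0.3],
                                      [0.2, 0, 0.4],
                                      [0.3, 0.4, 0]]))
        tree = nj_tree(dm)
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b", "c"}
        # the three-taxon star has exact branch lengths
        lens = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lens["a"] == pytest.approx(0.05)
        assert lens["b"] == pytest.approx(0.15)
        assert lens["c"] == pytest.approx(0.25)

    def test_quartet_recovery_matches_least_squares_enumeration(self):
        newick = "((a:0.1,b:0.15):0.2,(c:0.12,d:0.3):0.05);"
        dm = _tree_path_matrix(newick, ["a", "b", "c", "d"])
        tree = nj_tree(dm)
        assert _tree_quartet_split(tree) == _ls_best_quartet_topology(dm)
        assert _rf_zero(tree, newick)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_on_random_additive_five_taxon_matrices(self, seed):
        rng = np.random.default_rng(seed)
        bl = rng.uniform(0.05, 0.4, size=7)
        newick = (f"((a:{bl[0]},b:{bl[1]}):{bl[2]},c:{bl[3]},"
                  f"(d:{bl[4]},e:{bl[5]}):{bl[6]});")
        dm = _tree_path_matrix(newick, list("abcde"))
        assert _rf_zero(nj_tree(dm), newick)

    def test_well_separated_pairs_form_cherries(self):
        labels = ("a1", "a2", "b1", "b2")
        m = np.array([[0.0, 0.02, 1.0, 1.0],
                      [0.02, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 0.02],
                      [1.0, 1.0, 0.02, 0.0]])
        tree = nj_tree(DistanceMatrix(labels, m))
        split = _tree_quartet_split(tree)
        assert split == frozenset((frozenset({"a1", "a2"}),
                                   frozenset({"b1", "b2"})))

    def test_matches_dendropy_nj_topology(self):
        rng = np.random.default_rng(5)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 300))
                for i in range(6)}
        dm = pairwise_distance_matrix(seqs)
        mine = nj_tree(dm)
        csv = "," + ",".join(dm.labels) + "\n" + "\n".join(
            l + "," + ",".join(str(v) for v in row)
            for l, row in zip(dm.labels, dm.values))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=",")
        ref = pdm.nj_tree()
        mine.encode_bipartitions()
        ref2 = dendropy.Tree.get(data=ref.as_string(schema="newick"),
                                 schema="newick",
                                 taxon_namespace=mine.taxon_namespace)
        ref2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(
            mine, ref2) == 0

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"),
                                   np.array([[0.0, 0.1], [0.1, 0.0]])))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            base = rng.uniform(0.01, 0.5, size=(6, 6))
            m = (base + base.T) / 2
            np.fill_diagonal(m, 0.0)
            tree = nj_tree(DistanceMatrix(tuple("abcdef"), m))
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0.0


class TestMonophyly:
    newick = "((A:1,B:1):1,(C:1,D:1):1,O:3);"

    def _tree(self):
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def test_true_clade(self):
        assert monophyly_check(self._tree(), {"A", "B"}, "O")

    def test_paraphyletic_group(self):
        assert not monophyly_check(self._tree(), {"A", "C"}, "O")

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            monophyly_check(self._tree(), {"A", "Z"}, "O")

    def test_rooting_on_basal_outgroup_succeeds(self):
        assert monophyly_check(self._tree(), {"A", "B", "C", "D"}, "O")


class TestSimulatedCladeStructure:
    """With every clade sharing a stem amplification of one family, the
    species consensuses carry the phylogenetic signal: smaller distances
    within clades, and each clade monophyletic on the NJ tree rooted on
    the outgroup."""

    def test_within_clade_distances_smaller_and_clades_monophyletic(
            self, full_survey):
        cm = clade_assignments()
        dm = full_survey.consensus_distance_matrix("FAM3")
        res = clade_distance_test(dm, cm, outgroup="SGRE")
        assert res.statistic > 0
        assert res.p_value < 0.01
        tree = nj_tree(dm)
        for clade in ["1", "2", "3", "4"]:
            group = {s for s, c in cm.items() if c == clade}
            assert monophyly_check(tree, group, "SGRE")
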