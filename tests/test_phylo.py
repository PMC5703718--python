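"""K2P distances, neighbor joining, monophyly classification and
strict-clock calibration."""

import math

import dendropy
import numpy as np
import pytest
from conftest import bipartition_oracle, evolve_on_tree

from numtsome.phylo import (SaturationError, calibrate, k2p, k2p_matrix, nj,
                            species_pattern, to_newick)
from numtsome.simulate import mutate_k2p


def tree_distances(tree):
    """Leaf-to-leaf path lengths from a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ta = tree.taxon_namespace.get_taxon(a)
            tb = tree.taxon_namespace.get_taxon(b)
            out[(a, b)] = pdm.patristic_distance(ta, tb)
    return out


class TestK2P:
    def test_identical_sequences(self):
        d = k2p("ACGTACGT", "ACGTACGT")
        assert (d.P, d.Q, d.d) == (0.0, 0.0, 0.0)

    def test_worked_case_ten_transitions(self):
        """100 columns, 10 transitions, no transversions:
        d = -0.5 ln(0.8) ~ 0.1116."""
        a = "A" * 100
        b = "G" * 10 + "A" * 90          # A->G are transitions
        d = k2p(a, b)
        assert d.P == pytest.approx(0.10)
        assert d.Q == 0.0
        assert d.d == pytest.approx(-0.5 * math.log(0.8))
        assert d.d == pytest.approx(0.1116, abs=5e-4)

    def test_gap_and_n_columns_pairwise_deleted(self):
        d = k2p("ACG-TN", "ACGATA")
        assert d.n_sites == 4

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p("A" * 10, "G" * 10)

    def test_simulation_recovers_distance(self):
        rng = np.random.default_rng(44)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        b = mutate_k2p(a, 0.1, 4.0, rng)
        est = k2p(a, b)
        assert abs(est.d - 0.1) <= 3 * est.variance ** 0.5

    def test_jukes_cantor_limit_when_p_equals_2q(self):
        """At P=2Q the K2P distance matches the Jukes-Cantor correction of
        the same total difference to within 2%."""
        a = "A" * 1000
        b = "G" * 40 + "C" * 10 + "T" * 10 + "A" * 940   # P=.04, Q=.02
        d = k2p(a, b)
        p_total = 0.06
        jc = -0.75 * math.log(1 - 4 * p_total / 3)
        assert d.d == pytest.approx(jc, rel=0.02)


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj(D, ["a", "b", "c"])
        got = tree_distances(tree)
        assert got[("a", "b")] == pytest.approx(5)
        assert got[("a", "c")] == pytest.approx(9)
        assert got[("b", "c")] == pytest.approx(10)
        # three-point branch lengths: va=(5+9-10)/2=2, vb=3, vc=7
        lens = sorted(lf.edge.length for lf in tree.leaf_node_iter())
        assert lens == pytest.approx([2, 3, 7])

    def test_four_taxon_additive_recovered_exactly(self):
        # tree ((a:2,b:3):1,(c:4,d:5)) -> additive matrix
        D = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 0, 0]], dtype=float)
        D[2, 3] = D[3, 2] = 9.0
        tree = nj(D, ["a", "b", "c", "d"])
        got = tree_distances(tree)
        labels = ["a", "b", "c", "d"]
        for i, x in enumerate(labels):
            for j in range(i + 1, 4):
                assert got[(x, labels[j])] == pytest.approx(D[i, j], abs=1e-9)

    def test_matches_dendropy_nj_topology(self):
        rng = np.random.default_rng(10)
        n = 7
        labels = [f"t{i}" for i in range(n)]
        # random additive-ish distances via random points on a line + noise
        pts = rng.random(n) * 10
        D = np.abs(pts[:, None] - pts[None, :]) + 0.01
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2
        mine = nj(D, labels)
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(D[i, j]) for j in range(n))
            for i in range(n))
        import io
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), taxon_namespace=mine.taxon_namespace)
        ref = pdm.nj_tree()
        rf = dendropy.calculate.treecompare.symmetric_difference(mine, ref)
        assert rf == 0

    def test_nonsymmetric_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj(D, ["a", "b", "c"])

    def test_eight_taxon_topology_recovery(self):
        """K2P + NJ recovers a known 8-taxon topology (RF = 0) in at least
        4 of 5 seeded 1-kb simulation replicates."""
        newick = ("(((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05):0.05,"
                  "((E:0.05,F:0.05):0.05,(G:0.05,H:0.05):0.05):0.05);")
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            taxa = dendropy.TaxonNamespace()
            true = dendropy.Tree.get(data=newick, schema="newick",
                                     taxon_namespace=taxa)
            root_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
            seqs = evolve_on_tree(true, root_seq, 4.0, rng)
            D, labels = k2p_matrix(seqs)
            est = nj(D, labels, taxon_namespace=taxa)
            true.encode_bipartitions()
            est.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(true, est)
            wins += (rf == 0)
        assert wins >= 4


class TestSpeciesPattern:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_two_clean_clusters(self):
        t = self._tree("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        got = species_pattern(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert got == {"A": "monophyletic", "B": "monophyletic"}

    def test_intermingled(self):
        t = self._tree("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        got = species_pattern(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert got == {"A": "intermingled", "B": "intermingled"}

    def test_singleton_not_assessable(self):
        t = self._tree("((a1:1,a2:1):1,b1:1);")
        got = species_pattern(t, {"a1": "A", "a2": "A", "b1": "B"})
        assert got["B"] == "not assessable"

    def test_matches_edge_removal_oracle_on_random_trees(self):
        rng = np.random.default_rng(77)
        for rep in range(10):
            taxa = [f"l{i}" for i in range(8)]
            species = {t: f"S{int(rng.integers(0, 3))}" for t in taxa}
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
                rng=__import__("random").Random(int(rng.integers(1 << 30))))
            for leaf, name in zip(tree.leaf_node_iter(), taxa):
                leaf.taxon.label = name
            assert species_pattern(tree, species) == \
                bipartition_oracle(tree, species)

    def test_invariant_under_rerooting(self):
        t1 = self._tree("((a1:1,a2:1):1,(b1:1,(b2:1,a3:1):1):1);")
        sp = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        before = species_pattern(t1, sp)
        node = t1.mrca(taxa=[t for t in t1.taxon_namespace
                             if t.label in ("b2", "a3")])
        t1.reroot_at_node(node)
        assert species_pattern(t1, sp) == before


class TestCalibrate:
    def _tree(self):
        return dendropy.Tree.get(
            data="((a:0.05,b:0.05):0.05,(c:0.08,d:0.15):0.02);",
            schema="newick")

    def test_proportional_scaling(self):
        tree = calibrate(self._tree(), ["a", "b", "c", "d"],
                         age_window=(95, 105))
        root_age = tree.seed_node.age
        assert root_age == pytest.approx(100.0)
        mrca_ab = tree.mrca(taxa=[t for t in tree.taxon_namespace
                                  if t.label in ("a", "b")])
        # height(ab)=0.05 vs calibration height 0.12+... proportional
        h = {}
        for node in tree.postorder_node_iter():
            h[node] = 0.0 if node.is_leaf() else max(
                h[c] + c.edge.length for c in node.child_nodes())
        assert mrca_ab.age == pytest.approx(100.0 * h[mrca_ab] / h[tree.seed_node])

    def test_degenerate_window_point_ages(self):
        tree = calibrate(self._tree(), ["a", "b", "c", "d"],
                         age_window=(100, 100))
        for node in tree.preorder_node_iter():
            lo = float(node.annotations.get_value("age_lo"))
            hi = float(node.annotations.get_value("age_hi"))
            assert lo == pytest.approx(hi)

    def test_ages_monotone_root_to_tip(self):
        rng = np.random.default_rng(123)
        for rep in range(5):
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=10,
                rng=__import__("random").Random(int(rng.integers(1 << 30))))
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            cal = calibrate(tree, leaves, age_window=(90, 110))
            for node in cal.preorder_node_iter():
                for child in node.child_nodes():
                    assert node.age >= child.age - 1e-9
            for leaf in cal.leaf_node_iter():
                assert leaf.age == pytest.approx(0.0)

    def test_missing_calibration_leaves_rejected(self):
        with pytest.raises(ValueError):
            calibrate(self._tree(), ["a", "zz"])

    def test_newick_round_trip(self):
        tree = self._tree()
        text = to_newick(tree)
        again = dendropy.Tree.get(data=text, schema="newick")
        assert dendropy.calculate.treecompare.symmetric_difference(
            tree, dendropy.Tree.get(data=to_newick(again), schema="newick",
                                    taxon_namespace=tree.taxon_namespace)) == 0
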