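import math

import dendropy
import numpy as np
import pytest

from barcodegap.distance import DistanceMatrix, distance_matrix
from barcodegap.io import LocusAlignment
from barcodegap.tree import (
    bootstrap_support,
    monophyly_rate,
    nj_tree,
    read_newick,
    section_clustering,
    write_newick,
)

from conftest import oracle_is_monophyletic, random_additive_tree, random_alignment


def dmatrix(accs, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(accs, d, np.full(d.shape, 100))


def bipartitions(tree):
    tree.encode_bipartitions()
    all_mask = tree.taxon_namespace.all_taxa_bitmask()
    out = set()
    for bp in tree.bipartition_encoding:
        m = bp.leafset_bitmask
        size = bin(m).count("1")
        if 1 < size < bin(all_mask).count("1") - 1:
            out.add(min(m, m ^ all_mask))
    return out


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxa[i], taxa[j])
    return [t.label for t in taxa], d


class TestNJTree:
    def test_three_taxa_three_point_formulas(self):
        dm = dmatrix(["a", "b", "c"], [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(dm)
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_additive_quartet_recovered(self):
        # ((a,b),(c,d)) with tip lengths 0.1 and internal edge 0.05
        d = np.array([
            [0.00, 0.20, 0.25, 0.25],
            [0.20, 0.00, 0.25, 0.25],
            [0.25, 0.25, 0.00, 0.20],
            [0.25, 0.25, 0.20, 0.00],
        ])
        tree = nj_tree(dmatrix(["a", "b", "c", "d"], d))
        labels, rec = patristic(tree)
        assert labels == ["a", "b", "c", "d"]
        assert np.allclose(rec, d, atol=1e-12)

    def test_random_additive_matrices_exactly_recovered(self, rng):
        for _ in range(10):
            true_tree, taxa, d = random_additive_tree(rng, 8)
            dm = dmatrix(taxa, d)
            est = nj_tree(dm)
            # topology: identical bipartition sets on a shared namespace
            est2 = dendropy.Tree.get(data=est.as_string(schema="newick"),
                                     schema="newick",
                                     taxon_namespace=true_tree.taxon_namespace)
            assert bipartitions(est2) == bipartitions(true_tree)
            _, rec = patristic(est)
            order = np.argsort(taxa)
            assert np.allclose(rec, d[np.ix_(order, order)], atol=1e-9)

    def test_ultrametric_two_cluster_matrix(self):
        accs = ["a1", "a2", "b1", "b2"]
        d = np.full((4, 4), 0.4)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0)
        tree = nj_tree(dmatrix(accs, d))
        assert bipartitions(tree) == {
            min(m, m ^ tree.taxon_namespace.all_taxa_bitmask())
            for m in [sum(tree.taxon_namespace.taxon_bitmask(t)
                          for t in tree.taxon_namespace if t.label in ("a1", "a2"))]
        }

    def test_agrees_with_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        aln = random_alignment(rng, 9, 400, n_species=3, mutation_rate=0.05)
        dm = distance_matrix(aln)
        ours = nj_tree(dm)
        ref = skbio.tree.nj(skbio.DistanceMatrix(dm.d, dm.accessions))
        ref_dp = dendropy.Tree.get(data=str(ref), schema="newick",
                                   taxon_namespace=ours.taxon_namespace)
        assert bipartitions(ref_dp) == bipartitions(ours)

    def test_undefined_distance_names_the_pair(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        dm = DistanceMatrix(["a", "b", "c"], d, np.full((3, 3), 10))
        with pytest.raises(ValueError, match="a.*c"):
            nj_tree(dm)

    def test_negative_branch_estimates_clamped(self):
        # non-additive matrix known to produce a negative NJ branch estimate
        d = np.array([
            [0.0, 0.1, 0.6, 0.6],
            [0.1, 0.0, 0.1, 0.6],
            [0.6, 0.1, 0.0, 0.1],
            [0.6, 0.6, 0.1, 0.0],
        ])
        tree = nj_tree(dmatrix(["a", "b", "c", "d"], d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0


class TestBootstrapSupport:
    def test_single_replicate_supports_are_binary(self, rng):
        aln = random_alignment(rng, 8, 300, n_species=4, mutation_rate=0.05)
        tree = bootstrap_support(aln, replicates=1, seed=7)
        supports = [n.support for n in tree.preorder_node_iter()
                    if hasattr(n, "support")]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_fixed_seed_reproducible(self, rng):
        aln = random_alignment(rng, 8, 300, n_species=4, mutation_rate=0.05)
        t1 = bootstrap_support(aln, replicates=20, seed=11)
        t2 = bootstrap_support(aln, replicates=20, seed=11)
        s1 = sorted(n.support for n in t1.preorder_node_iter() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.preorder_node_iter() if hasattr(n, "support"))
        assert s1 == s2

    def test_strong_clean_signal_gives_full_support(self):
        # two maximally distinct haplotype groups, no homoplasy
        a = "A" * 120
        b = "A" * 90 + "G" * 30
        aln = LocusAlignment(
            "x", ["a1", "a2", "b1", "b2"],
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            [a, a[:-1] + "C", b, b[:-1] + "T"])
        tree = bootstrap_support(aln, replicates=50, seed=3)
        supports = [n.support for n in tree.preorder_node_iter() if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)


def tree_from_newick(s, taxa=None):
    ns = dendropy.TaxonNamespace(taxa) if taxa else None
    return dendropy.Tree.get(data=s, schema="newick", taxon_namespace=ns,
                             preserve_underscores=True)


class TestMonophylyRate:
    def test_clean_split_scores_hundred(self):
        t = tree_from_newick("((a1,a2),(b1,b2));")
        score = monophyly_rate(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert score.rate == 100.0 and score.species_monophyletic == 2

    def test_interleaved_species_score_zero(self):
        t = tree_from_newick("((a1,b1),(a2,b2));")
        score = monophyly_rate(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert score.rate == 0.0

    def test_singleton_counts_as_monophyletic_and_is_flagged(self):
        t = tree_from_newick("((a1,a2),(b1,c1));")
        score = monophyly_rate(t, {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        assert score.per_species == {"A": True, "B": True, "C": True}
        assert sorted(score.singletons) == ["B", "C"]
        assert score.rate == 100.0
        assert score.rate_multi_only == 100.0

    def test_matches_edge_enumeration_oracle_on_random_trees(self, rng):
        for _ in range(10):
            true_tree, taxa, _ = random_additive_tree(rng, 20)
            labels = {t: f"sp{rng.integers(0, 5)}" for t in taxa}
            score = monophyly_rate(true_tree, labels)
            for sp, members in [
                (sp, {t for t in taxa if labels[t] == sp})
                for sp in set(labels.values())
            ]:
                assert score.per_species[sp] == oracle_is_monophyletic(true_tree, members)

    def test_invariant_to_rerooting(self, rng):
        true_tree, taxa, _ = random_additive_tree(rng, 12)
        labels = {t: f"sp{i % 4}" for i, t in enumerate(taxa)}
        base = monophyly_rate(true_tree, labels)
        for leaf_label in taxa[:4]:
            rerooted = dendropy.Tree(true_tree)
            node = rerooted.find_node_with_taxon_label(leaf_label)
            rerooted.reroot_at_edge(node.edge, update_bipartitions=True)
            assert monophyly_rate(rerooted, labels).per_species == base.per_species

    def test_missing_leaf_label_rejected(self):
        t = tree_from_newick("((a1,a2),(b1,b2));")
        with pytest.raises(KeyError):
            monophyly_rate(t, {"a1": "A", "a2": "A", "b1": "B"})


class TestSectionClustering:
    def test_reduces_to_species_monophyly_when_labels_coincide(self):
        t = tree_from_newick("((a1,a2),(b1,b2));")
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert section_clustering(t, species).per_species == \
            monophyly_rate(t, species).per_species

    def test_section_split_across_clades_fails(self):
        t = tree_from_newick("((a1,b1),(a2,c1));")
        sections = {"a1": "S1", "a2": "S1", "b1": "S2", "c1": "S2"}
        score = section_clustering(t, sections)
        assert score.per_species == {"S1": False, "S2": False}


def test_newick_roundtrip(tmp_path, rng):
    tree, taxa, _ = random_additive_tree(rng, 6)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path, taxon_namespace=tree.taxon_namespace)
    assert bipartitions(back) == bipartitions(tree)
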