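import dendropy
import numpy as np
import pytest

import phylodissect as pdx
from phylodissect.errors import UnknownTaxonError
from phylodissect.seqio import LocusSet, read_tree, write_tree
from phylodissect.synthdata import (
    SimulationConfig,
    assign_clades,
    make_competing_pair,
    mask_missing,
    sample_species_tree,
    scale_branches,
    simulate_alignment,
    simulate_study,
)

from conftest import random_alignment


def _splits(tree):
    """Non-trivial bipartitions as frozensets of the smaller side."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for n in tree.preorder_node_iter():
        if n.parent_node is None or n.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in n.leaf_iter())
        if 2 <= len(below) <= len(leaves) - 2:
            out.add(min(below, leaves - below, key=lambda s: (len(s), sorted(s))))
    return out


class TestSampleSpeciesTree:
    def test_counts(self):
        tree = sample_species_tree(4, 0.1, 7)
        leaves = list(tree.leaf_node_iter())
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        branches = [
            e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
        ]
        assert len(leaves) == 4
        assert len(internals) == 3
        assert len(branches) == 6

    def test_seed_determinism(self):
        a = write_tree(sample_species_tree(9, 0.1, 42))
        b = write_tree(sample_species_tree(9, 0.1, 42))
        c = write_tree(sample_species_tree(9, 0.1, 43))
        assert a == b
        assert a != c

    def test_triplet(self):
        tree = sample_species_tree(3, 0.1, 1)
        assert len(list(tree.leaf_node_iter())) == 3
        assert all(
            len(n.child_nodes()) in (0, 2) for n in tree.preorder_node_iter()
        )

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            sample_species_tree(2, 0.1, 1)

    def test_positive_branch_lengths(self):
        tree = sample_species_tree(10, 0.2, 5)
        for e in tree.preorder_edge_iter():
            if e.head_node is not tree.seed_node:
                assert e.length > 0


class TestCompetingPair:
    def _base(self):
        return read_tree(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,X:1):1):1);"
        )

    def test_t2_has_focal_clade_t1_does_not(self):
        t1, t2 = make_competing_pair(self._base(), {"A", "B", "C", "D"}, {"X"})
        focal = frozenset("ABCD")
        assert focal in {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in t2.preorder_node_iter()
        }
        t1_clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in t1.preorder_node_iter()
        }
        assert focal not in t1_clades
        assert focal | {"X"} in t1_clades  # outpost nested inside focal span

    def test_rf_distance_at_least_two(self):
        t1, t2 = make_competing_pair(self._base(), {"A", "B", "C", "D"}, {"X"})
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=write_tree(t1), schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=write_tree(t2), schema="newick", taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(a, b) >= 2

    def test_unrelated_clades_shared(self):
        """Bipartition enumeration: every split disjoint from focal+outpost
        appears in both hypotheses."""
        t1, t2 = make_competing_pair(self._base(), {"A", "B", "C", "D"}, {"X"})
        involved = frozenset("ABCDX")
        s1 = {s for s in _splits(t1) if not (s & involved)}
        s2 = {s for s in _splits(t2) if not (s & involved)}
        assert s1 == s2
        assert frozenset("EF") in s1

    def test_same_leaf_sets(self):
        t1, t2 = make_competing_pair(self._base(), {"A", "B"}, {"E", "F"})
        l1 = {l.taxon.label for l in t1.leaf_node_iter()}
        l2 = {l.taxon.label for l in t2.leaf_node_iter()}
        assert l1 == l2 == set("ABCDEFGX")

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            make_competing_pair(self._base(), {"A", "B"}, {"B"})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            make_competing_pair(self._base(), set(), {"X"})


class TestScaleBranches:
    def test_identity(self):
        tree = sample_species_tree(6, 0.1, 3)
        out = scale_branches(tree, {t: 1.0 for t in ("T1", "T2")} if False else {})
        assert write_tree(out) == write_tree(tree)

    def test_leaf_multiplier(self):
        tree = read_tree("(A:1,(B:2,C:3):1);")
        out = scale_branches(tree, {"B": 10.0})
        lengths = {
            l.taxon.label: l.edge.length for l in out.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 20.0, "C": 3.0}

    def test_patristic_grows_by_added_length(self):
        tree = read_tree("(A:1,(B:2,C:3):1);")
        before, labels = pdx.patristic_matrix(tree)
        out = scale_branches(tree, {"B": 10.0})
        after, _ = pdx.patristic_matrix(out, taxa=labels)
        i, j = labels.index("A"), labels.index("B")
        assert after[i, j] - before[i, j] == pytest.approx(18.0)
        k = labels.index("C")
        assert after[i, k] == pytest.approx(before[i, k])

    def test_clade_key(self):
        tree = read_tree("(A:1,(B:2,C:3):1);")
        out = scale_branches(tree, {"inner": 2.0}, clade_map={"B": "inner", "C": "inner"})
        lengths = {l.taxon.label: l.edge.length for l in out.leaf_node_iter()}
        assert lengths["B"] == 4.0
        assert lengths["C"] == 6.0
        assert lengths["A"] == 1.0

    def test_unknown_key(self):
        tree = read_tree("(A:1,(B:2,C:3):1);")
        with pytest.raises(UnknownTaxonError):
            scale_branches(tree, {"Z": 2.0})


class TestSimulateAlignment:
    def test_zero_branch_lengths_constant_columns(self):
        model = pdx.build_model("lg", alpha=0.5, k=4)
        tree = read_tree("(A:0,(B:0,C:0):0);")
        aln = simulate_alignment(tree, model, 25, 5)
        for j in range(25):
            assert len(set(aln.codes[:, j])) == 1

    def test_seed_determinism(self):
        model = pdx.build_model("poisson", frequencies="uniform")
        tree = sample_species_tree(5, 0.1, 2)
        a = simulate_alignment(tree, model, 50, 9)
        b = simulate_alignment(tree, model, 50, 9)
        c = simulate_alignment(tree, model, 50, 10)
        assert np.array_equal(a.codes, b.codes)
        assert not np.array_equal(a.codes, c.codes)

    def test_stationary_frequencies(self):
        """Single-row residue frequencies are uniform under Poisson/uniform:
        each within sampling error of 1/20 (rows are marginally stationary;
        pooling rows would correlate cells through the shared root state)."""
        from scipy import stats

        model = pdx.build_model("poisson", frequencies="uniform")
        tree = read_tree("(A:0.1,(B:0.2,C:0.1):0.1);")
        aln = simulate_alignment(tree, model, 10_000, 3)
        n = aln.n_columns
        counts = np.bincount(aln.row("A"), minlength=20)
        se = np.sqrt(n * 0.05 * 0.95)
        assert np.abs(counts - n / 20).max() < 4 * se  # 20 simultaneous bins
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_negative_branch_rejected(self):
        model = pdx.build_model("poisson")
        tree = read_tree("(A:0.1,B:0.1);")
        list(tree.leaf_node_iter())[0].edge.length = -0.5
        with pytest.raises(ValueError):
            simulate_alignment(tree, model, 5, 1)


class TestMaskMissing:
    def _loci(self, rng, n_loci=100, n_taxa=20):
        return LocusSet.from_pairs(
            (f"l{i:03d}", random_alignment(rng, n_taxa, 10)) for i in range(n_loci)
        )

    def test_zero_dropout_identity(self, rng):
        loci = self._loci(rng, 5)
        assert mask_missing(loci, 0.0, 1) is loci

    def test_binomial_retention(self, rng):
        loci = self._loci(rng)
        out = mask_missing(loci, 0.25, 7)
        kept = sum(aln.n_taxa for _, aln in out)
        total = 100 * 20
        se = np.sqrt(total * 0.25 * 0.75)
        assert abs(kept - 0.75 * total) < 3 * se

    def test_dropped_taxa_absent(self, rng):
        loci = self._loci(rng, 10)
        out = mask_missing(loci, 0.4, 3)
        for name, aln in out:
            orig = loci[name]
            assert set(aln.taxa) <= set(orig.taxa)
            # surviving rows are bit-identical, not gap-padded
            for t in aln.taxa:
                assert np.array_equal(aln.row(t), orig.row(t))


class TestStudy:
    def test_determinism_and_structure(self):
        cfg = SimulationConfig(n_taxa=10, n_loci=8, locus_length_range=(50, 80),
                               seed=5, dropout_prob=0.1, noise_fraction=0.25)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert write_tree(a.t1) == write_tree(b.t1)
        assert a.loci.names == b.loci.names
        for name in a.loci.names:
            assert np.array_equal(a.loci[name].codes, b.loci[name].codes)
        assert a.focal_taxa.isdisjoint(a.outpost_taxa)
        assert set(a.clade_map) == {
            l.taxon.label for l in a.species_tree.leaf_node_iter()
        }
        assert 0 < len(a.noise_loci) <= len(a.loci)

    def test_clade_assignment_monophyletic(self):
        tree = sample_species_tree(12, 0.1, 8)
        mapping = assign_clades(tree, 4)
        assert len(set(mapping.values())) == 4
        for clade in set(mapping.values()):
            members = [t for t, c in mapping.items() if c == clade]
            mrca = tree.mrca(taxon_labels=members)
            assert {l.taxon.label for l in mrca.leaf_iter()} == set(members)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=1)
        with pytest.raises(ValueError):
            SimulationConfig(gamma_shape=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(dropout_prob=1.0)
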