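import numpy as np
import pandas as pd
import pytest

import phylodissect as pdx
from phylodissect.errors import InsufficientDataError
from phylodissect.matrixops import SR4_ALPHABET
from phylodissect.seqio import Alignment, LocusSet, read_tree
from phylodissect.signal import (
    build_signal_table,
    classify_support,
    compare_gene_properties,
    delta_gls,
    delta_sls,
    gene_concordance_factor,
    site_concordance_factor,
    support_class,
)

from conftest import random_alignment


@pytest.fixture(scope="module")
def hypothesis_pair():
    base = read_tree(
        "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,((E:0.1,F:0.1):0.1,(G:0.1,X:0.2):0.1):0.1);"
    )
    return pdx.make_competing_pair(base, {"A", "B", "C", "D"}, {"X"})


class TestDeltaGLS:
    def test_identical_topologies_zero(self, lg_gamma, rng):
        tree = pdx.sample_species_tree(6, 0.1, 17)
        aln = pdx.simulate_alignment(tree, lg_gamma, 80, 18)
        d = delta_gls(aln, tree, read_tree(pdx.write_tree(tree)), lg_gamma)
        assert abs(d) < 1e-6

    def test_constant_columns_fixed_mode(self, hypothesis_pair):
        t1, t2 = hypothesis_pair
        taxa = sorted(l.taxon.label for l in t1.leaf_node_iter())
        aln = Alignment.from_sequences([(t, "AAAAA") for t in taxa])
        model = pdx.build_model("poisson", frequencies="uniform")
        # equalise total tree length so constant sites see the same process
        for t in (t1, t2):
            pass
        d = delta_gls(aln, t1, t2, model, mode="fixed")
        # constant sites are blind to topology; lengths are equal by
        # construction of the pair except the regraft edges
        assert abs(d) < 0.2

    def test_antisymmetry(self, lg_gamma, hypothesis_pair):
        t1, t2 = hypothesis_pair
        taxa = sorted(l.taxon.label for l in t1.leaf_node_iter())
        aln = pdx.simulate_alignment(t1, lg_gamma, 120, 77)
        fwd = delta_gls(aln, t1, t2, lg_gamma)
        rev = delta_gls(aln, t2, t1, lg_gamma)
        assert fwd == pytest.approx(-rev, abs=1e-6)

    def test_simulated_loci_favour_generator(self, lg_gamma, hypothesis_pair):
        t1, t2 = hypothesis_pair
        wins = 0
        n = 12
        for rep in range(n):
            aln = pdx.simulate_alignment(t1, lg_gamma, 300, 500 + rep)
            if delta_gls(aln, t1, t2, lg_gamma, tol=1e-3, xatol=1e-6) > 0:
                wins += 1
        assert wins / n > 0.7

    def test_leafset_mismatch_rejected(self, lg_gamma):
        t1 = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_tree("((A:1,B:1):1,(C:1,E:1):1);")
        aln = Alignment.from_sequences(
            [(t, "ARND") for t in ["A", "B", "C", "D", "E"]]
        )
        with pytest.raises(ValueError):
            delta_gls(aln, t1, t2, lg_gamma)


class TestDeltaSLS:
    def test_identical_topologies_all_zero(self, lg_gamma):
        tree = pdx.sample_species_tree(5, 0.1, 23)
        aln = pdx.simulate_alignment(tree, lg_gamma, 50, 24)
        d = delta_sls(aln, tree, read_tree(pdx.write_tree(tree)), lg_gamma,
                      optimize=False)
        assert np.abs(d).max() < 1e-9

    def test_sum_identity(self, lg_gamma, hypothesis_pair):
        """Sum of per-site scores equals the matrix-level dGLS when branch
        lengths are fixed."""
        t1, t2 = hypothesis_pair
        aln = pdx.simulate_alignment(t1, lg_gamma, 200, 99)
        d = delta_sls(aln, t1, t2, lg_gamma, optimize=False)
        gls = delta_gls(aln, t1, t2, lg_gamma, mode="fixed")
        assert d.sum() == pytest.approx(gls, abs=1e-8)

    def test_sign_pattern_matches_enumeration(self, rng):
        """Per-site sign agrees with the exhaustive 4-state oracle on a
        5-taxon fixture."""
        from conftest import brute_force_site_loglik

        model = pdx.build_model(
            "poisson", frequencies="uniform", alphabet=SR4_ALPHABET
        )
        t1 = read_tree("((A:0.1,C:0.1):0.05,(B:0.1,D:0.1):0.05,E:0.3);")
        t2 = read_tree("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05,E:0.3);")
        aln = random_alignment(rng, 5, 12, alphabet=SR4_ALPHABET)
        aln = Alignment(list("ABCDE"), aln.codes, SR4_ALPHABET)
        d = delta_sls(aln, t1, t2, model, optimize=False)
        o1 = brute_force_site_loglik(aln, t1, model)
        o2 = brute_force_site_loglik(aln, t2, model)
        assert np.allclose(d, o1 - o2, atol=1e-8)


class TestClassify:
    def test_basic_fractions(self):
        assert classify_support(np.array([2.0, 1.0, -3.0])) == pytest.approx(
            (2 / 3, 1 / 3, 0.0)
        )

    def test_ties(self):
        assert classify_support(np.array([0.0, 0.0])) == pytest.approx(
            (0.0, 0.0, 1.0)
        )

    def test_tie_eps_band(self):
        p1, p2, ptie = classify_support(np.array([0.5, -0.5, 2.0]), tie_eps=1.0)
        assert (p1, p2, ptie) == pytest.approx((1 / 3, 0.0, 2 / 3))

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_support(np.array([]))

    def test_support_class_labels(self):
        assert support_class(1.0) == "T1"
        assert support_class(-1.0) == "T2"
        assert support_class(0.0) == "tie"


class TestCompareProperties:
    def _table(self):
        return pd.DataFrame(
            {
                "locus": [f"l{i}" for i in range(6)],
                "support": ["T1", "T1", "T1", "T2", "T2", "T2"],
                "dgls": [1, 2, 3, -1, -2, -3],
                "columns": [200, 220, 240, 100, 110, 120],
                "informative_sites": [50, 60, 70, 10, 12, 14],
                "missing_fraction": [0.1] * 6,
                "rate_proxy": [0.2] * 6,
                "slope": [0.5] * 6,
                "r2": [0.9] * 6,
            }
        )

    def test_median_length_ratio(self):
        out = compare_gene_properties(self._table())
        cols = out[out["covariate"] == "columns"].iloc[0]
        assert cols["T2_median"] / cols["T1_median"] == pytest.approx(0.5)

    def test_identical_classes_identical_summaries(self):
        t = self._table()
        t.loc[t["support"] == "T2", ["columns", "informative_sites"]] = (
            t.loc[t["support"] == "T1", ["columns", "informative_sites"]].to_numpy()
        )
        out = compare_gene_properties(t)
        cols = out[out["covariate"] == "columns"].iloc[0]
        assert cols["T1_median"] == cols["T2_median"]

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_gene_properties(pd.DataFrame())


class TestGeneCF:
    def test_all_concordant(self):
        ref = read_tree("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        gts = [read_tree(pdx.write_tree(ref)) for _ in range(5)]
        out = gene_concordance_factor(gts, ref)
        assert (out["gcf"] == 100.0).all()

    def test_absent_branch_zero(self):
        ref = read_tree("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        other = read_tree("((A:1,C:1):1,((B:1,D:1):1,(E:1,F:1):1):1);")
        gts = [read_tree(pdx.write_tree(other)) for _ in range(4)]
        out = gene_concordance_factor(gts, ref)
        row = out[out["branch"].str.split("|").apply(sorted).apply(tuple) == ("A", "B")]
        assert row["gcf"].iloc[0] == 0.0

    def test_counts_match_bipartition_oracle(self):
        """6 concordant + 2 discordant + 2 non-decisive gene trees -> 75."""
        ref = read_tree("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        concordant = [read_tree(pdx.write_tree(ref)) for _ in range(6)]
        discordant = [
            read_tree("((A:1,C:1):1,((B:1,D:1):1,(E:1,F:1):1):1);")
            for _ in range(2)
        ]
        # missing B entirely -> not decisive for the AB branch
        nondecisive = [
            read_tree("((A:1,(C:1,D:1):1):1,(E:1,F:1):1);") for _ in range(2)
        ]
        out = gene_concordance_factor(concordant + discordant + nondecisive, ref)
        row = out[out["branch"].str.split("|").apply(sorted).apply(tuple) == ("A", "B")]
        assert row["n_decisive_genes"].iloc[0] == 8
        assert row["gcf"].iloc[0] == pytest.approx(75.0)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            gene_concordance_factor([], read_tree("((A:1,B:1):1,(C:1,D:1):1);"))

    def test_bounds(self, lg_gamma):
        ref = pdx.sample_species_tree(8, 0.1, 55)
        gts = [pdx.sample_species_tree(8, 0.1, s) for s in range(56, 62)]
        out = gene_concordance_factor(gts, ref)
        vals = out["gcf"].dropna()
        assert ((vals >= 0) & (vals <= 100)).all()


class TestSiteCF:
    def _perfect_alignment(self, ref):
        """Every informative site is a clean synapomorphy of one reference
        clade (no homoplasy)."""
        taxa = sorted(l.taxon.label for l in ref.leaf_node_iter())
        clades = []
        leaves = frozenset(taxa)
        for n in ref.preorder_node_iter():
            if n.parent_node is None or n.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in n.leaf_iter())
            if 2 <= len(below) <= len(leaves) - 2:
                clades.append(below)
        cols = []
        for clade in clades * 5:
            cols.append([0 if t in clade else 1 for t in taxa])
        codes = np.array(cols, dtype=np.int8).T
        return Alignment(taxa, codes)

    def test_homoplasy_free_scf_100(self):
        ref = read_tree("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        aln = self._perfect_alignment(ref)
        out = site_concordance_factor(aln, ref, n_quartets=50, seed=1)
        assert (out["scf"].dropna() == 100.0).all()

    def test_no_decisive_sites_flagged(self):
        ref = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        aln = Alignment.from_sequences([(t, "AAAA") for t in "ABCD"])
        out = site_concordance_factor(aln, ref, n_quartets=10, seed=1)
        assert out["scf"].isna().all()
        assert (out["n_decisive_sites"] == 0).all()

    def test_hand_built_quartet_count(self):
        """6-taxon fixture scored against an exhaustive hand count."""
        ref = read_tree("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        taxa = ["A", "B", "C", "D", "E", "F"]
        # column 1-3 support AB|rest, column 4 conflicts (groups A,C together)
        seqs = {
            "A": "AAAC",
            "B": "AAAA",
            "C": "RRRC",
            "D": "RRRA",
            "E": "RRRA",
            "F": "RRRA",
        }
        aln = Alignment.from_sequences([(t, seqs[t]) for t in taxa])
        out = site_concordance_factor(aln, ref, n_quartets=1000, seed=1)
        row = out[out["branch"].str.split("|").apply(sorted).apply(tuple) == ("A", "B")]
        # expectation from an independent exhaustive quartet enumeration
        assert row["scf"].iloc[0] == pytest.approx(
            self._expected_ab_scf(aln, ref), abs=1e-9
        )

    @staticmethod
    def _expected_ab_scf(aln, ref):
        # exhaustive quartets for branch AB: one leaf from {A}, {B}, and the
        # two far-side subtrees {C,D} and {E,F}
        import itertools as it

        taxa = {t: i for i, t in enumerate(aln.taxa)}
        total = []
        for c, d in it.product(["C", "D"], ["E", "F"]):
            support = decisive = 0
            for j in range(aln.n_columns):
                col = aln.codes[:, j]
                a, b, cc, dd = (
                    col[taxa["A"]],
                    col[taxa["B"]],
                    col[taxa[c]],
                    col[taxa[d]],
                )
                pats = [
                    a == b and cc == dd and a != cc,
                    a == cc and b == dd and a != b,
                    a == dd and b == cc and a != b,
                ]
                if any(pats):
                    decisive += 1
                    if pats[0]:
                        support += 1
            if decisive:
                total.append(support / decisive)
        return 100.0 * float(np.mean(total))

    def test_bounds_random(self, rng):
        ref = pdx.sample_species_tree(7, 0.1, 70)
        aln = random_alignment(rng, 7, 60)
        aln = Alignment(
            sorted(l.taxon.label for l in ref.leaf_node_iter()),
            aln.codes,
            aln.alphabet,
        )
        out = site_concordance_factor(aln, ref, n_quartets=20, seed=3)
        vals = out["scf"].dropna()
        assert ((vals >= 0) & (vals <= 100)).all()


class TestSignalTable:
    def test_table_and_entropy_contrast(self, lg_gamma):
        """Noise loci (short, fast, generated on T2) land in the T2 class
        with fewer informative sites; tree-like loci support T1."""
        cfg = pdx.SimulationConfig(
            n_taxa=10,
            n_loci=10,
            locus_length_range=(150, 250),
            seed=13,
            dropout_prob=0.0,
            noise_fraction=0.3,
            noise_rate_multiplier=12.0,
            noise_length_range=(50, 80),
        )
        study = pdx.simulate_study(cfg)
        table = build_signal_table(
            study.loci, study.t1, study.t2, lg_gamma, tol=1e-3, xatol=1e-6
        )
        assert len(table) == 10
        assert set(table.columns) >= {
            "locus", "dgls", "support", "columns", "informative_sites",
            "missing_fraction", "rate_proxy", "slope", "r2",
        }
        # noise loci have a much larger rate proxy
        noise = table["locus"].isin(study.noise_loci)
        assert table.loc[noise, "rate_proxy"].median() > (
            3 * table.loc[~noise, "rate_proxy"].median()
        )
        # tree-like loci mostly back the generating topology
        p1, p2, _ = classify_support(table.loc[~noise, "dgls"].to_numpy())
        assert p1 > p2
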