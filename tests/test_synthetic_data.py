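import math

import dendropy
import numpy as np
import pytest

from opsinevol import codon_evol
from opsinevol.clade_compare import prob_exceed_exact
from opsinevol.coevolution import match_count
from opsinevol.io_formats import SiteClassDistribution
from opsinevol.synthetic_data import (SimulationConfig, inject_pseudogene,
                                      simulate_codon_alignment,
                                      simulate_omega_table,
                                      simulate_siteclass_pair,
                                      simulate_traits, simulate_tree)

from .oracles import brute_prob_exceed


class TestSimulateTree:
    def test_two_taxa_is_a_cherry(self):
        tree = simulate_tree(2, seed=1)
        assert len(tree.leaf_nodes()) == 2
        assert len(tree.seed_node.child_nodes()) == 2

    def test_seed_determinism(self):
        a = simulate_tree(10, seed=7).as_string(schema="newick")
        b = simulate_tree(10, seed=7).as_string(schema="newick")
        assert a == b

    def test_48_tips_47_internals(self):
        tree = simulate_tree(48, seed=3)
        assert len(tree.leaf_nodes()) == 48
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internals) == 47

    def test_height_rescaling(self):
        tree = simulate_tree(12, seed=5, tree_height=0.3)
        height = max(l.distance_from_root() for l in tree.leaf_node_iter())
        assert height == pytest.approx(0.3)


class TestSimulateCodonAlignment:
    def test_zero_branch_lengths_give_identical_tips(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):0,(C:0,D:0):0);",
                                 schema="newick")
        aln = simulate_codon_alignment(tree, omega=0.5, kappa=2, gc=0.5,
                                       length=50, seed=1)
        assert len(set(aln.sequences)) == 1

    def test_omega_zero_forces_dn_zero(self):
        tree = simulate_tree(6, seed=2, tree_height=0.3)
        aln = simulate_codon_alignment(tree, omega=0.0, kappa=2, gc=0.5,
                                       length=200, seed=3)
        r = codon_evol.ng86_dnds(aln.sequences[0], aln.sequences[1])
        assert r.dn == 0.0
        assert r.ds > 0.0

    def test_seed_determinism(self):
        tree = simulate_tree(5, seed=4, tree_height=0.2)
        a = simulate_codon_alignment(tree, 0.3, 2, 0.5, 60, seed=9)
        b = simulate_codon_alignment(tree, 0.3, 2, 0.5, 60, seed=9)
        assert a.sequences == b.sequences

    def test_no_stop_codons_at_tips(self):
        tree = simulate_tree(6, seed=5, tree_height=0.4)
        aln = simulate_codon_alignment(tree, 1.0, 4, 0.6, 150, seed=6)
        for taxon in aln.taxa:
            assert not any(c in ("TAA", "TAG", "TGA")
                           for c in aln.codons(taxon))

    def test_neutral_omega_recovered_by_ng86(self):
        # two lineages, 0.2 substitutions/site apart, 3000 codons; kappa=1
        # because the counting estimator assumes unbiased mutation when
        # classifying sites
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        aln = simulate_codon_alignment(tree, omega=1.0, kappa=1.0, gc=0.5,
                                       length=3000, seed=11)
        r = codon_evol.ng86_dnds(aln.sequence("A"), aln.sequence("B"))
        assert r.omega == pytest.approx(1.0, abs=0.15)


class TestInjectPseudogene:
    def test_planted_stop_is_reported(self):
        tree = simulate_tree(4, seed=8, tree_height=0.1)
        aln = simulate_codon_alignment(tree, 0.2, 2, 0.5, 200, seed=8)
        mutated, truth = inject_pseudogene(aln, aln.taxa[0],
                                           stop_codon_positions=[168])
        report = codon_evol.pseudogene_screen(mutated, aln.taxa[0])
        assert [s.codon_index for s in report.internal_stops] == [168]
        assert truth.stop_codon_positions == (168,)

    def test_position_beyond_sequence_rejected(self, tiny_alignment):
        with pytest.raises(ValueError):
            inject_pseudogene(tiny_alignment, "A", stop_codon_positions=[99])

    @pytest.mark.parametrize("length,frameshift", [(4, True), (3, False)])
    def test_deletion_frameshift_rule(self, length, frameshift):
        tree = simulate_tree(4, seed=9, tree_height=0.1)
        aln = simulate_codon_alignment(tree, 0.2, 2, 0.5, 50, seed=9)
        ref = aln.taxa[1]
        mutated, _ = inject_pseudogene(aln, aln.taxa[0],
                                       deletions=[(10, length)])
        report = codon_evol.pseudogene_screen(mutated, aln.taxa[0], ref)
        if frameshift:
            assert len(report.frameshifts) == 1
            assert report.frameshifts[0].length == length
            assert not report.inframe_indels
        else:
            assert len(report.inframe_indels) == 1
            assert not report.frameshifts


class TestSimulateOmegaTable:
    def test_rho_one_matches_everywhere(self):
        table, truth = simulate_omega_table(["g1", "g2"], [f"s{i}" for i in range(48)],
                                            rho=1.0, seed=1)
        from opsinevol.coevolution import categorize_omegas
        cats = categorize_omegas(table)
        n, k = match_count(cats.data.loc["g1"], cats.data.loc["g2"])
        assert (truth.categories.loc["g1"] == truth.categories.loc["g2"]).all()
        assert n == 48
        # sample-quantile noise can flip boundary lineages; matches dominate
        assert k >= 40

    def test_independent_genes_match_at_6_16(self):
        species = [f"s{i}" for i in range(10_000)]
        _, truth = simulate_omega_table(["g1", "g2"], species, rho=0.0, seed=2)
        match = (truth.categories.loc["g1"] == truth.categories.loc["g2"]).mean()
        assert match == pytest.approx(6 / 16, abs=0.015)

    def test_marginal_category_frequencies(self):
        species = [f"s{i}" for i in range(10_000)]
        _, truth = simulate_omega_table(["g1"], species, seed=3)
        counts = truth.categories.loc["g1"].value_counts(normalize=True)
        assert counts["A"] == pytest.approx(0.25, abs=0.02)
        assert counts["C"] == pytest.approx(0.25, abs=0.02)
        assert counts["N"] == pytest.approx(0.50, abs=0.02)

    def test_seed_determinism_and_missingness(self):
        args = (["g1", "g2"], [f"s{i}" for i in range(30)])
        t1, _ = simulate_omega_table(*args, rho=0.3, seed=5, missingness=0.2)
        t2, _ = simulate_omega_table(*args, rho=0.3, seed=5, missingness=0.2)
        assert t1.data.equals(t2.data)
        assert t1.data.isna().to_numpy().sum() > 0


class TestSimulateTraits:
    def test_saturating_intercept_makes_all_vs(self):
        omegas = {f"s{i}": 0.01 * i for i in range(20)}
        traits = simulate_traits(omegas, beta0=50.0, beta1=0.0, seed=1)
        assert (traits.data == 1).all()

    def test_vs_probability_at_omega_zero(self):
        # published coefficients: P(VS | omega=0) = invlogit(4.44) = 0.988
        omegas = {f"s{i}": 0.0 for i in range(100_000)}
        traits = simulate_traits(omegas, beta0=4.44, beta1=-79.91, seed=2)
        assert traits.data.mean() == pytest.approx(0.988, abs=0.003)

    def test_seed_determinism(self):
        omegas = {f"s{i}": 0.02 for i in range(50)}
        a = simulate_traits(omegas, 4.44, -79.91, seed=7)
        b = simulate_traits(omegas, 4.44, -79.91, seed=7)
        assert a.data.equals(b.data)


class TestSimulateSiteclassPair:
    def test_explicit_pair_has_known_exceedance(self):
        b, m = simulate_siteclass_pair({0.1: 0.5, 0.9: 0.5}, {0.5: 1.0})
        assert prob_exceed_exact(b, m) == pytest.approx(0.5)

    def test_identical_atoms_never_exceed_strictly(self):
        b, m = simulate_siteclass_pair({0.3: 1.0}, {0.3: 1.0})
        assert prob_exceed_exact(b, m) == 0.0

    def test_random_pair_matches_enumeration_oracle(self):
        b, m = simulate_siteclass_pair(10, 10, seed=4)
        assert prob_exceed_exact(b, m) == pytest.approx(
            brute_prob_exceed(b, m), abs=1e-12)
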