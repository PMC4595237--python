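import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from opsinevol.codon_evol import (discretize_beta, fitch_ancestral_site, lrt,
                                  mean_omega_from_categories, ng86_dnds,
                                  omega_lineage_table, pseudogene_screen,
                                  reference_site_map, root_to_tip_omega)
from opsinevol.io_formats import CodonAlignment, SiteClassDistribution
from opsinevol.synthetic_data import (inject_pseudogene,
                                      simulate_codon_alignment, simulate_tree)

from .oracles import (GENETIC_CODE, STOPS, brute_ng86, exhaustive_min_changes,
                      sankoff_min_changes)

SENSE = sorted(c for c in GENETIC_CODE if c not in STOPS)


class TestMeanOmega:
    def test_single_class(self):
        d = SiteClassDistribution((0.2,), (1.0,))
        assert mean_omega_from_categories(d) == pytest.approx(0.2)

    def test_even_mixture(self):
        d = SiteClassDistribution((0.0, 1.0), (0.5, 0.5))
        assert mean_omega_from_categories(d) == pytest.approx(0.5)

    def test_m8_mixture_against_quadrature_oracle(self):
        # 0.9 * Beta(0.5, 2) classes + 0.1 * omega=1.5 class
        beta_part = discretize_beta(0.5, 2.0, 10)
        omegas = beta_part.omegas + (1.5,)
        props = tuple(0.9 * p for p in beta_part.proportions) + (0.1,)
        d = SiteClassDistribution(omegas, props)
        beta_mean, _ = integrate.quad(
            lambda x: x * stats.beta.pdf(x, 0.5, 2.0), 0, 1)
        assert mean_omega_from_categories(d) == pytest.approx(
            0.9 * beta_mean + 0.15, abs=1e-3)

    def test_linearity_in_proportions(self):
        omegas = (0.1, 0.4, 0.9)
        d1 = SiteClassDistribution(omegas, (0.2, 0.3, 0.5))
        d2 = SiteClassDistribution(omegas, (0.6, 0.2, 0.2))
        mixed = SiteClassDistribution(omegas, (0.4, 0.25, 0.35))
        assert mean_omega_from_categories(mixed) == pytest.approx(
            0.5 * mean_omega_from_categories(d1)
            + 0.5 * mean_omega_from_categories(d2))


class TestDiscretizeBeta:
    def test_uniform_closed_form(self):
        d = discretize_beta(1.0, 1.0, 4)
        assert d.omegas == pytest.approx((0.125, 0.375, 0.625, 0.875))
        assert d.proportions == pytest.approx((0.25,) * 4)

    def test_k1_is_the_mean(self):
        d = discretize_beta(2.0, 3.0, 1)
        assert d.omegas[0] == pytest.approx(2 / 5)

    @given(p=st.floats(0.1, 5.0), q=st.floats(0.1, 5.0),
           k=st.integers(1, 20))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_preserves_beta_mean_for_all_k(self, p, q, k):
        d = discretize_beta(p, q, k)
        assert mean_omega_from_categories(d) == pytest.approx(
            p / (p + q), abs=1e-9)


class TestLrt:
    def test_equal_likelihoods(self):
        r = lrt(-100.0, -100.0)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_chi_square_reference(self):
        r = lrt(-100.0, -98.08, df=1)
        assert r.statistic == pytest.approx(3.84)
        assert r.p_value == pytest.approx(0.050, abs=5e-4)

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            r = lrt(-99.0, -100.0)
        assert r.statistic == 0.0

    def test_mixture_null_halves_the_tail(self):
        plain = lrt(-100.0, -98.0, df=1)
        mixed = lrt(-100.0, -98.0, df=1, mixture=True)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)


class TestNg86:
    def test_synonymous_only_change(self):
        # Phe TTT->TTC with enough context codons that the synonymous
        # proportion stays inside the Jukes-Cantor domain
        r = ng86_dnds("TTT" * 5, "TTC" + "TTT" * 4)
        assert r.dn == 0.0
        assert r.ds > 0.0
        assert r.omega == 0.0

    def test_saturated_synonymous_proportion_is_undefined(self):
        # a single synonymous change in one codon saturates pS (> 3/4)
        r = ng86_dnds("TTT", "TTC")
        assert math.isnan(r.ds)

    def test_nonsynonymous_only_change(self):
        r = ng86_dnds("GCT", "GTT")
        assert r.dn > 0.0
        assert r.ds == 0.0
        assert math.isinf(r.omega)

    def test_identical_sequences_undefined_omega(self):
        r = ng86_dnds("ATGAAA", "ATGAAA")
        assert math.isnan(r.omega)

    def test_no_comparable_codons_is_an_error(self):
        with pytest.raises(ValueError):
            ng86_dnds("---", "ATG")

    def test_symmetry_is_exact(self):
        rng = np.random.default_rng(0)
        seq = lambda: "".join(rng.choice(SENSE, size=40))
        for _ in range(5):
            a, b = seq(), seq()
            assert ng86_dnds(a, b) == ng86_dnds(b, a)

    def test_matches_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(8):
            a = "".join(rng.choice(SENSE, size=300))
            # derive b by mutating a so divergence stays moderate
            b = list(a)
            for i in rng.choice(300, size=60, replace=False):
                b[3 * i: 3 * i + 3] = rng.choice(SENSE)
            b = "".join(b)
            mine = ng86_dnds(a, b)
            ref = brute_ng86(a, b)
            assert mine.dn == pytest.approx(ref[0], abs=1e-12)
            assert mine.ds == pytest.approx(ref[1], abs=1e-12)


class TestRootToTipOmega:
    def test_zero_branch_lengths_give_missing(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):0,(C:0,D:0):0);",
                                 schema="newick")
        aln = simulate_codon_alignment(tree, 0.5, 2, 0.5, 60, seed=1)
        assert math.isnan(root_to_tip_omega(aln, tree, "A"))

    def test_purifying_regime_forces_zero(self):
        tree = simulate_tree(6, seed=2, tree_height=0.3)
        aln = simulate_codon_alignment(tree, 0.0, 2, 0.5, 300, seed=2)
        for sp in aln.taxa[:3]:
            w = root_to_tip_omega(aln, tree, sp)
            assert w == 0.0 or math.isnan(w)

    def test_recovers_simulated_omega(self):
        tree = simulate_tree(48, seed=3, tree_height=0.4)
        aln = simulate_codon_alignment(tree, 0.5, 4, 0.5, 3000, seed=3)
        table = omega_lineage_table({"gene": aln}, tree)
        median = table.data.loc["gene"].median()
        assert median == pytest.approx(0.5, abs=0.15)

    def test_unknown_species_rejected(self, tiny_alignment):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:1);", schema="newick")
        with pytest.raises(KeyError):
            root_to_tip_omega(tiny_alignment, tree, "Z")


class TestPseudogeneScreen:
    def test_clean_sequence_empty_report(self):
        tree = simulate_tree(4, seed=4, tree_height=0.2)
        aln = simulate_codon_alignment(tree, 0.2, 2, 0.5, 150, seed=4)
        report = pseudogene_screen(aln, aln.taxa[0], aln.taxa[1])
        assert report.is_clean

    def test_terminal_stop_not_reported(self):
        aln = CodonAlignment(taxa=("A", "B"),
                             sequences=("ATGAAATAA", "ATGAAAAAA"))
        report = pseudogene_screen(aln, "A", "B")
        assert not report.internal_stops

    def test_planted_stop_reference_numbered(self):
        tree = simulate_tree(4, seed=5, tree_height=0.2)
        aln = simulate_codon_alignment(tree, 0.2, 2, 0.5, 400, seed=5)
        mutated, _ = inject_pseudogene(aln, aln.taxa[0],
                                       stop_codon_positions=[168])
        report = pseudogene_screen(mutated, aln.taxa[0], aln.taxa[1])
        (stop,) = report.internal_stops
        assert stop.codon_index == 168
        assert stop.ref_position == 168  # gapless reference: identity numbering

    def test_inframe_segmental_deletion(self):
        # a 12-nt (4 codon) deletion like the penguin S295-S298 loss
        tree = simulate_tree(4, seed=6, tree_height=0.2)
        aln = simulate_codon_alignment(tree, 0.2, 2, 0.5, 400, seed=6)
        mutated, _ = inject_pseudogene(aln, aln.taxa[0],
                                       deletions=[(3 * 294 + 1, 12)])
        report = pseudogene_screen(mutated, aln.taxa[0], aln.taxa[1])
        (indel,) = report.inframe_indels
        assert not report.frameshifts
        assert indel.length == 12
        assert indel.ref_start == 295

    def test_absent_taxon_rejected(self, tiny_alignment):
        with pytest.raises(KeyError):
            pseudogene_screen(tiny_alignment, "nope")


class TestReferenceSiteMap:
    def test_gapless_reference_is_identity(self):
        aln = CodonAlignment(taxa=("R", "X"),
                             sequences=("ATGAAA", "ATGAAG"))
        m = reference_site_map(aln, "R")
        assert all(m.position_of(c) == c for c in range(1, 7))

    def test_gap_shifts_numbering(self):
        from opsinevol.io_formats import SequenceAlignment
        aln = SequenceAlignment(taxa=("R", "X"), sequences=("M-K", "MAK"))
        m = reference_site_map(aln, "R")
        assert m.position_of(2) is None
        assert m.position_of(3) == 2
        assert m.column_of(2) == 3

    def test_round_trip_off_gaps(self):
        from opsinevol.io_formats import SequenceAlignment
        aln = SequenceAlignment(taxa=("R",), sequences=("MA--KLW-P",))
        m = reference_site_map(aln, "R")
        for col, pos in m.column_to_position.items():
            assert m.column_of(pos) == col


class TestFitchAncestralSite:
    def test_constant_character(self):
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        rec = fitch_ancestral_site(tree, {t: "M" for t in "ABCD"})
        assert rec.min_changes == 0
        assert rec.root_states == frozenset("M")

    def test_known_two_change_topology(self):
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        states = {"A": "T", "B": "T", "C": "M", "D": "A"}
        rec = fitch_ancestral_site(tree, states)
        assert rec.min_changes == 2
        assert rec.min_changes == exhaustive_min_changes(tree, states)

    def test_missing_tip_wildcard_vs_error(self):
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        states = {"A": "T", "B": "T", "C": "M"}
        rec = fitch_ancestral_site(tree, states)
        assert rec.min_changes == 1
        with pytest.raises(ValueError):
            fitch_ancestral_site(tree, states, missing="error")

    def test_assignment_achieves_minimum(self):
        tree = simulate_tree(8, seed=7)
        rng = np.random.default_rng(7)
        states = {l.taxon.label: rng.choice(list("ACDE"))
                  for l in tree.leaf_node_iter()}
        rec = fitch_ancestral_site(tree, states)
        realized = _count_assignment_changes(tree, rec)
        assert realized == rec.min_changes

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dp_oracle_on_random_trees(self, seed):
        tree = simulate_tree(12, seed=seed)
        rng = np.random.default_rng(seed)
        states = {l.taxon.label: rng.choice(list("ACGT"))
                  for l in tree.leaf_node_iter()}
        rec = fitch_ancestral_site(tree, states)
        assert rec.min_changes == sankoff_min_changes(tree, states)

    def test_matches_exhaustive_oracle_small_trees(self):
        for seed in range(4):
            tree = simulate_tree(6, seed=seed)
            rng = np.random.default_rng(seed + 10)
            states = {l.taxon.label: rng.choice(list("TMA"))
                      for l in tree.leaf_node_iter()}
            rec = fitch_ancestral_site(tree, states)
            assert rec.min_changes == exhaustive_min_changes(tree, states)
            assert rec.min_changes <= len(states) - 1


def _count_assignment_changes(tree, rec):
    labels = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            labels[node] = node.taxon.label
        else:
            labels[node] = node.label or f"node{counter}"
            counter += 1
    return sum(rec.assignment[labels[n]] != rec.assignment[labels[n.parent_node]]
               for n in tree.preorder_node_iter() if n.parent_node is not None)
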