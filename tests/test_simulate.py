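import numpy as np
import pandas as pd
import pytest

from _oracles import resimulate_dollo
from pseudolock.active_site import call_active_site
from pseudolock.biochem import alkylation_accessibility
from pseudolock.errors import InvalidArgumentError, NotFoundError
from pseudolock.simulate import (
    GeneSpec,
    sim_alkylation_table,
    sim_assay,
    sim_catalytic_msa,
    sim_dollo_character,
    sim_mutation_catalog,
    sim_profile_matrix,
    sim_tree,
)


class TestSimTree:
    def test_smallest_tree(self):
        tree = sim_tree(2, 7)
        assert len(tree.tips) == 2 and len(tree) == 3

    def test_node_count_formula(self):
        tree = sim_tree(8, 1)
        assert len(tree.tips) == 8
        assert len(tree) == 15  # 2n - 1 for a rooted binary tree

    def test_seeded_determinism(self):
        assert sim_tree(50, 3).to_newick() == sim_tree(50, 3).to_newick()

    def test_branch_lengths_positive_and_labels_unique(self):
        tree = sim_tree(20, 5)
        assert all(l > 0 for l in tree.branch_lengths.values())
        assert len(set(tree.nodes)) == len(tree)
        assert set(tree.tips) == {f"t{i}" for i in range(1, 21)}

    def test_too_few_tips_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sim_tree(1, 0)


class TestSimDolloCharacter:
    def test_zero_loss_rate_fills_gain_clade(self, balanced_tree8):
        node = balanced_tree8.children(balanced_tree8.root)[0]
        states, (gain, losses) = sim_dollo_character(balanced_tree8, node, 0.0, 3)
        clade = set(balanced_tree8.subtree_tips(node))
        assert losses == []
        assert all(states[t] == 1 for t in clade)
        assert all(states[t] == 0 for t in balanced_tree8.tips if t not in clade)

    def test_root_gain_zero_loss_all_present(self, balanced_tree8):
        states, _ = sim_dollo_character(balanced_tree8, balanced_tree8.root, 0.0, 3)
        assert all(s == 1 for s in states.values())

    def test_matches_independent_resimulation(self):
        tree = sim_tree(20, 9)
        for seed in range(20):
            states, (gain, losses) = sim_dollo_character(tree, tree.root, 0.1, seed)
            o_states, o_losses = resimulate_dollo(tree, tree.root, 0.1, seed)
            assert states == o_states
            assert losses == o_losses

    def test_losses_lie_within_gain_clade(self):
        tree = sim_tree(15, 2)
        node = tree.children(tree.root)[1]
        clade = set(tree.subtree_nodes(node)) - {node}
        for seed in range(30):
            _, (_, losses) = sim_dollo_character(tree, node, 0.3, seed)
            assert set(losses) <= clade

    def test_per_edge_loss_frequency_calibrated(self):
        """Empirical loss frequency on the first always-active edge over
        many replicates sits within 3 standard errors of loss_rate."""
        tree = sim_tree(8, 1)
        first_edge = tree.children(tree.root)[0]
        rate, n = 0.2, 10_000
        hits = sum(
            first_edge in sim_dollo_character(tree, tree.root, rate, s)[1][1]
            for s in range(n)
        )
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(hits / n - rate) < 3 * se

    def test_missing_fraction_masks_tips(self, balanced_tree8):
        states, _ = sim_dollo_character(
            balanced_tree8, balanced_tree8.root, 0.0, 4, missing_fraction=0.5
        )
        assert any(s is None for s in states.values())

    def test_unknown_edge_raises(self, balanced_tree8):
        with pytest.raises(NotFoundError):
            sim_dollo_character(balanced_tree8, "nope", 0.1, 0)

    def test_invalid_loss_rate_rejected(self, balanced_tree8):
        with pytest.raises(InvalidArgumentError):
            sim_dollo_character(balanced_tree8, balanced_tree8.root, 1.0, 0)


class TestSimProfileMatrix:
    def test_noiseless_coevolvers_copy_query(self):
        tree = sim_tree(20, 4)
        matrix, truth = sim_profile_matrix(tree, 10, 3, 0.0, 4)
        q = matrix.frame["query"]
        for gene in truth.coevolving_gene_ids:
            assert (matrix.frame[gene] == q).all()

    def test_no_coevolvers_empty_truth(self):
        tree = sim_tree(10, 1)
        _, truth = sim_profile_matrix(tree, 5, 0, 0.1, 1)
        assert truth.coevolving_gene_ids == []

    def test_matrix_shape_contract(self):
        tree = sim_tree(12, 11)
        matrix, _ = sim_profile_matrix(tree, 50, 3, 0.02, 11)
        assert matrix.frame.shape == (12, 51)

    def test_coevolving_exceeding_genes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sim_profile_matrix(sim_tree(5, 0), 2, 3, 0.0, 0)

    def test_determinism(self):
        tree = sim_tree(15, 8)
        m1, _ = sim_profile_matrix(tree, 20, 2, 0.05, 8)
        m2, _ = sim_profile_matrix(tree, 20, 2, 0.05, 8)
        assert m1.frame.equals(m2.frame)


class TestSimCatalyticMsa:
    def test_single_tip_pseudo_clade(self, balanced_tree8, site_model):
        tip = balanced_tree8.tips[0]
        _, truth = sim_catalytic_msa(balanced_tree8, site_model, tip, 3)
        pseudo = [s for s, c in truth.sequence_classes.items() if c == "pseudo"]
        assert pseudo == [tip]

    def test_classifier_round_trip_is_exact(self, balanced_tree8, site_model):
        clade = balanced_tree8.children(balanced_tree8.root)[0]
        aln, truth = sim_catalytic_msa(balanced_tree8, site_model, clade, 5)
        calls = {
            c.sequence_id: c.classification
            for c in call_active_site(aln, site_model)
        }
        for tip, cls in truth.sequence_classes.items():
            assert calls[tip] == cls

    def test_cysteine_appears_at_degraded_m2_position(self, balanced_tree8, site_model):
        # over replicates, the disallowed-substitution palette produces C
        # at an M2 aspartate position of some pseudo sequence
        clade = balanced_tree8.children(balanced_tree8.root)[0]
        m2_cols = [s.position for s in site_model.sites if s.role == "M2"]
        seen_c = False
        for seed in range(20):
            aln, truth = sim_catalytic_msa(balanced_tree8, site_model, clade, seed)
            for tip, cls in truth.sequence_classes.items():
                if cls == "pseudo" and any(aln[tip][p - 1] == "C" for p in m2_cols):
                    seen_c = True
        assert seen_c

    def test_determinism(self, balanced_tree8, site_model):
        a1, _ = sim_catalytic_msa(balanced_tree8, site_model, balanced_tree8.tips[0], 9)
        a2, _ = sim_catalytic_msa(balanced_tree8, site_model, balanced_tree8.tips[0], 9)
        assert a1 == a2

    def test_unknown_clade_raises(self, balanced_tree8, site_model):
        with pytest.raises(NotFoundError):
            sim_catalytic_msa(balanced_tree8, site_model, "zzz", 0)


class TestSimMutationCatalog:
    def test_zero_rates_empty_catalog(self):
        spec = GeneSpec("G", "neutral", 400, syn_rate=0.0, nonsyn_rate=0.0)
        catalog, _, _ = sim_mutation_catalog([spec], 50, seed=0)
        assert catalog.records.empty

    def test_hotspot_is_modal_codon(self):
        spec = GeneSpec.oncogene("ONC", 400, hotspot_codons=(200,))
        catalog, _, _ = sim_mutation_catalog([spec], 200, seed=2)
        missense = catalog.records.query("consequence == 'missense'")
        assert missense["position"].mode().iloc[0] == 200

    def test_tsg_cnl_dominates_cng(self):
        spec = GeneSpec("T", "tsg", 400, cnl_prob=0.8, cng_prob=0.05)
        _, cnv, _ = sim_mutation_catalog([spec], 200, seed=3)
        calls = cnv["T"]["call"]
        assert (calls == "loss").sum() > (calls == "gain").sum()

    def test_determinism(self):
        specs = [GeneSpec.tsg("A"), GeneSpec.neutral("B")]
        c1, v1, _ = sim_mutation_catalog(specs, 100, seed=4)
        c2, v2, _ = sim_mutation_catalog(specs, 100, seed=4)
        assert c1.records.equals(c2.records)
        assert all(v1[g].equals(v2[g]) for g in v1)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            GeneSpec("G", "neutral", 400, syn_rate=-1.0)

    def test_short_gene_rejected(self):
        with pytest.raises(InvalidArgumentError):
            GeneSpec("G", "neutral", 30)


class TestSimAlkylation:
    def test_all_exposed_when_no_buried(self):
        _, truth = sim_alkylation_table(0, 5, 6.0, seed=0)
        assert set(truth.cysteine_classes.values()) == {"exposed"}

    def test_separation_six_classified_perfectly(self):
        table, truth = sim_alkylation_table(4, 4, 6.0, seed=1)
        out = alkylation_accessibility(table)
        calls = dict(zip(out["residue"], out["call"]))
        assert all(calls[r] == c for r, c in truth.cysteine_classes.items())

    def test_determinism(self):
        t1, _ = sim_alkylation_table(3, 3, 4.0, seed=5)
        t2, _ = sim_alkylation_table(3, 3, 4.0, seed=5)
        assert t1.equals(t2)

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sim_alkylation_table(2, 2, 0.0, seed=0)


class TestSimAssay:
    def test_inhibitor_course_flat_when_only_contaminant(self):
        sim = sim_assay([0.0], 5e8, 0.01, 2e-11, True, noise_sd=0.0, seed=2)
        course = next(
            c["timecourse"] for c in sim.courses if c["condition"] == "inhibitor"
        )
        assert np.ptp(course.absorbance) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_slopes_exact(self):
        r = 4e-11
        sim = sim_assay([r], 5e8, 0.0, 0.0, False, noise_sd=0.0, seed=0)
        course = next(
            c["timecourse"] for c in sim.courses if c["condition"] == "untreated"
        )
        from pseudolock.biochem import timecourse_rate

        rate, warn = timecourse_rate(course, conversion_factor=1 / 5e8)
        assert not warn
        assert rate == pytest.approx(r, rel=1e-9)

    def test_determinism(self):
        s1 = sim_assay([1e-11], 5e8, 0.01, 1e-11, True, 0.002, seed=6)
        s2 = sim_assay([1e-11], 5e8, 0.01, 1e-11, True, 0.002, seed=6)
        assert s1.standards.equals(s2.standards)
        assert s1.endpoints.equals(s2.endpoints)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sim_assay([0.0], 1.0, 0.0, 0.0, False, -0.1, seed=0)
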