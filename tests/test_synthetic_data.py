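"""Generator determinism, simulation expectations, injection closure."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import replace

import pytest

from cptrna.cloverleaf import parse_structure, region_profile
from cptrna.synthetic_data import (ISOACCEPTOR_SET, SimConfig,
                                   evolve_trna_sequences, generate_cohort,
                                   inject_variants, make_trna_template,
                                   simulate_gene_family, simulate_k2p_alignment,
                                   simulate_species_tree)


class TestTemplate:
    def test_deterministic(self):
        a = make_trna_template("Phe", "GAA", seed=5)
        b = make_trna_template("Phe", "GAA", seed=5)
        assert a.sequence == b.sequence and a.dot_bracket == b.dot_bracket

    def test_psi_loop_uuc_core(self, phe_structure):
        loop = phe_structure.region_seq("t_loop")
        assert loop.startswith("UUC") and len(loop) == 7

    def test_bad_anticodon_rejected(self):
        with pytest.raises(ValueError):
            make_trna_template("Phe", "GXA")

    def test_watson_crick_stems(self, phe_structure):
        wc = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
        for i, j in phe_structure.pairs:
            assert (phe_structure.sequence[i], phe_structure.sequence[j]) in wc


class TestSpeciesTree:
    def test_two_species_cherry(self):
        tree = simulate_species_tree(2, 1.0, seed=1)
        assert len(tree.leaf_nodes()) == 2

    def test_seed_reproducibility(self):
        a = simulate_species_tree(8, 1.0, seed=4).as_string(schema="newick")
        b = simulate_species_tree(8, 1.0, seed=4).as_string(schema="newick")
        assert a == b

    def test_ultrametric(self):
        tree = simulate_species_tree(6, 1.0, seed=9)
        depths = {round(leaf.distance_from_root(), 9)
                  for leaf in tree.leaf_node_iter()}
        assert len(depths) == 1

    def test_depth_matches_yule_expectation(self):
        """Mean origin-to-tip depth over replicates matches the pure-birth
        expectation sum_{k=1}^{n-1} 1/(k rate): the epoch with k lineages
        lasts Exp(k rate), starting from a single lineage."""
        n, rate = 6, 2.0
        expected = sum(1.0 / (k * rate) for k in range(1, n))
        depths = []
        for rep in range(300):
            t = simulate_species_tree(n, rate, seed=rep)
            depths.append(next(t.leaf_node_iter()).distance_from_root())
        mean = sum(depths) / len(depths)
        assert mean == pytest.approx(expected, rel=0.15)


class TestGeneFamily:
    def test_zero_rates_congruent(self):
        sp = simulate_species_tree(5, 1.0, seed=2)
        gt, truth = simulate_gene_family(sp, 0.0, 0.0, seed=3, family="f")
        assert truth.family_events["f"] == (0, 0)
        leaves = sorted(l.taxon.label for l in gt.leaf_node_iter())
        assert leaves == [f"sp{k:02d}|copy1" for k in range(1, 6)]

    def test_heavy_loss_can_extinguish(self):
        sp = simulate_species_tree(4, 1.0, seed=2)
        extinct = 0
        for rep in range(20):
            gt, truth = simulate_gene_family(sp, 0.0, 50.0, seed=rep, family="f")
            extinct += gt is None
            assert truth.family_events["f"][1] >= 1
        assert extinct == 20

    def test_duplication_count_branching_expectation(self):
        """Duplications beget lineages that duplicate again: expected events
        per branch are exp(lam*d_bottom) - exp(lam*d_top), depths measured
        from the gene family's origin at the species root."""
        sp = simulate_species_tree(6, 1.0, seed=10)
        lam = 0.3
        off = sp.seed_node.distance_from_root()  # seed edge is not traversed
        expected = 0.0
        for node in sp.preorder_node_iter():
            if node.parent_node is None:
                continue
            d_bot = node.distance_from_root() - off
            d_top = node.parent_node.distance_from_root() - off
            expected += math.exp(lam * d_bot) - math.exp(lam * d_top)
        counts = []
        for rep in range(200):
            _, truth = simulate_gene_family(sp, lam, 0.0, seed=rep, family="f")
            counts.append(truth.family_events["f"][0])
        mean = sum(counts) / len(counts)
        assert mean == pytest.approx(expected, rel=0.15)


class TestSequenceEvolution:
    def test_rate_zero_identity(self):
        sp = simulate_species_tree(4, 1.0, seed=6)
        gt, _ = simulate_gene_family(sp, 0.0, 0.0, seed=1, family="f")
        tpl = make_trna_template("Glu", "UUC", seed=1)
        genes = evolve_trna_sequences(gt, tpl, rate=0.0, kappa=2.0, seed=2)
        assert all(g.sequence == tpl.sequence for g in genes)

    def test_infinite_kappa_only_transitions(self):
        sp = simulate_species_tree(4, 1.0, seed=6)
        gt, _ = simulate_gene_family(sp, 0.0, 0.0, seed=1, family="f")
        tpl = make_trna_template("Glu", "UUC", seed=1)
        genes = evolve_trna_sequences(gt, tpl, rate=0.5,
                                      kappa=float("inf"), p_comp=0.0, seed=3)
        ts = {frozenset("AG"), frozenset("CU")}
        changed = 0
        for g in genes:
            for a, b in zip(tpl.sequence, g.sequence):
                if a != b:
                    changed += 1
                    assert frozenset((a, b)) in ts
        assert changed > 0

    def test_anticodon_frozen(self):
        sp = simulate_species_tree(4, 1.0, seed=6)
        gt, _ = simulate_gene_family(sp, 0.0, 0.0, seed=1, family="f")
        tpl = make_trna_template("Tyr", "GUA", seed=1)
        from cptrna.cloverleaf import extract_anticodon
        for g in evolve_trna_sequences(gt, tpl, rate=2.0, kappa=2.0, seed=4):
            triplet, _ = extract_anticodon(parse_structure(g))
            assert triplet == "GUA"

    def test_compensatory_preserves_pairing(self):
        sp = simulate_species_tree(4, 1.0, seed=6)
        gt, _ = simulate_gene_family(sp, 0.0, 0.0, seed=1, family="f")
        tpl = make_trna_template("Glu", "UUC", seed=1)
        wc = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
              ("G", "U"), ("U", "G")}
        genes = evolve_trna_sequences(gt, tpl, rate=0.3, kappa=2.0,
                                      p_comp=1.0, seed=5)
        cl = parse_structure(tpl)
        for g in genes:
            for i, j in cl.pairs:
                assert (g.sequence[i], g.sequence[j]) in wc


class TestInjection:
    def test_zero_probabilities_identity(self, small_cohort):
        _, _, genes, _, _ = small_cohort
        out, truth = inject_variants(genes[:20], 0, 0, 0, 0, seed=1)
        assert [g.sequence for g in out] == [g.sequence for g in genes[:20]]
        assert all(str(t) == "Normal" for t in truth.values())

    def test_all_type3(self, phe_template):
        from cptrna.cloverleaf import StructuralType, classify_structure
        genes, _ = inject_variants([phe_template] * 10, 0, 0, 1, 0, seed=2)
        for g in genes:
            assert classify_structure(parse_structure(g)) is StructuralType.TYPE3

    def test_all_type1_ac_arm_zero(self, phe_template):
        genes, _ = inject_variants([phe_template] * 10, 1, 0, 0, 0, seed=3)
        for g in genes:
            assert region_profile(parse_structure(g)).ac_arm == 0

    def test_probability_overflow_rejected(self, phe_template):
        with pytest.raises(ValueError):
            inject_variants([phe_template], 0.5, 0.5, 0.5, 0.0)


class TestCohort:
    def test_bit_identical_reruns(self):
        cfg = SimConfig(n_species=4, seed=13)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert [g.sequence for g in a[1]] == [g.sequence for g in b[1]]
        assert a[0].as_string(schema="newick") == b[0].as_string(schema="newick")
        assert a[2].family_events == b[2].family_events

    def test_gene_count_envelope(self, small_cohort):
        _, _, genes, _, _ = small_cohort
        per_sp = Counter(g.species for g in genes)
        assert all(27 <= n <= 39 for n in per_sp.values())

    def test_lengths_within_accepted_range(self, small_cohort):
        _, _, genes, _, _ = small_cohort
        assert all(50 <= len(g.sequence) <= 120 for g in genes)

    def test_isoacceptor_set_has_33_families(self):
        assert len(ISOACCEPTOR_SET) == 33
        assert len(set(ISOACCEPTOR_SET)) == 33

    def test_truth_covers_every_gene(self, small_cohort):
        _, _, genes, truth, _ = small_cohort
        assert set(truth.structural_types) == {g.gene_id for g in genes}


class TestK2PAlignmentSimulator:
    def test_deterministic(self):
        t = simulate_species_tree(5, 1.0, seed=3)
        a = simulate_k2p_alignment(t, 100, 0.1, 2.0, seed=4)
        b = simulate_k2p_alignment(t, 100, 0.1, 2.0, seed=4)
        assert a == b

    def test_rate_zero_identical_leaves(self):
        t = simulate_species_tree(5, 1.0, seed=3)
        aln = simulate_k2p_alignment(t, 200, 0.0, 2.0, seed=4)
        assert len(set(aln.values())) == 1
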