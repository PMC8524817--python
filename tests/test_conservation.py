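"""Frequency tables, histograms, the simple aligner, consensus calling."""

from __future__ import annotations

import itertools
import random

import pytest

from cptrna.cloverleaf import RegionProfile, parse_structure
from cptrna.conservation import (Alignment, align_isotype_regions,
                                 anticodon_presence_counts, call_consensus,
                                 isotype_frequency_matrix, length_stats,
                                 region_length_distribution)
from cptrna.io_formats import TRNAGene
from cptrna.synthetic_data import make_trna_template


def _gene(gid, species, isotype, anticodon=None, n=70):
    t = make_trna_template(isotype, anticodon or "GAA", seed=1)
    return TRNAGene(gene_id=gid, species=species, sequence=t.sequence,
                    isotype=isotype, anticodon=anticodon)


class TestFrequencyTables:
    def test_two_species_matrix(self):
        genes = [_gene(f"{sp}{k}", sp, iso, ac)
                 for sp in ("spA", "spB")
                 for k, (iso, ac) in enumerate(
                     [("Ala", "UGC")] + [("Ser", "GGA")] * 3)]
        ft = isotype_frequency_matrix(genes)
        assert ft.isotype_by_species.values.tolist() == [[1, 3], [1, 3]]
        assert ft.totals.tolist() == [4, 4]
        assert ft.mean_genes_per_species == 4.0

    def test_empty_input(self):
        ft = isotype_frequency_matrix([])
        assert ft.isotype_by_species.empty

    def test_synthetic_cohort_mean(self, small_cohort):
        _, _, genes, _, _ = small_cohort
        ft = isotype_frequency_matrix(genes)
        # 33 isoacceptor families target ~33 genes/species
        assert 27 <= ft.mean_genes_per_species <= 39


class TestAnticodonPresence:
    def test_presence_not_copy_count(self):
        genes = [_gene("a1", "sp1", "Ala", "UGC"),
                 _gene("a2", "sp1", "Ala", "UGC"),
                 _gene("a3", "sp2", "Ala", "UGC")]
        counts = anticodon_presence_counts(genes, n_species=3)
        assert counts[("Ala", "UGC")] == 2

    def test_universal_anticodon(self, small_cohort):
        cfg, _, genes, _, _ = small_cohort
        counts = anticodon_presence_counts(genes, n_species=cfg.n_species)
        assert counts[("Trp", "CCA")] == cfg.n_species

    def test_cau_isotypes_kept_separate(self, small_cohort):
        cfg, _, genes, _, _ = small_cohort
        counts = anticodon_presence_counts(genes, n_species=cfg.n_species)
        assert ("Met", "CAU") in counts and ("Ile", "CAU") in counts


class TestRegionHistograms:
    def _profile(self, ac_arm):
        return RegionProfile("g", ac_arm, 4, 8, 5, 7, 5, 5, 7, True, 0, 70)

    def test_counts_and_percentages(self):
        profs = [self._profile(7)] * 3 + [self._profile(6)]
        hist = region_length_distribution(profs)
        assert hist["ac_arm"] == {6: (1, 25.0), 7: (3, 75.0)}

    def test_published_scale_percentages(self):
        # 1659 seven-bp acceptor arms out of 1779 genes -> 93.25%
        profs = [self._profile(7)] * 1659 + [self._profile(6)] * 120
        hist = region_length_distribution(profs)
        assert hist["ac_arm"][7] == (1659, 93.25)

    def test_counts_sum_to_n(self, small_cohort):
        _, _, genes, _, _ = small_cohort
        profs = [parse_structure(g) for g in genes]
        profs = [__import__("cptrna.cloverleaf", fromlist=["region_profile"])
                 .region_profile(c) for c in profs]
        hist = region_length_distribution(profs)
        for region, d in hist.items():
            assert sum(c for c, _ in d.values()) == len(profs)


class TestLengthStats:
    def test_examples(self):
        mk = lambda n: TRNAGene(gene_id=f"g{n}", species="s", sequence="A" * n)
        assert length_stats([mk(56), mk(90)]) == (56, 90, 73.0)
        assert length_stats([mk(73)] * 3) == (73, 73, 73.0)
        assert length_stats([mk(88)]) == (88, 88, 88.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            length_stats([])


# ---------------------------------------------------------------------------
# Aligner

def _brute_force_pairwise(a: str, b: str, match=2.0, mismatch=-1.0,
                          gap_open=-12.0, gap_extend=-2.0) -> float:
    """Exhaustive optimal global alignment score via recursion over all
    alignment paths with affine gap costs (exponential; tiny inputs only)."""
    best = [float("-inf")]

    def go(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch), "M")
        if i < len(a):
            pen = gap_extend if state == "A" else gap_open
            go(i + 1, j, score + pen, "A")
        if j < len(b):
            pen = gap_extend if state == "B" else gap_open
            go(i, j + 1, score + pen, "B")

    go(0, 0, 0.0, "M")
    return best[0]


def _alignment_score(row_a: str, row_b: str, match=2.0, mismatch=-1.0,
                     gap_open=-12.0, gap_extend=-2.0) -> float:
    score = 0.0
    prev = "M"
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            score += match if x == y else mismatch
            prev = "M"
        else:
            state = "A" if y == "-" else "B"
            score += gap_extend if state == prev else gap_open
            prev = state
    return score


class TestAligner:
    def test_identical_sequences(self):
        aln = align_isotype_regions(["GCUC", "GCUC"])
        assert aln.rows == ["GCUC", "GCUC"]
        for col in aln.column_frequencies():
            assert max(col.values()) == 1.0

    def test_gapped_pair_matches_exhaustive_optimum(self):
        aln = align_isotype_regions(["GCUC", "GCC"])
        assert aln.n_cols == 4
        assert sum(1 for c in aln.rows[1] if c == "-") == 1
        ours = _alignment_score(aln.rows[0], aln.rows[1])
        assert ours == _brute_force_pairwise("GCUC", "GCC")

    @pytest.mark.parametrize("a,b", [
        ("GGAGA", "GGGA"), ("ACGUA", "ACUA"), ("UUCGA", "UUCG"),
        ("GCGGAUU", "GCGAUU"),
    ])
    def test_random_pairs_reach_optimum(self, a, b):
        aln = align_isotype_regions([a, b])
        ours = _alignment_score(aln.rows[0], aln.rows[1])
        assert ours == _brute_force_pairwise(a, b)

    def test_single_sequence_passthrough(self):
        assert align_isotype_regions(["ACGU"]).rows == ["ACGU"]

    def test_identical_psi_loops_give_invariant_columns(self):
        aln = align_isotype_regions(["UUCGAAU"] * 54)
        motif = call_consensus(aln)
        assert str(motif) == "U-U-C-G-A-A-U"


class TestConsensus:
    def _aln_from_columns(self, cols: list[dict[str, int]], n: int) -> Alignment:
        rows = ["" for _ in range(n)]
        for col in cols:
            chars = list(itertools.chain.from_iterable(
                [b] * c for b, c in col.items()))
            assert len(chars) == n
            for r in range(n):
                rows[r] += chars[r]
        return Alignment(rows=rows)

    def test_token_rules(self):
        aln = self._aln_from_columns(
            [{"G": 20},                       # invariant
             {"C": 12, "U": 7, "A": 1},       # C/U alternative (0.95 >= 0.9)
             {"A": 8, "C": 6, "G": 6}],       # no call
            n=20)
        motif = call_consensus(aln)
        assert motif.columns == ["G", "C/U", "X"]

    def test_monotonicity_in_high(self):
        """Raising `high` never converts an X token into a base token."""
        rng = random.Random(3)
        rows = ["".join(rng.choice("AACGU") for _ in range(30)) for _ in range(12)]
        aln = Alignment(rows=rows)
        for lo, hi in [(0.6, 0.8), (0.8, 0.9), (0.9, 0.99)]:
            a = call_consensus(aln, high=lo).columns
            b = call_consensus(aln, high=hi).columns
            for ta, tb in zip(a, b):
                if ta.startswith("X"):
                    assert tb.startswith("X")

    def test_gap_run_collapse_notation(self):
        aln = Alignment(rows=["AC--G", "ACU-G", "AC-UG"])
        motif = call_consensus(aln)
        assert motif.columns == ["A", "C", "X_0-1", "G"]

    def test_template_recovery_at_low_divergence(self):
        """<= 5% per-site divergence keeps >= 95% template columns."""
        rng = random.Random(8)
        template = make_trna_template("Glu", "UUC", seed=2).sequence
        rows = []
        for _ in range(54):
            seq = list(template)
            for k in range(len(seq)):
                if rng.random() < 0.05:
                    seq[k] = rng.choice("ACGU")
            rows.append("".join(seq))
        motif = call_consensus(align_isotype_regions(rows), high=0.90, low=0.50)
        hits = sum(1 for tok, base in zip(motif.columns, template) if tok == base)
        assert hits / len(template) >= 0.95
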