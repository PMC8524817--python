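"""K2P distances, pattern tables, kappa recovery, and NJ correctness."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest
import dendropy

from cptrna.evolution import (distance_matrix, estimate_kappa, k2p_distance,
                              k2p_pq, nj_tree, pattern_row)
from cptrna.synthetic_data import simulate_k2p_alignment, simulate_species_tree


class TestK2PCounts:
    def test_identical_sequences(self):
        assert k2p_pq("ACGU", "ACGU") == (0.0, 0.0, 4)

    def test_transition(self):
        P, Q, n = k2p_pq("AG", "GG")
        assert (P, Q, n) == (0.5, 0.0, 2)

    def test_transversions(self):
        P, Q, n = k2p_pq("AC", "CA")
        assert (P, Q, n) == (0.0, 1.0, 2)

    def test_pairwise_deletion(self):
        P, Q, n = k2p_pq("A-GU", "AC-U")
        assert n == 2 and P == 0.0 and Q == 0.0

    def test_all_gapped_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p_pq("--", "AA")


class TestK2PDistance:
    def test_zero(self):
        assert k2p_distance(0.0, 0.0) == 0.0

    def test_closed_form_value(self):
        # independent numeric evaluation:
        # -0.5 ln(0.75) - 0.25 ln(0.9) = 0.170183...
        assert k2p_distance(0.1, 0.05) == pytest.approx(0.170183, abs=1e-5)

    def test_small_distance_limit(self):
        for P in (1e-4, 1e-5):
            assert k2p_distance(P, 0.0) == pytest.approx(P, rel=1e-3)

    def test_saturation_errors(self):
        with pytest.raises(ValueError, match="saturated"):
            k2p_distance(0.5, 0.2)


class TestPatternTable:
    def test_all_transitions_row(self):
        # an alignment whose differences are exclusively transitions
        pat = estimate_kappa(["AAAA", "GAAA"])
        assert (pat.ts_entry, pat.tv_entry) == (25.0, 0.0)

    def test_kappa_two_closed_form(self):
        assert pattern_row(2.0) == (12.5, 6.25)

    def test_published_alanine_row_self_consistency(self):
        # printed entries (12.53, 6.23) satisfy ts + 2 tv = 24.99 ~ 25
        assert 12.53 + 2 * 6.23 == pytest.approx(25.0, abs=0.01)

    def test_row_sum_invariant_on_estimates(self):
        rng = random.Random(2)
        for _ in range(25):
            seqs = ["".join(rng.choice("ACGU") for _ in range(60))
                    for _ in range(4)]
            pat = estimate_kappa(seqs)
            if pat.defined:
                assert pat.ts_entry + 2 * pat.tv_entry == pytest.approx(25.0, abs=0.01)

    def test_undefined_without_variation(self):
        pat = estimate_kappa(["ACGU" * 5] * 3)
        assert not pat.defined

    def test_transition_bias_preserved(self):
        """kappa > 1 in simulation always yields ts_entry > tv_entry."""
        for rep in range(10):
            tree = simulate_species_tree(8, 1.0, seed=300 + rep)
            aln = simulate_k2p_alignment(tree, 500, 0.1, 4.0, seed=400 + rep)
            pat = estimate_kappa(list(aln.values()))
            assert pat.ts_entry > pat.tv_entry


class TestKappaRecovery:
    @pytest.mark.parametrize("true_kappa", [2.0, 5.0])
    def test_recovery_within_ten_percent(self, true_kappa):
        """>= 90% of 50 replicates (10 taxa, 2000 sites) within 10%."""
        ok = 0
        for rep in range(50):
            tree = simulate_species_tree(10, 1.0, seed=1000 + rep)
            aln = simulate_k2p_alignment(tree, 2000, 0.2, true_kappa,
                                         seed=2000 + rep)
            pat = estimate_kappa(list(aln.values()))
            ok += abs(pat.kappa - true_kappa) / true_kappa <= 0.10
        assert ok >= 45


# ---------------------------------------------------------------------------
# Neighbor joining

def _tree_paths(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


def _additive_matrix(newick: str, labels: list[str]):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    paths = _tree_paths(tree)
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = paths[frozenset((labels[i], labels[j]))]
    return m


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(taxa) - 1:
            out.add(min(below, frozenset(taxa - below),
                        key=lambda s: (len(s), sorted(s))))
    return out


class TestNJ:
    def test_three_taxa_three_point_formulas(self):
        labels = ["a", "b", "c"]
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(labels, m)
        lens = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lens == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_four_taxon_additive_recovery(self):
        labels = ["a", "b", "c", "d"]
        newick = "((a:1,b:2):3,(c:4,d:5):1);"
        m = _additive_matrix(newick, labels)
        tree = nj_tree(labels, m)
        # exact topology
        assert _bipartitions(tree) == {frozenset(("a", "b"))}
        # exact path lengths (NJ is consistent on additive input)
        assert _tree_paths(tree) == pytest.approx(
            _tree_paths(dendropy.Tree.get(data=newick, schema="newick")))

    def test_five_taxon_random_additive_vs_exhaustive_oracle(self):
        """NJ topology matches brute-force minimum evolution over all 15
        unrooted 5-taxon topologies (least-squares fitted lengths)."""
        rng = random.Random(17)
        labels = list("abcde")
        for _ in range(10):
            bl = [round(rng.uniform(0.5, 5.0), 2) for _ in range(7)]
            newick = (f"((a:{bl[0]},b:{bl[1]}):{bl[2]},c:{bl[3]},"
                      f"(d:{bl[4]},e:{bl[5]}):{bl[6]});")
            m = _additive_matrix(newick, labels)
            got = _bipartitions(nj_tree(labels, m))
            best = _min_evolution_oracle(labels, m)
            assert got == best

    def test_against_scikit_bio(self):
        """Independent implementation cross-check on a non-additive matrix."""
        skbio = pytest.importorskip("skbio")
        rng = random.Random(23)
        labels = [f"t{k}" for k in range(6)]
        base = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            base[i, j] = base[j, i] = rng.uniform(0.2, 2.0)
        ours = nj_tree(labels, base)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(base, labels))
        t2 = dendropy.Tree.get(data=str(theirs), schema="newick")
        assert _bipartitions(ours) == _bipartitions(t2)

    def test_nonfinite_rejected(self):
        m = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(["a", "b", "c"], m)

    def test_distance_matrix_from_alignment(self):
        labels, dm = distance_matrix(["x", "y"], ["AAAA", "AGAA"])
        assert dm[0, 1] == pytest.approx(k2p_distance(0.25, 0.0))


def _min_evolution_oracle(labels, m) -> set[frozenset]:
    """Brute force: enumerate all 15 unrooted 5-taxon topologies, fit branch
    lengths by unweighted least squares, pick the minimum total length."""
    import numpy.linalg as la
    best = None
    for perm_split in _five_taxon_topologies(labels):
        # topology given as its two nontrivial bipartitions
        paths = _topology_path_matrix(labels, perm_split)
        A, idx = paths
        d = np.array([m[i, j] for i, j in idx])
        x, *_ = la.lstsq(A, d, rcond=None)
        resid = A @ x - d
        if np.abs(resid).max() > 1e-8:
            continue  # not the generating topology: cannot fit additively
        total = x.sum()
        if best is None or total < best[0] - 1e-12:
            best = (total, perm_split)
    return {frozenset(p) for p in best[1]}


def _five_taxon_topologies(labels):
    """All 15 unrooted binary topologies on 5 taxa, each identified by its
    two cherries (nontrivial bipartitions of size 2)."""
    seen = []
    for pair1 in itertools.combinations(labels, 2):
        rest = [l for l in labels if l not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            key = {frozenset(pair1), frozenset(pair2)}
            if key not in seen:
                seen.append(key)
    return [tuple(tuple(sorted(p)) for p in sorted(k, key=sorted))
            for k in seen]


def _topology_path_matrix(labels, cherries):
    """Design matrix mapping the 7 branch lengths of a 5-taxon caterpillar
    (two cherries + one free leaf + internal edges) to pairwise paths."""
    (a, b), (d, e) = cherries
    (c,) = [l for l in labels if l not in (a, b, d, e)]
    # edges: a, b, c, d, e leaf edges + 2 internal edges (cherry1-mid, mid-cherry2)
    edge_index = {a: 0, b: 1, c: 2, d: 3, e: 4, "i1": 5, "i2": 6}

    def path(x, y):
        row = np.zeros(7)
        row[edge_index[x]] += 1
        row[edge_index[y]] += 1
        in1 = {a, b}
        in2 = {d, e}
        if (x in in1) != (y in in1):
            row[5] += 1
        if (x in in2) != (y in in2):
            row[6] += 1
        return row

    pairs = list(itertools.combinations(sorted(labels), 2))
    idx = [(sorted(labels).index(x), sorted(labels).index(y)) for x, y in pairs]
    A = np.array([path(x, y) for x, y in pairs])
    return (A, idx)
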