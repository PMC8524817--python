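"""Kimura two-parameter distances, substitution-pattern tables and NJ trees.

The K2P model has one transition rate (alpha) and one transversion rate per
target base (beta), equal base frequencies.  From the observed proportions
of transition differences P and transversion differences Q between two
aligned sequences:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and the per-site transition and transversion components

    s = -1/2 ln(1 - 2P - Q) + 1/4 ln(1 - 2Q)
    v = -1/2 ln(1 - 2Q)

give kappa = alpha/beta = 2 s / v.  The pattern table prints x100
substitution probabilities under equal base frequencies, so each row holds
one transition cell ts = 25 kappa/(kappa+2) and two transversion cells
tv = 25/(kappa+2); every row sums to 25 and the 4x4 table to 100.

kappa is estimated by pooling transition/transversion difference counts
over all unordered sequence pairs (pairwise deletion of gapped sites): a
closed-form, seed-free approximation to maximum-likelihood pattern
estimation; the deviation is documented in the methods note.

Neighbor joining follows Saitou & Nei with deterministic lexicographic
tie-breaking, so identical inputs always yield identical trees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from ._util import is_transition, is_transversion

__all__ = [
    "SubstitutionPattern",
    "k2p_pq",
    "k2p_distance",
    "estimate_kappa",
    "pattern_row",
    "distance_matrix",
    "nj_tree",
]

_GAPS = set("-.~NX")


@dataclass
class SubstitutionPattern:
    """Pooled transition/transversion pattern for one isotype (or overall)."""

    isotype: str
    P: float
    Q: float
    kappa: float
    ts_entry: float
    tv_entry: float
    n_sites: int
    defined: bool = True


def k2p_pq(seq_a: str, seq_b: str) -> tuple[float, float, int]:
    """Observed transition (P) and transversion (Q) difference proportions.

    Sites where either sequence has a gap/ambiguity are excluded (pairwise
    deletion).  Zero comparable sites is an error.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    ts = tv = n = 0
    for a, b in zip(seq_a, seq_b):
        if a in _GAPS or b in _GAPS:
            continue
        n += 1
        if is_transition(a, b):
            ts += 1
        elif is_transversion(a, b):
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return ts / n, tv / n, n


def k2p_distance(P: float, Q: float) -> float:
    """K2P distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q); errors on saturation."""
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(
            f"K2P distance undefined (saturated) for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pattern_row(kappa: float) -> tuple[float, float]:
    """(ts, tv) pattern-table entries on the x100 scale: row sums to 25."""
    if math.isinf(kappa):
        return 25.0, 0.0
    return 25.0 * kappa / (kappa + 2.0), 25.0 / (kappa + 2.0)


def pooled_difference_counts(alignment: list[str]) -> tuple[int, int, int]:
    """(transition, transversion, comparable-site) counts pooled over all
    unordered sequence pairs with pairwise deletion.  Vectorized."""
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in alignment}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in alignment]
    valid = [np.isin(a, (b"A", b"C", b"G", b"U")) for a in arrs]
    purine = [np.isin(a, (b"A", b"G")) for a in arrs]
    ts = tv = n = 0
    for i, j in itertools.combinations(range(len(alignment)), 2):
        ok = valid[i] & valid[j]
        diff = (arrs[i] != arrs[j]) & ok
        same_class = purine[i] == purine[j]
        n += int(ok.sum())
        ts += int((diff & same_class).sum())
        tv += int((diff & ~same_class).sum())
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return ts, tv, n


def alignment_sv(alignment: list[str]) -> tuple[float, float, int, int, int]:
    """Summed per-pair transition/transversion components of an alignment.

    For every unordered pair the observed P, Q go through the K2P closed
    forms for the per-site transition component s and transversion
    component v; the pair components are summed (applying the log
    correction per pair keeps the estimate unbiased when pair distances
    are heterogeneous).  Saturated pairs are skipped.  Returns
    (S, V, pooled transition count, pooled transversion count, pooled sites).
    """
    S = V = 0.0
    ts_all = tv_all = n_all = 0
    for a, b in itertools.combinations(alignment, 2):
        P, Q, n = k2p_pq(a, b)
        ts_all += round(P * n)
        tv_all += round(Q * n)
        n_all += n
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            continue  # saturated pair carries no usable signal
        S += -0.5 * math.log(w1) + 0.25 * math.log(w2)
        V += -0.5 * math.log(w2)
    return S, V, ts_all, tv_all, n_all


def pattern_from_sv(S: float, V: float, ts: int, tv: int, n: int,
                    isotype: str = "overall") -> SubstitutionPattern:
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    if ts == 0 and tv == 0:
        return SubstitutionPattern(isotype, 0.0, 0.0, float("nan"),
                                   float("nan"), float("nan"), n, defined=False)
    kappa = float("inf") if V == 0.0 else max(0.0, 2.0 * S / V)
    tse, tve = pattern_row(kappa)
    return SubstitutionPattern(isotype, P, Q, kappa, tse, tve, n)


def estimate_kappa(alignment: list[str], isotype: str = "overall") -> SubstitutionPattern:
    """Kappa estimate over an alignment of >= 2 sequences (pairwise deletion).

    Transition/transversion components are computed per unordered pair via
    the K2P closed forms and summed; kappa = 2 sum(s) / sum(v).  Q = 0
    everywhere yields kappa = +inf (ts 25.00 / tv 0.00); an alignment with
    no variable sites is flagged undefined.  ``P`` and ``Q`` report the
    pooled difference proportions.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    return pattern_from_sv(*alignment_sv(alignment), isotype)


def distance_matrix(labels: list[str], sequences: list[str]) -> tuple[list[str], np.ndarray]:
    """Symmetric K2P distance matrix over aligned sequences."""
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        P, Q, _ = k2p_pq(sequences[i], sequences[j])
        try:
            d[i, j] = d[j, i] = k2p_distance(P, Q)
        except ValueError as exc:
            raise ValueError(f"{labels[i]} vs {labels[j]}: {exc}") from exc
    return labels, d


def nj_tree(labels: list[str], matrix: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted tree, deterministic tie-breaks.

    Ties in the Q criterion are broken by the lexicographically smallest
    (label_i, label_j) pair, where a cluster is represented by its smallest
    member label.  Three-taxon inputs use the three-point formulas directly.
    Branch lengths are kept as computed (they may be negative for
    non-additive input).
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite distances")
    n = len(labels)
    if n < 3:
        raise ValueError("need at least three taxa")
    # active clusters: newick fragment + representative (min) label
    nodes = {k: (labels[k], labels[k]) for k in range(n)}
    d = {(i, j): matrix[i, j] for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_id = n

    def dist(i, j):
        return d[(i, j)] if i != j else 0.0

    while len(active) > 2:
        if len(active) == 3:
            i, j, k = active
            # connect the last three clusters to a central node
            li = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
            lj = 0.5 * (dist(j, i) + dist(j, k) - dist(i, k))
            lk = 0.5 * (dist(k, i) + dist(k, j) - dist(i, j))
            newick = (f"({nodes[i][0]}:{li:.10g},{nodes[j][0]}:{lj:.10g},"
                      f"{nodes[k][0]}:{lk:.10g});")
            return dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        r = len(active)
        totals = {i: sum(dist(i, j) for j in active if j != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (r - 2) * dist(i, j) - totals[i] - totals[j]
            key = (q,) + tuple(sorted((nodes[i][1], nodes[j][1])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * dist(i, j) + (totals[i] - totals[j]) / (2.0 * (r - 2))
        lj = dist(i, j) - li
        new = next_id
        next_id += 1
        rep = min(nodes[i][1], nodes[j][1])
        nodes[new] = (f"({nodes[i][0]}:{li:.10g},{nodes[j][0]}:{lj:.10g})", rep)
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
            d[(new, k)] = d[(k, new)] = dk
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active  # only reached for n == 2 (excluded above), defensive
    newick = f"({nodes[i][0]}:{dist(i, j):.10g},{nodes[j][0]}:0);"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
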