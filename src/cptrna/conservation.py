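"""Frequency, length-distribution and consensus-motif analyses.

Covers four analyses over a cohort of annotated tRNA genes:

* species x isotype gene-count matrices with per-species totals;
* anticodon presence counts (number of species carrying at least one copy,
  not gene-copy totals; Ile-CAU and Met-CAU are tallied separately);
* per-region length histograms with percentages;
* consensus motifs per isoacceptor region, called from a progressive
  global alignment at a high/low threshold pair (defaults 0.90 / 0.50).

The aligner is deliberately simple: progressive pairwise profile alignment
with affine gaps (match +2, mismatch -1, gap open -12, gap extend -2),
guide order = input order.  Region subsequences are short and near
identical, so any sane global aligner recovers the same columns; the scores
are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_away
from .cloverleaf import RegionProfile
from .io_formats import TRNAGene

__all__ = [
    "FrequencyTables",
    "Alignment",
    "ConsensusMotif",
    "isotype_frequency_matrix",
    "anticodon_presence_counts",
    "region_length_distribution",
    "length_stats",
    "align_isotype_regions",
    "call_consensus",
]


@dataclass
class FrequencyTables:
    """Species x isotype counts, per-species totals, and the cohort mean."""

    isotype_by_species: pd.DataFrame
    totals: pd.Series
    mean_genes_per_species: float


def isotype_frequency_matrix(genes: list[TRNAGene]) -> FrequencyTables:
    """Count genes per (species, isotype); genes without a species label are
    excluded with a warning."""
    import warnings
    rows = []
    for g in genes:
        if not g.species:
            warnings.warn(f"{g.gene_id}: no species label; excluded")
            continue
        rows.append((g.species, g.isotype or "?"))
    if not rows:
        empty = pd.DataFrame()
        return FrequencyTables(empty, pd.Series(dtype=int), float("nan"))
    df = pd.DataFrame(rows, columns=["species", "isotype"])
    mat = (df.value_counts().unstack(fill_value=0)
           .sort_index(axis=0).sort_index(axis=1))
    totals = mat.sum(axis=1)
    return FrequencyTables(mat, totals, float(totals.mean()))


def anticodon_presence_counts(genes: list[TRNAGene],
                              n_species: int | None = None,
                              ) -> dict[tuple[str, str], int]:
    """Per (isotype, anticodon): number of distinct species with >= 1 copy.

    Keyed by isotype as well as anticodon so that Ile-CAU and Met-CAU are
    tallied separately.  Values never exceed ``n_species`` when given.
    """
    seen: dict[tuple[str, str], set[str]] = {}
    for g in genes:
        if g.anticodon is None:
            continue
        key = (g.isotype or "?", g.anticodon)
        seen.setdefault(key, set()).add(g.species)
    out = {k: len(v) for k, v in sorted(seen.items())}
    if n_species is not None:
        bad = {k: v for k, v in out.items() if v > n_species}
        if bad:
            raise ValueError(f"presence counts exceed n_species={n_species}: {bad}")
    return out


_REGION_FIELDS = ("ac_arm", "d_arm", "d_loop", "anc_arm",
                  "anc_loop", "variable", "psi_arm", "psi_loop")


def region_length_distribution(profiles: list[RegionProfile],
                               ) -> dict[str, dict[int, tuple[int, float]]]:
    """Histogram of region lengths: region -> {length: (count, percent)}.

    Percentages are over the number of input profiles, rounded half away
    from zero to two decimals; per-region counts always sum to N.
    """
    n = len(profiles)
    out: dict[str, dict[int, tuple[int, float]]] = {}
    for fieldname in _REGION_FIELDS:
        counts: dict[int, int] = {}
        for p in profiles:
            v = getattr(p, fieldname)
            counts[v] = counts.get(v, 0) + 1
        out[fieldname] = {
            length: (c, round_half_away(100.0 * c / n, 2))
            for length, c in sorted(counts.items())
        }
        assert sum(c for c, _ in out[fieldname].values()) == n
    return out


def length_stats(genes: list[TRNAGene]) -> tuple[int, int, float]:
    """(min, max, mean-to-1-decimal) of gene lengths; empty input is an error."""
    if not genes:
        raise ValueError("length_stats of an empty gene list")
    lengths = [len(g.sequence) for g in genes]
    return min(lengths), max(lengths), round_half_away(sum(lengths) / len(lengths), 1)


# ---------------------------------------------------------------------------
# Progressive alignment

GAP = "-"


@dataclass
class Alignment:
    """A gapped multiple alignment of region subsequences."""

    rows: list[str]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column_frequencies(self) -> list[dict[str, float]]:
        """Per column: base -> frequency over all rows (gaps under ``"-"``)."""
        n = len(self.rows)
        freqs = []
        for k in range(self.n_cols):
            col: dict[str, float] = {}
            for row in self.rows:
                col[row[k]] = col.get(row[k], 0) + 1
            freqs.append({b: c / n for b, c in col.items()})
        return freqs


def _align_seq_to_profile(rows: list[str], seq: str,
                          match: float, mismatch: float,
                          gap_open: float, gap_extend: float) -> list[str]:
    """Affine-gap global alignment of one sequence against a profile.

    Column score for base b = mean over rows of (+match if same base,
    mismatch if different, 0 against an existing gap).  Needleman-Wunsch
    with three states (M, gap-in-seq, gap-in-profile); deterministic
    traceback preference M > gap-in-seq > gap-in-profile.
    """
    ncol, m = len(rows[0]), len(seq)
    nrows = len(rows)
    cols = [[row[k] for row in rows] for k in range(ncol)]

    def colscore(k: int, b: str) -> float:
        s = 0.0
        for c in cols[k]:
            if c == GAP:
                continue
            s += match if c == b else mismatch
        return s / nrows

    NEG = -1e18
    M = np.full((ncol + 1, m + 1), NEG)
    X = np.full((ncol + 1, m + 1), NEG)  # gap in seq (consume profile col)
    Y = np.full((ncol + 1, m + 1), NEG)  # gap in profile (consume seq char)
    ptr = {}
    M[0][0] = 0.0
    for i in range(1, ncol + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
        ptr[("X", i, 0)] = ("X", i - 1, 0) if i > 1 else ("M", 0, 0)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
        ptr[("Y", 0, j)] = ("Y", 0, j - 1) if j > 1 else ("M", 0, 0)
    for i in range(1, ncol + 1):
        for j in range(1, m + 1):
            s = colscore(i - 1, seq[j - 1])
            best, arg = NEG, None
            for st, val in (("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]),
                            ("Y", Y[i - 1][j - 1])):
                if val + s > best:
                    best, arg = val + s, (st, i - 1, j - 1)
            M[i][j], ptr[("M", i, j)] = best, arg
            best, arg = NEG, None
            for st, pen in (("M", gap_open), ("X", gap_extend), ("Y", gap_open)):
                val = {"M": M, "X": X, "Y": Y}[st][i - 1][j] + pen
                if val > best:
                    best, arg = val, (st, i - 1, j)
            X[i][j], ptr[("X", i, j)] = best, arg
            best, arg = NEG, None
            for st, pen in (("M", gap_open), ("X", gap_open), ("Y", gap_extend)):
                val = {"M": M, "X": X, "Y": Y}[st][i][j - 1] + pen
                if val > best:
                    best, arg = val, (st, i, j - 1)
            Y[i][j], ptr[("Y", i, j)] = best, arg

    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][ncol][m])
    i, j = ncol, m
    ops = []  # "M" consume both, "X" profile col + gap in seq, "Y" new col
    while (i, j) != (0, 0):
        ops.append(state)
        state, i, j = ptr[(state, i, j)]
    ops.reverse()

    new_rows = [""] * nrows
    new_seq = ""
    ci = si = 0
    for op in ops:
        if op == "M":
            for r in range(nrows):
                new_rows[r] += cols[ci][r]
            new_seq += seq[si]
            ci += 1
            si += 1
        elif op == "X":
            for r in range(nrows):
                new_rows[r] += cols[ci][r]
            new_seq += GAP
            ci += 1
        else:  # Y: insert a gap column into the profile
            for r in range(nrows):
                new_rows[r] += GAP
            new_seq += seq[si]
            si += 1
    return new_rows + [new_seq]


def align_isotype_regions(sequences: list[str], *, match: float = 2.0,
                          mismatch: float = -1.0, gap_open: float = -12.0,
                          gap_extend: float = -2.0) -> Alignment:
    """Progressively align region subsequences of one isoacceptor class.

    Guide order is input order; a single sequence passes through unaligned.
    """
    sequences = [s for s in sequences]
    if not sequences:
        raise ValueError("no sequences to align")
    if len(sequences) == 1:
        return Alignment(rows=list(sequences))
    rows = [sequences[0]]
    for seq in sequences[1:]:
        if not seq:
            rows = [r for r in rows] + [GAP * len(rows[0])]
            continue
        rows = _align_seq_to_profile(rows, seq, match, mismatch, gap_open, gap_extend)
    return Alignment(rows=rows)


# ---------------------------------------------------------------------------
# Consensus calling

@dataclass
class ConsensusMotif:
    """Dash-separated consensus tokens for one region of one isoacceptor.

    Tokens are a single base (column frequency >= ``high``), a two-base
    alternative ``N1/N2``, or ``X``; runs of X columns with variable gap
    occupancy collapse to ``X_a-b`` (min-max residues across rows).
    """

    isotype: str = ""
    anticodon: str = ""
    region: str = ""
    columns: list[str] = field(default_factory=list)
    high: float = 0.90
    low: float = 0.50

    def __str__(self) -> str:
        return "-".join(self.columns)


def _column_token(freqs: dict[str, float], high: float, low: float) -> str:
    bases = sorted(((f, b) for b, f in freqs.items() if b != GAP),
                   key=lambda t: (-t[0], t[1]))
    if not bases:
        return "X"
    f1, b1 = bases[0]
    if f1 >= high:
        return b1
    if len(bases) > 1:
        f2, b2 = bases[1]
        # two-base alternative: the top two jointly reach the high threshold
        # and the minor base carries at least `low` of the major's weight
        if f1 + f2 >= high and f2 >= low * f1:
            return f"{b1}/{b2}"
    return "X"


def call_consensus(alignment: Alignment, high: float = 0.90, low: float = 0.50,
                   isotype: str = "", anticodon: str = "", region: str = "",
                   ) -> ConsensusMotif:
    """Call a consensus motif from column frequencies.

    Raising ``high`` can only demote base tokens towards X, never promote
    (monotonicity); X-runs over columns containing gaps collapse to the
    ``X_a-b`` occupancy notation, or ``X_a`` when every row holds the same
    number of residues in the span.
    """
    freqs = alignment.column_frequencies()
    raw = [_column_token(f, high, low) for f in freqs]

    columns: list[str] = []
    k = 0
    n = alignment.n_cols
    while k < n:
        if raw[k] != "X":
            columns.append(raw[k])
            k += 1
            continue
        end = k
        while end < n and raw[end] == "X":
            end += 1
        span_has_gap = any(GAP in alignment.rows[r][k:end]
                           for r in range(len(alignment.rows)))
        if not span_has_gap:
            columns.extend(["X"] * (end - k))
        else:
            occ = [sum(1 for c in row[k:end] if c != GAP) for row in alignment.rows]
            a, b = min(occ), max(occ)
            columns.append(f"X_{a}" if a == b else f"X_{a}-{b}")
        k = end
    return ConsensusMotif(isotype=isotype, anticodon=anticodon, region=region,
                          columns=columns, high=high, low=low)
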