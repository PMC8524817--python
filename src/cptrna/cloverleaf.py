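"""Cloverleaf decomposition of tRNA secondary structures.

A tRNA folds into four helices (acceptor, D, anticodon, TPsiC) joined by a
multibranch loop.  This module partitions every nucleotide of an annotated
dot-bracket structure into the named cloverleaf regions, extracts the
anticodon, detects genomically precoded 3' CCA tails, and classifies the
four structural-variant types observed in gymnosperm chloroplast tRNAs:

* TYPE1 - the acceptor arm is missing (no acceptor base pairs);
* TYPE2 - the 3' end carries extra nucleotides (a non-CCA trailer);
* TYPE3 - the variable region folds an internal stem ("variable arm");
* TYPE4 - both the TYPE2 and TYPE3 conditions hold.

TYPE1 takes precedence over the others, so every structure receives exactly
one label.

Region accounting convention
----------------------------
The two unpaired linker nucleotides between the acceptor stem and the D stem
(canonical positions 8-9) and the single linker between the D stem and the
anticodon stem (canonical 26) are counted *within the D-loop total*: the
eight-region accounting used throughout this package leaves them no other
home, and the observed D-loop mode (9 nt) matches this convention.  Bulged
nucleotides tolerated inside a stem are likewise counted with the adjacent
loop (D-stem bulges with the D loop, anticodon-stem bulges with the
anticodon loop, T-stem and acceptor 3'-side bulges with the Psi loop,
acceptor 5'-side bulges with the D loop) so that the region counts always
reconstruct the sequence length exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio.Seq import Seq

from ._util import revcomp
from .io_formats import TRNAGene, _ONE_TO_THREE

__all__ = [
    "CloverleafStructure",
    "RegionProfile",
    "StructuralType",
    "NotCloverleafError",
    "PseudoknotError",
    "pairs_from_dot_bracket",
    "parse_structure",
    "region_profile",
    "extract_anticodon",
    "anticodon_to_isotype",
    "detect_precoded_cca",
    "classify_structure",
]

REGION_NAMES = (
    "acceptor_stem_5p", "d_stem_5p", "d_loop", "d_stem_3p",
    "anticodon_stem_5p", "anticodon_loop", "anticodon_stem_3p",
    "variable_region", "t_stem_5p", "t_loop", "t_stem_3p",
    "acceptor_stem_3p", "discriminator", "trailer_3p",
)

#: bulges of at most this many nucleotides do not split a helix in two
HELIX_BULGE_TOLERANCE = 2

#: minimum stacked pairs for a variable-region helix to count as a variable arm
VARIABLE_ARM_MIN_PAIRS = 2


class NotCloverleafError(ValueError):
    """Structure has too few helices to be decomposed as a cloverleaf."""


class PseudoknotError(ValueError):
    """Crossing base pairs cannot occur in dot-bracket input; defensive."""


class StructuralType(enum.Enum):
    NORMAL = "Normal"
    TYPE1 = "Type1"
    TYPE2 = "Type2"
    TYPE3 = "Type3"
    TYPE4 = "Type4"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass
class CloverleafStructure:
    """A base-pair set partitioned into the named cloverleaf regions.

    ``regions`` maps each region name to an ordered list of 0-based sequence
    indices; every index belongs to exactly one region.  ``variable_arm_pairs``
    is the subset of ``pairs`` internal to the variable region.
    """

    sequence: str
    pairs: frozenset[tuple[int, int]]
    regions: dict[str, list[int]]
    variable_arm_pairs: frozenset[tuple[int, int]] = frozenset()

    def region_seq(self, name: str) -> str:
        return "".join(self.sequence[i] for i in self.regions[name])

    @property
    def trailer_seq(self) -> str:
        return self.region_seq("trailer_3p")


@dataclass
class RegionProfile:
    """Per-region nucleotide counts; stem counts are in base pairs."""

    gene_id: str
    ac_arm: int
    d_arm: int
    d_loop: int
    anc_arm: int
    anc_loop: int
    variable: int
    psi_arm: int
    psi_loop: int
    has_discriminator: bool
    trailer_len: int
    sequence_length: int = 0

    def counts(self) -> tuple[int, ...]:
        return (self.ac_arm, self.d_arm, self.d_loop, self.anc_arm,
                self.anc_loop, self.variable, self.psi_arm, self.psi_loop)


def pairs_from_dot_bracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {k}")
            pairs.append((stack.pop(), k))
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket")
    return sorted(pairs)


def _find_helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group nested pairs into maximal helices, tolerating small bulges.

    Pairs are sorted by 5' index; a pair continues the current helix when it
    nests directly inside the previous pair with at most
    ``HELIX_BULGE_TOLERANCE`` inserted nucleotides on each strand.
    """
    helices: list[list[tuple[int, int]]] = []
    for p in sorted(pairs):
        if helices:
            qi, qj = helices[-1][-1]
            if (qi < p[0] <= qi + HELIX_BULGE_TOLERANCE + 1
                    and qj > p[1] >= qj - HELIX_BULGE_TOLERANCE - 1):
                helices[-1].append(p)
                continue
        helices.append([p])
    return helices


def _strand_indices(helix: list[tuple[int, int]]) -> tuple[list[int], list[int], list[int], list[int]]:
    """Paired 5'/3' strand indices of a helix plus its bulged indices per side."""
    i_set = {i for i, _ in helix}
    j_set = {j for _, j in helix}
    i5 = list(range(min(i_set), max(i_set) + 1))
    j3 = list(range(min(j_set), max(j_set) + 1))
    bulge5 = [k for k in i5 if k not in i_set]
    bulge3 = [k for k in j3 if k not in j_set]
    return sorted(i_set), sorted(j_set), bulge5, bulge3


def parse_structure(gene: TRNAGene) -> CloverleafStructure:
    """Decompose an annotated dot-bracket structure into cloverleaf regions.

    Helices are maximal stacks of nested pairs (bulges <= 2 nt tolerated);
    the helix pairing the 5'-most and 3'-most paired positions is the
    acceptor stem.  The remaining helices, in 5'->3' order of their 5'
    strands, are the D stem, the anticodon stem, zero or more variable-arm
    helices, and the T stem.  The unpaired nucleotide immediately 3' of the
    acceptor stem's 3' strand is the discriminator; anything further 3' is
    the trailer.  Structures without acceptor pairs (TYPE1 candidates) are
    parsed with an empty acceptor stem, no discriminator, and all 3'
    unpaired residues as trailer.
    """
    if gene.dot_bracket is None:
        raise ValueError(f"{gene.gene_id}: no dot-bracket structure to parse")
    seq = gene.sequence
    n = len(seq)
    try:
        pairs = pairs_from_dot_bracket(gene.dot_bracket)
    except ValueError as exc:
        raise PseudoknotError(str(exc)) from exc
    helices = _find_helices(pairs)
    if len(helices) < 2:
        raise NotCloverleafError(
            f"{gene.gene_id}: only {len(helices)} helix(es); not a cloverleaf")

    # acceptor stem: the helix enclosing every other paired position
    min_i = min(i for i, _ in pairs)
    max_j = max(j for _, j in pairs)
    acceptor = None
    rest = helices
    for h in helices:
        if any(p == (min_i, max_j) for p in h) or (
                h[0][0] == min_i and h[0][1] == max_j):
            acceptor = h
            rest = [x for x in helices if x is not h]
            break

    if len(rest) < 3:
        raise NotCloverleafError(
            f"{gene.gene_id}: {len(rest)} non-acceptor helices; cannot assign "
            "D/anticodon/T stems")

    rest.sort(key=lambda h: h[0][0])
    d_helix, anc_helix, t_helix = rest[0], rest[1], rest[-1]
    var_helices = rest[2:-1]

    regions: dict[str, list[int]] = {name: [] for name in REGION_NAMES}

    d_i, d_j, d_b5, d_b3 = _strand_indices(d_helix)
    a_i, a_j, a_b5, a_b3 = _strand_indices(anc_helix)
    t_i, t_j, t_b5, t_b3 = _strand_indices(t_helix)

    regions["d_stem_5p"] = d_i
    regions["d_stem_3p"] = d_j
    regions["anticodon_stem_5p"] = a_i
    regions["anticodon_stem_3p"] = a_j
    regions["t_stem_5p"] = t_i
    regions["t_stem_3p"] = t_j

    if acceptor is not None:
        c_i, c_j, c_b5, c_b3 = _strand_indices(acceptor)
        regions["acceptor_stem_5p"] = c_i
        regions["acceptor_stem_3p"] = c_j
        lead_end = min(c_i)          # indices before acceptor 5' strand
        after_t = range(max(t_j) + 1, min(c_j))
        after_acc = max(c_j) + 1
    else:
        c_b5, c_b3 = [], []
        lead_end = min(d_i)
        after_t = range(0)
        after_acc = max(t_j) + 1

    # D loop: leading spacer(s) + enclosed loop + D->anticodon linker + bulges
    regions["d_loop"] = sorted(
        [k for k in range(lead_end) if not acceptor]  # 5' leader when no acceptor
        + ([] if not acceptor else
           list(range(max(regions["acceptor_stem_5p"]) + 1, min(d_i))))
        + list(range(max(d_i) + 1, min(d_j)))
        + list(range(max(d_j) + 1, min(a_i)))
        + d_b5 + d_b3 + c_b5)
    regions["anticodon_loop"] = sorted(
        list(range(max(a_i) + 1, min(a_j))) + a_b5 + a_b3)
    regions["variable_region"] = list(range(max(a_j) + 1, min(t_i)))
    regions["t_loop"] = sorted(
        list(range(max(t_i) + 1, min(t_j))) + t_b5 + t_b3 + c_b3
        + list(after_t))

    var_set = set(regions["variable_region"])
    variable_arm_pairs = frozenset(
        (i, j) for i, j in pairs if i in var_set and j in var_set)

    # discriminator and trailer
    if acceptor is not None and after_acc < n:
        regions["discriminator"] = [after_acc]
        regions["trailer_3p"] = list(range(after_acc + 1, n))
    else:
        regions["discriminator"] = []
        regions["trailer_3p"] = list(range(after_acc, n))

    assigned = sorted(k for idx in regions.values() for k in idx)
    if assigned != list(range(n)):
        missing = sorted(set(range(n)) - set(assigned))
        raise NotCloverleafError(
            f"{gene.gene_id}: region partition failed (unassigned: {missing[:5]}...)")

    return CloverleafStructure(
        sequence=seq,
        pairs=frozenset(pairs),
        regions=regions,
        variable_arm_pairs=variable_arm_pairs,
    )


def region_profile(cl: CloverleafStructure, gene_id: str = "") -> RegionProfile:
    """Count nucleotides per region (stems in base pairs, loops in nt).

    The reconstruction invariant
    ``2*(ac+d+anc+psi arms) + loops + variable + discriminator + trailer ==
    sequence length`` is re-checked and a violation raises ``RuntimeError``.
    """
    r = cl.regions
    stem_bp = lambda name: sum(1 for i, j in cl.pairs
                               if i in set(r[name]) and j in set(r[name.replace("_5p", "_3p")]))
    prof = RegionProfile(
        gene_id=gene_id,
        ac_arm=stem_bp("acceptor_stem_5p"),
        d_arm=stem_bp("d_stem_5p"),
        d_loop=len(r["d_loop"]),
        anc_arm=stem_bp("anticodon_stem_5p"),
        anc_loop=len(r["anticodon_loop"]),
        variable=len(r["variable_region"]),
        psi_arm=stem_bp("t_stem_5p"),
        psi_loop=len(r["t_loop"]),
        has_discriminator=bool(r["discriminator"]),
        trailer_len=len(r["trailer_3p"]),
        sequence_length=len(cl.sequence),
    )
    total = (2 * (prof.ac_arm + prof.d_arm + prof.anc_arm + prof.psi_arm)
             + prof.d_loop + prof.anc_loop + prof.variable + prof.psi_loop
             + int(prof.has_discriminator) + prof.trailer_len)
    if total != len(cl.sequence):
        raise RuntimeError(
            f"{gene_id}: region counts sum to {total}, sequence is "
            f"{len(cl.sequence)} nt — internal consistency error")
    return prof


def extract_anticodon(cl: CloverleafStructure) -> tuple[str, int]:
    """Return the anticodon triplet and its 0-based start index.

    For the canonical 7-nt loop the triplet occupies loop positions 3-5
    (1-based).  Loops of other odd lengths yield the centered triplet; even
    lengths skip the extra 5' nucleotide first.
    """
    loop = cl.regions["anticodon_loop"]
    L = len(loop)
    if L < 3:
        raise ValueError(f"anticodon loop of {L} nt is too short")
    offset = (L - 3) // 2 if L % 2 else (L - 2) // 2
    idx = loop[offset:offset + 3]
    return "".join(cl.sequence[i] for i in idx), idx[0]


_THREE_LETTER = set(_ONE_TO_THREE.values()) | {"fMet"}


def anticodon_to_isotype(anticodon: str, declared_isotype: str | None = None) -> str:
    """Decode an anticodon to its amino-acid isotype via the standard code.

    The anticodon is reverse-complemented to the codon it reads and
    translated.  CAU is ambiguous between Met, Ile (lysidine-modified C34)
    and the initiator fMet: a declared annotation wins there, and a declared
    isotype consistent with the decoding is always returned.  Anticodons
    decoding to a stop codon are flagged as putative suppressors (``Sup``),
    expected absent from chloroplast genomes.
    """
    anticodon = anticodon.upper().replace("T", "U")
    if len(anticodon) != 3 or any(c not in "ACGU" for c in anticodon):
        raise ValueError(f"bad anticodon {anticodon!r}")
    codon = revcomp(anticodon)
    aa = str(Seq(codon.replace("U", "T")).translate())
    decoded = "Sup" if aa == "*" else _ONE_TO_THREE[aa]
    if declared_isotype:
        if declared_isotype not in _THREE_LETTER and declared_isotype != "Sup":
            raise ValueError(f"unknown isotype {declared_isotype!r}")
        if declared_isotype == decoded:
            return declared_isotype
        if anticodon == "CAU" and declared_isotype in ("Ile", "fMet", "Met"):
            return declared_isotype
        import warnings
        warnings.warn(
            f"declared isotype {declared_isotype} inconsistent with anticodon "
            f"{anticodon} (decodes to {decoded}); keeping the annotation")
        return declared_isotype
    return decoded


def detect_precoded_cca(cl: CloverleafStructure) -> bool:
    """True iff the trailer begins with exactly C,C,A (genomically encoded CCA)."""
    return cl.trailer_seq[:3] == "CCA"


def classify_structure(cl: CloverleafStructure) -> StructuralType:
    """Assign one of the five structural classes.

    TYPE1 (no acceptor pairs) takes precedence.  Otherwise ``extra3`` is a
    nonempty trailer that is not exactly the precoded CCA tail, and
    ``vararm`` is an internal variable-region helix of >= 2 base pairs;
    TYPE4 = both, TYPE2 = extra3 only, TYPE3 = vararm only, else NORMAL.
    """
    ac_pairs = sum(1 for i, j in cl.pairs
                   if i in set(cl.regions["acceptor_stem_5p"]))
    if ac_pairs == 0:
        return StructuralType.TYPE1
    extra3 = bool(cl.regions["trailer_3p"]) and cl.trailer_seq != "CCA"
    vararm = any(len(h) >= VARIABLE_ARM_MIN_PAIRS
                 for h in _find_helices(sorted(cl.variable_arm_pairs)))
    if extra3 and vararm:
        return StructuralType.TYPE4
    if extra3:
        return StructuralType.TYPE2
    if vararm:
        return StructuralType.TYPE3
    return StructuralType.NORMAL
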