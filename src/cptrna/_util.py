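"""Small shared helpers: rounding, RNA alphabet handling."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

RNA_BASES = "ACGU"
COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: purine<->purine and pyrimidine<->pyrimidine exchanges
TRANSITION_PAIRS = {frozenset("AG"), frozenset("CU")}


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (printed-table convention).

    Python's built-in round() is banker's rounding; tabulated means such as
    -28.25 must print as -28.3, so ties are broken away from zero.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U. Does not validate."""
    return seq.upper().replace("T", "U")


def is_pure_rna(seq: str) -> bool:
    return all(c in RNA_BASES for c in seq)


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def is_transition(a: str, b: str) -> bool:
    return a != b and frozenset((a, b)) in TRANSITION_PAIRS


def is_transversion(a: str, b: str) -> bool:
    return a != b and frozenset((a, b)) not in TRANSITION_PAIRS
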