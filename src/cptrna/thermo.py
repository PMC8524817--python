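"""Folding free energy of annotated tRNA structures.

The default engine (``nn_eval``) evaluates the *given* secondary structure
under a nearest-neighbor model: Watson-Crick stacked-pair free energies from
the embedded Turner-style table (kcal/mol at 37 C) plus fixed loop penalties
by size class (hairpin / bulge / internal / multibranch).  It is an
evaluation of the annotated structure, not a search over structures: the
pipeline's structures arrive annotated, so no folding is required.  A full
minimum-free-energy search can be delegated to ViennaRNA when its Python
bindings are importable (``engine="external"``).

Stacks in which one pair is a G.U wobble receive a single flat negative
term (:data:`WOBBLE_STACK`); synthetic stems are pure Watson-Crick, so this
only matters for annotated real-world input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from ._util import round_half_away
from .cloverleaf import CloverleafStructure, StructuralType

__all__ = [
    "MFERecord",
    "evaluate_structure_energy",
    "aggregate_mfe_by_type",
    "PARAMETER_SET",
]

PARAMETER_SET = "turner-wc-stacks-2004/simplified-loops-v1"

# Watson-Crick stacked pairs, 5'XY3' over 3'WZ5' given as ((X,W),(Y,Z)):
# energy of pair (i,j) stacked under pair (i+1,j-1).  kcal/mol, 37 C.
_WC_STACK = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("UA", "UA"): -0.93,
    ("AU", "CG"): -2.24,
    ("AU", "GC"): -2.08,
    ("UA", "CG"): -2.35,
    ("UA", "GC"): -2.11,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("CG", "CG"): -3.26,
    ("CG", "GC"): -2.36,
    ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26,
}

#: flat term for any stack involving a G.U pair (kept negative so that
#: adding a stacked pair never destabilizes under this table)
WOBBLE_STACK = -0.5

_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 6.1, 9: 6.3}
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL = {2: 0.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}

_RT = 0.616  # kcal/mol at 37 C, for Jacobson-Stockmayer extrapolation
_MULTILOOP_OFFSET = 3.4
_MULTILOOP_PER_BRANCH = 0.4

_CANONICAL = {"AU", "UA", "CG", "GC", "GU", "UG"}


def _loop_energy(table: dict[int, float], size: int) -> float:
    if size in table:
        return table[size]
    m = max(table)
    return table[m] + 1.75 * _RT * math.log(size / m)


def _stack_energy(bp_outer: str, bp_inner: str) -> float:
    if "GU" in (bp_outer, bp_inner) or "UG" in (bp_outer, bp_inner):
        return WOBBLE_STACK
    return _WC_STACK.get((bp_outer, bp_inner), WOBBLE_STACK)


@dataclass
class MFERecord:
    gene_id: str
    structural_type: StructuralType
    delta_g: float  # kcal/mol, recorded to 1 decimal
    engine: str = "nn_eval"


def evaluate_structure_energy(cl: CloverleafStructure) -> float:
    """Free energy (kcal/mol) of the annotated structure under the NN model.

    Sums stacked-pair energies over all directly nested pairs and adds a
    loop penalty for every hairpin, bulge, internal and multibranch loop
    closed by a pair.  A structure with zero pairs evaluates to 0.0 with a
    warning (nothing is stacked, no loop is closed).
    """
    pairs = sorted(cl.pairs)
    if not pairs:
        warnings.warn("structure has no base pairs; delta G set to 0.0")
        return 0.0
    seq = cl.sequence
    pair_set = set(pairs)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    def bp(i: int, j: int) -> str:
        return seq[i] + seq[j]

    dg = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pair_set:
            b1, b2 = bp(i, j), bp(i + 1, j - 1)
            if b1 in _CANONICAL and b2 in _CANONICAL:
                dg += _stack_energy(b1, b2)
        # loop closed by (i, j): find directly enclosed pairs
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            dg += _loop_energy(_HAIRPIN, j - i - 1)
        elif len(children) == 1:
            (a, b), = children
            up5, up3 = a - i - 1, j - b - 1
            if up5 == 0 and up3 == 0:
                pass  # stacked; handled above
            elif up5 == 0 or up3 == 0:
                dg += _loop_energy(_BULGE, up5 + up3)
            else:
                dg += _loop_energy(_INTERNAL, up5 + up3)
        else:
            dg += _MULTILOOP_OFFSET + _MULTILOOP_PER_BRANCH * len(children)
    return dg


def evaluate_external(sequence: str, dot_bracket: str) -> float:
    """Evaluate the structure with ViennaRNA's Turner model (optional engine)."""
    import RNA  # optional dependency; raises ImportError when absent
    return RNA.fold_compound(sequence).eval_structure(dot_bracket)


def aggregate_mfe_by_type(records: list[MFERecord]) -> dict[StructuralType, tuple[int, float]]:
    """Per-type (n, mean delta G) with the mean rounded half away from zero
    to one decimal; empty groups are absent from the mapping."""
    groups: dict[StructuralType, list[float]] = {}
    for rec in records:
        groups.setdefault(rec.structural_type, []).append(rec.delta_g)
    return {
        t: (len(v), round_half_away(sum(v) / len(v), 1))
        for t, v in sorted(groups.items(), key=lambda kv: kv[0].value)
    }
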