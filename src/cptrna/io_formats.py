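"""Readers and writers for the external formats the pipeline touches.

Formats handled here: FASTA, GenBank flat files with tRNA features,
tRNAscan-SE tabular output plus its secondary-structure text blocks, and
Newick trees.  Everything downstream works on :class:`TRNAGene` records and
dendropy trees produced by this module.

Conventions
-----------
* External GenBank coordinates are 1-based inclusive; internal positions are
  0-based half-open.  The conversion happens only at this boundary.
* DNA input is silently normalized to the RNA alphabet (T -> U).  Ambiguity
  codes (N, R, Y, ...) reject the individual gene with a warning, never the
  whole run.
* tRNAscan-SE structure strings may use either ``>``/``<`` or ``(``/``)``.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

import dendropy
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3

from ._util import is_pure_rna, normalize_rna

__all__ = [
    "TRNAGene",
    "ParseError",
    "GeneValidationError",
    "read_fasta",
    "write_fasta",
    "read_genbank_trnas",
    "read_trnascan",
    "read_newick",
    "write_newick",
]

#: accepted sequence length range for a tRNA gene record (nt)
MIN_GENE_LEN = 50
MAX_GENE_LEN = 120

ISOTYPES = tuple(sorted(
    {protein_letters_1to3[a] for a in "ACDEFGHIKLMNPQRSTVWY"}
)) + ("fMet", "Sup")


class ParseError(ValueError):
    """Malformed input in one of the supported external formats."""


class GeneValidationError(ValueError):
    """A tRNA gene record violating the domain invariants."""


def _check_balanced(db: str) -> bool:
    depth = 0
    for c in db:
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                return False
        elif c != ".":
            return False
    return depth == 0


@dataclass
class TRNAGene:
    """One annotated tRNA gene.

    ``isotype`` is a three-letter amino-acid name (plus ``fMet`` for the
    initiator and ``Sup`` for a putative suppressor, expected absent in
    chloroplast data).  ``sequence`` is 5'->3' RNA.  ``dot_bracket``, when
    present, is the annotated secondary structure in ``(``/``)``/``.``
    notation, same length as the sequence.
    """

    gene_id: str
    species: str
    sequence: str
    isotype: str | None = None
    anticodon: str | None = None
    structure_source: str = "none"  # annotated | folded | none
    dot_bracket: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if self.anticodon:
            self.anticodon = normalize_rna(self.anticodon)
        self.validate()

    def validate(self) -> None:
        if not is_pure_rna(self.sequence):
            raise GeneValidationError(
                f"{self.gene_id}: sequence contains non-ACGU characters "
                "(ambiguity codes are rejected at the gene level)")
        n = len(self.sequence)
        if not MIN_GENE_LEN <= n <= MAX_GENE_LEN:
            raise GeneValidationError(
                f"{self.gene_id}: length {n} outside accepted range "
                f"[{MIN_GENE_LEN}, {MAX_GENE_LEN}]")
        if self.anticodon is not None and self.anticodon not in self.sequence:
            raise GeneValidationError(
                f"{self.gene_id}: anticodon {self.anticodon} not found in sequence")
        if self.dot_bracket is not None:
            if len(self.dot_bracket) != n:
                raise GeneValidationError(
                    f"{self.gene_id}: dot-bracket length {len(self.dot_bracket)} "
                    f"!= sequence length {n}")
            if not _check_balanced(self.dot_bracket):
                raise GeneValidationError(
                    f"{self.gene_id}: unbalanced dot-bracket string")
        if self.structure_source not in ("annotated", "folded", "none"):
            raise GeneValidationError(
                f"{self.gene_id}: bad structure_source {self.structure_source!r}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(stream: IO[str] | str) -> list[tuple[str, str]]:
    """Parse FASTA into an order-preserving list of (id, RNA sequence).

    T/t are normalized to U; input case is ignored.  Malformed headers and
    empty sequences raise :class:`ParseError` naming the offending line.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[tuple[str, list[str]]] = []
    current: tuple[str, list[str]] | None = None
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current is not None and not current[1]:
                raise ParseError(
                    f"line {lineno}: record {current[0]!r} has an empty sequence")
            header = line[1:].strip()
            if not header:
                raise ParseError(f"line {lineno}: empty FASTA header")
            current = (header.split()[0], [])
            records.append(current)
        else:
            if current is None:
                raise ParseError(
                    f"line {lineno}: sequence data before any '>' header")
            current[1].append(line)
    if current is not None and not current[1]:
        raise ParseError(f"record {current[0]!r} has an empty sequence")
    return [(name, normalize_rna("".join(parts))) for name, parts in records]


def write_fasta(records: Iterable[tuple[str, str]], stream: IO[str], width: int = 60) -> None:
    for name, seq in records:
        stream.write(f">{name}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank

_TRN_QUAL = re.compile(r"^trn(fM|[A-Z])-?([ACGTUacgtu]{3})?")

_ONE_TO_THREE = dict(protein_letters_1to3)


def _parse_trn_qualifier(text: str) -> tuple[str | None, str | None]:
    """Parse a trnX-NNN style qualifier into (isotype, anticodon)."""
    m = _TRN_QUAL.match(text)
    if m:
        letter, anticodon = m.groups()
        if letter == "fM":
            iso = "fMet"
        else:
            iso = _ONE_TO_THREE.get(letter)
        return iso, normalize_rna(anticodon) if anticodon else None
    # tRNA-His style product qualifiers
    m = re.match(r"^tRNA-([A-Za-z]{3})(?:\(([ACGTUacgtu]{3})\))?", text)
    if m:
        name, anticodon = m.groups()
        iso = name.capitalize() if name.capitalize() in _ONE_TO_THREE.values() else None
        if text.startswith("tRNA-fMet") or name == "fMe":
            iso = "fMet"
        return iso, normalize_rna(anticodon) if anticodon else None
    return None, None


def read_genbank_trnas(stream: IO[str]) -> list[TRNAGene]:
    """Extract one :class:`TRNAGene` per tRNA feature of a GenBank flat file.

    Sequences are extracted respecting strand (minus-strand features are
    reverse-complemented).  Isotype/anticodon are parsed from ``/gene`` or
    ``/product`` qualifiers of the form ``trnH-GUG`` or ``tRNA-His``.
    Features that cannot be located or validated are skipped with a warning.
    """
    genes: list[TRNAGene] = []
    for record in SeqIO.parse(stream, "genbank"):
        n = 0
        for feat in record.features:
            if feat.type != "tRNA":
                continue
            n += 1
            gene_id = f"{record.id}.trna{n}"
            try:
                seq = str(feat.extract(record.seq))
            except Exception as exc:  # unlocatable feature
                warnings.warn(f"{gene_id}: cannot extract sequence ({exc}); skipped")
                continue
            quals = feat.qualifiers
            text = (quals.get("gene") or quals.get("product") or [""])[0]
            isotype, anticodon = _parse_trn_qualifier(text)
            flags = []
            if text and isotype is None:
                flags.append(f"unparseable_qualifier:{text}")
            try:
                gene = TRNAGene(
                    gene_id=gene_id,
                    species=record.annotations.get("organism", record.id),
                    sequence=seq,
                    isotype=isotype,
                    anticodon=anticodon,
                    flags=flags,
                )
            except GeneValidationError as exc:
                warnings.warn(f"skipping {gene_id}: {exc}")
                continue
            genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# tRNAscan-SE

def _translate_structure(s: str) -> str:
    return s.replace(">", "(").replace("<", ")")


def _parse_structure_blocks(stream: IO[str]) -> dict[str, tuple[str, str | None]]:
    """Return {record name: (sequence, dot-bracket or None)} from Seq:/Str: blocks."""
    blocks: dict[str, tuple[str, str | None]] = {}
    name = seq = struct = None

    def flush() -> None:
        nonlocal name, seq, struct
        if name is not None and seq is not None:
            if struct is not None and len(seq) != len(struct):
                raise ParseError(
                    f"{name}: Seq/Str length mismatch ({len(seq)} vs {len(struct)})")
            blocks[name] = (seq, _translate_structure(struct) if struct else None)
        name = seq = struct = None

    for raw in stream:
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.startswith("Seq:"):
            seq = stripped[4:].strip()
        elif stripped.startswith("Str:"):
            struct = stripped[4:].strip()
        elif stripped.startswith("Type:") or stripped.startswith("*"):
            continue
        else:
            # header line: "<name> (<begin>-<end>)  Length: NN bp"
            flush()
            name = stripped.split()[0]
    flush()
    return blocks


def read_trnascan(tabular_stream: IO[str], structure_stream: IO[str] | None = None) -> list[TRNAGene]:
    """Parse tRNAscan-SE tabular output (plus structure text) into genes.

    Tabular columns: sequence name, tRNA#, begin, end, isotype, anticodon,
    intron begin, intron end, score.  Structure blocks are matched by
    ``<name>.trna<#>``.  Intron-bearing entries are returned pre-spliced when
    intron bounds are given (1-based inclusive positions within the gene).
    Records lacking a structure block get ``structure_source="none"``.
    """
    blocks = _parse_structure_blocks(structure_stream) if structure_stream else {}
    genes: list[TRNAGene] = []
    for lineno, raw in enumerate(tabular_stream, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("Sequence", "Name", "----", "#")):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            cols = line.split()
        if len(cols) < 9:
            raise ParseError(f"line {lineno}: expected >=9 tRNAscan-SE columns")
        name, num, begin, end, isotype, anticodon, ib, ie, _score = cols[:9]
        key = f"{name.strip()}.trna{num.strip()}"
        if key not in blocks:
            warnings.warn(f"{key}: no sequence block in structure output; skipped")
            continue
        seq, db = blocks[key]
        ib, ie = int(ib), int(ie)
        if ib > 0 and ie >= ib:  # splice the intron (1-based inclusive bounds)
            seq = seq[:ib - 1] + seq[ie:]
            if db is not None:
                db = db[:ib - 1] + db[ie:]
        iso = isotype.strip()
        if iso not in ISOTYPES:
            iso = {"fMet": "fMet", "iMet": "fMet"}.get(iso)
        genes.append(TRNAGene(
            gene_id=key,
            species=name.strip(),
            sequence=seq,
            isotype=iso,
            anticodon=normalize_rna(anticodon.strip()) or None,
            structure_source="annotated" if db is not None else "none",
            dot_bracket=db,
        ))
    return genes


# ---------------------------------------------------------------------------
# Newick

def read_newick(source: IO[str] | str) -> dendropy.Tree:
    """Parse a Newick tree (branch lengths and internal labels allowed)."""
    text = source.read() if hasattr(source, "read") else source
    try:
        return dendropy.Tree.get(
            data=text, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()
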