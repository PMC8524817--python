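"""Synthetic chloroplast tRNA cohorts with known ground truth.

Emulates the statistical structure of a gymnosperm chloroplast tRNA data
set so that every analysis stage is testable without any download:

* a Yule species tree over ``n_species`` taxa;
* per isoacceptor family, birth-death gene duplication/loss along the
  species tree (rates per unit branch length), with true event counts
  recorded - including events invisible after extinction;
* cloverleaf-constrained template sequences per isoacceptor, evolved along
  the gene tree under K2P with transition bias ``kappa``; stem substitutions
  are accompanied by the complementary change at the partner site with
  probability ``p_comp`` (compensatory evolution, structure preserved); the
  three anticodon positions are frozen (purifying selection), so the
  declared anticodon stays correct by construction;
* injected structural variants of the four defined classes, mutually
  exclusive per gene, with the true class recorded.

Everything is driven by one integer seed; identical config + seed gives
bit-identical output.  Defaults reflect the gymnosperm chloroplast cohort:
54 species, 33 isoacceptor families (so ~33 genes per species), kappa 5.8.
"""

from __future__ import annotations

import math
import random
import zlib
from dataclasses import dataclass, field, replace

import dendropy

from ._util import COMPLEMENT, revcomp
from .cloverleaf import StructuralType, parse_structure
from .io_formats import TRNAGene

__all__ = [
    "SimConfig",
    "SimTruth",
    "ISOACCEPTOR_SET",
    "make_trna_template",
    "simulate_species_tree",
    "simulate_gene_family",
    "evolve_trna_sequences",
    "inject_variants",
    "generate_cohort",
]

#: the isoacceptor repertoire of gymnosperm chloroplast genomes: the 32
#: anticodons observed with nonzero species presence, plus the initiator.
ISOACCEPTOR_SET: tuple[tuple[str, str], ...] = (
    ("Ala", "UGC"),
    ("Arg", "ACG"), ("Arg", "CCG"), ("Arg", "UCU"),
    ("Asn", "GUU"),
    ("Asp", "GUC"),
    ("Cys", "GCA"),
    ("Gln", "UUG"),
    ("Glu", "UUC"),
    ("Gly", "GCC"), ("Gly", "UCC"),
    ("His", "GUG"),
    ("Ile", "GAU"), ("Ile", "CAU"),
    ("Leu", "GAG"), ("Leu", "UAG"), ("Leu", "CAA"), ("Leu", "UAA"),
    ("Lys", "UUU"),
    ("Met", "CAU"), ("fMet", "CAU"),
    ("Phe", "GAA"),
    ("Pro", "GGG"), ("Pro", "UGG"),
    ("Ser", "GGA"), ("Ser", "UGA"), ("Ser", "GCU"),
    ("Thr", "GGU"), ("Thr", "UGU"),
    ("Trp", "CCA"),
    ("Tyr", "GUA"),
    ("Val", "GAC"), ("Val", "UAC"),
)


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Rates are events per unit branch length; probabilities in [0, 1].
    Defaults are the cohort-level conditions of the gymnosperm chloroplast
    data set this generator emulates.
    """

    n_species: int = 54
    speciation_rate: float = 1.0
    duplication_rate: float = 0.05
    loss_rate: float = 0.05
    substitution_rate: float = 0.05  # expected substitutions/site/unit length
    kappa: float = 5.8               # Table-level transition bias
    p_comp: float = 0.9              # compensatory stem substitutions
    p_t1: float = 0.002
    p_t2: float = 0.008
    p_t3: float = 0.18
    p_t4: float = 0.002
    genes_per_species_target: int = 33
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("speciation_rate", "duplication_rate", "loss_rate",
                     "substitution_rate", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_comp", "p_t1", "p_t2", "p_t3", "p_t4"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_t1 + self.p_t2 + self.p_t3 + self.p_t4 > 1.0:
            raise ValueError("variant injection probabilities sum to > 1")


@dataclass
class SimTruth:
    """Ground truth for one generated cohort or family."""

    #: family name -> (duplication events, loss events), all events counted
    family_events: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: family name -> (detectable duplications, detectable losses): events
    #: visible against the surviving backbone (what LCA reconciliation sees)
    family_events_detectable: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: gene_id -> injected structural type
    structural_types: dict[str, StructuralType] = field(default_factory=dict)
    kappa: float = float("nan")
    #: (isotype, anticodon) -> template gene
    templates: dict[tuple[str, str], TRNAGene] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Templates

_TEMPLATE_LAYOUT = (
    ("acc5", 7), ("spacer2", 2), ("d5", 4), ("dcore", 5), ("d3", 4),
    ("spacer1", 1), ("anc5", 5), ("ancloop", 7), ("anc3", 5),
    ("var", 5), ("t5", 5), ("tloop", 7), ("t3", 5), ("acc3", 7), ("disc", 1),
)


def make_trna_template(isotype: str, anticodon: str, seed: int = 0) -> TRNAGene:
    """A canonical cloverleaf template gene for one isoacceptor.

    Layout: acceptor stem 7 bp (5' G), merged D loop 8 nt (2+5+1 with the
    canonical A anchors), D stem 4 bp, anticodon stem 5 bp with the 7-nt
    loop C-U-<anticodon>-A-A, 5-nt variable region ending in C, T stem 5 bp,
    7-nt Psi loop U-U-C-N-N-N-U, one discriminator nucleotide, no trailer.
    All stems are Watson-Crick.  Deterministic in (isotype, anticodon, seed).
    """
    anticodon = anticodon.upper().replace("T", "U")
    if len(anticodon) != 3 or any(c not in "ACGU" for c in anticodon):
        raise ValueError(f"anticodon must be a 3-letter ACGU string, got {anticodon!r}")
    # zlib.crc32 is a stable hash; builtin hash() is salted per process
    tag = zlib.crc32(f"{isotype}-{anticodon}".encode())
    rng = random.Random((tag ^ seed) & 0x7FFFFFFF)
    rnd = lambda k: "".join(rng.choice("ACGU") for _ in range(k))

    acc5 = "G" + rnd(6)
    d5 = rnd(4)
    anc5 = rnd(5)
    t5 = rnd(5)
    parts = {
        "acc5": acc5,
        "spacer2": rnd(2),
        "d5": d5,
        "dcore": "A" + rnd(3) + "A",
        "d3": revcomp(d5),
        "spacer1": rnd(1),
        "anc5": anc5,
        "ancloop": "CU" + anticodon + "AA",
        "anc3": revcomp(anc5),
        "var": rnd(4) + "C",
        "t5": t5,
        "tloop": "UUC" + rnd(3) + "U",
        "t3": revcomp(t5),
        "acc3": revcomp(acc5),
        "disc": rng.choice("ACGU"),
    }
    seq = "".join(parts[name] for name, _ in _TEMPLATE_LAYOUT)
    db = ("(" * 7 + "." * 2 + "(" * 4 + "." * 5 + ")" * 4 + "."
          + "(" * 5 + "." * 7 + ")" * 5 + "." * 5
          + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + ".")
    assert len(seq) == len(db)
    return TRNAGene(
        gene_id=f"{isotype}-{anticodon}|template",
        species="template",
        sequence=seq,
        isotype=isotype,
        anticodon=anticodon,
        structure_source="annotated",
        dot_bracket=db,
    )


# ---------------------------------------------------------------------------
# Trees

def simulate_species_tree(n_species: int, rate: float = 1.0,
                          seed: int = 0) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) species tree with ``n_species`` leaves.

    Leaves are relabeled sp01..spNN in a deterministic traversal order.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    from dendropy.model import birthdeath
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=rate, death_rate=0.0, num_extant_tips=n_species, rng=rng)
    width = max(2, len(str(n_species)))
    ns = dendropy.TaxonNamespace()
    for k, leaf in enumerate(tree.leaf_node_iter(), 1):
        leaf.taxon = ns.new_taxon(f"sp{k:0{width}d}")
    tree.taxon_namespace = ns
    tree.is_rooted = True
    return tree


class _GLineage:
    """One gene lineage during the birth-death walk (full event tree)."""

    __slots__ = ("children", "species", "alive", "label", "length", "event")

    def __init__(self, species=None, length=0.0):
        self.children: list[_GLineage] = []
        self.species = species
        self.alive = True
        self.label: str | None = None
        self.length = length
        self.event: str | None = None  # duplication | speciation | loss | leaf


def simulate_gene_family(species_tree: dendropy.Tree, duplication_rate: float,
                         loss_rate: float, seed: int = 0,
                         family: str = "fam") -> tuple[dendropy.Tree | None, SimTruth]:
    """Birth-death gene family along a species tree.

    Lineages bifurcate (duplication) at ``duplication_rate`` and die (loss)
    at ``loss_rate`` per unit branch length; at each speciation node every
    surviving lineage is copied into both child branches.  Surviving leaves
    are labeled ``species|copyN``.  Truth records all events and the
    detectable subset (duplications with survivors on both sides; losses as
    maximal extinct subtrees attached to the surviving part).  A family
    driven extinct returns ``(None, truth)``.
    """
    rng = random.Random(seed)
    events = {"dup": 0, "loss": 0}

    def walk_branch(node: _GLineage, remaining: float) -> list[_GLineage]:
        """Evolve one lineage along a branch; return its tips at branch end."""
        total = duplication_rate + loss_rate
        while True:
            t = rng.expovariate(total) if total > 0 else math.inf
            if t >= remaining:
                node.length += remaining
                return [node]
            remaining -= t
            node.length += t
            if rng.random() < (duplication_rate / total):
                events["dup"] += 1
                node.event = "duplication"
                a, b = _GLineage(), _GLineage()
                node.children = [a, b]
                out = walk_branch(a, remaining)
                out += walk_branch(b, remaining)
                return out
            events["loss"] += 1
            node.event = "loss"
            node.alive = False
            return []

    root = _GLineage()
    copy_counter: dict[str, int] = {}

    def descend(sp_node, lineages: list[_GLineage]) -> None:
        if sp_node.is_leaf():
            sp = sp_node.taxon.label
            for lin in lineages:
                copy_counter[sp] = copy_counter.get(sp, 0) + 1
                lin.species = sp
                lin.label = f"{sp}|copy{copy_counter[sp]}"
                lin.event = "leaf"
            return
        for child in sp_node.child_nodes():
            next_lineages = []
            for lin in lineages:
                sub = _GLineage()
                lin.children.append(sub)
                lin.event = lin.event or "speciation"
                tips = walk_branch(sub, child.edge.length or 0.0)
                next_lineages.extend(tips)
            descend(child, next_lineages)

    descend(species_tree.seed_node, walk_branch(root, 0.0))

    # mark survival (has a labeled leaf below)
    def survives(n: _GLineage) -> bool:
        if n.event == "leaf":
            return True
        return any(survives(c) for c in n.children)

    det_dup = 0
    det_loss = 0

    def count_detectable(n: _GLineage) -> None:
        nonlocal det_dup, det_loss
        if not survives(n):
            return
        if n.event == "duplication" and all(survives(c) for c in n.children):
            det_dup += 1
        for c in n.children:
            if survives(c):
                count_detectable(c)
            elif n.event == "speciation":
                # a maximal extinct subtree is one visible loss, but only
                # when it hangs off a speciation: a dead duplication copy
                # leaves no witness in the pruned gene tree
                det_loss += 1

    truth = SimTruth()
    truth.family_events[family] = (events["dup"], events["loss"])

    if not survives(root):
        truth.family_events_detectable[family] = (0, 0)
        return None, truth
    # events above the pruned gene-tree root (the first node with two
    # surviving sides) are invisible to reconciliation: start counting there
    backbone_root = root
    while True:
        surv = [c for c in backbone_root.children if survives(c)]
        if len(surv) != 1:
            break
        backbone_root = surv[0]
    count_detectable(backbone_root)
    truth.family_events_detectable[family] = (det_dup, det_loss)

    def to_newick(n: _GLineage, extra: float = 0.0) -> str | None:
        """Newick with branch lengths; unifurcations from losses and
        speciations are suppressed by summing edge lengths downward."""
        if n.event == "leaf":
            return f"{n.label}:{n.length + extra:.10g}"
        surv = [c for c in n.children if survives(c)]
        if not surv:
            return None
        if len(surv) == 1:
            return to_newick(surv[0], extra + n.length)
        parts = [to_newick(c) for c in surv]
        return "(" + ",".join(parts) + f"):{n.length + extra:.10g}"

    nwk = to_newick(root)
    if "(" not in (nwk or ""):
        nwk = f"({nwk});" if nwk else None
    else:
        nwk += ";"
    tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree, truth


# ---------------------------------------------------------------------------
# Sequence evolution

def _k2p_probs(kappa: float, rate: float, t: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after branch length t."""
    if math.isinf(kappa):
        alpha, beta = rate, 0.0
    else:
        beta = rate / (kappa + 2.0)
        alpha = rate * kappa / (kappa + 2.0)
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_ts, p_tv


_TS_PARTNER = {"A": "G", "G": "A", "C": "U", "U": "C"}


def _mutate(seq: list[str], partner: dict[int, int], frozen: set[int],
            t: float, rate: float, kappa: float, p_comp: float,
            rng: random.Random) -> None:
    p_ts, p_tv = _k2p_probs(kappa, rate, t)
    for i in range(len(seq)):
        if i in frozen:
            continue
        r = rng.random()
        old = seq[i]
        if r < p_ts:
            new = _TS_PARTNER[old]
        elif r < p_ts + 2.0 * p_tv:
            tv = [b for b in "ACGU" if b != old and _TS_PARTNER[old] != b]
            new = tv[0] if r < p_ts + p_tv else tv[1]
        else:
            continue
        seq[i] = new
        j = partner.get(i)
        if j is not None and rng.random() < p_comp:
            seq[j] = COMPLEMENT[new]


def evolve_trna_sequences(gene_tree: dendropy.Tree, template: TRNAGene,
                          rate: float, kappa: float, p_comp: float = 0.9,
                          seed: int = 0) -> list[TRNAGene]:
    """Evolve the template along a gene tree under K2P(kappa).

    Stem substitutions are made compensatory (partner site set to the
    complement) with probability ``p_comp``, preserving the annotated
    structure.  The three anticodon positions are frozen.  Leaves yield
    :class:`TRNAGene` records labeled by their ``species|copy`` leaf names.
    """
    from .cloverleaf import extract_anticodon, pairs_from_dot_bracket
    rng = random.Random(seed)
    pairs = pairs_from_dot_bracket(template.dot_bracket)
    partner: dict[int, int] = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    cl = parse_structure(template)
    _, ac_start = extract_anticodon(cl)
    frozen = {ac_start, ac_start + 1, ac_start + 2}

    genes: list[TRNAGene] = []

    def walk(node, seq: list[str]) -> None:
        if node.edge.length:
            seq = list(seq)
            _mutate(seq, partner, frozen, node.edge.length, rate, kappa,
                    p_comp, rng)
        if node.is_leaf():
            label = node.taxon.label
            genes.append(replace(
                template,
                gene_id=f"{template.isotype}-{template.anticodon}|{label}",
                species=label.split("|")[0],
                sequence="".join(seq),
            ))
        else:
            for c in node.child_nodes():
                walk(c, seq)

    walk(gene_tree.seed_node, list(template.sequence))
    return genes


def simulate_k2p_alignment(tree: dendropy.Tree, n_sites: int, rate: float,
                           kappa: float, seed: int = 0) -> dict[str, str]:
    """Evolve an unconstrained alignment under K2P along a tree.

    Independent sites, uniform root composition; returns leaf label ->
    sequence.  Used for estimator-recovery experiments where cloverleaf
    constraints would only add noise.
    """
    import numpy as np
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    # index maps: transition partner and the two transversion targets
    ts_map = np.array([2, 3, 0, 1])   # A<->G, C<->U
    tv1_map = np.array([1, 0, 1, 0])  # first transversion target per base
    tv2_map = np.array([3, 2, 3, 2])  # second transversion target per base

    out: dict[str, str] = {}

    def walk(node, seq):
        t = node.edge.length or 0.0
        if t > 0:
            p_ts, p_tv = _k2p_probs(kappa, rate, t)
            r = rng.random(n_sites)
            seq = np.where(r < p_ts, ts_map[seq],
                           np.where(r < p_ts + p_tv, tv1_map[seq],
                                    np.where(r < p_ts + 2 * p_tv,
                                             tv2_map[seq], seq)))
        if node.is_leaf():
            out[node.taxon.label] = "".join(bases[seq])
        else:
            for c in node.child_nodes():
                walk(c, seq)

    root_seq = rng.integers(0, 4, n_sites)
    walk(tree.seed_node, root_seq)
    return out


# ---------------------------------------------------------------------------
# Variant injection

def inject_variants(genes: list[TRNAGene], p_t1: float, p_t2: float,
                    p_t3: float, p_t4: float, seed: int = 0,
                    ) -> tuple[list[TRNAGene], dict[str, StructuralType]]:
    """Inject the four structural-variant classes, one draw per gene.

    TYPE1 deletes the acceptor 5' strand (and unpairs the orphaned 3'
    strand); TYPE2 appends a 2-6 nt random trailer that is never exactly
    CCA; TYPE3 replaces the variable region with a 10-16 nt stem-loop of
    >= 3 bp; TYPE4 applies both edits.  Assignment is mutually exclusive;
    the remaining probability mass leaves the gene unchanged (NORMAL).
    """
    if p_t1 + p_t2 + p_t3 + p_t4 > 1.0:
        raise ValueError("variant probabilities sum to > 1")
    rng = random.Random(seed)
    out: list[TRNAGene] = []
    truth: dict[str, StructuralType] = {}
    for gene in genes:
        r = rng.random()
        if r < p_t1:
            st = StructuralType.TYPE1
        elif r < p_t1 + p_t2:
            st = StructuralType.TYPE2
        elif r < p_t1 + p_t2 + p_t3:
            st = StructuralType.TYPE3
        elif r < p_t1 + p_t2 + p_t3 + p_t4:
            st = StructuralType.TYPE4
        else:
            st = StructuralType.NORMAL
        g = _apply_variant(gene, st, rng)
        truth[g.gene_id] = st
        out.append(g)
    return out, truth


def _random_trailer(rng: random.Random) -> str:
    while True:
        tail = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 6)))
        if tail != "CCA":
            return tail


def _variable_arm(rng: random.Random) -> tuple[str, str]:
    stem = rng.randint(3, 5)
    total = rng.randint(max(10, 2 * stem + 3), 16)
    loop = total - 2 * stem
    s5 = "".join(rng.choice("ACGU") for _ in range(stem))
    mid = "".join(rng.choice("ACGU") for _ in range(loop))
    seq = s5 + mid + revcomp(s5)
    db = "(" * stem + "." * loop + ")" * stem
    return seq, db


def _apply_variant(gene: TRNAGene, st: StructuralType,
                   rng: random.Random) -> TRNAGene:
    if st is StructuralType.NORMAL:
        return gene
    cl = parse_structure(gene)
    seq, db = list(gene.sequence), list(gene.dot_bracket)

    def splice(indices: list[int], new_seq: str, new_db: str) -> None:
        lo, hi = min(indices), max(indices) + 1
        seq[lo:hi] = list(new_seq)
        db[lo:hi] = list(new_db)

    if st in (StructuralType.TYPE3, StructuralType.TYPE4):
        arm_seq, arm_db = _variable_arm(rng)
        splice(cl.regions["variable_region"], arm_seq, arm_db)
    if st in (StructuralType.TYPE2, StructuralType.TYPE4):
        tail = _random_trailer(rng)
        seq += list(tail)
        db += ["."] * len(tail)
    if st is StructuralType.TYPE1:
        for i in cl.regions["acceptor_stem_3p"]:
            db[i] = "."
        acc5 = cl.regions["acceptor_stem_5p"]
        lo, hi = min(acc5), max(acc5) + 1
        del seq[lo:hi]
        del db[lo:hi]
    return replace(gene, sequence="".join(seq), dot_bracket="".join(db))


# ---------------------------------------------------------------------------
# Whole cohorts

def generate_cohort(config: SimConfig,
                    ) -> tuple[dendropy.Tree, list[TRNAGene], SimTruth,
                               dict[str, dendropy.Tree]]:
    """Generate a full synthetic cohort under one config and seed.

    Returns the species tree, all gene records (variants injected), the
    ground truth, and the per-family gene trees (families driven extinct
    are absent).  Fully deterministic in ``config`` including its seed.
    """
    master = random.Random(config.seed)
    sub = lambda: master.randrange(2 ** 31)

    species_tree = simulate_species_tree(
        config.n_species, config.speciation_rate, seed=sub())
    truth = SimTruth(kappa=config.kappa)
    genes: list[TRNAGene] = []
    gene_trees: dict[str, dendropy.Tree] = {}

    for isotype, anticodon in ISOACCEPTOR_SET:
        fam = f"{isotype}-{anticodon}"
        template = make_trna_template(isotype, anticodon, seed=sub())
        truth.templates[(isotype, anticodon)] = template
        gtree, ftruth = simulate_gene_family(
            species_tree, config.duplication_rate, config.loss_rate,
            seed=sub(), family=fam)
        truth.family_events.update(ftruth.family_events)
        truth.family_events_detectable.update(ftruth.family_events_detectable)
        if gtree is None:
            continue
        gene_trees[fam] = gtree
        genes.extend(evolve_trna_sequences(
            gtree, template, config.substitution_rate, config.kappa,
            config.p_comp, seed=sub()))

    genes, types = inject_variants(
        genes, config.p_t1, config.p_t2, config.p_t3, config.p_t4, seed=sub())
    truth.structural_types.update(types)
    return species_tree, genes, truth, gene_trees
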