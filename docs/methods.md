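# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical conventions, so that results can be interpreted without
reading the code.

## Cloverleaf decomposition

Input structures are annotated dot-bracket strings (tRNAscan-SE-style
`>`/`<` output is translated on read).  Helices are maximal stacks of
nested pairs; interior bulges of ≤ 2 nt on a strand do not split a helix.
The helix whose outermost pair spans the 5′-most and 3′-most paired
positions is the acceptor stem; the remaining helices, ordered by their 5′
strands, are the D stem, the anticodon stem, zero or more variable-arm
helices, and the T stem.  Structures with no enclosing helix (no acceptor
pairs) are parsed in degraded mode: empty acceptor stem, no discriminator,
all 3′ unpaired residues as trailer — enough to classify them as Type 1.

**Spacer convention (flagged prominently).**  The eight-region accounting
assigns the two unpaired linkers between acceptor stem and D stem
(canonical positions 8–9) and the single linker between D stem and
anticodon stem (canonical 26) to the **D-loop total**; they have no other
home in an eight-region scheme, and the resulting D-loop mode (9 nt over
surveyed plastomes) matches this convention.  Bulged nucleotides tolerated
inside a stem are counted with the adjacent loop (acceptor 5′-side bulges
with the D loop, 3′-side with the Ψ loop), so the partition invariant
`2·(stems in bp) + loops + variable + discriminator + trailer = length`
holds for every parse and is re-checked on every profile.

**Anticodon.**  For the canonical 7-nt loop the anticodon is loop
positions 3–5; other odd lengths take the centered triplet; even lengths
skip the extra 5′ residue first.  Decoding reverse-complements the
anticodon and translates by the standard genetic code; CAU is ambiguous
(Met / Ile with lysidine-modified C34 / initiator fMet) and a declared
annotation wins there.  Triplets reading a stop codon are flagged as
putative suppressors.

**Variant classes.**  Type 1 iff zero acceptor pairs (takes precedence).
Otherwise `extra3` = nonempty trailer ≠ exactly `CCA` (a genomically
precoded CCA tail is maturation, not a structural change, and is reported
separately), and `vararm` = an internal variable-region helix of ≥ 2 bp
(the 2-bp floor excludes incidental single pairs; the long-variable-arm
isotypes Ser/Leu/Tyr clear it comfortably).  Type 4 = both, Type 2 =
`extra3` only, Type 3 = `vararm` only, else Normal.

## Free energies

The default engine evaluates the **given** structure (no search): summed
Watson–Crick stacked-pair energies from an embedded Turner-style table
(kcal/mol, 37 °C) plus fixed loop penalties by size class (hairpin, bulge,
internal, multibranch: offset 3.4 + 0.4 per branch), with
Jacobson–Stockmayer extrapolation beyond tabulated sizes.  Stacks
involving a G·U wobble pair get a single flat −0.5 term: it keeps every
stack strictly stabilizing (the monotonicity property tests rely on that)
at the cost of wobble-stack fidelity; synthetic stems are pure
Watson–Crick so this only touches annotated real-world input.  The
parameter set is version-stamped (`turner-wc-stacks-2004/simplified-loops-v1`)
in every output.  ViennaRNA can be used as an external engine when its
bindings are importable; it is never the default, and absolute ΔG values
from the simplified evaluator are systematically weaker than Turner-full
values — per-class *orderings* and the recomputation of published
per-tRNA survey means are the supported uses.  Means are rounded half away
from zero at one decimal (a class mean of exactly −28.25 prints −28.3).

## Conservation and consensus

The aligner is a deliberately simple progressive profile aligner: affine
gaps (match +2, mismatch −1, open −12, extend −2), guide order = input
order, deterministic traceback.  Region subsequences within an
isoacceptor family are short (4–16 nt) and near identical, where any sane
global aligner finds the same columns; the scores are parameters.
Consensus tokens per column: the top base if its frequency ≥ `high`
(default 0.90); else `N1/N2` when the top two sum to ≥ `high` **and** the
minor base carries at least `low` (default 0.50) of the major's weight —
this minor/major reading is the one consistent with alternative calls
like C(60%)/U(35%); else `X`.  Runs of X columns containing gaps collapse
to `X_a-b` (min–max residues per row across the span), or `X_a` when
occupancy is constant.  Raising `high` can only demote base tokens
(monotonicity, property-tested).

## Substitution patterns

K2P throughout: distance d = −½ln(1−2P−Q) − ¼ln(1−2Q) with pairwise
deletion of gapped sites.  κ is estimated from the per-pair transition and
transversion components s, v (same closed forms) **summed over pairs**,
κ = 2Σs/Σv.  Pooling raw P, Q across pairs before the logs is biased
downward when pair distances are heterogeneous (Jensen); the per-pair sum
is unbiased in that regime and identical in the low-divergence limit that
chloroplast tRNAs occupy.  Q = 0 gives κ = ∞, printed as entries
25.00/0.00; alignments without variable sites are flagged undefined.
Pattern tables assume equal base frequencies, so each 4×4 row carries one
transition entry 25κ/(κ+2) and two transversion entries 25/(κ+2)
(row sum 25, table sum 100) — the ×100 probability scale reverse-engineered
from the arithmetic of published tables of this kind.  The estimator
recovery experiment uses 10-taxon Yule(1.0) trees and 2000 sites at 0.2
substitutions/site/unit, a divergence at which transversion events are
plentiful enough for a well-conditioned estimate; κ ∈ {2, 5} recovery
within 10% succeeds in ≥ 90% of 50 replicates.

Trees are Saitou–Nei neighbor joining over K2P distances, with Q-matrix
ties broken by the lexicographically smallest cluster-representative
labels, so identical matrices always give identical trees.  Branch lengths
are left as computed (possibly negative for non-additive input); additive
matrices are recovered exactly.  ML tree search, bootstrap and model
selection are out of scope; the NJ tree is a desk-scale stand-in.

## Reconciliation

Standard LCA mapping of a rooted binary gene tree onto a rooted binary
species tree: M(leaf) = its species, M(v) = LCA(M(children)).  v is a
duplication iff a child maps to M(v); losses per child edge are
max(0, dist(M(v), M(u)) − 1 + [v dup]).  Multifurcations are refused
(resolution choice changes counts; failing loudly beats guessing);
unrooted gene trees can be rooted by exhaustively minimizing D + L over
all edges, ties broken by smallest Newick string.  Conditional
duplications (weak-support rescue) are not implemented — they need
bootstrap supports this pipeline does not produce.

The implementation is verified against an independent brute-force dynamic
program that minimizes total events over *all* valid gene→species node
mappings (200 random instances, ≤ 6 species, ≤ 8 genes), both for D + L
and for D alone.

## Synthetic cohorts

Defaults are the study conditions of the gymnosperm chloroplast cohort
this generator emulates, fixed once: 54 species, 33 isoacceptor families
(the observed anticodon repertoire plus the initiator, giving the ~33
genes/species target), Yule speciation rate 1.0, duplication and loss
rates 0.05 per unit branch, substitution rate 0.05/site/unit, κ = 5.8
(the overall transition/transversion entry ratio 18.63/3.19), compensatory
probability 0.9, and variant injection probabilities proportional to the
published variant counts (Type 3 dominant at ≈ 0.18: long-variable-arm
isotypes are class-II in every species).

Templates are 70-nt canonical cloverleaves — acceptor 7 bp (5′ G), merged
D loop 8 nt, D stem 4 bp, anticodon stem 5 bp with loop
C-U-⟨anticodon⟩-A-A, 5-nt variable region, T stem 5 bp, Ψ loop
U-U-C-N-N-N-U, one discriminator — with Watson–Crick stems.  Gene
families follow a birth–death walk along the species tree; truth records
**all** events and separately the *detectable* subset: duplications whose
both daughter lineages survive, and losses as maximal extinct subtrees
hanging off speciation nodes of the surviving backbone, counted only at or
below the pruned gene-tree root.  That subset is precisely what LCA
reconciliation can in principle see — dead duplication copies leave no
witness, and events above the root mapping are unknowable — and the
recovery tests compare against it; raw counts remain available.  Sequences
evolve by per-branch K2P sampling; a stem substitution is mirrored by the
complementary change at its partner with probability `p_comp`, preserving
the annotated structure; the three anticodon positions are frozen
(purifying selection), which also keeps each record's declared anticodon
literally true.  Variant injection makes one draw per gene (mutually
exclusive classes); Type 1 deletion also unpairs the orphaned acceptor 3′
strand so the dot-bracket stays balanced.

**What the generator does not emulate:** genomic context (inverted
repeats, operons), indel evolution outside the defined variant edits,
rate heterogeneity across sites or lineages, base-composition bias, GU
wobble pairs in stems, precoded CCA tails at cohort level, and real
accession-level sequence identity.  Passing tests therefore demonstrate
correctness of the *methods* under K2P/birth–death assumptions, not
fidelity to any particular real genome set; dataset-level published
totals (e.g. genome-wide duplication/loss counts) require the original
54 genomes and are not reproduced here.

## Numerical conventions and degenerate inputs

Printed percentages and means round half away from zero at the printed
precision (2 decimals for percentages, 1 for ΔG).  DNA input is
normalized to RNA (T→U); ambiguity codes reject the individual record
with a warning.  Accepted gene lengths are 50–120 nt (observed range
56–90 plus margin).  Zero-pair structures evaluate to ΔG = 0.0 with a
warning; empty gene lists are errors for statistics that need data;
families driven extinct return an empty gene tree with truth retained.
All external GenBank coordinates are 1-based inclusive, internal indices
0-based half-open; conversion happens only at the I/O boundary.

## Sizes used by the default runs

The analysis scripts run the full 54-species conditions (~1750 genes of
~70 nt; seconds of CPU).  The acceptance script uses 54 species for
cohort summaries, 18 species (500 genes kept) for variant recovery, 33
species (1000 genes kept) for partition identity, 50 replicates per κ for
estimator recovery, 200 random instances for the reconciliation oracle,
and 20 random additive matrices for NJ recovery — sizes chosen so the
whole script completes in well under a minute while keeping every rate
estimate at its specified replicate count.
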