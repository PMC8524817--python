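"""End-to-end orchestration of the analysis stages.

``run_pipeline`` chains the stages in order — simulate (or load) a cohort,
annotate cloverleaf structures, frequency/length profiling, consensus
motifs, free-energy typing, substitution patterns, NJ trees and
duplication-loss reconciliation — writing one TSV (or Newick) per analysis
plus a JSON run manifest.  Every output starts with ``#`` header lines
carrying the tool version, seed and config hash, and a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from ._util import round_half_away
from .cloverleaf import (classify_structure, detect_precoded_cca,
                         parse_structure, region_profile)
from .conservation import (align_isotype_regions, anticodon_presence_counts,
                           call_consensus, isotype_frequency_matrix,
                           length_stats, region_length_distribution)
from .evolution import distance_matrix, nj_tree
from .io_formats import TRNAGene, read_fasta, write_fasta, read_newick, write_newick
from .reconciliation import NotBinaryError, reconcile
from .synthetic_data import SimConfig, generate_cohort
from .thermo import MFERecord, PARAMETER_SET, aggregate_mfe_by_type, evaluate_structure_energy

logger = logging.getLogger("cptrna")

STAGES = ("simulate", "annotate", "profile", "consensus", "mfe", "subst",
          "tree", "reconcile")

#: regions whose subsequences enter the consensus analysis
_CONSENSUS_REGIONS = (
    "acceptor_stem_5p", "d_stem_5p", "d_loop", "anticodon_stem_5p",
    "anticodon_loop", "variable_region", "t_stem_5p", "t_loop",
)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    """Validated run configuration, echoed into the output directory."""

    output_dir: str = "results/run"
    input_dir: str | None = None  # cohort directory; None -> simulate
    seed: int = 0
    n_species: int = 54
    consensus_high: float = 0.90
    consensus_low: float = 0.50
    sim: SimConfig = field(default_factory=SimConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.consensus_low <= self.consensus_high <= 1.0:
            raise ValueError("need 0 < consensus_low <= consensus_high <= 1")
        self.sim = dataclasses.replace(self.sim, n_species=self.n_species,
                                       seed=self.seed)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (paths and logging are
        excluded so identical analyses hash identically anywhere)."""
        d = dataclasses.asdict(self)
        for key in ("output_dir", "input_dir", "log_level"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (f"# cptrna {__version__}\n"
            f"# seed={config.seed} config={config.config_hash()}\n")


def _write_tsv(path: Path, df: pd.DataFrame, config: RunConfig,
               extra: str = "", index: bool = False) -> None:
    with path.open("w") as fh:
        fh.write(_header(config))
        if extra:
            fh.write(extra)
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Cohort serialization (FASTA + dot-bracket sidecar + Newick + truth TSV)

def write_cohort(outdir: Path, species_tree, genes: list[TRNAGene], truth,
                 gene_trees: dict, config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "genes.fasta").open("w") as fh:
        write_fasta(((g.gene_id, g.sequence) for g in genes), fh)
    with (outdir / "genes.db").open("w") as fh:
        fh.write(_header(config))
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.dot_bracket or ''}\n")
    (outdir / "species.nwk").write_text(write_newick(species_tree) + "\n")
    with (outdir / "gene_trees.tsv").open("w") as fh:
        fh.write(_header(config))
        fh.write("family\tnewick\n")
        for fam in sorted(gene_trees):
            nwk = write_newick(gene_trees[fam]).replace("\n", " ")
            fh.write(f"{fam}\t{nwk}\n")
    rows = [{"gene_id": gid, "structural_type": str(st)}
            for gid, st in sorted(truth.structural_types.items())]
    _write_tsv(outdir / "truth_types.tsv", pd.DataFrame(rows), config)
    ev = [{"family": fam,
           "duplications": d, "losses": l,
           "detectable_duplications": truth.family_events_detectable[fam][0],
           "detectable_losses": truth.family_events_detectable[fam][1]}
          for fam, (d, l) in sorted(truth.family_events.items())]
    _write_tsv(outdir / "truth_events.tsv", pd.DataFrame(ev), config,
               extra=f"# kappa={truth.kappa}\n")


def load_cohort(indir: Path) -> tuple[dendropy.Tree, list[TRNAGene], dict]:
    """Read a cohort directory back into genes + trees.

    Gene metadata is recovered from the ``Isotype-Anticodon|species|copy``
    id convention used by the generator.
    """
    indir = Path(indir)
    if not indir.is_dir():
        raise PipelineError(f"input directory {indir} does not exist")
    db = {}
    for line in (indir / "genes.db").read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        gid, _, struct = line.partition("\t")
        db[gid] = struct or None
    genes = []
    with (indir / "genes.fasta").open() as fh:
        for gid, seq in read_fasta(fh):
            fam, species, _copy = gid.split("|")
            isotype, _, anticodon = fam.partition("-")
            genes.append(TRNAGene(
                gene_id=gid, species=species, sequence=seq,
                isotype=isotype, anticodon=anticodon,
                structure_source="annotated" if db.get(gid) else "none",
                dot_bracket=db.get(gid)))
    species_tree = read_newick((indir / "species.nwk").read_text())
    species_tree.is_rooted = True
    gene_trees = {}
    gt_path = indir / "gene_trees.tsv"
    if gt_path.exists():
        for line in gt_path.read_text().splitlines():
            if line.startswith("#") or line.startswith("family") or not line.strip():
                continue
            fam, _, nwk = line.partition("\t")
            t = read_newick(nwk)
            t.is_rooted = True
            gene_trees[fam] = t
    return species_tree, genes, gene_trees


# ---------------------------------------------------------------------------
# Stages

def _annotate(genes: list[TRNAGene]):
    """Parse every structured gene; returns (rows, profiles, structures)."""
    rows, profiles, structures = [], [], {}
    for g in genes:
        if not g.dot_bracket:
            continue
        cl = parse_structure(g)
        prof = region_profile(cl, g.gene_id)
        st = classify_structure(cl)
        structures[g.gene_id] = cl
        profiles.append(prof)
        rows.append({
            "gene_id": g.gene_id, "species": g.species,
            "isotype": g.isotype, "anticodon": g.anticodon,
            "length": len(g.sequence),
            "ac_arm": prof.ac_arm, "d_arm": prof.d_arm,
            "d_loop": prof.d_loop, "anc_arm": prof.anc_arm,
            "anc_loop": prof.anc_loop, "variable": prof.variable,
            "psi_arm": prof.psi_arm, "psi_loop": prof.psi_loop,
            "precoded_cca": detect_precoded_cca(cl),
            "structural_type": str(st),
        })
    return rows, profiles, structures


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in canonical order; returns the manifest.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are left in place.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "energy_parameters": PARAMETER_SET,
        "outputs": [],
    }
    state: dict = {}
    stage_order = [s for s in STAGES if s in stages]
    for stage in stage_order:
        t0 = time.monotonic()
        try:
            _run_stage(stage, config, outdir, state, manifest)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", stage, time.monotonic() - t0)
    manifest["outputs"] = sorted(manifest["outputs"])
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _ensure_cohort(config: RunConfig, outdir: Path, state: dict,
                   manifest: dict) -> None:
    if "genes" in state:
        return
    if config.input_dir is not None:
        species_tree, genes, gene_trees = load_cohort(Path(config.input_dir))
    else:
        species_tree, genes, truth, gene_trees = generate_cohort(config.sim)
        state["truth"] = truth
    state.update(species_tree=species_tree, genes=genes, gene_trees=gene_trees)


def _run_stage(stage: str, config: RunConfig, outdir: Path, state: dict,
               manifest: dict) -> None:
    add = manifest["outputs"].append

    if stage == "simulate":
        if config.input_dir is not None:
            logger.info("input_dir given; simulate stage loads instead")
        _ensure_cohort(config, outdir, state, manifest)
        if "truth" in state:
            write_cohort(outdir / "cohort", state["species_tree"],
                         state["genes"], state["truth"],
                         state["gene_trees"], config)
            add("cohort")
        return

    _ensure_cohort(config, outdir, state, manifest)
    genes = state["genes"]

    if stage == "annotate":
        rows, profiles, structures = _annotate(genes)
        state["profiles"], state["structures"] = profiles, structures
        state["rows"] = rows
        _write_tsv(outdir / "annotated_genes.tsv", pd.DataFrame(rows), config)
        add("annotated_genes.tsv")
        return

    if "rows" not in state:
        _run_stage("annotate", config, outdir, state, manifest)

    if stage == "profile":
        freq = isotype_frequency_matrix(genes)
        _write_tsv(outdir / "isotype_frequency.tsv", freq.isotype_by_species,
                   config,
                   extra=f"# mean_genes_per_species={freq.mean_genes_per_species:.2f}\n",
                   index=True)
        pres = anticodon_presence_counts(genes, n_species=config.n_species)
        pres_df = pd.DataFrame(
            [{"isotype": i, "anticodon": a, "n_species": n}
             for (i, a), n in pres.items()])
        _write_tsv(outdir / "anticodon_presence.tsv", pres_df, config)
        hist = region_length_distribution(state["profiles"])
        hist_df = pd.DataFrame(
            [{"region": reg, "length": ln, "count": c, "percent": pct}
             for reg, d in hist.items() for ln, (c, pct) in d.items()])
        mn, mx, mean = length_stats(genes)
        _write_tsv(outdir / "region_histograms.tsv", hist_df, config,
                   extra=f"# gene_length min={mn} max={mx} mean={mean}\n")
        add("isotype_frequency.tsv")
        add("anticodon_presence.tsv")
        add("region_histograms.tsv")
        return

    if stage == "consensus":
        structures = state["structures"]
        fams: dict[tuple[str, str], list] = {}
        for g in genes:
            if g.gene_id in structures and g.isotype and g.anticodon:
                fams.setdefault((g.isotype, g.anticodon), []).append(g)
        rows = []
        for (iso, ac), members in sorted(fams.items()):
            members.sort(key=lambda g: g.gene_id)
            for region in _CONSENSUS_REGIONS:
                seqs = [structures[g.gene_id].region_seq(region) for g in members]
                aln = align_isotype_regions([s for s in seqs if s] or [""])
                motif = call_consensus(aln, config.consensus_high,
                                       config.consensus_low, iso, ac, region)
                rows.append({"isotype": iso, "anticodon": ac,
                             "region": region, "motif": str(motif)})
        _write_tsv(outdir / "consensus_motifs.tsv", pd.DataFrame(rows), config)
        add("consensus_motifs.tsv")
        return

    if stage == "mfe":
        structures = state["structures"]
        from .cloverleaf import StructuralType
        records = []
        for row in state["rows"]:
            cl = structures[row["gene_id"]]
            records.append(MFERecord(
                gene_id=row["gene_id"],
                structural_type=StructuralType(row["structural_type"]),
                delta_g=round_half_away(evaluate_structure_energy(cl), 1)))
        state["mfe_records"] = records
        df = pd.DataFrame([{
            "gene_id": r.gene_id, "structural_type": str(r.structural_type),
            "delta_g": f"{r.delta_g:.1f}", "engine": r.engine} for r in records])
        _write_tsv(outdir / "mfe.tsv", df, config,
                   extra=f"# parameters={PARAMETER_SET}\n")
        agg = aggregate_mfe_by_type(records)
        agg_df = pd.DataFrame([
            {"structural_type": str(t), "n": n, "mean_delta_g": f"{m:.1f}"}
            for t, (n, m) in agg.items()])
        _write_tsv(outdir / "mfe_summary.tsv", agg_df, config)
        add("mfe.tsv")
        add("mfe_summary.tsv")
        return

    if stage == "subst":
        from .evolution import alignment_sv, pattern_from_sv
        # homologous alignments exist within an isoacceptor family (equal
        # lengths; indel-free evolution); per-pair components are summed
        # across the families of an isotype, then across all isotypes
        fams: dict[tuple[str, str], list[str]] = {}
        for g in genes:
            fams.setdefault((g.isotype or "?", g.anticodon or "?"),
                            []).append(g.sequence)
        per_iso: dict[str, list[float]] = {}
        for (iso, _ac), seqs in sorted(fams.items()):
            lengths = pd.Series([len(s) for s in seqs])
            mode = int(lengths.mode().iloc[0])
            seqs = [s for s in seqs if len(s) == mode]
            if len(seqs) < 2:
                continue
            parts = alignment_sv(seqs)
            acc = per_iso.setdefault(iso, [0.0, 0.0, 0, 0, 0])
            for k in range(5):
                acc[k] += parts[k]
        rows = []
        overall = [0.0, 0.0, 0, 0, 0]
        for iso in sorted(per_iso) + ["overall"]:
            if iso == "overall":
                if overall[4] == 0:
                    continue
                S, V, ts, tv, n = overall
            else:
                S, V, ts, tv, n = per_iso[iso]
                overall = [a + b for a, b in zip(overall, per_iso[iso])]
            pat = pattern_from_sv(S, V, ts, tv, n, iso)
            if not pat.defined:
                rows.append({"isotype": iso, "ts": "undefined",
                             "tv": "undefined", "kappa": "undefined",
                             "n_sites": n})
                continue
            rows.append({"isotype": iso,
                         "ts": f"{pat.ts_entry:.2f}", "tv": f"{pat.tv_entry:.2f}",
                         "kappa": "inf" if pat.kappa == float("inf") else f"{pat.kappa:.3f}",
                         "n_sites": n})
        _write_tsv(outdir / "substitution_patterns.tsv", pd.DataFrame(rows), config)
        add("substitution_patterns.tsv")
        return

    if stage == "tree":
        # one representative per (species, family), families present everywhere,
        # concatenated into a per-species supermatrix
        species = sorted({g.species for g in genes})
        fams: dict[str, dict[str, str]] = {}
        for g in genes:
            fam = f"{g.isotype}-{g.anticodon}"
            fams.setdefault(fam, {})
            cur = fams[fam].get(g.species)
            if cur is None or g.gene_id < cur[0]:
                fams[fam][g.species] = (g.gene_id, g.sequence)
        concat = {sp: "" for sp in species}
        for fam in sorted(fams):
            rep = fams[fam]
            if set(rep) != set(species):
                continue
            if len({len(s) for _, s in rep.values()}) != 1:
                continue
            for sp in species:
                concat[sp] += rep[sp][1]
        labels = [sp for sp in species if concat[sp]]
        if len(labels) >= 3:
            _, dm = distance_matrix(labels, [concat[sp] for sp in labels])
            tree = nj_tree(labels, dm)
            (outdir / "species_nj.nwk").write_text(
                _header(config) + write_newick(tree) + "\n")
            add("species_nj.nwk")
        return

    if stage == "reconcile":
        species_tree = state["species_tree"]
        rows = []
        totals = [0, 0]
        truth = state.get("truth")
        for fam in sorted(state["gene_trees"]):
            gtree = state["gene_trees"][fam]
            try:
                res = reconcile(gtree, species_tree)
            except (NotBinaryError, KeyError):
                continue
            row = {"family": fam, "duplications": res.duplications,
                   "losses": res.losses}
            if truth is not None:
                d, l = truth.family_events_detectable[fam]
                row["true_detectable_duplications"] = d
                row["true_detectable_losses"] = l
            totals[0] += res.duplications
            totals[1] += res.losses
            rows.append(row)
        _write_tsv(outdir / "reconciliation.tsv", pd.DataFrame(rows), config,
                   extra=f"# total_duplications={totals[0]} total_losses={totals[1]}\n")
        add("reconciliation.tsv")
        return

    raise PipelineError(f"unknown stage {stage!r}")
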