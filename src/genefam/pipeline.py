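"""End-to-end orchestration of the gene-family characterization workflow.

Stages: domain scan and curation of both genomes, naming, combined
protein phylogeny with bootstrap, paralog/ortholog terminal pairs,
duplicate detection and tandem/segmental classification, Ka/Ks and
divergence dating of duplicated pairs, dual-genome collinearity,
promoter cis-element scan, motif discovery, and (when supplied)
expression and qPCR summaries. Every output is a TSV (or Newick) under
the configured output directory, plus a machine-readable run manifest.
The pipeline is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .curation import (CurationParams, DomainModel, assign_names, curate_family,
                       scan_domains)
from .dupsyn import (DuplicationParams, chain_collinearity, classify_duplication,
                     find_duplicates, reciprocal_best_sequences)
from .expression import (ExpressionMatrix, QpcrMeasurement, delta_delta_ct,
                         normalize_for_heatmap, order_rows)
from .io import read_fasta, read_gff3
from .molevol import (MolEvolParams, build_codon_alignment, kaks_estimate,
                      ng86_counts)
from .motif import (DEFAULT_CIS_CATALOG, discover_motifs, gene_structure,
                    load_catalog_tsv, scan_cis_elements)
from .phylo import (PhyloParams, bootstrap_support, extract_terminal_pairs,
                    neighbor_joining, pairwise_align_global,
                    poisson_distance_matrix, progressive_msa)
from .simulate import SimulationConfig, simulate_expression_and_qpcr, \
    simulate_family_genomes

__all__ = ["GenomeInput", "PipelineConfig", "PipelineError", "run_pipeline",
           "run_pipeline_from_bundles", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


STAGES = ["curate", "phylo", "dupsyn", "kaks", "structure", "motif",
          "cispromo", "express", "qpcr"]


@dataclass
class GenomeInput:
    label: str
    species_prefix: str  # three-letter code, e.g. Gma
    genome_fasta: str = ""
    gff3: str = ""
    protein_fasta: str = ""
    cds_fasta: str = ""


@dataclass
class PipelineConfig:
    genomes: list[GenomeInput] = field(default_factory=list)
    family: str = "FAM"
    domain_consensus: str = ""
    outdir: str = "genefam_out"
    rng_seed: int = 0
    log_level: str = "INFO"
    curation: CurationParams = field(default_factory=CurationParams)
    phylo: PhyloParams = field(default_factory=PhyloParams)
    duplication: DuplicationParams = field(default_factory=DuplicationParams)
    molevol: MolEvolParams = field(default_factory=MolEvolParams)
    max_motifs: int = 10
    motif_width_range: tuple[int, int] = (6, 50)
    promoter_length: int = 1000
    cis_catalog_tsv: str = ""
    synteny_min_block: int = 5
    synteny_max_gap: int = 25
    expression_tsv: str = ""
    qpcr_tsv: str = ""
    qpcr_control: str = "0h"


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file with flat sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    for key in ("family", "domain_consensus", "outdir", "rng_seed", "log_level",
                "max_motifs", "promoter_length", "cis_catalog_tsv",
                "synteny_min_block", "synteny_max_gap", "expression_tsv",
                "qpcr_tsv", "qpcr_control"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "motif_width_range" in raw:
        cfg.motif_width_range = tuple(raw["motif_width_range"])
    for section, target in (("curation", cfg.curation), ("phylo", cfg.phylo),
                            ("duplication", cfg.duplication),
                            ("molevol", cfg.molevol)):
        for k, v in (raw.get(section) or {}).items():
            setattr(target, k, v)
    for g in raw.get("genomes", []):
        cfg.genomes.append(GenomeInput(**g))
    return cfg


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


class _Bundle:
    """In-memory genome bundle as the pipeline consumes it."""

    def __init__(self, label, prefix, genome, genes, proteins, cds):
        self.label = label
        self.prefix = prefix
        self.genome = genome
        self.genes = genes
        self.proteins = proteins
        self.cds = cds


def _load_bundle(gi: GenomeInput) -> _Bundle:
    genome = read_fasta(gi.genome_fasta, alphabet="dna")
    genes = read_gff3(gi.gff3)
    proteins = {r.id: r for r in read_fasta(gi.protein_fasta, alphabet="protein")}
    cds = {r.id: r.residues for r in read_fasta(gi.cds_fasta, alphabet="dna")}
    return _Bundle(gi.label, gi.species_prefix, genome, genes, proteins, cds)


def run_pipeline(cfg: PipelineConfig):
    """File-based entry point: load the configured bundles and run."""
    if len(cfg.genomes) != 2:
        raise PipelineError("curate", ValueError("exactly two genome bundles required"))
    bundles = [_load_bundle(g) for g in cfg.genomes]
    return run_pipeline_from_bundles(bundles[0], bundles[1], cfg)


def run_pipeline_from_bundles(bundle_a, bundle_b, cfg: PipelineConfig):
    """Run every stage on two loaded bundles; returns a result dict.

    On stage failure, partial outputs are kept and a FAILED marker file
    names the stage; the failure is re-raised as :class:`PipelineError`.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "curate"
    try:
        model = DomainModel(cfg.curation.domain_model_id, cfg.domain_consensus)
        members_by_genome = []
        for bundle, prefix in ((bundle_a, getattr(bundle_a, "prefix", "Gaa")),
                               (bundle_b, getattr(bundle_b, "prefix", "Gbb"))):
            prots = list(bundle.proteins.values())
            hits = scan_domains(prots, model, cfg.curation)
            members, report = curate_family(bundle.genes, bundle.proteins,
                                            bundle.cds, hits, cfg.curation)
            assign_names(members, prefix, cfg.family)
            members_by_genome.append(members)
            _write_tsv(outdir / f"curation_report_{bundle.label}.tsv",
                       ["gene_id", "kept", "reason"], report)
            _write_tsv(
                outdir / f"members_{bundle.label}.tsv",
                ["name", "gene_id", "chrom", "start", "end", "strand",
                 "protein_length", "mw_kda", "pi"],
                [(m.name, m.gene.gene_id, m.gene.chrom, m.gene.start,
                  m.gene.end, m.gene.strand, m.properties.length_aa,
                  f"{m.properties.mw_kda:.2f}", f"{m.properties.pi:.2f}")
                 for m in members],
            )
        members_a, members_b = members_by_genome
        results["members"] = {bundle_a.label: members_a, bundle_b.label: members_b}

        stage = "phylo"
        all_members = members_a + members_b
        species_of = {m.name: ("A" if m in members_a else "B") for m in all_members}
        msa = progressive_msa([(m.name, m.protein.residues) for m in all_members])
        dm = poisson_distance_matrix(msa, cfg.phylo.gap_policy)
        tree = neighbor_joining(dm)
        tree = bootstrap_support(msa, cfg.phylo, tree)
        (outdir / "family_tree.nwk").write_text(tree.newick() + "\n")
        paralogs, orthologs = extract_terminal_pairs(
            tree, species_of, cfg.phylo.support_threshold_for_pairs)
        _write_tsv(outdir / "terminal_pairs.tsv",
                   ["gene_a", "gene_b", "support", "relation"],
                   [(a, b, f"{s:.1f}", "paralog") for a, b, s in paralogs]
                   + [(a, b, f"{s:.1f}", "ortholog") for a, b, s in orthologs])
        results["tree"] = tree
        results["paralogs"], results["orthologs"] = paralogs, orthologs

        stage = "dupsyn"
        events = []
        for bundle, members in ((bundle_a, members_a), (bundle_b, members_b)):
            by_name = {m.name: m for m in members}
            for na, nb, ident in find_duplicates(members, cfg.duplication):
                events.append((bundle.label,
                               classify_duplication(by_name[na], by_name[nb],
                                                    ident, bundle.genes,
                                                    cfg.duplication)))
        results["duplications"] = events
        anchors = reciprocal_best_sequences(
            {g.gene_id: bundle_a.proteins[g.transcripts[0].transcript_id].residues
             for g in bundle_a.genes if g.transcripts
             and g.transcripts[0].transcript_id in bundle_a.proteins},
            {g.gene_id: bundle_b.proteins[g.transcripts[0].transcript_id].residues
             for g in bundle_b.genes if g.transcripts
             and g.transcripts[0].transcript_id in bundle_b.proteins},
        )
        blocks = chain_collinearity(bundle_a.genes, bundle_b.genes, anchors,
                                    cfg.synteny_min_block, cfg.synteny_max_gap)
        _write_tsv(outdir / "synteny_blocks.tsv",
                   ["block_id", "chrom_a", "chrom_b", "orientation",
                    "n_anchors", "anchors"],
                   [(b.block_id, b.chrom_a, b.chrom_b, b.orientation, b.score,
                     ";".join(f"{x}|{y}" for x, y in b.anchors)) for b in blocks])
        results["synteny"] = blocks

        stage = "kaks"
        kaks_rows = []
        member_index = {m.name: m for m in all_members}
        for label, ev in events:
            ma, mb = member_index[ev.pair[0]], member_index[ev.pair[1]]
            aln, _ = pairwise_align_global(ma.protein.residues, mb.protein.residues,
                                           ids=(ma.name, mb.name))
            ca = build_codon_alignment(ma.cds, mb.cds, aln,
                                       cfg.molevol.genetic_code)
            S, N, Sd, Nd = ng86_counts(ca, cfg.molevol)
            res = kaks_estimate(S, N, Sd, Nd, cfg.molevol)
            kaks_rows.append((f"{ev.pair[0]}/{ev.pair[1]}", f"{res.Ka:.4f}",
                              f"{res.Ks:.4f}", f"{res.ratio:.4f}",
                              f"{res.time_mya:.2f}", ev.type, res.selection))
            results.setdefault("kaks", []).append((label, ev, res))
        _write_tsv(outdir / "duplication_kaks.tsv",
                   ["pair", "Ka", "Ks", "Ka/Ks", "Mya", "duplicate_type",
                    "selection"], kaks_rows)

        stage = "structure"
        structure_rows = []
        for m in all_members:
            gs = gene_structure(m.gene, m.transcript)
            structure_rows.append((m.name, gs.exon_count, gs.intron_count,
                                   ";".join(f"{s}-{e}" for s, e in gs.exons)))
        _write_tsv(outdir / "gene_structure.tsv",
                   ["name", "exons", "introns", "exon_intervals"], structure_rows)

        stage = "motif"
        motifs = discover_motifs([m.protein for m in all_members],
                                 max_motifs=cfg.max_motifs,
                                 width_range=cfg.motif_width_range,
                                 rng_seed=cfg.rng_seed)
        _write_tsv(outdir / "motifs.tsv",
                   ["rank", "width", "information_bits", "consensus",
                    "n_occurrences"],
                   [(k + 1, m.width, f"{m.information_bits:.2f}", m.consensus,
                     len(m.occurrences)) for k, m in enumerate(motifs)])
        results["motifs"] = motifs

        stage = "cispromo"
        catalog = (load_catalog_tsv(cfg.cis_catalog_tsv)
                   if cfg.cis_catalog_tsv else DEFAULT_CIS_CATALOG)
        promoters = []
        from .io import extract_upstream
        for bundle, members in ((bundle_a, members_a), (bundle_b, members_b)):
            for m in members:
                rec = extract_upstream(bundle.genome, m.gene, cfg.promoter_length,
                                       m.transcript)
                rec.id = m.name
                promoters.append(rec)
        hits, summary = scan_cis_elements(promoters, catalog)
        _write_tsv(outdir / "cis_hits.tsv", ["gene", "element", "position", "strand"],
                   [(h.gene, h.element, h.position, h.strand) for h in hits])
        _write_tsv(outdir / "cis_summary.tsv", ["gene", "class", "count"],
                   [(g, c, n) for g in sorted(summary)
                    for c, n in sorted(summary[g].items())])
        results["cis_hits"] = hits

        stage = "express"
        if cfg.expression_tsv:
            import pandas as pd
            table = pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
            norm = normalize_for_heatmap(ExpressionMatrix(table))
            perm = order_rows(norm)
            ordered = norm.values.iloc[perm]
            ordered.to_csv(outdir / "expression_zscores.tsv", sep="\t")
            results["expression"] = norm

        stage = "qpcr"
        if cfg.qpcr_tsv:
            import pandas as pd
            table = pd.read_csv(cfg.qpcr_tsv, sep="\t")
            rows = []
            for gene, sub in table.groupby("gene"):
                meas = QpcrMeasurement(
                    gene,
                    {c: list(s["ct_target"]) for c, s in sub.groupby("condition")},
                    {c: list(s["ct_reference"]) for c, s in sub.groupby("condition")},
                )
                res = delta_delta_ct(meas, cfg.qpcr_control)
                for cond in sorted(res.fold_change):
                    rows.append((gene, cond, f"{res.delta_delta_ct[cond]:.4f}",
                                 f"{res.fold_change[cond]:.4f}",
                                 f"{res.fold_sd[cond]:.4f}"))
            _write_tsv(outdir / "qpcr_folds.tsv",
                       ["gene", "condition", "ddCt", "fold_change", "fold_sd"], rows)
    except PipelineError:
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc

    manifest = {
        "genefam_version": __version__,
        "python": sys.version.split()[0],
        "rng_seed": cfg.rng_seed,
        "family": cfg.family,
        "params": {
            "curation": asdict(cfg.curation),
            "phylo": asdict(cfg.phylo),
            "duplication": asdict(cfg.duplication),
            "molevol": asdict(cfg.molevol),
        },
    }
    (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return results


def simulate_to_dir(sim_cfg: SimulationConfig, outdir) -> None:
    """Emit a full synthetic dataset (bundles, truth, expression, qPCR)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle_a, bundle_b, truth = simulate_family_genomes(sim_cfg)
    bundle_a.write(outdir)
    bundle_b.write(outdir)
    matrix, measurements = simulate_expression_and_qpcr(
        sim_cfg, truth.family_genes_a, truth)
    matrix.values.to_csv(outdir / "expression.tsv", sep="\t")
    _write_tsv(outdir / "qpcr.tsv",
               ["gene", "condition", "replicate", "ct_target", "ct_reference"],
               [(m.gene, cond, k + 1, f"{t:.4f}", f"{r:.4f}")
                for m in measurements for cond in m.ct_target
                for k, (t, r) in enumerate(zip(m.ct_target[cond],
                                               m.ct_reference[cond]))])
    _write_tsv(outdir / "truth_duplications.tsv",
               ["parent", "copy", "type", "target_ks"], truth.duplications)
    _write_tsv(outdir / "truth_family.tsv", ["genome", "gene_id"],
               [("A", g) for g in truth.family_genes_a]
               + [("B", g) for g in truth.family_genes_b])
    _write_tsv(outdir / "truth_orthologs.tsv", ["gene_a", "gene_b"],
               truth.ortholog_pairs)
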