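"""Synthetic two-genome data with known ground truth.

The generator emulates the inputs of a whole-genome gene-family study on
a pair of closely related species: one genome carrying a multigene
family defined by a shared conserved protein domain among background
genes, tandem and segmental duplicate copies at controlled synonymous
divergence, a sister genome diverged by a configured ortholog Ks with
gene order preserved (apart from planted inversions), promoters with
planted cis elements, and tissue-biased expression plus qPCR Ct tables
with known fold changes. Every emitter is deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .expression import ExpressionMatrix, QpcrMeasurement
from .io import GeneModel, SequenceRecord, TranscriptModel
from .motif import DEFAULT_CIS_CATALOG, IUPAC

__all__ = [
    "SimulationConfig",
    "GenomeBundle",
    "GroundTruth",
    "evolve_codons",
    "simulate_family_genomes",
    "simulate_expression_and_qpcr",
    "DEFAULT_DOMAIN_CONSENSUS",
]

# A 50-residue conserved-domain consensus used to define the simulated family.
DEFAULT_DOMAIN_CONSENSUS = "WLKGHFDRWMPEYCQNVAKTGWLSHFERYMCDPNQVIKAGWFHTEYLRMC"

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Tissue labels of a 14-tissue expression atlas (leaf, flower, pod, pod
# shell, seed stages in days after flowering, root, nodule).
DEFAULT_TISSUES = ["YL", "F", "P.1cm", "PS.10d", "PS.14d", "S.10d", "S.14d",
                   "S.21d", "S.25d", "S.28d", "S.35d", "S.42d", "R", "N"]

DEFAULT_QPCR_CONDITIONS = ["0h", "4h", "8h", "12h"]


@dataclass
class SimulationConfig:
    rng_seed: int = 0
    n_family_genes: int = 6
    n_background_genes: int = 60
    n_chromosomes: int = 3
    domain_consensus: str = DEFAULT_DOMAIN_CONSENSUS
    # (type, target synonymous divergence Ks); parents cycle over family genes
    duplication_plan: list[tuple[str, float]] = field(default_factory=lambda: [
        ("tandem", 0.03), ("tandem", 0.03),
        ("segmental", 0.04), ("segmental", 0.04), ("segmental", 0.05),
    ])
    ortholog_ks: float = 0.03
    # synonymous divergence of each base family gene from the family's
    # common ancestor (deep paralog divergence; keeps members homologous
    # over their full length yet well below the duplication threshold)
    family_divergence_ks: float = 1.2
    omega: float = 0.2
    protein_length: int = 180
    introns_per_gene: tuple[int, int] = (1, 4)  # inclusive range
    promoter_length: int = 1000
    promoter_plan: list[tuple[str, int]] = field(default_factory=lambda: [
        ("ABRE", 2), ("MYC", 1), ("STRE", 1), ("ARE", 1),
    ])
    # contiguous run of genes reversed in genome B, per chromosome index
    inversion_plan: list[tuple[int, int, int]] = field(default_factory=lambda: [
        (2, 5, 11),
    ])
    include_decoys: bool = True
    # expression / qPCR study conditions
    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    tissue_effect: float = 8.0
    expression_noise_sd: float = 0.2
    baseline_expression: float = 20.0
    qpcr_conditions: list[str] = field(default_factory=lambda: list(DEFAULT_QPCR_CONDITIONS))
    qpcr_fold_plan: dict[str, float] = field(default_factory=lambda: {
        "4h": 2.0, "8h": 4.0, "12h": 2.0,
    })
    qpcr_replicates: int = 3
    qpcr_noise_sd: float = 0.15
    qpcr_base_ct: float = 24.0
    qpcr_reference_ct: float = 20.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if any(ks < 0 for _, ks in self.duplication_plan) or self.ortholog_ks < 0:
            raise ValueError("Ks targets must be non-negative")


@dataclass
class GenomeBundle:
    label: str
    genome: list[SequenceRecord]
    genes: list[GeneModel]
    proteins: dict[str, SequenceRecord]  # keyed by transcript id
    cds: dict[str, str]

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io import write_fasta, write_gff3

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / f"{self.label}_genome.fasta")
        write_gff3(self.genes, outdir / f"{self.label}.gff3")
        write_fasta(list(self.proteins.values()), outdir / f"{self.label}_proteins.fasta")
        write_fasta(
            [SequenceRecord(tid, seq, alphabet="dna") for tid, seq in self.cds.items()],
            outdir / f"{self.label}_cds.fasta",
        )


@dataclass
class GroundTruth:
    family_genes_a: list[str]
    family_genes_b: list[str]
    background_genes_a: list[str]
    decoy_genes_a: dict[str, str]  # gene id -> expected drop reason
    duplications: list[tuple[str, str, str, float]]  # (parent, copy, type, Ks)
    ortholog_pairs: list[tuple[str, str]]
    cis_elements: dict[str, list[tuple[str, int, str]]]  # gene -> (element, pos, strand)
    domain_positions: dict[str, int]  # transcript id -> 1-based aa start
    expression_effects: dict[str, str]  # gene -> boosted tissue
    qpcr_folds: dict[str, dict[str, float]]


# ---------------------------------------------------------------------------
# Codon evolution


def _codon_maps(table_id: int = 1):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa_of = dict(table.forward_table)
    stops = set(table.stop_codons)
    by_aa: dict[str, list[str]] = {}
    for codon, aa in aa_of.items():
        by_aa.setdefault(aa, []).append(codon)
    for codons in by_aa.values():
        codons.sort()
    return aa_of, stops, by_aa


def _synonymous_sites(cds: str, table_id: int = 1) -> float:
    from .molevol import _codon_sites

    _, stops, _ = _codon_maps(table_id)
    s = 0.0
    for k in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[k:k + 3]
        if codon in stops:
            continue
        s += _codon_sites(codon, table_id, "exclude")[0]
    return s


def evolve_codons(cds: str, target_ks: float, omega: float,
                  rng: np.random.Generator, table_id: int = 1) -> str:
    """Mutate a CDS to a target synonymous divergence.

    Point substitutions are proposed uniformly over positions and
    alternative bases; proposals creating stop codons are rejected,
    synonymous outcomes are accepted with probability 1 and nonsynonymous
    with probability ``omega``. Proposals continue until the number of
    accepted synonymous substitutions reaches ``target_ks`` times the
    sequence's synonymous site count, which calibrates the realized Ks
    (multiple hits are recovered downstream by the Jukes-Cantor
    correction). A trailing stop codon is preserved. No indels.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    if target_ks == 0:
        return cds
    aa_of, stops, _ = _codon_maps(table_id)
    seq = list(cds)
    n_codons = len(cds) // 3
    sense = [k for k in range(n_codons) if cds[3 * k:3 * k + 3] not in stops]
    target_syn = _synonymous_sites(cds, table_id) * target_ks
    accepted_syn = 0.0
    guard = 0
    while accepted_syn < target_syn and guard < 10_000_000:
        guard += 1
        ci = sense[rng.integers(len(sense))]
        pos = int(rng.integers(3))
        old_codon = "".join(seq[3 * ci:3 * ci + 3])
        alternatives = [nt for nt in "ACGT" if nt != old_codon[pos]]
        nt = alternatives[rng.integers(3)]
        new_codon = old_codon[:pos] + nt + old_codon[pos + 1:]
        if new_codon in stops:
            continue
        synonymous = aa_of[new_codon] == aa_of[old_codon]
        if synonymous or rng.random() < omega:
            seq[3 * ci + pos] = nt
            if synonymous:
                accepted_syn += 1.0
    return "".join(seq)


# ---------------------------------------------------------------------------
# Sequence construction helpers


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(np.array(list(AA20))[rng.integers(0, 20, size=length - 1)])
    return "M" + body


def _back_translate(protein: str, rng: np.random.Generator,
                    table_id: int = 1) -> str:
    _, _, by_aa = _codon_maps(table_id)
    codons = [by_aa[aa][rng.integers(len(by_aa[aa]))] for aa in protein]
    codons.append("TAA")
    return "".join(codons)


def _concretize_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in pattern.upper()
    )


def _plant_promoter(rng: np.random.Generator, length: int, plan,
                    catalog_patterns: dict[str, str]):
    """Random promoter with planted elements; returns (seq, placements)."""
    seq = list(_random_dna(rng, length))
    placements: list[tuple[str, int, str]] = []
    taken: list[tuple[int, int]] = []
    for element, copies in plan:
        pattern = catalog_patterns[element]
        for _ in range(copies):
            for _attempt in range(200):
                start = int(rng.integers(0, length - len(pattern)))
                if all(start + len(pattern) <= s or start >= e for s, e in taken):
                    break
            else:
                continue
            concrete = _concretize_iupac(pattern, rng)
            seq[start:start + len(concrete)] = list(concrete)
            taken.append((start, start + len(concrete)))
            placements.append((element, start + 1, "+"))
    return "".join(seq), sorted(placements, key=lambda p: p[1])


@dataclass
class _GeneSpec:
    gene_id: str
    kind: str  # family | background | decoy_*
    protein: str
    cds: str  # includes trailing stop codon
    intron_lengths: list[int]
    strand: str
    promoter: str
    cis_placements: list[tuple[str, int, str]]
    domain_start: int | None = None  # 1-based aa position


def _split_cds(cds: str, n_exons: int, rng: np.random.Generator) -> list[str]:
    if n_exons == 1:
        return [cds]
    # split points anywhere (not necessarily codon boundaries)
    points = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1,
                               replace=False).tolist())
    pieces, prev = [], 0
    for p in points + [len(cds)]:
        pieces.append(cds[prev:p])
        prev = p
    return pieces


def _lay_out_gene(spec: _GeneSpec, chrom: str, offset: int,
                  rng: np.random.Generator):
    """Place one gene (with its promoter) at ``offset`` (0-based) on a chromosome.

    Returns (fragment sequence, GeneModel, fragment length).
    """
    exon_seqs = _split_cds(spec.cds, len(spec.intron_lengths) + 1, rng)
    introns = [_random_dna(rng, L) for L in spec.intron_lengths]
    sense_parts = []
    exon_spans_sense = []  # 0-based [s, e) within gene body, transcription order
    pos = 0
    for k, ex in enumerate(exon_seqs):
        sense_parts.append(ex)
        exon_spans_sense.append((pos, pos + len(ex)))
        pos += len(ex)
        if k < len(introns):
            sense_parts.append(introns[k])
            pos += len(introns[k])
    body = "".join(sense_parts)
    L = len(body)
    phases = []
    cum = 0
    for ex in exon_seqs:
        phases.append((3 - cum % 3) % 3)
        cum += len(ex)

    if spec.strand == "+":
        fragment = spec.promoter + body
        body_off = offset + len(spec.promoter)
        spans = [(body_off + s, body_off + e - 1) for s, e in exon_spans_sense]
        seg_phases = phases
    else:
        fragment = str(Seq(body).reverse_complement()) + \
            str(Seq(spec.promoter).reverse_complement())
        body_off = offset
        spans = [(body_off + (L - e), body_off + (L - 1 - s))
                 for s, e in exon_spans_sense]
        spans.reverse()  # ascending genomic order
        seg_phases = list(reversed(phases))
    # convert to 1-based inclusive
    spans = [(s + 1, e + 1) for s, e in spans]
    tid = f"{spec.gene_id}.t1"
    transcript = TranscriptModel(tid, exons=list(spans),
                                 cds_segments=list(spans), phases=seg_phases)
    gene = GeneModel(spec.gene_id, chrom, spans[0][0], spans[-1][1],
                     spec.strand, transcripts=[transcript])
    return fragment, gene, len(fragment)


# ---------------------------------------------------------------------------
# Genome simulation


def simulate_family_genomes(cfg: SimulationConfig | None = None):
    """Emit two genome bundles and the ground truth of every planted event.

    Genome A carries the family plus its planted tandem/segmental
    duplicates (and optional curation decoys); genome B carries orthologs
    of the base family and background genes, diverged by ``ortholog_ks``,
    in the same gene order except for planted inversions.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    catalog_patterns = {e.name: e.pattern for e in DEFAULT_CIS_CATALOG}
    n_chrom = cfg.n_chromosomes
    per_chrom_bg = cfg.n_background_genes // n_chrom
    if any(kind == "tandem" for kind, _ in cfg.duplication_plan) and per_chrom_bg < 2:
        raise ValueError("too few background genes per chromosome for tandem insertions")

    # ancestral family gene: domain embedded in an otherwise random protein;
    # all family members descend from it, so they stay homologous end to end
    _core = _random_protein(rng, cfg.protein_length - len(cfg.domain_consensus))
    _ins = int(rng.integers(10, len(_core) - 5))
    ancestor_protein = _core[:_ins] + cfg.domain_consensus + _core[_ins:]
    ancestor_domain_start = _ins + 1
    ancestor_cds = _back_translate(ancestor_protein, rng)

    def evolve_gene(cds: str, target_ks: float) -> tuple[str, str]:
        """Evolve a CDS, keeping the start codon intact; returns (cds, protein)."""
        out = evolve_codons(cds, target_ks, cfg.omega, rng)
        out = "ATG" + out[3:]
        return out, str(Seq(out[:-3]).translate())

    def make_protein_and_cds(kind: str):
        if kind == "family":
            cds, protein = evolve_gene(ancestor_cds, cfg.family_divergence_ks)
            return protein, cds, ancestor_domain_start
        protein = _random_protein(rng, cfg.protein_length)
        return protein, _back_translate(protein, rng), None

    def new_spec(gene_id: str, kind: str, protein: str, cds: str,
                 domain_start=None, promoter_plan=None) -> _GeneSpec:
        n_introns = int(rng.integers(cfg.introns_per_gene[0],
                                     cfg.introns_per_gene[1] + 1))
        intron_lengths = [int(rng.integers(80, 300)) for _ in range(n_introns)]
        strand = "+" if rng.random() < 0.5 else "-"
        plan = promoter_plan if promoter_plan is not None else cfg.promoter_plan
        promoter, placements = _plant_promoter(rng, cfg.promoter_length, plan,
                                               catalog_patterns)
        return _GeneSpec(gene_id, kind, protein, cds, intron_lengths, strand,
                         promoter, placements, domain_start)

    # --- genome A gene order ------------------------------------------------
    chrom_specs: list[list[_GeneSpec]] = [[] for _ in range(n_chrom)]
    gid = 0

    def next_id(prefix: str) -> str:
        nonlocal gid
        gid += 1
        return f"{prefix}{gid:03d}"

    for c in range(n_chrom):
        for _ in range(per_chrom_bg):
            prot, cds, _ = make_protein_and_cds("background")
            chrom_specs[c].append(new_spec(next_id("Ag"), "background", prot, cds,
                                           promoter_plan=[]))

    family_specs: list[_GeneSpec] = []
    for k in range(cfg.n_family_genes):
        c = k % n_chrom
        prot, cds, dom = make_protein_and_cds("family")
        spec = new_spec(next_id("Ag"), "family", prot, cds, domain_start=dom)
        slot = int(rng.integers(0, len(chrom_specs[c]) + 1))
        chrom_specs[c].insert(slot, spec)
        family_specs.append(spec)

    def locate(spec: _GeneSpec) -> tuple[int, int]:
        for c, specs in enumerate(chrom_specs):
            if spec in specs:
                return c, specs.index(spec)
        raise AssertionError

    duplications: list[tuple[str, str, str, float]] = []
    aa_of, stops, _ = _codon_maps()
    for k, (kind, target_ks) in enumerate(cfg.duplication_plan):
        parent = family_specs[k % len(family_specs)]
        new_cds, protein = evolve_gene(parent.cds, target_ks)
        copy = new_spec(next_id("Ag"), "family", protein, new_cds,
                        domain_start=parent.domain_start)
        c, idx = locate(parent)
        if kind == "tandem":
            intervening = int(rng.integers(0, 4))  # <= 5 by construction
            chrom_specs[c].insert(min(idx + 1 + intervening, len(chrom_specs[c])), copy)
        else:
            c2 = (c + 1) % n_chrom
            slot = int(rng.integers(0, len(chrom_specs[c2]) + 1))
            chrom_specs[c2].insert(slot, copy)
        family_specs.append(copy)
        duplications.append((parent.gene_id, copy.gene_id, kind, target_ks))

    decoys: dict[str, str] = {}
    if cfg.include_decoys:
        # short CDS: below the minimum length, no domain
        short_prot = _random_protein(rng, 49)
        short_cds = _back_translate(short_prot, rng)[:149]
        sp = new_spec(next_id("Ag"), "decoy_short", short_prot, short_cds,
                      promoter_plan=[])
        decoys[sp.gene_id] = "cds_shorter_than_minimum"
        chrom_specs[0].append(sp)
        # incomplete domain: only the first 40% of the consensus present
        frag = cfg.domain_consensus[: int(0.4 * len(cfg.domain_consensus))]
        core = _random_protein(rng, cfg.protein_length - len(frag))
        prot = core[:30] + frag + core[30:]
        sp = new_spec(next_id("Ag"), "decoy_incomplete", prot,
                      _back_translate(prot, rng))
        decoys[sp.gene_id] = "incomplete_domain"
        chrom_specs[1 % n_chrom].append(sp)
        # truncated protein: full domain but an internal stop
        prot, cds, dom = make_protein_and_cds("family")
        half = len(prot) // 2
        # ensure the stop is outside the domain
        stop_at = half if not (dom and dom <= half + 1 <= dom + len(cfg.domain_consensus)) \
            else dom + len(cfg.domain_consensus) + 2
        trunc_prot = prot[:stop_at] + "*" + prot[stop_at + 1:]
        trunc_cds = cds[:3 * stop_at] + "TGA" + cds[3 * stop_at + 3:]
        sp = new_spec(next_id("Ag"), "decoy_truncated", trunc_prot, trunc_cds,
                      domain_start=dom)
        decoys[sp.gene_id] = "truncated_protein"
        chrom_specs[2 % n_chrom].append(sp)

    # give one family gene a second, shorter transcript (representative rule)
    multi_tx_gene = family_specs[0].gene_id

    # --- assemble chromosomes ----------------------------------------------
    def assemble(label: str, specs_by_chrom: list[list[_GeneSpec]]):
        spacer = 1500
        genome: list[SequenceRecord] = []
        genes: list[GeneModel] = []
        proteins: dict[str, SequenceRecord] = {}
        cds_map: dict[str, str] = {}
        for c, specs in enumerate(specs_by_chrom):
            chrom = f"Chr{c + 1}"
            parts = [_random_dna(rng, spacer)]
            offset = spacer
            for spec in specs:
                fragment, gene, flen = _lay_out_gene(spec, chrom, offset, rng)
                parts.append(fragment)
                offset += flen
                parts.append(_random_dna(rng, spacer))
                offset += spacer
                genes.append(gene)
                tid = gene.transcripts[0].transcript_id
                proteins[tid] = SequenceRecord(tid, spec.protein, alphabet="protein")
                cds_map[tid] = spec.cds
            genome.append(SequenceRecord(chrom, "".join(parts), alphabet="dna"))
        return GenomeBundle(label, genome, genes, proteins, cds_map)

    bundle_a = assemble("genomeA", chrom_specs)

    # second transcript for the multi-transcript family gene: first exon only
    for gene in bundle_a.genes:
        if gene.gene_id == multi_tx_gene:
            t1 = gene.transcripts[0]
            first = t1.cds_segments[0] if gene.strand == "+" else t1.cds_segments[-1]
            if first[1] - first[0] + 1 < 3:
                break
            k3 = ((first[1] - first[0] + 1) // 3) * 3
            span = (first[0], first[0] + k3 - 1) if gene.strand == "+" \
                else (first[1] - k3 + 1, first[1])
            t2 = TranscriptModel(f"{gene.gene_id}.t2", exons=[span],
                                 cds_segments=[span], phases=[0])
            gene.transcripts.append(t2)
            seq = next(r for r in bundle_a.genome if r.id == gene.chrom).residues
            sub = seq[span[0] - 1:span[1]]
            if gene.strand == "-":
                sub = str(Seq(sub).reverse_complement())
            bundle_a.cds[t2.transcript_id] = sub
            prot2 = str(Seq(sub).translate()).replace("*", "X") or "M"
            bundle_a.proteins[t2.transcript_id] = SequenceRecord(
                t2.transcript_id, prot2, alphabet="protein")
            break

    # --- genome B: orthologs of base genes, order preserved + inversions ----
    b_specs: list[list[_GeneSpec]] = [[] for _ in range(n_chrom)]
    ortholog_pairs: list[tuple[str, str]] = []
    base_ids = {s.gene_id for s in family_specs[:cfg.n_family_genes]}
    bg_ids = {s.gene_id for s in sum(chrom_specs, []) if s.kind == "background"}
    counter = 0
    for c, specs in enumerate(chrom_specs):
        for spec in specs:
            if spec.gene_id not in base_ids and spec.gene_id not in bg_ids:
                continue
            counter += 1
            new_cds, protein = evolve_gene(spec.cds, cfg.ortholog_ks)
            bspec = new_spec(f"Bg{counter:03d}", spec.kind, protein, new_cds,
                             domain_start=spec.domain_start,
                             promoter_plan=cfg.promoter_plan if spec.kind == "family" else [])
            b_specs[c].append(bspec)
            ortholog_pairs.append((spec.gene_id, bspec.gene_id))
    for c, lo, hi in cfg.inversion_plan:
        if c < n_chrom and hi <= len(b_specs[c]):
            b_specs[c][lo:hi] = list(reversed(b_specs[c][lo:hi]))

    bundle_b = assemble("genomeB", b_specs)

    family_a = [s.gene_id for s in family_specs]
    family_b = [b for a, b in ortholog_pairs
                if a in {s.gene_id for s in family_specs[:cfg.n_family_genes]}]
    truth = GroundTruth(
        family_genes_a=family_a,
        family_genes_b=family_b,
        background_genes_a=sorted(bg_ids),
        decoy_genes_a=decoys,
        duplications=duplications,
        ortholog_pairs=ortholog_pairs,
        cis_elements={s.gene_id: s.cis_placements
                      for s in sum(chrom_specs, []) + sum(b_specs, [])
                      if s.cis_placements},
        domain_positions={f"{s.gene_id}.t1": s.domain_start
                          for s in family_specs if s.domain_start},
        expression_effects={},
        qpcr_folds={},
    )
    return bundle_a, bundle_b, truth


# ---------------------------------------------------------------------------
# Expression and qPCR simulation


def simulate_expression_and_qpcr(cfg: SimulationConfig, gene_ids: list[str],
                                 truth: GroundTruth | None = None):
    """Tissue expression matrix and qPCR Ct tables with planted effects.

    Each gene gets one boosted tissue (multiplicative ``tissue_effect``)
    with lognormal noise; Ct values encode the planned fold changes against
    the control condition (first in ``qpcr_conditions``), with a constant
    reference gene.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    tissues = cfg.tissues
    effects = {g: tissues[k % len(tissues)] for k, g in enumerate(gene_ids)}
    rows = []
    for g in gene_ids:
        base = cfg.baseline_expression
        noise = rng.normal(0.0, cfg.expression_noise_sd, size=len(tissues)) \
            if cfg.expression_noise_sd > 0 else np.zeros(len(tissues))
        vals = [base * (cfg.tissue_effect if t == effects[g] else 1.0) * float(np.exp(e))
                for t, e in zip(tissues, noise)]
        rows.append(vals)
    matrix = ExpressionMatrix(pd.DataFrame(rows, index=gene_ids, columns=tissues))

    control = cfg.qpcr_conditions[0]
    folds = {g: {control: 1.0, **dict(cfg.qpcr_fold_plan)} for g in gene_ids}
    measurements = []
    for g in gene_ids:
        ct_t: dict[str, list[float]] = {}
        ct_r: dict[str, list[float]] = {}
        for cond in cfg.qpcr_conditions:
            fold = folds[g].get(cond, 1.0)
            noise = rng.normal(0.0, cfg.qpcr_noise_sd, size=cfg.qpcr_replicates) \
                if cfg.qpcr_noise_sd > 0 else np.zeros(cfg.qpcr_replicates)
            ct_t[cond] = [float(cfg.qpcr_base_ct - np.log2(fold) + e) for e in noise]
            ct_r[cond] = [cfg.qpcr_reference_ct] * cfg.qpcr_replicates
        measurements.append(QpcrMeasurement(g, ct_t, ct_r))
    if truth is not None:
        truth.expression_effects = effects
        truth.qpcr_folds = folds
    return matrix, measurements
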