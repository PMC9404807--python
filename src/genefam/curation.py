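"""Family-member identification and curation.

Candidate genes are recognized by the presence of a conserved protein
domain, then filtered by three rules: one representative (longest-CDS)
transcript per locus, a minimum CDS length, and a complete domain on an
untruncated protein. Surviving members are named by species prefix,
family, chromosome number and rank along the chromosome
(e.g. ``GmaAPX11.4`` = fourth family gene on chromosome 11 of the
species abbreviated ``Gma``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .io import GeneModel, SequenceRecord, TranscriptModel

__all__ = [
    "CurationParams",
    "DomainModel",
    "DomainHit",
    "ProteinProperties",
    "FamilyMember",
    "scan_domains",
    "curate_family",
    "assign_names",
    "protein_properties",
]


@dataclass
class CurationParams:
    min_cds_bp: int = 150
    domain_model_id: str = "DOM00001"
    # absolute score threshold; None = 0.3 x the model's self-alignment score
    domain_score_threshold: float | None = None
    complete_fraction: float = 0.8
    one_transcript_per_locus: bool = True

    def __post_init__(self) -> None:
        if self.min_cds_bp <= 0:
            raise ValueError("min_cds_bp must be positive")


@dataclass
class DomainModel:
    """A conserved-domain model given as an amino-acid consensus.

    Scoring is an ungapped BLOSUM62 local alignment (best segment pair)
    of the consensus against each protein; this is a deliberate
    simplification of profile-HMM search, adequate for domains present
    verbatim or near-verbatim in sequences.
    """

    model_id: str
    consensus: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 10:
            raise ValueError("domain model width must be >= 10 aa")

    @property
    def width(self) -> int:
        return len(self.consensus)


@dataclass
class DomainHit:
    protein_id: str
    model_id: str
    start: int  # 1-based aa position in the protein
    end: int
    score: float
    complete: bool


@dataclass
class ProteinProperties:
    length_aa: int
    mw_kda: float
    pi: float


@dataclass
class FamilyMember:
    gene: GeneModel
    transcript: TranscriptModel
    protein: SequenceRecord
    cds: str
    domain_hit: DomainHit | None = None
    properties: ProteinProperties | None = None
    name: str = ""
    species_prefix: str = ""
    family: str = ""
    chrom_label: str = ""
    rank_on_chrom: int = 0


def _local_aligner() -> Align.PairwiseAligner:
    # effectively ungapped: the scan reports the best contiguous
    # consensus-to-protein segment, so hit span measures true coverage
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -1000
    aligner.extend_gap_score = -1000
    return aligner


def self_score(model: DomainModel) -> float:
    """Local-alignment score of the model consensus against itself."""
    return _local_aligner().score(model.consensus, model.consensus)


def scan_domains(proteins, model: DomainModel,
                 params: CurationParams | None = None) -> list[DomainHit]:
    """Best local hit of the domain model in each protein, above threshold.

    Completeness: the aligned span of the model must cover at least
    ``params.complete_fraction`` of the model width.
    """
    params = params or CurationParams()
    threshold = params.domain_score_threshold
    if threshold is None:
        threshold = 0.3 * self_score(model)
    aligner = _local_aligner()
    hits: list[DomainHit] = []
    for prot in proteins:
        # Biopython's aligner rejects '*'; treat stops as X for scanning
        residues = prot.residues.replace("*", "X")
        score = aligner.score(residues, model.consensus)
        if score < threshold:
            continue
        aln = aligner.align(residues, model.consensus)[0]
        target_ranges, query_ranges = aln.aligned
        p_start = int(target_ranges[0][0]) + 1
        p_end = int(target_ranges[-1][1])
        model_span = int(query_ranges[-1][1]) - int(query_ranges[0][0])
        hits.append(
            DomainHit(
                protein_id=prot.id,
                model_id=model.model_id,
                start=p_start,
                end=p_end,
                score=float(score),
                complete=model_span / model.width >= params.complete_fraction,
            )
        )
    return hits


def _representative_transcript(gene: GeneModel) -> TranscriptModel | None:
    """Longest-CDS transcript; ties broken by transcript id."""
    candidates = [t for t in gene.transcripts if t.cds_segments]
    if not candidates:
        return None
    return max(candidates, key=lambda t: (t.cds_length(), t.transcript_id))


def curate_family(genes, proteins: dict[str, SequenceRecord],
                  cds: dict[str, str], hits, params: CurationParams | None = None):
    """Apply the three curation filters and return kept members + report.

    ``proteins`` and ``cds`` are keyed by transcript id. ``hits`` is the
    output of :func:`scan_domains` (or an externally supplied hit table).
    The report lists every gene with keep/drop status and, for drops, the
    first failing rule in order: representative transcript exists; CDS
    length; complete domain on an untruncated protein.
    """
    params = params or CurationParams()
    hit_by_protein = {h.protein_id: h for h in hits}
    members: list[FamilyMember] = []
    report: list[tuple[str, bool, str]] = []

    for gene in genes:
        rep = _representative_transcript(gene)
        if rep is None:
            report.append((gene.gene_id, False, "no_transcript_with_cds"))
            continue
        if rep.cds_length() < params.min_cds_bp:
            report.append((gene.gene_id, False, "cds_shorter_than_minimum"))
            continue
        prot = proteins.get(rep.transcript_id)
        if prot is None:
            report.append((gene.gene_id, False, "no_protein_sequence"))
            continue
        hit = hit_by_protein.get(rep.transcript_id)
        if hit is None:
            report.append((gene.gene_id, False, "no_domain_hit"))
            continue
        if not hit.complete:
            report.append((gene.gene_id, False, "incomplete_domain"))
            continue
        if not prot.residues.startswith("M") or "*" in prot.residues:
            report.append((gene.gene_id, False, "truncated_protein"))
            continue
        members.append(
            FamilyMember(
                gene=gene,
                transcript=rep,
                protein=prot,
                cds=cds.get(rep.transcript_id, ""),
                domain_hit=hit,
                properties=protein_properties(prot),
            )
        )
        report.append((gene.gene_id, True, "kept"))
    return members, report


_CHROM_NUM = re.compile(r"(\d+)\s*$")


def chromosome_number(chrom_label: str) -> int:
    """Trailing integer of a chromosome label ('Chr11' -> 11)."""
    m = _CHROM_NUM.search(chrom_label)
    if not m:
        raise ValueError(f"cannot extract chromosome number from {chrom_label!r}")
    return int(m.group(1))


def assign_names(members: list[FamilyMember], species_prefix: str,
                 family: str) -> list[FamilyMember]:
    """Name members prefix+family+chromNumber+'.'+rank, rank by gene start.

    Single-member chromosomes still get rank '.1'. Identical (chrom, start)
    pairs are tie-broken by gene id with a warning. Idempotent.
    """
    by_chrom: dict[str, list[FamilyMember]] = {}
    for m in members:
        by_chrom.setdefault(m.gene.chrom, []).append(m)
    for chrom, group in sorted(by_chrom.items()):
        starts = [g.gene.start for g in group]
        if len(set(starts)) != len(starts):
            warnings.warn(f"tied gene starts on {chrom}; breaking ties by gene id")
        group.sort(key=lambda m: (m.gene.start, m.gene.gene_id))
        num = chromosome_number(chrom)
        for rank, m in enumerate(group, 1):
            m.species_prefix = species_prefix
            m.family = family
            m.chrom_label = chrom
            m.rank_on_chrom = rank
            m.name = f"{species_prefix}{family}{num}.{rank}"
    return members


# ---------------------------------------------------------------------------
# Physicochemical properties

# Average (not monoisotopic) residue masses in Da; X contributes no mass.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 0.0,
}
WATER_MASS = 18.0153

# Bjellqvist-style pKa values; swappable for a different convention.
DEFAULT_PKA = {
    "n_term": 7.5,
    "c_term": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,   # acidic side chains
    "H": 5.98, "K": 10.0, "R": 12.0,             # basic side chains
}
_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


def net_charge(sequence: str, ph: float, pka: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH."""
    pka = pka or DEFAULT_PKA
    pos = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    for aa in _BASIC:
        pos += sequence.count(aa) / (1.0 + 10 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for aa in _ACIDIC:
        neg += sequence.count(aa) / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def isoelectric_point(sequence: str, pka: dict[str, float] | None = None,
                      tol: float = 1e-4, max_iter: int = 60) -> float:
    """pI by bisection on the (monotone decreasing) net-charge curve."""
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_properties(protein: SequenceRecord,
                       pka: dict[str, float] | None = None) -> ProteinProperties:
    """Length, average molecular weight (kDa) and isoelectric point."""
    seq = protein.residues
    if not seq:
        raise ValueError("empty protein sequence")
    mass = WATER_MASS + sum(AVERAGE_RESIDUE_MASS.get(aa, 0.0) for aa in seq)
    return ProteinProperties(
        length_aa=len(seq),
        mw_kda=mass / 1000.0,
        pi=isoelectric_point(seq, pka),
    )
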