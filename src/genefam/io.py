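"""Genome file I/O and coordinate-safe sequence extraction.

All genomic coordinates are GFF3-native: 1-based, inclusive on both ends.
Any half-open arithmetic is internal to a function and never leaks into
the domain types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "TranscriptModel",
    "GeneModel",
    "FormatError",
    "LinkageError",
    "CoordinateError",
    "FrameError",
    "UndefinedStartError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "extract_cds_and_translate",
    "extract_upstream",
]

DNA_ALPHABET = set("ACGTN")
# 20 standard residues plus ambiguity X and stop *
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}


class FormatError(ValueError):
    """Malformed FASTA/GFF3 input."""


class LinkageError(ValueError):
    """GFF3 feature whose Parent cannot be resolved."""


class CoordinateError(ValueError):
    """Interval outside its sequence, or end < start."""


class FrameError(ValueError):
    """CDS length not divisible by 3 after phase adjustment."""


class UndefinedStartError(ValueError):
    """Gene has no CDS, so no translation start exists."""


@dataclass
class SequenceRecord:
    """A named sequence over a declared alphabet ('dna' or 'protein')."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} is empty")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal {self.alphabet} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TranscriptModel:
    """A transcript: ordered exons and CDS segments (1-based inclusive)."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    # GFF3 phase per CDS segment, parallel to cds_segments (0 when absent)
    phases: list[int] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def validate(self) -> None:
        for name, ivals in (("exon", self.exons), ("CDS", self.cds_segments)):
            for s, e in ivals:
                if e < s:
                    raise CoordinateError(
                        f"{self.transcript_id}: {name} interval end {e} < start {s}"
                    )
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise CoordinateError(
                        f"{self.transcript_id}: {name} intervals overlap or unsorted"
                    )


@dataclass
class GeneModel:
    """A gene locus with one or more transcripts on a single strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CoordinateError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-FASTA file.

    Sequences are uppercased; record order is preserved. Duplicate ids and
    illegal characters raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=desc,
                alphabet=alphabet,
            )
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as multi-FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().strip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` hierarchies.

    Recognized feature types: gene, mRNA (or transcript), exon, CDS.
    mRNA links to gene, exon/CDS to mRNA, via the Parent attribute.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    transcript_gene: dict[str, str] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _source, ftype, start_s, end_s, _score, strand, phase_s, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise CoordinateError(f"{path}:{lineno}: end {end} < start {start}")
            attrs = _parse_attributes(attr_s)

            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = GeneModel(gid, chrom, start, end, strand, attributes=attrs)
                order.append(gid)
            elif ftype in {"mRNA", "transcript"}:
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise FormatError(f"{path}:{lineno}: mRNA needs ID and Parent")
                if parent not in genes:
                    raise LinkageError(
                        f"{path}:{lineno}: mRNA {tid!r} references unknown gene {parent!r}"
                    )
                t = TranscriptModel(tid)
                transcripts[tid] = t
                transcript_gene[tid] = parent
                genes[parent].transcripts.append(t)
            elif ftype in {"exon", "CDS"}:
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: {ftype} without Parent")
                if parent not in transcripts:
                    raise LinkageError(
                        f"{path}:{lineno}: {ftype} references unknown mRNA {parent!r}"
                    )
                t = transcripts[parent]
                if ftype == "exon":
                    t.exons.append((start, end))
                else:
                    t.cds_segments.append((start, end))
                    t.phases.append(int(phase_s) if phase_s.isdigit() else 0)
            # other feature types are ignored

    result = []
    for gid in order:
        gene = genes[gid]
        for t in gene.transcripts:
            # sort by genomic start; keep phases parallel to CDS order
            t.exons.sort()
            if t.cds_segments:
                cds_order = sorted(range(len(t.cds_segments)),
                                   key=lambda i: t.cds_segments[i])
                t.cds_segments = [t.cds_segments[i] for i in cds_order]
                t.phases = [t.phases[i] for i in cds_order]
            t.validate()
        result.append(gene)
    return result


def write_gff3(genes, path) -> None:
    """Emit GeneModels back to GFF3 (gene/mRNA/exon/CDS lines)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([g.chrom, "genefam", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", f"ID={g.gene_id}"]) + "\n")
            for t in g.transcripts:
                lo = min([s for s, _ in t.exons], default=g.start)
                hi = max([e for _, e in t.exons], default=g.end)
                fh.write("\t".join([g.chrom, "genefam", "mRNA", str(lo), str(hi),
                                    ".", g.strand, ".",
                                    f"ID={t.transcript_id};Parent={g.gene_id}"]) + "\n")
                for s, e in t.exons:
                    fh.write("\t".join([g.chrom, "genefam", "exon", str(s), str(e),
                                        ".", g.strand, ".",
                                        f"Parent={t.transcript_id}"]) + "\n")
                for (s, e), ph in zip(t.cds_segments, t.phases):
                    fh.write("\t".join([g.chrom, "genefam", "CDS", str(s), str(e),
                                        ".", g.strand, str(ph),
                                        f"Parent={t.transcript_id}"]) + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction


def _chrom_index(genome) -> dict[str, SequenceRecord]:
    return {rec.id: rec for rec in genome}


def extract_cds_and_translate(genome, transcript: TranscriptModel, strand: str,
                              chrom: str, table: int = 1):
    """Extract the spliced CDS and translate it.

    Minus-strand CDS segments are concatenated in transcription order
    (descending genomic position) after reverse complementing. The terminal
    stop codon, if present, is trimmed and not emitted in the protein.

    Returns ``(cds_nt, protein, truncated)`` where ``truncated`` is True when
    the translation contains an internal stop (the protein is still returned,
    stops rendered as ``*``).
    """
    chroms = _chrom_index(genome)
    if chrom not in chroms:
        raise CoordinateError(f"unknown chromosome {chrom!r}")
    seq = chroms[chrom].residues
    if not transcript.cds_segments:
        raise UndefinedStartError(f"{transcript.transcript_id}: no CDS segments")
    parts = []
    for s, e in transcript.cds_segments:
        if s < 1 or e > len(seq):
            raise CoordinateError(
                f"{transcript.transcript_id}: CDS {s}-{e} outside {chrom} (len {len(seq)})"
            )
        parts.append(seq[s - 1:e])
    if strand == "+":
        cds = "".join(parts)
        phase = transcript.phases[0] if transcript.phases else 0
    else:
        cds = str(Seq("".join(parts)).reverse_complement())
        phase = transcript.phases[-1] if transcript.phases else 0
    cds = cds[phase:]
    if len(cds) % 3 != 0:
        raise FrameError(
            f"{transcript.transcript_id}: CDS length {len(cds)} not divisible by 3"
        )
    protein = str(Seq(cds).translate(table=table))
    if protein.endswith("*"):
        protein = protein[:-1]
    truncated = "*" in protein
    return cds, protein, truncated


def translation_start(gene: GeneModel, transcript: TranscriptModel) -> int:
    """Genomic coordinate of the first CDS base in transcription order."""
    if not transcript.cds_segments:
        raise UndefinedStartError(f"{gene.gene_id}: no CDS")
    if gene.strand == "+":
        return transcript.cds_segments[0][0]
    return transcript.cds_segments[-1][1]


def extract_upstream(genome, gene: GeneModel, length: int = 1000,
                     transcript: TranscriptModel | None = None) -> SequenceRecord:
    """Promoter region: ``length`` bp upstream of the translation start site.

    On the minus strand the region downstream in genome coordinates is taken
    and reverse complemented, so the returned sequence always reads 5'→3'
    toward the start codon. Regions running off the contig are clamped with
    a warning; the actual length is whatever remains.
    """
    chroms = _chrom_index(genome)
    seq = chroms[gene.chrom].residues
    if transcript is None:
        with_cds = [t for t in gene.transcripts if t.cds_segments]
        if not with_cds:
            raise UndefinedStartError(f"{gene.gene_id}: no transcript with CDS")
        transcript = with_cds[0]
    tss = translation_start(gene, transcript)
    if gene.strand == "+":
        lo, hi = tss - length, tss - 1
        clamped_lo = max(lo, 1)
        region = seq[clamped_lo - 1:hi] if hi >= clamped_lo else ""
        if clamped_lo != lo:
            warnings.warn(
                f"{gene.gene_id}: upstream region truncated to {len(region)} bp at contig start"
            )
    else:
        lo, hi = tss + 1, tss + length
        clamped_hi = min(hi, len(seq))
        region = seq[lo - 1:clamped_hi] if clamped_hi >= lo else ""
        if clamped_hi != hi:
            warnings.warn(
                f"{gene.gene_id}: upstream region truncated to {len(region)} bp at contig end"
            )
        region = str(Seq(region).reverse_complement()) if region else region
    if not region:
        raise CoordinateError(f"{gene.gene_id}: empty upstream region")
    return SequenceRecord(
        id=f"{gene.gene_id}_upstream",
        residues=region,
        description=f"{len(region)} bp upstream of translation start",
        alphabet="dna",
    )
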