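"""Gene structure, EM motif discovery and promoter cis-element scanning.

Motif discovery is a ZOOPS (zero-or-one occurrence per sequence)
expectation-maximization over protein sequences: motifs are found one at
a time, each seeded from candidate subsequences, refined to convergence,
ranked by information content and masked out before the next search.
Cis elements are IUPAC consensus patterns scanned on both strands of
promoter sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io import GeneModel, SequenceRecord, TranscriptModel

__all__ = [
    "GeneStructure",
    "MotifModel",
    "CisElement",
    "CisHit",
    "DEFAULT_CIS_CATALOG",
    "gene_structure",
    "discover_motifs",
    "scan_cis_elements",
    "load_catalog_tsv",
]


# ---------------------------------------------------------------------------
# Gene structure


@dataclass
class GeneStructure:
    gene_id: str
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    utrs: list[tuple[int, int]]
    exon_count: int
    intron_count: int


def _subtract_intervals(base: list[tuple[int, int]],
                        minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in base:
        cuts = [(ms, me) for ms, me in minus if ms <= e and me >= s]
        cur = s
        for ms, me in sorted(cuts):
            if ms > cur:
                out.append((cur, ms - 1))
            cur = max(cur, me + 1)
        if cur <= e:
            out.append((cur, e))
    return out


def gene_structure(gene: GeneModel,
                   transcript: TranscriptModel | None = None) -> GeneStructure:
    """Exons, introns (inter-exon gaps) and UTRs (exonic minus CDS)."""
    if transcript is None:
        if not gene.transcripts:
            raise ValueError(f"{gene.gene_id}: no transcripts")
        transcript = gene.transcripts[0]
    exons = sorted(transcript.exons)
    if not exons:
        raise ValueError(f"{gene.gene_id}: transcript has no exons")
    introns = [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    utrs = _subtract_intervals(exons, sorted(transcript.cds_segments))
    return GeneStructure(gene.gene_id, exons, introns, utrs,
                         exon_count=len(exons), intron_count=len(introns))


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_LETTERS)}


@dataclass
class MotifModel:
    width: int
    pwm: np.ndarray  # (width, 20) column-stochastic
    background: np.ndarray  # (20,)
    consensus: str
    information_bits: float
    occurrences: list[tuple[str, int]] = field(default_factory=list)  # (seq id, 1-based start)

    def log_odds(self) -> np.ndarray:
        return np.log(self.pwm) - np.log(self.background)[None, :]


def _encode(sequences: list[SequenceRecord]) -> list[np.ndarray]:
    return [
        np.array([_AA_INDEX.get(ch, -1) for ch in rec.residues], dtype=np.int64)
        for rec in sequences
    ]


def _windows(encoded: list[np.ndarray], width: int):
    """Flattened valid windows: (matrix, seq_index, start_index)."""
    mats, seq_idx, starts = [], [], []
    for s, x in enumerate(encoded):
        if len(x) < width:
            continue
        win = np.lib.stride_tricks.sliding_window_view(x, width)
        valid = (win >= 0).all(axis=1)
        pos = np.nonzero(valid)[0]
        if pos.size == 0:
            continue
        mats.append(win[pos])
        seq_idx.append(np.full(pos.size, s))
        starts.append(pos)
    if not mats:
        return None
    return np.concatenate(mats), np.concatenate(seq_idx), np.concatenate(starts)


def _em(windows: np.ndarray, seq_idx: np.ndarray, n_seqs: int,
        theta: np.ndarray, background: np.ndarray, pseudocount: float,
        max_iter: int, tol: float = 1e-4):
    """Run ZOOPS EM; returns (theta, gamma, per-window posterior, loglik)."""
    w = theta.shape[0]
    gamma = 0.5
    cols = np.arange(w)
    log_bg = np.log(background)
    counts_per_seq = np.bincount(seq_idx, minlength=n_seqs).astype(float)
    counts_per_seq[counts_per_seq == 0] = 1.0
    prev_ll = -np.inf
    z = None
    for _ in range(max_iter):
        lod = (np.log(theta)[cols, windows] - log_bg[windows]).sum(axis=1)
        # per-sequence normalization: motif at window j vs no occurrence
        w_motif = (gamma / counts_per_seq[seq_idx]) * np.exp(
            np.clip(lod, -700, 700))
        denom = np.bincount(seq_idx, weights=w_motif, minlength=n_seqs) + (1.0 - gamma)
        z = w_motif / denom[seq_idx]
        ll = float(np.log(denom).sum())
        # M-step
        counts = np.full((w, len(AA_LETTERS)), pseudocount)
        np.add.at(counts, (cols[None, :], windows), z[:, None])
        theta = counts / counts.sum(axis=1, keepdims=True)
        q_present = np.bincount(seq_idx, weights=z, minlength=n_seqs)
        gamma = float(np.clip(q_present.mean(), 1e-3, 1 - 1e-3))
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return theta, gamma, z, prev_ll


def _information_bits(theta: np.ndarray, background: np.ndarray) -> float:
    return float((theta * (np.log2(theta) - np.log2(background)[None, :])).sum())


def discover_motifs(sequences: list[SequenceRecord], max_motifs: int = 10,
                    width_range: tuple[int, int] = (6, 50), rng_seed: int = 0,
                    pseudocount: float = 0.25, max_iter: int = 200,
                    width_penalty_bits: float = 1.0,
                    min_information_bits: float = 2.0) -> list[MotifModel]:
    """Discover up to ``max_motifs`` ungapped motifs by ZOOPS EM.

    For each candidate width, EM is seeded from subsequence windows of a
    reference sequence (screened with two iterations, best seed run to
    convergence); the width maximizing information content minus a
    per-column penalty wins. Found occurrences are masked before the next
    motif. Deterministic given ``rng_seed``.
    """
    lo, hi = width_range
    if not (6 <= lo <= hi <= 50):
        raise ValueError("width range must lie within [6, 50]")
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    encoded = _encode(sequences)
    if all(len(x) < lo for x in encoded):
        raise ValueError("all sequences shorter than the minimum motif width")
    rng = np.random.default_rng(rng_seed)
    n_seqs = len(sequences)
    flat = np.concatenate(encoded)
    flat = flat[flat >= 0]
    background = (np.bincount(flat, minlength=len(AA_LETTERS)) + pseudocount)
    background = background / background.sum()

    motifs: list[MotifModel] = []
    for _ in range(max_motifs):
        best = None  # (penalized score, width, theta, z, windows meta)
        for width in range(lo, hi + 1):
            packed = _windows(encoded, width)
            if packed is None:
                continue
            windows, seq_idx, starts = packed
            # seeds: every window of the first sequence that still has
            # windows (subsampled only for very long sequences), screened
            # with a single EM iteration
            ref = seq_idx[0]
            seed_pool = np.nonzero(seq_idx == ref)[0]
            if seed_pool.size > 150:
                seed_pool = rng.choice(seed_pool, size=150, replace=False)
                seed_pool.sort()
            screened = []
            for k in seed_pool:
                theta0 = np.full((width, len(AA_LETTERS)), 0.3 / (len(AA_LETTERS) - 1))
                theta0[np.arange(width), windows[k]] = 0.7
                _theta, _gamma, _z, ll = _em(windows, seq_idx, n_seqs, theta0,
                                             background, pseudocount, max_iter=1)
                screened.append((ll, k, theta0))
            screened.sort(key=lambda t: (-t[0], t[1]))
            _, _, theta0 = screened[0]
            theta, gamma, z, _ = _em(windows, seq_idx, n_seqs, theta0,
                                     background, pseudocount, max_iter=max_iter)
            ic = _information_bits(theta, background)
            score = ic - width_penalty_bits * width
            if best is None or score > best[0]:
                best = (score, width, theta, z, (windows, seq_idx, starts))
        if best is None:
            break
        _, width, theta, z, (windows, seq_idx, starts) = best
        ic = _information_bits(theta, background)
        if ic < min_information_bits:
            break
        consensus = "".join(AA_LETTERS[a] for a in theta.argmax(axis=1))
        occurrences = []
        for s in range(n_seqs):
            mask = seq_idx == s
            if not mask.any():
                continue
            zs = z[mask]
            if zs.sum() < 0.5:  # ZOOPS: sequence judged to lack the motif
                continue
            k = int(np.argmax(zs))
            start = int(starts[mask][k])
            occurrences.append((sequences[s].id, start + 1))
            encoded[s] = encoded[s].copy()
            encoded[s][start:start + width] = -1  # mask before next motif
        motifs.append(MotifModel(width=width, pwm=theta, background=background,
                                 consensus=consensus, information_bits=ic,
                                 occurrences=occurrences))
    motifs.sort(key=lambda m: -m.information_bits)
    return motifs


# ---------------------------------------------------------------------------
# Cis-element scanning

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class CisElement:
    name: str
    pattern: str  # IUPAC nucleotide consensus
    functional_class: str

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"element {self.name!r}: invalid IUPAC letters {sorted(bad)}"
            )


@dataclass
class CisHit:
    gene: str
    element: str
    position: int  # 1-based within the promoter
    strand: str


# Literature-conventional consensus strings; configuration, not ground truth.
DEFAULT_CIS_CATALOG: list[CisElement] = [
    CisElement("ABRE", "ACGTG", "hormone"),
    CisElement("ERE", "ATTTCAAA", "hormone"),
    CisElement("as-1", "TGACG", "hormone"),
    CisElement("ARE", "AAACCA", "abiotic stress"),
    CisElement("MYB", "CNGTTR", "abiotic stress"),
    CisElement("MYC", "CANNTG", "abiotic stress"),
    CisElement("STRE", "AGGGG", "abiotic stress"),
    CisElement("LTR", "CCGAAA", "abiotic stress"),
    CisElement("WUN-motif", "AAATTTCCT", "biotic stress"),
    CisElement("W-box", "TTGACC", "biotic stress"),
    CisElement("Box4", "ATTAAT", "light"),
    CisElement("GT1-motif", "GGTTAA", "light"),
    CisElement("G-box", "CACGTG", "light"),
    CisElement("TATA-box", "TATAAA", "transcription"),
    CisElement("CAAT-box", "CCAAT", "transcription"),
    CisElement("CAT-box", "GCCACT", "growth"),
    CisElement("O2-site", "GATGACATGG", "growth"),
]


def load_catalog_tsv(path) -> list[CisElement]:
    """Catalog TSV with header: element, iupac_pattern, class."""
    catalog = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("element"):
            raise ValueError("catalog TSV must start with a header row")
        for line in fh:
            if not line.strip():
                continue
            name, pattern, cls = line.rstrip("\n").split("\t")
            catalog.append(CisElement(name, pattern, cls))
    return catalog


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def scan_cis_elements(promoters: list[SequenceRecord],
                      catalog: list[CisElement] | None = None):
    """Every occurrence of each catalog pattern, both strands.

    Returns ``(hits, summary)`` where summary maps
    gene -> functional class -> count.
    """
    catalog = catalog if catalog is not None else DEFAULT_CIS_CATALOG
    hits: list[CisHit] = []
    summary: dict[str, dict[str, int]] = {}
    for promoter in promoters:
        gene = promoter.id
        summary.setdefault(gene, {})
        seq = promoter.residues
        for element in catalog:
            fwd = _iupac_regex(element.pattern)
            rev = _iupac_regex(str(Seq(element.pattern).reverse_complement()))
            found = [(m.start() + 1, "+") for m in fwd.finditer(seq)]
            found += [(m.start() + 1, "-") for m in rev.finditer(seq)]
            for pos, strand in sorted(found):
                hits.append(CisHit(gene, element.name, pos, strand))
            if found:
                cls = element.functional_class
                summary[gene][cls] = summary[gene].get(cls, 0) + len(found)
    return hits, summary
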