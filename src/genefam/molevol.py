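"""Codon-level Ka/Ks estimation, selection classification and dating.

The estimator is the approximate Nei-Gojobori (1986) method: synonymous
and nonsynonymous site counts per codon, pathway-averaged difference
counts for codons differing at more than one position, Jukes-Cantor
multiple-hit correction, and divergence time T = Ks / (2 lambda) with a
default synonymous rate lambda = 6.1e-9 substitutions per site per year
(the soybean lineage rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

__all__ = [
    "MolEvolParams",
    "CodonAlignment",
    "KaKsResult",
    "build_codon_alignment",
    "ng86_counts",
    "kaks_estimate",
    "classify_selection",
    "divergence_time",
]

DEFAULT_LAMBDA = 6.1e-9  # synonymous substitutions / site / year
NUCLEOTIDES = "ACGT"


@dataclass
class MolEvolParams:
    lambda_rate: float = DEFAULT_LAMBDA
    genetic_code: int = 1
    pathway_stop_policy: str = "exclude"  # or "count-nonsyn"

    def __post_init__(self) -> None:
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be positive")


@dataclass
class CodonAlignment:
    """Triplet-aligned CDS pair: retained codon columns plus exclusions."""

    codon_pairs: list[tuple[str, str]]
    excluded: list[tuple[int, str]] = field(default_factory=list)  # (column, reason)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float  # math.inf when Ks == 0 < Ka; nan when both zero
    selection: str
    time_mya: float
    saturated: bool = False


def _code(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    stops = set(table.stop_codons)
    return aa, stops


def build_codon_alignment(cds_a: str, cds_b: str, protein_alignment,
                          table_id: int = 1) -> CodonAlignment:
    """Back-translate a pairwise protein alignment onto the two CDSs.

    Each protein gap becomes a 3-nt codon gap. Columns containing a gap,
    an ambiguous base (N) or a stop codon are excluded with a reason.
    """
    (_, prot_a), (_, prot_b) = protein_alignment.rows
    for name, cds, prot in (("a", cds_a, prot_a), ("b", cds_b, prot_b)):
        ungapped = prot.replace("-", "")
        if len(cds) // 3 < len(ungapped) or len(cds) % 3 != 0:
            raise ValueError(
                f"sequence {name}: CDS length {len(cds)} does not cover "
                f"{len(ungapped)} aligned residues"
            )
    _, stops = _code(table_id)
    pairs: list[tuple[str, str]] = []
    excluded: list[tuple[int, str]] = []
    ia = ib = 0
    for col, (ca, cb) in enumerate(zip(prot_a, prot_b)):
        codon_a = codon_b = None
        if ca != "-":
            codon_a = cds_a[3 * ia:3 * ia + 3]
            ia += 1
        if cb != "-":
            codon_b = cds_b[3 * ib:3 * ib + 3]
            ib += 1
        if codon_a is None or codon_b is None:
            excluded.append((col, "gap"))
            continue
        if "N" in codon_a or "N" in codon_b:
            excluded.append((col, "ambiguous"))
            continue
        if codon_a in stops or codon_b in stops:
            excluded.append((col, "stop"))
            continue
        pairs.append((codon_a, codon_b))
    return CodonAlignment(pairs, excluded)


@lru_cache(maxsize=None)
def _codon_sites(codon: str, table_id: int, policy: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each position contributes one site, split by the fraction of one-step
    changes that are synonymous. Under the 'exclude' policy changes to stop
    codons are removed from the denominator; under 'count-nonsyn' they
    count as nonsynonymous changes.
    """
    aa, stops = _code(table_id)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in stops:
                if policy == "count-nonsyn":
                    valid += 1
                continue
            valid += 1
            if aa[alt] == aa[codon]:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(codon_a: str, codon_b: str, table_id: int,
                      policy: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are skipped under 'exclude' (falling back
    to all pathways, stop steps nonsynonymous, if none survive).
    """
    aa, stops = _code(table_id)
    diff_pos = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff_pos:
        return 0.0, 0.0

    def classify(path_orders, skip_stops: bool):
        totals = []
        for order in path_orders:
            cur = codon_a
            sd = nd = 0.0
            ok = True
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                if nxt in stops:
                    if skip_stops:
                        ok = False
                        break
                    nd += 1.0
                elif cur in stops:
                    nd += 1.0  # leaving a stop intermediate: nonsynonymous
                elif aa[nxt] == aa[cur]:
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            if ok:
                totals.append((sd, nd))
        return totals

    orders = list(permutations(diff_pos))
    totals = classify(orders, skip_stops=(policy == "exclude"))
    if not totals:
        totals = classify(orders, skip_stops=False)
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def ng86_counts(ca: CodonAlignment, params: MolEvolParams | None = None):
    """Nei-Gojobori site and difference counts over retained codon columns.

    Sites are averaged between the two sequences; differences use uniform
    pathway averaging. Returns (S, N, Sd, Nd).
    """
    params = params or MolEvolParams()
    if not ca.codon_pairs:
        raise ValueError("no retained codon columns")
    S = N = Sd = Nd = 0.0
    for codon_a, codon_b in ca.codon_pairs:
        sa, na = _codon_sites(codon_a, params.genetic_code, params.pathway_stop_policy)
        sb, nb = _codon_sites(codon_b, params.genetic_code, params.pathway_stop_policy)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pair_differences(codon_a, codon_b, params.genetic_code,
                                   params.pathway_stop_policy)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def classify_selection(ratio: float, tol: float = 1e-9) -> str:
    """Ka/Ks < 1 purifying, > 1 positive, == 1 (within tol) neutral."""
    if math.isnan(ratio):
        raise ValueError("selection undefined for nan ratio")
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def divergence_time(ks: float, lambda_rate: float = DEFAULT_LAMBDA) -> float:
    """T = Ks / (2 lambda), reported in millions of years (Mya)."""
    if ks < 0 or not math.isfinite(ks):
        raise ValueError(f"Ks must be finite and non-negative, got {ks}")
    years = ks / (2.0 * lambda_rate)
    return years / 1e6


def kaks_estimate(S: float, N: float, Sd: float, Nd: float,
                  params: MolEvolParams | None = None) -> KaKsResult:
    """Jukes-Cantor-corrected Ka and Ks from NG86 counts.

    pS >= 3/4 means synonymous saturation: Ks and the ratio are undefined
    (returned as nan with the saturated flag set). Ks = 0 with Ka > 0 is
    reported as an infinite ratio and classified positive.
    """
    params = params or MolEvolParams()
    if S <= 0 or N <= 0:
        raise ValueError("site counts must be positive")
    pS, pN = Sd / S, Nd / N
    saturated = pS >= 0.75
    ks = float("nan") if saturated else _jukes_cantor(pS)
    ka = float("nan") if pN >= 0.75 else _jukes_cantor(pN)
    if saturated or math.isnan(ka):
        ratio = float("nan")
        selection = "undefined"
        time = float("nan")
    else:
        if ks == 0.0:
            ratio = math.inf if ka > 0 else float("nan")
        else:
            ratio = ka / ks
        selection = classify_selection(ratio) if not math.isnan(ratio) else "undefined"
        time = divergence_time(ks, params.lambda_rate)
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=ks, Ka=ka,
                      ratio=ratio, selection=selection, time_mya=time,
                      saturated=saturated)
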