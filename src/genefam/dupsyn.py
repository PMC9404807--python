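"""Duplicated-pair detection, tandem/segmental classification, synteny.

A pair of family members is a duplication candidate when pairwise
identity exceeds a threshold (default: strictly more than 90%).
Same-chromosome pairs separated by at most five intervening genes in the
full annotation are tandem duplicates; everything else (more intervening
genes, or different chromosomes) is segmental. Collinearity between two
genomes is chained MCScan-style: longest order-monotone runs of homolog
anchors within a gene-rank gap limit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .curation import FamilyMember
from .phylo import GAP, pairwise_align_global

__all__ = [
    "DuplicationParams",
    "DuplicationEvent",
    "SyntenyBlock",
    "percent_identity",
    "find_duplicates",
    "classify_duplication",
    "reciprocal_best_pairs",
    "reciprocal_best_sequences",
    "chain_collinearity",
]


@dataclass
class DuplicationParams:
    identity_threshold: float = 90.0  # strict >
    max_intervening_genes_tandem: int = 5
    identity_level: str = "protein"  # or "cds"

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity threshold must be in (0, 100]")


@dataclass
class DuplicationEvent:
    pair: tuple[str, str]
    identity: float
    type: str  # "tandem" | "segmental"
    intervening_genes: int | None  # None when on different chromosomes


@dataclass
class SyntenyBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[tuple[str, str]]

    @property
    def score(self) -> int:
        return len(self.anchors)


def percent_identity(a: str, b: str, alphabet: str = "protein") -> float:
    """Pairwise identity (%) over a trimmed global alignment.

    Terminal gap overhangs are trimmed; identity = matching columns /
    remaining alignment columns (gapped internal columns count as
    mismatches).
    """
    if not a or not b:
        raise ValueError("cannot compute identity of empty sequences")
    msa, _ = pairwise_align_global(a, b, alphabet=alphabet)
    (_, ra), (_, rb) = msa.rows
    lo, hi = 0, len(ra)
    while lo < hi and (ra[lo] == GAP or rb[lo] == GAP):
        lo += 1
    while hi > lo and (ra[hi - 1] == GAP or rb[hi - 1] == GAP):
        hi -= 1
    ra, rb = ra[lo:hi], rb[lo:hi]
    if not ra:
        return 0.0
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
    return 100.0 * matches / len(ra)


def _member_sequence(member: FamilyMember, level: str) -> str:
    return member.protein.residues if level == "protein" else member.cds


def find_duplicates(members: list[FamilyMember],
                    params: DuplicationParams | None = None):
    """All unordered member pairs with identity strictly above threshold.

    A member may take part in several duplicated pairs. Returns a list of
    ``(name_a, name_b, identity)``.
    """
    params = params or DuplicationParams()
    alphabet = "protein" if params.identity_level == "protein" else "dna"
    out: list[tuple[str, str, float]] = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            ident = percent_identity(
                _member_sequence(members[i], params.identity_level),
                _member_sequence(members[j], params.identity_level),
                alphabet=alphabet,
            )
            if ident > params.identity_threshold:
                out.append((members[i].name or members[i].gene.gene_id,
                            members[j].name or members[j].gene.gene_id, ident))
    return out


def classify_duplication(member_a: FamilyMember, member_b: FamilyMember,
                         identity: float, all_genes,
                         params: DuplicationParams | None = None) -> DuplicationEvent:
    """Tandem vs segmental call for one duplicated pair.

    ``all_genes`` is the full annotation (every gene, family or not).
    Intervening genes are those strictly between the pair on the same
    chromosome; at most ``max_intervening_genes_tandem`` of them makes the
    pair tandem. Symmetric in pair order.
    """
    params = params or DuplicationParams()
    ga, gb = member_a.gene, member_b.gene
    name_a = member_a.name or ga.gene_id
    name_b = member_b.name or gb.gene_id
    ids = {g.gene_id for g in all_genes}
    for g in (ga, gb):
        if g.gene_id not in ids:
            raise ValueError(f"gene {g.gene_id} missing from annotation")
    if ga.chrom != gb.chrom:
        return DuplicationEvent((name_a, name_b), identity, "segmental", None)
    lo, hi = sorted([ga.start, gb.start])
    between = sum(
        1 for g in all_genes
        if g.chrom == ga.chrom and lo < g.start < hi
        and g.gene_id not in (ga.gene_id, gb.gene_id)
    )
    kind = "tandem" if between <= params.max_intervening_genes_tandem else "segmental"
    return DuplicationEvent((name_a, name_b), identity, kind, between)


# ---------------------------------------------------------------------------
# Collinearity


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def reciprocal_best_sequences(seqs_a: dict[str, str], seqs_b: dict[str, str],
                              min_identity: float = 40.0,
                              alphabet: str = "protein",
                              prefilter_top: int = 3):
    """Reciprocal best identity matches between two sequence sets.

    A k-mer Jaccard prefilter restricts alignments to the most promising
    candidates per query; surviving candidates are scored by global
    alignment identity. Returns ``(id_a, id_b, identity)`` triples.
    """
    kmers_a = {i: _kmer_set(s) for i, s in seqs_a.items()}
    kmers_b = {i: _kmer_set(s) for i, s in seqs_b.items()}

    def candidates(query_kmers, pool):
        scored = sorted(
            pool.items(),
            key=lambda kv: (-len(query_kmers & kv[1]), kv[0]),
        )
        return [i for i, _ in scored[:prefilter_top]]

    ident: dict[tuple[str, str], float] = {}

    def get_ident(ia: str, ib: str) -> float:
        if (ia, ib) not in ident:
            ident[(ia, ib)] = percent_identity(seqs_a[ia], seqs_b[ib], alphabet)
        return ident[(ia, ib)]

    best_a = {}
    for ia in sorted(seqs_a):
        cands = candidates(kmers_a[ia], kmers_b)
        best_a[ia] = max(cands, key=lambda ib: (get_ident(ia, ib), ib))
    best_b = {}
    for ib in sorted(seqs_b):
        cands = candidates(kmers_b[ib], kmers_a)
        best_b[ib] = max(cands, key=lambda ia: (get_ident(ia, ib), ia))
    pairs = []
    for ia, ib in sorted(best_a.items()):
        if best_b.get(ib) == ia and ident[(ia, ib)] >= min_identity:
            pairs.append((ia, ib, ident[(ia, ib)]))
    return pairs


def reciprocal_best_pairs(members_a: list[FamilyMember],
                          members_b: list[FamilyMember],
                          min_identity: float = 40.0,
                          level: str = "protein"):
    """Reciprocal best identity matches between two member sets.

    This lower-threshold matching supplies homolog anchors for synteny
    chaining; it is distinct from the strict duplication threshold.
    """
    alphabet = "protein" if level == "protein" else "dna"
    seqs_a = {m.name or m.gene.gene_id: _member_sequence(m, level) for m in members_a}
    seqs_b = {m.name or m.gene.gene_id: _member_sequence(m, level) for m in members_b}
    return reciprocal_best_sequences(seqs_a, seqs_b, min_identity, alphabet,
                                     prefilter_top=max(3, len(seqs_b)))


def _rank_maps(genes):
    """Gene id -> (chrom, rank along chromosome by start)."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    ranks = {}
    for chrom, group in by_chrom.items():
        group.sort(key=lambda g: (g.start, g.gene_id))
        for k, g in enumerate(group):
            ranks[g.gene_id] = (chrom, k)
    return ranks


def _chain(anchors, direction: int, max_gap: int):
    """Heaviest strictly monotone chain by DP over rank-sorted anchors.

    ``anchors`` is a list of (rank_a, rank_b, index); chains increase in
    rank_a and increase (direction=+1) or decrease (-1) in rank_b, with
    consecutive anchors at most ``max_gap`` ranks apart in both genomes.
    """
    order = sorted(range(len(anchors)), key=lambda k: (anchors[k][0], anchors[k][1]))
    best = [1] * len(order)
    prev = [-1] * len(order)
    for u in range(len(order)):
        ra_u, rb_u, _ = anchors[order[u]]
        for v in range(u):
            ra_v, rb_v, _ = anchors[order[v]]
            if ra_v >= ra_u:
                continue
            if direction * (rb_u - rb_v) <= 0:
                continue
            if ra_u - ra_v > max_gap or abs(rb_u - rb_v) > max_gap:
                continue
            if best[v] + 1 > best[u]:
                best[u] = best[v] + 1
                prev[u] = v
    if not order:
        return []
    end = max(range(len(order)), key=lambda u: (best[u], -u))
    chain = []
    while end != -1:
        chain.append(anchors[order[end]][2])
        end = prev[end]
    chain.reverse()
    return chain


def chain_collinearity(genes_a, genes_b, homolog_pairs,
                       min_block_size: int = 5, max_gap_genes: int = 25):
    """Chain homolog anchors into collinear blocks, per chromosome pair.

    Greedy extraction: repeatedly take the heaviest monotone chain (same or
    inverted orientation) among unused anchors, drop it if shorter than
    ``min_block_size``. Each anchor joins at most one block.
    """
    ranks_a = _rank_maps(genes_a)
    ranks_b = _rank_maps(genes_b)
    by_chrompair: dict[tuple[str, str], list] = {}
    for idx, (ga, gb, *_rest) in enumerate(homolog_pairs):
        if ga not in ranks_a or gb not in ranks_b:
            continue
        ca, ra = ranks_a[ga]
        cb, rb = ranks_b[gb]
        by_chrompair.setdefault((ca, cb), []).append((ra, rb, (ga, gb)))
    blocks: list[SyntenyBlock] = []
    bid = 0
    for (ca, cb), anchor_list in sorted(by_chrompair.items()):
        remaining = list(anchor_list)
        while remaining:
            indexed = [(ra, rb, k) for k, (ra, rb, _) in enumerate(remaining)]
            fwd = _chain(indexed, +1, max_gap_genes)
            rev = _chain(indexed, -1, max_gap_genes)
            chain, orientation = (fwd, "same") if len(fwd) >= len(rev) else (rev, "inverted")
            if len(chain) < min_block_size:
                break
            bid += 1
            blocks.append(SyntenyBlock(
                block_id=bid, chrom_a=ca, chrom_b=cb, orientation=orientation,
                anchors=[remaining[k][2] for k in chain],
            ))
            used = set(chain)
            remaining = [x for k, x in enumerate(remaining) if k not in used]
    return blocks
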