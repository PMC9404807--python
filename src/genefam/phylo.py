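"""Alignment, Poisson-corrected distances, neighbor joining and bootstrap.

The distance pipeline mirrors the classic amino-acid workflow: multiple
alignment, complete deletion of gapped columns, proportion of differing
sites p, Poisson correction d = -ln(1 - p), Saitou-Nei neighbor joining,
and nonparametric bootstrap of alignment columns for branch support.
Paralogous and orthologous pairs are read off the tree as supported
cherries (two-leaf sister clades).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloParams",
    "pairwise_align_global",
    "progressive_msa",
    "poisson_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "extract_terminal_pairs",
]

PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWYX"
GAP = "-"


@dataclass
class PhyloParams:
    bootstrap_reps: int = 1000
    gap_policy: str = "complete-deletion"  # or "pairwise-deletion"
    support_threshold_for_pairs: float = 50.0
    rng_seed: int = 0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class MultipleAlignment:
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def ungapped(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq.replace(GAP, "")
        raise KeyError(rid)


@dataclass
class DistanceMatrix:
    ids: list[str]
    p: np.ndarray
    d: np.ndarray
    undefined: set[tuple[str, str]] = field(default_factory=set)


class TreeNode:
    """Tree node; branch length is the length of the edge above the node."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name: str | None = None, children=None,
                 length: float = 0.0, support: float | None = None):
        self.name = name
        self.children: list[TreeNode] = children or []
        self.length = length
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf distances induced by the tree."""
        dists: dict[tuple[str, str], float] = {}

        def depths(node, acc):
            if node.is_leaf():
                return {node.name: acc}
            out = {}
            for c in node.children:
                out.update(depths(c, acc + c.length))
            return out

        def rec(node):
            child_maps = [depths(c, c.length) for c in node.children]
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for a, da in child_maps[i].items():
                        for b, db in child_maps[j].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
            for c in node.children:
                rec(c)

        rec(self)
        return dists

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: "TreeNode") -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# Pairwise and progressive alignment


def _aligner(alphabet: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = 5
        aligner.mismatch_score = -4
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_align_global(a: str, b: str, alphabet: str = "protein",
                          gap_open: float = 10.0, gap_extend: float = 0.5,
                          ids: tuple[str, str] = ("a", "b")):
    """Optimal affine-gap global alignment of two sequences.

    Returns ``(MultipleAlignment, score)``. The first optimal alignment in
    the aligner's deterministic enumeration order is taken.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a, b = a.replace("*", "X"), b.replace("*", "X")
    aligner = _aligner(alphabet, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    aln = alignments[0]
    rows = [(ids[0], str(aln[0])), (ids[1], str(aln[1]))]
    return MultipleAlignment(rows), float(aln.score)


def _substitution_array(alphabet: str) -> tuple[np.ndarray, dict[str, int]]:
    if alphabet == "protein":
        letters = PROTEIN_LETTERS
        blosum = substitution_matrices.load("BLOSUM62")
        idx = {aa: i for i, aa in enumerate(letters)}
        S = np.zeros((len(letters), len(letters)))
        for a in letters:
            for b in letters:
                S[idx[a], idx[b]] = blosum[a][b]
    else:
        letters = "ACGTN"
        idx = {nt: i for i, nt in enumerate(letters)}
        S = np.full((5, 5), -4.0)
        np.fill_diagonal(S, 5.0)
        S[4, :] = S[:, 4] = 0.0
    return S, idx


def _profile(msa: MultipleAlignment, idx: dict[str, int]) -> np.ndarray:
    """Per-column letter frequencies (gap mass dropped, occupancy kept).

    Shape (columns, letters). Columns sum to the fraction of non-gap rows,
    so fully gapped columns contribute nothing to match scores.
    """
    k = len(idx)
    prof = np.zeros((msa.columns, k))
    for _, seq in msa.rows:
        for j, ch in enumerate(seq):
            if ch != GAP:
                prof[j, idx.get(ch, idx.get("X", 0))] += 1.0
    return prof / len(msa.rows)


def _align_profiles(pa: np.ndarray, pb: np.ndarray, S: np.ndarray,
                    gap_open: float, gap_extend: float):
    """Affine-gap global alignment of two profiles (Gotoh, vectorized rows).

    Gap penalties are scaled by the occupancy (non-gap fraction) of the
    consumed column, so new gaps preferentially stack onto columns that
    already contain gaps — the usual position-specific penalty of
    progressive aligners. Returns the traceback as a list of moves
    ('M', 'A', 'B'): 'A' consumes a column of profile A only (gap in B),
    'B' the converse. Ties prefer M > A > B.
    """
    n, m = pa.shape[0], pb.shape[0]
    col_scores = pa @ S @ pb.T  # (n, m) expected sum-of-pairs column score
    occ_a = pa.sum(axis=1)  # profile columns sum to their occupancy
    occ_b = pb.sum(axis=1)
    open_a, ext_a = gap_open * occ_a, gap_extend * occ_a
    open_b, ext_b = gap_open * occ_b, gap_extend * occ_b
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A), vertical
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B), horizontal
    M[0, 0] = 0.0
    # terminal gap rows/columns
    if n:
        X[1:, 0] = -(open_a[0] + np.concatenate(([0.0], np.cumsum(ext_a[1:]))))
    if m:
        Y[0, 1:] = -(open_b[0] + np.concatenate(([0.0], np.cumsum(ext_b[1:]))))
    cum_b = np.concatenate(([0.0], np.cumsum(ext_b)))  # cum_b[j] = sum ext_b[:j]
    for i in range(1, n + 1):
        prev_best = np.maximum(M[i - 1], np.maximum(X[i - 1], Y[i - 1]))
        M[i, 1:] = prev_best[:-1] + col_scores[i - 1]
        X[i] = np.maximum(X[i - 1] - ext_a[i - 1],
                          np.maximum(M[i - 1], Y[i - 1]) - open_a[i - 1])
        # horizontal pass: Y[i, j] = max_{k<j} (base[k] - open_b[k]
        #   - sum(ext_b[k+1..j-1])), vectorized with a running max
        base = np.maximum(M[i], X[i])
        shifted = base[:-1] - open_b + cum_b[1:]
        running = np.maximum.accumulate(shifted)
        Y[i, 1:] = running - cum_b[1:]
    # traceback
    moves: list[str] = []
    i, j = n, m
    scores = {"M": M, "A": X, "B": Y}
    state = max(("M", "A", "B"), key=lambda s: scores[s][i, j])
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            moves.append("M")
            val = M[i, j] - col_scores[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s in ("M", "A", "B"):
                if abs(scores[s][i, j] - val) < eps:
                    state = s
                    break
        elif state == "A":
            moves.append("A")
            val = X[i, j]
            i -= 1
            if abs(X[i, j] - ext_a[i] - val) < eps:
                state = "A"
            elif abs(M[i, j] - open_a[i] - val) < eps:
                state = "M"
            else:
                state = "B"
        else:
            moves.append("B")
            val = Y[i, j]
            j -= 1
            if abs(Y[i, j] - ext_b[j] - val) < eps:
                state = "B"
            elif abs(M[i, j] - open_b[j] - val) < eps:
                state = "M"
            else:
                state = "A"
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "B"
        elif j == 0:
            state = "A"
    moves.reverse()
    return moves


def _merge_alignments(ma: MultipleAlignment, mb: MultipleAlignment,
                      moves: list[str]) -> MultipleAlignment:
    rows = []
    for rid, seq in ma.rows:
        out, k = [], 0
        for mv in moves:
            if mv in ("M", "A"):
                out.append(seq[k])
                k += 1
            else:
                out.append(GAP)
        rows.append((rid, "".join(out)))
    for rid, seq in mb.rows:
        out, k = [], 0
        for mv in moves:
            if mv in ("M", "B"):
                out.append(seq[k])
                k += 1
            else:
                out.append(GAP)
        rows.append((rid, "".join(out)))
    return MultipleAlignment(rows)


def progressive_msa(sequences: list[tuple[str, str]], alphabet: str = "protein",
                    gap_open: float = 10.0, gap_extend: float = 0.5) -> MultipleAlignment:
    """Progressive multiple alignment along an NJ guide tree.

    Pairwise p-distances from global alignments build the guide tree;
    profiles are merged bottom-up with the same affine scheme.
    """
    if len(sequences) == 1:
        warnings.warn("single sequence: returned unaligned")
        return MultipleAlignment(list(sequences))
    if len(sequences) == 2:
        (ida, sa), (idb, sb) = sequences
        msa, _ = pairwise_align_global(sa, sb, alphabet, gap_open, gap_extend,
                                       ids=(ida, idb))
        return msa
    ids = [rid for rid, _ in sequences]
    n = len(ids)
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            msa, _ = pairwise_align_global(sequences[i][1], sequences[j][1],
                                           alphabet, gap_open, gap_extend)
            (_, ra), (_, rb) = msa.rows
            both = [(x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP]
            diffs = sum(1 for x, y in both if x != y)
            P[i, j] = P[j, i] = diffs / len(both) if both else 1.0
    guide = neighbor_joining(DistanceMatrix(ids, P, P.copy()))
    S, idx = _substitution_array(alphabet)
    seq_by_id = dict(sequences)

    def build(node: TreeNode) -> MultipleAlignment:
        if node.is_leaf():
            return MultipleAlignment([(node.name, seq_by_id[node.name])])
        sub = build(node.children[0])
        for child in node.children[1:]:
            other = build(child)
            pa, pb = _profile(sub, idx), _profile(other, idx)
            moves = _align_profiles(pa, pb, S, gap_open, gap_extend)
            sub = _merge_alignments(sub, other, moves)
        return sub

    merged = build(guide)
    # restore input row order
    order = {rid: k for k, rid in enumerate(ids)}
    merged.rows.sort(key=lambda r: order[r[0]])
    return merged


# ---------------------------------------------------------------------------
# Distances


def poisson_distance_matrix(msa: MultipleAlignment,
                            gap_policy: str = "complete-deletion") -> DistanceMatrix:
    """Poisson-corrected amino-acid distances d = -ln(1 - p).

    Complete deletion removes every column containing a gap in any row
    before computing p; pairwise deletion drops gapped sites per pair.
    """
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    ids = msa.ids
    mat = np.array([list(seq) for _, seq in msa.rows])
    n = len(ids)
    p = np.zeros((n, n))
    undefined: set[tuple[str, str]] = set()
    if gap_policy == "complete-deletion":
        keep = ~(mat == GAP).any(axis=0)
        sub = mat[:, keep]
        for i in range(n):
            for j in range(i + 1, n):
                if sub.shape[1] == 0:
                    p[i, j] = p[j, i] = np.nan
                    undefined.add((ids[i], ids[j]))
                else:
                    p[i, j] = p[j, i] = np.mean(sub[i] != sub[j])
    elif gap_policy == "pairwise-deletion":
        for i in range(n):
            for j in range(i + 1, n):
                ok = (mat[i] != GAP) & (mat[j] != GAP)
                if not ok.any():
                    p[i, j] = p[j, i] = np.nan
                    undefined.add((ids[i], ids[j]))
                else:
                    p[i, j] = p[j, i] = np.mean(mat[i][ok] != mat[j][ok])
    else:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -np.log(1.0 - p)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(p[i, j]) or p[i, j] >= 1.0:
                d[i, j] = d[j, i] = np.inf
                undefined.add((ids[i], ids[j]))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, p, d, undefined)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic (min i, min j) tie-break.

    Negative branch-length estimates are clamped to zero. The unrooted tree
    is returned rooted at the last junction, which preserves all leaf-to-leaf
    path lengths.
    """
    ids = list(dm.ids)
    n = len(ids)
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("neighbor joining requires finite distances")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    D = dm.d.astype(float).copy()
    if n == 2:
        warnings.warn("fewer than 3 taxa: degenerate tree")
        a, b = nodes
        a.length = b.length = D[0, 1] / 2.0
        return TreeNode(children=[a, b])
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = smallest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
    a, b = nodes
    if not b.is_leaf():
        a, b = b, a
    if a.is_leaf():  # both leaves never happens for n >= 3
        root = TreeNode(children=[a, b])
        a.length = b.length = D[0, 1] / 2.0
        return root
    b.length = max(D[0, 1], 0.0)
    a.children.append(b)
    a.length = 0.0
    return a


# ---------------------------------------------------------------------------
# Bootstrap


def _splits(tree: TreeNode) -> dict[int, frozenset[str]]:
    """Nontrivial bipartitions keyed by id(node), canonicalized.

    Each internal edge is represented by the leaf set on the child side,
    replaced by its complement when that does not contain the reference
    (lexicographically smallest) leaf — making splits invariant to rooting.
    """
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: dict[int, frozenset[str]] = {}
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[id(node)] = side
    return out


def bootstrap_support(msa: MultipleAlignment, params: PhyloParams | None = None,
                      tree: TreeNode | None = None) -> TreeNode:
    """Column-resampling bootstrap; supports mapped onto the original tree.

    Each replicate resamples alignment columns with replacement, recomputes
    Poisson distances under the configured gap policy, rebuilds the NJ tree
    and counts bipartition recurrence. Replicates with undefined distances
    are skipped (counted toward none of the splits, denominators unchanged).
    """
    params = params or PhyloParams()
    if tree is None:
        dm = poisson_distance_matrix(msa, params.gap_policy)
        tree = neighbor_joining(dm)
    target = _splits(tree)
    counts = {node_id: 0 for node_id in target}
    rng = np.random.default_rng(params.rng_seed)
    ncols = msa.columns
    mat = np.array([list(seq) for _, seq in msa.rows])
    skipped = 0
    for _ in range(params.bootstrap_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep_rows = [(rid, "".join(mat[k][cols])) for k, (rid, _) in enumerate(msa.rows)]
        rep = MultipleAlignment(rep_rows)
        try:
            rep_dm = poisson_distance_matrix(rep, params.gap_policy)
            rep_tree = neighbor_joining(rep_dm)
        except ValueError:
            skipped += 1
            continue
        rep_splits = set(_splits(rep_tree).values())
        for node_id, split in target.items():
            if split in rep_splits:
                counts[node_id] += 1
    for node in tree.walk():
        if id(node) in counts:
            node.support = 100.0 * counts[id(node)] / params.bootstrap_reps
    return tree


def extract_terminal_pairs(tree: TreeNode, species_of: dict[str, str],
                           support_threshold: float = 50.0):
    """Supported cherries, split into paralog and ortholog pairs.

    A cherry is an internal node with exactly two leaf children. Pairs whose
    node support is below the threshold (or absent) are not emitted. Same
    species -> paralog pair; different species -> ortholog pair.
    """
    paralogs: list[tuple[str, str, float]] = []
    orthologs: list[tuple[str, str, float]] = []
    for node in tree.walk():
        if node.is_leaf() or len(node.children) != 2:
            continue
        a, b = node.children
        if not (a.is_leaf() and b.is_leaf()):
            continue
        support = node.support
        if support is None or support < support_threshold:
            continue
        pair = tuple(sorted((a.name, b.name)))
        if species_of[pair[0]] == species_of[pair[1]]:
            paralogs.append((*pair, support))
        else:
            orthologs.append((*pair, support))
    return paralogs, orthologs
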