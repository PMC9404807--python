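import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from genefam.phylo import (DistanceMatrix, MultipleAlignment, PhyloParams,
                           TreeNode, bootstrap_support, extract_terminal_pairs,
                           neighbor_joining, pairwise_align_global,
                           poisson_distance_matrix, progressive_msa)

BLOSUM = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# Oracles


def brute_force_affine_score(a, b, gap_open=10.0, gap_extend=0.5):
    """Exhaustive enumeration of all global alignments (tiny inputs only)."""
    best = [-np.inf]

    def rec(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + BLOSUM[a[i]][b[j]], "M")
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open
            rec(i + 1, j, score - cost, "A")
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open
            rec(i, j + 1, score - cost, "B")

    rec(0, 0, 0.0, None)
    return best[0]


GAP_COST = 8.0


def sum_of_pairs(msa: MultipleAlignment) -> float:
    """Linear-gap sum-of-pairs score (gap-gap columns score 0)."""
    total = 0.0
    for (_, ra), (_, rb) in itertools.combinations(msa.rows, 2):
        for x, y in zip(ra, rb):
            if x == "-" and y == "-":
                continue
            total += -GAP_COST if "-" in (x, y) else BLOSUM[x][y]
    return total


def optimal_three_way_sop(s1, s2, s3):
    """Exhaustive 3-sequence alignment by dynamic programming over (i,j,k)."""
    n1, n2, n3 = len(s1), len(s2), len(s3)
    NEG = -np.inf
    dp = np.full((n1 + 1, n2 + 1, n3 + 1), NEG)
    dp[0, 0, 0] = 0.0

    def col_score(x, y, z):
        total = 0.0
        for a, b in ((x, y), (x, z), (y, z)):
            if a is None and b is None:
                continue
            total += -GAP_COST if (a is None or b is None) else BLOSUM[a][b]
        return total

    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                if dp[i, j, k] == NEG:
                    continue
                for di, dj, dk in itertools.product((0, 1), repeat=3):
                    if (di, dj, dk) == (0, 0, 0):
                        continue
                    if i + di > n1 or j + dj > n2 or k + dk > n3:
                        continue
                    x = s1[i] if di else None
                    y = s2[j] if dj else None
                    z = s3[k] if dk else None
                    val = dp[i, j, k] + col_score(x, y, z)
                    if val > dp[i + di, j + dj, k + dk]:
                        dp[i + di, j + dj, k + dk] = val
    return float(dp[n1, n2, n3])


def random_additive_matrix(rng, n):
    """Distances induced by a random binary tree with random edge lengths."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    pool = list(nodes)
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[j], pool[i]
        a.length = float(rng.uniform(0.5, 3.0))
        b.length = float(rng.uniform(0.5, 3.0))
        parent = TreeNode(children=[b, a])
        pool = [p for p in pool if p not in (a, b)] + [parent]
    pool[0].length = float(rng.uniform(0.5, 3.0))
    pool[1].length = float(rng.uniform(0.5, 3.0))
    root = TreeNode(children=pool)
    pl = root.path_lengths()
    ids = sorted(n.name for n in nodes)
    D = np.zeros((n, n))
    for x, y in itertools.combinations(range(n), 2):
        D[x, y] = D[y, x] = pl[(ids[x], ids[y])]
    return ids, D


# ---------------------------------------------------------------------------
# Pairwise and progressive alignment


class TestPairwise:
    def test_identical_sequences_align_without_gaps(self):
        msa, _ = pairwise_align_global("MKLV", "MKLV")
        assert msa.rows[0][1] == msa.rows[1][1] == "MKLV"

    def test_length_difference_forces_gap(self):
        msa, _ = pairwise_align_global("ACD", "AD")
        assert msa.rows[1][1].count("-") == 1

    @pytest.mark.parametrize("a,b", [
        ("MKV", "MV"), ("ACDEFG", "ACDG"), ("WWK", "KWW"),
        ("MKLVAE", "MKVAEL"), ("HHH", "HDH"),
    ])
    def test_score_matches_exhaustive_enumeration(self, a, b):
        _, score = pairwise_align_global(a, b)
        assert score == pytest.approx(brute_force_affine_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align_global("", "MK")


class TestProgressiveMsa:
    def test_identical_sequences_give_gap_free_alignment(self):
        seqs = [(f"s{i}", "MKLVAEHW") for i in range(5)]
        msa = progressive_msa(seqs)
        assert all("-" not in row for _, row in msa.rows)
        assert msa.columns == 8

    def test_two_sequences_reduce_to_pairwise(self):
        pair, _ = pairwise_align_global("MKLVAE", "MKVAEL", ids=("a", "b"))
        msa = progressive_msa([("a", "MKLVAE"), ("b", "MKVAEL")])
        assert msa.rows == pair.rows

    def test_single_sequence_warns(self):
        with pytest.warns(UserWarning):
            msa = progressive_msa([("a", "MKLV")])
        assert msa.rows == [("a", "MKLV")]

    def test_rows_ungap_to_inputs(self):
        seqs = [("a", "MKLVAEHW"), ("b", "MKLAEHW"), ("c", "MKLVEHWW"),
                ("d", "MKLVAHW")]
        msa = progressive_msa(seqs)
        for rid, s in seqs:
            assert msa.ungapped(rid) == s
        assert msa.columns >= max(len(s) for _, s in seqs)

    @pytest.mark.parametrize("seqs", [
        ("MKLVAEHW", "MKLAEHW", "MKLVEHW"),
        ("WKDEC", "WKDQC", "WDEC"),
        ("MKVH", "MKH", "MKVH"),
        ("MWKLE", "MWKE", "MWLE"),
        ("ACDEFGHK", "ACDEGHK", "ACDFGHK"),
    ])
    def test_sum_of_pairs_near_optimal_on_toys(self, seqs):
        """Progressive alignment reaches >= 90% of the exact 3-way optimum."""
        msa = progressive_msa([(f"s{i}", s) for i, s in enumerate(seqs)])
        opt = optimal_three_way_sop(*seqs)
        assert opt > 0
        assert sum_of_pairs(msa) >= 0.9 * opt


# ---------------------------------------------------------------------------
# Distances


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment([("a", "MKLV"), ("b", "MKLV")])
        dm = poisson_distance_matrix(msa)
        assert dm.p[0, 1] == 0 and dm.d[0, 1] == 0

    def test_closed_form(self):
        msa = MultipleAlignment([("a", "MKLV"), ("b", "MKLW")])
        dm = poisson_distance_matrix(msa)
        assert dm.p[0, 1] == pytest.approx(0.25)
        assert dm.d[0, 1] == pytest.approx(-np.log(0.75))

    def test_complete_deletion_column_count(self):
        # columns: 0 gap in b, 3 gap in c -> 3 columns usable (1,2,4)
        msa = MultipleAlignment([("a", "MKLVA"), ("b", "-KLVA"), ("c", "MKL-A")])
        dm = poisson_distance_matrix(msa, "complete-deletion")
        assert dm.p[0, 1] == 0.0  # over the 3 surviving columns
        # introduce a difference inside a surviving column
        msa2 = MultipleAlignment([("a", "MKLVA"), ("b", "-KWVA"), ("c", "MKL-A")])
        dm2 = poisson_distance_matrix(msa2, "complete-deletion")
        assert dm2.p[0, 1] == pytest.approx(1 / 3)

    def test_pairwise_deletion(self):
        msa = MultipleAlignment([("a", "MKLV"), ("b", "MK-V"), ("c", "----")])
        dm = poisson_distance_matrix(msa, "pairwise-deletion")
        assert dm.p[0, 1] == 0.0
        assert ("a", "c") in dm.undefined or ("c", "a") in dm.undefined

    def test_saturated_pair_flagged(self):
        msa = MultipleAlignment([("a", "AAAA"), ("b", "DDDD")])
        dm = poisson_distance_matrix(msa)
        assert np.isinf(dm.d[0, 1]) and ("a", "b") in dm.undefined

    def test_distance_dominates_p(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        rows = [(f"s{i}", "".join(letters[rng.integers(0, 20, 60)]))
                for i in range(4)]
        dm = poisson_distance_matrix(MultipleAlignment(rows))
        finite = np.isfinite(dm.d)
        assert (dm.d[finite] >= dm.p[finite] - 1e-12).all()


# ---------------------------------------------------------------------------
# Neighbor joining


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        t = neighbor_joining(DistanceMatrix(["a", "b", "c"], D, D.copy()))
        pl = t.path_lengths()
        assert pl[("a", "b")] == pytest.approx(5)
        assert pl[("a", "c")] == pytest.approx(9)
        assert pl[("b", "c")] == pytest.approx(10)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_matrix_recovered_exactly(self, n):
        rng = np.random.default_rng(n)
        ids, D = random_additive_matrix(rng, n)
        t = neighbor_joining(DistanceMatrix(ids, D.copy(), D.copy()))
        pl = t.path_lengths()
        for i, j in itertools.combinations(range(n), 2):
            assert pl[(ids[i], ids[j])] == pytest.approx(D[i, j], abs=1e-9)

    def test_four_taxon_split_matches_four_point_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ids, D = random_additive_matrix(rng, 4)
            t = neighbor_joining(DistanceMatrix(ids, D.copy(), D.copy()))
            # oracle: minimal pairing sum identifies the true split
            pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
            sums = [D[a, b] + D[c, d] for (a, b), (c, d) in pairings]
            (a, b), _ = pairings[int(np.argmin(sums))]
            want = frozenset({ids[a], ids[b]})
            splits = set()
            for node in t.walk():
                if node is not t and not node.is_leaf():
                    side = frozenset(node.leaf_names())
                    splits.add(side)
                    splits.add(frozenset(ids) - side)
            assert want in splits

    def test_matches_independent_nj_implementation(self):
        """Bipartitions agree with scikit-bio's neighbor joining."""
        import skbio

        rng = np.random.default_rng(3)
        for trial in range(5):
            n = 6
            M = rng.uniform(1, 10, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            ids = [f"t{i}" for i in range(n)]
            ours = neighbor_joining(DistanceMatrix(ids, D.copy(), D.copy()))
            ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids))

            def splits(names_all, iter_sides):
                out = set()
                for side in iter_sides:
                    side = frozenset(side)
                    if 2 <= len(side) <= len(names_all) - 2:
                        ref_leaf = min(names_all)
                        out.add(side if ref_leaf not in side
                                else frozenset(names_all) - side)
                return out

            ours_splits = splits(ids, (n.leaf_names() for n in ours.walk()
                                       if n is not ours and not n.is_leaf()))
            ref_splits = splits(ids, ([t.name for t in n.tips()]
                                      for n in ref.non_tips()))
            assert ours_splits == ref_splits

    def test_negative_branches_clamped(self):
        D = np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], float)
        t = neighbor_joining(DistanceMatrix(["a", "b", "c"], D, D.copy()))
        assert all(n.length >= 0 for n in t.walk())

    def test_two_leaves_degenerate(self):
        D = np.array([[0, 2], [2, 0]], float)
        with pytest.warns(UserWarning):
            t = neighbor_joining(DistanceMatrix(["a", "b"], D, D.copy()))
        assert t.path_lengths()[("a", "b")] == pytest.approx(2)


# ---------------------------------------------------------------------------
# Bootstrap and terminal pairs


def _split_alignment(n_informative=30, n_constant=10):
    """4-taxon alignment in which every variable column supports (a1,a2|b1,b2)."""
    rows = {"a1": [], "a2": [], "b1": [], "b2": []}
    for _ in range(n_informative):
        rows["a1"].append("A"), rows["a2"].append("A")
        rows["b1"].append("D"), rows["b2"].append("D")
    for _ in range(n_constant):
        for r in rows:
            rows[r].append("G")
    return MultipleAlignment([(k, "".join(v)) for k, v in sorted(rows.items())])


class TestBootstrap:
    def test_unanimous_split_gets_full_support(self):
        tree = bootstrap_support(_split_alignment(),
                                 PhyloParams(bootstrap_reps=100, rng_seed=0))
        supports = [n.support for n in tree.walk() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_reproducible(self):
        msa = _split_alignment(20, 20)
        t1 = bootstrap_support(msa, PhyloParams(bootstrap_reps=50, rng_seed=7))
        t2 = bootstrap_support(msa, PhyloParams(bootstrap_reps=50, rng_seed=7))
        assert t1.newick() == t2.newick()

    def test_random_alignment_has_weak_support(self):
        """i.i.d. columns carry no phylogenetic signal: median support < 80.

        A 6-letter alphabet keeps pairwise p below saturation so Poisson
        distances stay finite in every replicate.
        """
        letters = np.array(list("ACDEFG"))
        supports = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = [(f"t{i}", "".join(letters[rng.integers(0, 6, 100)]))
                    for i in range(4)]
            tree = bootstrap_support(MultipleAlignment(rows),
                                     PhyloParams(bootstrap_reps=100, rng_seed=seed))
            supports += [n.support for n in tree.walk() if n.support is not None]
        assert np.median(supports) < 80

    def test_supports_invariant_under_relabeling(self):
        msa = _split_alignment(25, 15)
        relabeled = MultipleAlignment([(f"x_{rid}", seq) for rid, seq in msa.rows])
        p = PhyloParams(bootstrap_reps=100, rng_seed=3)
        s1 = sorted(n.support for n in bootstrap_support(msa, p).walk()
                    if n.support is not None)
        s2 = sorted(n.support for n in bootstrap_support(relabeled, p).walk()
                    if n.support is not None)
        assert s1 == s2


class TestTerminalPairs:
    def _tree(self):
        # ((a1,a2)95,(b1,c1)30,d1)
        n1 = TreeNode(children=[TreeNode("a1"), TreeNode("a2")], support=95.0)
        n2 = TreeNode(children=[TreeNode("b1"), TreeNode("c1")], support=30.0)
        return TreeNode(children=[n1, n2, TreeNode("d1")])

    SPECIES = {"a1": "A", "a2": "A", "b1": "B", "c1": "C", "d1": "D"}

    def test_supported_same_species_cherry_is_paralog(self):
        par, orth = extract_terminal_pairs(self._tree(), self.SPECIES, 50.0)
        assert par == [("a1", "a2", 95.0)]

    def test_low_support_cherry_not_emitted(self):
        par, orth = extract_terminal_pairs(self._tree(), self.SPECIES, 50.0)
        assert not orth  # the (b1, c1) cherry has support 30 < 50

    def test_cross_species_cherry_is_ortholog(self):
        n = TreeNode(children=[TreeNode("a1"), TreeNode("b1")], support=98.0)
        tree = TreeNode(children=[n, TreeNode("c1")])
        par, orth = extract_terminal_pairs(tree, self.SPECIES, 50.0)
        assert orth == [("a1", "b1", 98.0)] and not par

    def test_polytomy_emits_nothing(self):
        n = TreeNode(children=[TreeNode("a1"), TreeNode("a2"), TreeNode("b1")],
                     support=99.0)
        tree = TreeNode(children=[n, TreeNode("d1")])
        par, orth = extract_terminal_pairs(tree, self.SPECIES, 50.0)
        assert not par and not orth
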