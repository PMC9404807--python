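# Methods

This note documents the models and procedures implemented in `genefam`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that a
user extending the package should know about.

## Family curation

Candidate members are identified by a conserved-domain scan: the domain
is described by an amino-acid consensus (width ≥ 10) and scored against
each protein by an **ungapped** BLOSUM62 local alignment (best segment
pair). This is a deliberate simplification of profile-HMM search — the
package's focus is the downstream comparative analysis, and an ungapped
scan keeps the completeness statistic honest: the hit span cannot be
inflated by chaining spurious gapped blocks. The default score threshold
is 0.3 × the consensus self-score; a hit is *complete* when its span
covers ≥ 80% of the model width. Precomputed domain-hit tables
(TSV: protein_id, model_id, ali_start, ali_end, score, complete) can be
supplied in place of the scanner.

Three filters follow: (1) the longest-CDS transcript represents each
locus; (2) coding sequences < 150 bp are eliminated; (3) genes with an
incomplete domain or a truncated protein are discarded. "Truncated" is
operationalized as missing initial methionine, an internal stop, or an
incomplete domain hit. The filters commute: a gene is kept iff it passes
all three, and the curation report names the first failing rule per gene.

Members are named `<prefix><family><chromosome-number>.<rank>` with rank
assigned by ascending gene start per chromosome; single-member
chromosomes still receive ".1"; ties break lexicographically with a
warning.

Physicochemical properties: molecular weight is the sum of average
(not monoisotopic) residue masses plus one water; unknown residues (X)
count toward length with zero mass. The isoelectric point solves
net-charge(pH) = 0 by bisection on [0, 14] with a Bjellqvist-style pKa
table (N-term 7.5, C-term 3.55; D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98,
K 10.0, R 12.0), converging to |charge| < 10⁻⁴ within 60 iterations.
The table is data, swappable per call. Agreement with Biopython's
independent implementation is within ≈ 0.2 pH units (their N-terminal
pKa values are residue-specific) and ≈ 0.5 Da (mass-table rounding).

## Phylogeny

Pairwise global alignment uses affine gaps (open 10, extend 0.5,
BLOSUM62 for protein; +5/−4 for nucleotide). The multiple aligner is
progressive: a neighbor-joining guide tree on pairwise p-distances, then
profile–profile merges under the same affine scheme with **gap penalties
scaled by column occupancy**, so new gaps stack preferentially onto
columns that already contain gaps. On toy three-sequence instances the
result reaches ≥ 90% (usually 100%) of the exhaustively optimal
sum-of-pairs score; like all progressive methods it is a heuristic and
can be beaten on adversarial inputs.

Distances are Poisson-corrected amino-acid distances d = −ln(1 − p),
with p the proportion of differing sites after **complete deletion**
(every column with any gap removed; pairwise deletion is available).
Pairs with p = 1 or no usable columns are flagged undefined.

Trees come from Saitou–Nei neighbor joining with a deterministic
(smallest row-major index) tie-break; negative branch-length estimates
are clamped to zero. On additive matrices the induced tree metric equals
the input exactly. Branch support is a nonparametric bootstrap: columns
resampled with replacement, distances and tree rebuilt per replicate,
bipartition recurrence mapped as a percentage onto the *original*
topology (not a consensus tree). The default is 1000 replicates, seeded
and bit-reproducible. Paralog/ortholog pairs are cherries (two-leaf
sister clades) with support ≥ 50% by default; polytomies emit nothing.

## Ka/Ks and dating

The estimator is approximate Nei–Gojobori (1986). Per sense codon, each
position contributes one site split by the fraction of one-step changes
that are synonymous; changes creating stop codons are excluded from the
denominator (the `exclude` policy; `count-nonsyn` treats them as
nonsynonymous instead). Site counts average the two sequences.
Differences between codons at 2–3 positions are averaged uniformly over
all substitution orderings, skipping pathways through stop codons (if
none survive, all pathways are used with stop steps counted
nonsynonymous). The implementation matches an independent exhaustive
pathway-enumeration oracle on every sense-codon pair.

Proportions pS = Sd/S and pN = Nd/N receive the Jukes–Cantor correction
d = −¾ ln(1 − 4p/3); pS ≥ ¾ flags synonymous saturation (Ks and the
ratio undefined). Ka/Ks < 1 is purifying, > 1 positive, = 1 (tolerance
10⁻⁹) neutral; Ks = 0 with Ka > 0 reports an infinite ratio, classified
positive. Divergence time is T = Ks/(2λ) with λ = 6.1×10⁻⁹ synonymous
substitutions/site/year (soybean lineage rate), reported in Mya and
rounded to two decimals only at presentation.

The published soybean APX/CAT duplicated-pair table is reproduced at the
level the printed data allow: all 12 Mya values follow exactly from the
printed Ks values, and the selection labels follow from the printed
ratios. The underlying sequences are not printed, so the Ka/Ks cells
themselves cannot be regenerated; note also that one printed ratio
(0.69 for Ka = 0.04, Ks = 0.06) differs from the printed-value quotient
(0.67) by rounding — classification uses the printed ratio.

## Duplication and synteny

Pairwise identity is computed on a global alignment after trimming
terminal gap overhangs: matches / remaining columns. Duplicated pairs
require identity **strictly above** 90% (the boundary value 90.0 is
excluded); identity is computed on proteins by default (the family is
defined on proteins), with a CDS option. A member may appear in several
pairs. Classification: different chromosomes ⇒ segmental; same
chromosome with ≤ 5 genes strictly between the pair in the *full*
annotation ⇒ tandem, else segmental. The ≤ 5 resolution of the
overlapping textual convention ("five or fewer" tandem vs "five or
more" segmental) is a deliberate choice.

Synteny anchors are reciprocal-best protein matches (k-mer Jaccard
prefilter, global-alignment identity ≥ 40% — a looser threshold than the
duplication cutoff). Blocks are extracted greedily: the heaviest chain
of anchors strictly monotone in both gene orders (same or inverted
orientation) within a 25-gene rank gap, repeated until no chain reaches
the minimum block size (5 anchors); each anchor joins at most one block.

## Motifs and cis elements

Motif discovery is a ZOOPS (zero-or-one occurrence per sequence) EM over
proteins. For each width in the grid (default 6–50), EM is seeded from
every subsequence window of a reference sequence (screened with one EM
iteration; the best seed is run to convergence, Δlog-likelihood < 10⁻⁴
or 200 iterations). The winning width maximizes information content
(relative entropy to the 0-order background, pseudocount 0.25) minus a
**1 bit/column penalty**; the penalty absorbs the ≈ 0.5 bit/column of
finite-sample and alignment-selection bias a noise "motif" accumulates
with ~30 sequences, so random inputs yield short, low-content motifs
while genuinely conserved motifs keep their exact width. Occurrences are
masked before the next motif; motifs are ranked by information content.
Discovery is deterministic given the seed, and the top consensus is
invariant to input order on clearly planted data. The full MEME
objective (E-values, OOPS/ANR models) is not reproduced — motifs are
used descriptively here.

Cis elements are IUPAC consensus strings scanned on both strands of the
1000-bp promoter upstream of the **translation start** (first CDS base
in transcription order; promoters are clamped with a warning at contig
ends). Overlapping occurrences are all reported. The shipped catalog
(ABRE, ARE, as-1, MYB, MYC, STRE, LTR, WUN-motif, W-box, Box4,
GT1-motif, G-box, ERE, TATA-box, CAAT-box, CAT-box, O2-site) carries
literature-conventional consensus strings; it is configuration, not
ground truth, and fully overrideable via TSV. Counts from a different
catalog (e.g. a web service's) are not comparable.

## Expression and qPCR

Heatmap normalization is log₂(x+1) followed by genewise z-scoring
(sample SD; zero-variance rows become zero and are flagged); both steps
are independently switchable since upstream conventions vary. Row order
is average-linkage hierarchical clustering leaf order (SciPy). Stress
response calls use |log₂ fold change| ≥ 1 by default — a conventional
threshold, configurable. Relative qPCR expression: ΔCt = Ct_target −
Ct_reference per replicate; ΔΔCt = mean ΔCt(condition) − mean
ΔCt(control); fold = 2^(−ΔΔCt). Replicates aggregate on the ΔCt scale
(not as mean of folds); the fold SD is propagated as
fold · ln 2 · sd(ΔCt).

## Synthetic data: what it emulates, and what it does not

`simulate_family_genomes` builds genome A with one ancestral family gene
(a 50-residue domain consensus embedded in a 180-residue protein) from
which six base members descend at a deep synonymous divergence
(Ks = 1.2, ω = 0.2) — keeping members homologous over their full length,
which real gene families are and which complete-deletion distances
require — plus 60 background genes with random-composition proteins to
stress the scanner's specificity. The duplication plan (2 tandem with
≤ 3 intervening genes + 3 segmental on other chromosomes, Ks
0.03–0.05) places every planted pair above the 90% identity threshold
while base-gene pairs stay far below it. Genome B carries orthologs of
base and background genes at Ks = 0.03 in preserved order except one
planted 6-gene inversion. Optional curation decoys plant one 149-bp CDS,
one 40%-domain fragment and one internal-stop protein. Promoters are
1000 bp with planted concretized IUPAC elements at recorded positions;
genes get 1–4 introns (80–300 bp), random strand, and exact
GFF3/FASTA/protein/CDS consistency (round-trips are byte-faithful).

Codon evolution is an accept/reject scheme: proposals uniform over
positions and alternative bases, stops rejected, synonymous changes
accepted with probability 1 and nonsynonymous with probability ω;
proposals continue until accepted synonymous substitutions reach
S × target-Ks, so the realized divergence is calibrated in expectation
and multiple hits are recovered by the downstream Jukes–Cantor
correction (mean recovered Ks within a few percent of target at
Ks ≤ 0.5). There are **no indels, no recombination, no rate
heterogeneity, and intergenic/intron sequence is uniform random** — so
passing tests demonstrate correctness of the machinery on clean signals,
not performance on real genomes with fragmented annotations, repetitive
DNA or domain divergence beyond the scanner's reach.

Expression simulation gives each gene one boosted tissue
(× 8, lognormal noise σ = 0.2 on a baseline of 20) across the 14 atlas
tissue labels; qPCR Ct tables encode planned fold changes (2×, 4×, 2× at
4/8/12 h against a 0 h control, 3 replicates, σ = 0.15 cycles) with a
constant reference gene.

## Problem sizes and reproducibility

Defaults throughout are chosen so the full test suite and the
acceptance script each complete in minutes on one CPU: the synthetic
study uses 66–74 genes per genome and 11 + 6 family members; parameter
recovery uses 50 replicates of 1500-nt sequences per Ks level; the NG86
oracle sweep covers all 61² sense-codon pairs; bootstrap uses 1000
replicates on the family alignment. Every random draw flows from a
single integer seed (NumPy `default_rng`); pipeline TSV outputs are
byte-identical across reruns with the same seed.

## Known limitations

- The domain scanner is not a profile HMM; remote homologs with
  insertions inside the domain will score as incomplete.
- Progressive MSA and greedy block extraction are heuristics; no
  guarantee of global optimality.
- NG86 is the approximate counting method; no codon-frequency or
  transition/transversion correction (YN00/ML methods out of scope).
- Bootstrap supports are mapped onto the NJ topology, which is itself a
  point estimate.
- Real-genome gene counts from the published soybean study (11/10 APX,
  4/4 CAT, 18→11 and 22→10 filtering attrition, 20/16 orthologue pairs,
  58 promoter element types, tissue heatmaps) depend on external genome
  assemblies, RNA-seq deposits and third-party element catalogs and are
  therefore not reproducible from this repository; the test suite
  validates the machinery on synthetic ground truth and on the printed
  duplicated-pair table instead.
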