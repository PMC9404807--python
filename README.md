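# genefam

A toolkit for whole-genome characterization of plant multigene families —
the workflow used to describe families such as the soybean ascorbate
peroxidase (*APX*) and catalase (*CAT*) H₂O₂-scavenging genes in a pair of
related genomes (e.g. a cultivated species and its wild progenitor).

Given two genome bundles (genome FASTA + GFF3 annotation + protein/CDS
FASTA), `genefam` runs the full comparative analysis:

1. **Family curation** — candidate genes are found by a conserved-domain
   scan; per locus the longest transcript represents the gene; coding
   sequences shorter than 150 bp, incomplete domains and truncated proteins
   are discarded. Members are named `<Prefix><Family><chrom>.<rank>`
   (e.g. `GmaAPX11.4` = fourth *APX* gene on chromosome 11), and length,
   average molecular weight and isoelectric point are computed.
2. **Phylogeny** — progressive protein alignment, Poisson-corrected
   distances *d* = −ln(1 − *p*) after complete deletion of gapped columns,
   Saitou–Nei neighbor joining, and a column bootstrap for branch support.
   Supported two-leaf sister clades ("cherries") are reported as paralogous
   (same species) or orthologous (different species) gene pairs.
3. **Molecular evolution** — Nei–Gojobori (1986) counting of synonymous and
   nonsynonymous sites and differences with uniform pathway averaging,
   Jukes–Cantor correction, selection class from Ka/Ks (< 1 purifying,
   > 1 positive), and divergence dating by **T = Ks / 2λ** with
   λ = 6.1×10⁻⁹ synonymous substitutions · site⁻¹ · year⁻¹.
4. **Duplication & synteny** — pairs above 90% identity are duplicated
   genes; same-chromosome pairs with ≤ 5 intervening genes are tandem,
   all others segmental. Collinear blocks between the two genomes are
   chained from reciprocal-best homolog anchors (monotone in both gene
   orders, MCScan-style).
5. **Structure, motifs and promoters** — exon/intron structure from the
   annotation; conserved protein motifs by ZOOPS expectation-maximization
   (up to 10 motifs, widths 6–50); cis-regulatory elements (ABRE, ARE, MYC,
   MYB, STRE, …) scanned as IUPAC consensus patterns on both strands of
   1000-bp promoters upstream of the translation start.
6. **Expression** — log₂(x+1) + genewise z-score normalization with
   hierarchical row ordering for heatmaps, and relative qPCR expression by
   2^(−ΔΔCt) against a reference gene and control condition.

A first-class synthetic-data generator (`genefam.simulate`) emits two
related genomes with *known ground truth* — planted duplications at
controlled synonymous divergence, orthologs, promoter elements, tissue
effects and qPCR fold changes — so every stage is testable without
downloads.

## Worked example

Simulate a dataset and run every stage:

```bash
genefam demo --seed 1 --outdir out/
```

`out/duplication_kaks.tsv` then contains the duplicated-pair table for the
synthetic family (planted: 2 tandem + 3 segmental events at Ks ≈ 0.03–0.05):

```
pair                 Ka      Ks      Ka/Ks   Mya   duplicate_type  selection
GaaFAM1.1/GaaFAM3.3  0.0024  0.0437  0.0542  3.59  segmental       purifying
GaaFAM1.2/GaaFAM2.4  0.0121  0.0412  0.2942  3.38  segmental       purifying
GaaFAM1.3/GaaFAM1.4  0.0024  0.0333  0.0720  2.73  tandem          purifying
GaaFAM2.1/GaaFAM2.3  0.0120  0.0339  0.3542  2.78  tandem          purifying
GaaFAM2.2/GaaFAM3.1  0.0168  0.0526  0.3192  4.31  segmental       purifying
```

Reading the first row: the two segmental copies differ at 0.24
nonsynonymous and 4.4 synonymous substitutions per 100 sites; Ka/Ks ≈ 0.05
indicates strong purifying selection, and T = 0.0437/(2 · 6.1×10⁻⁹) ≈ 3.59
million years since duplication. All five planted events are recovered with
their correct tandem/segmental labels. `out/terminal_pairs.tsv` lists the
bootstrap-supported paralog/ortholog cherries of the joint tree,
`out/members_*.tsv` the named members with physicochemical properties, and
`out/synteny_blocks.tsv` the collinear blocks (including a planted
inversion on Chr3).

The same stages run from files via a YAML config
(see `examples/config.yaml`):

```bash
genefam simulate --seed 1 --outdir data/
genefam run-all --config examples/config.yaml --seed 1
```

As a library:

```python
from genefam.molevol import divergence_time
divergence_time(0.74)   # 60.66 Mya — the oldest CAT duplication in the
                        # published soybean table
```

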