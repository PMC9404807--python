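# Annotated default pipeline configuration.
#
# Paths below assume a dataset produced by:  genefam simulate --seed 1 --outdir data/
# Replace them with real genome bundles to analyze your own family.

family: FAM                      # family short name used in member names
# amino-acid consensus defining the family's conserved domain
domain_consensus: WLKGHFDRWMPEYCQNVAKTGWLSHFERYMCDPNQVIKAGWFHTEYLRMC

outdir: out                      # every report TSV / Newick file lands here
rng_seed: 1                      # seeds bootstrap and motif discovery
log_level: INFO

genomes:                         # exactly two bundles
  - label: genomeA
    species_prefix: Gaa          # three-letter code, e.g. Gma for G. max
    genome_fasta: data/genomeA_genome.fasta
    gff3: data/genomeA.gff3
    protein_fasta: data/genomeA_proteins.fasta
    cds_fasta: data/genomeA_cds.fasta
  - label: genomeB
    species_prefix: Gbb
    genome_fasta: data/genomeB_genome.fasta
    gff3: data/genomeB.gff3
    protein_fasta: data/genomeB_proteins.fasta
    cds_fasta: data/genomeB_cds.fasta

curation:
  min_cds_bp: 150                # CDS shorter than this are eliminated
  complete_fraction: 0.8         # domain hit span / model width for "complete"
  # domain_score_threshold: 120  # absolute; default 0.3 x model self-score

phylo:
  bootstrap_reps: 1000
  gap_policy: complete-deletion  # or pairwise-deletion
  support_threshold_for_pairs: 50

duplication:
  identity_threshold: 90         # strict >, percent
  max_intervening_genes_tandem: 5
  identity_level: protein        # or cds

molevol:
  lambda_rate: 6.1e-9            # synonymous substitutions / site / year
  pathway_stop_policy: exclude   # or count-nonsyn

max_motifs: 10
motif_width_range: [6, 50]
promoter_length: 1000            # bp upstream of the translation start
# cis_catalog_tsv: my_elements.tsv   # columns: element, iupac_pattern, class

synteny_min_block: 5
synteny_max_gap: 25

# optional expression inputs (produced by `genefam simulate` for the demo)
expression_tsv: data/expression.tsv
qpcr_tsv: data/qpcr.tsv
qpcr_control: 0h
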