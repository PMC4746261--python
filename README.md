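# regulonkit

Comparative-genomics reconstruction of carbohydrate-utilization
transcription-factor (TF) regulons across small cohorts of bacterial
genomes — the workflow used to map sugar-catabolism regulatory networks in
gut commensals such as bifidobacteria.

Sugar catabolic pathways in bacteria are typically controlled by local
repressors and activators from a handful of protein families (LacI, ROK,
DeoR, RpiR, SorC, GntR, AraC, BglG, TetR).  These regulators bind
palindromic operator sites upstream of their target operons, and because
both the regulator and its sites are conserved across related genomes,
regulons can be reconstructed from genome sequence alone.  `regulonkit`
implements that reconstruction as a tested, reusable library:

1. **Ortholog grouping** — within each TF family, a neighbor-joining tree
   on pairwise protein-identity distances is cut into clades that also
   share genomic context (±5-gene neighborhood) and, when available,
   binding-site motifs.
2. **Palindromic motif discovery** — expectation-maximization over a
   one-occurrence-per-sequence model with the position weight matrix (PWM)
   constrained to reverse-complement symmetry, seeded from over-represented
   spaced half-site pairs in the upstream regions of the operons
   surrounding each TF gene.
3. **PWM scanning** — upstream windows from −350 to +50 nt around each
   operon's translation start are scored with additive log-odds weights
   `w(b,i) = log2(((n(b,i) + κ·q(b)) / (N + κ)) / q(b))` against the genome
   background `q`; the site threshold is set 10% below the weakest
   training site, and sites within a further 10% are kept as weak
   candidates.
4. **Weak-site rescue and consistency check** — a weak site is rescued
   only if a strong site sits at a similar position upstream of an
   ortholog in another genome and no stronger candidate competes in the
   same region; regulon members are accepted only when candidate sites
   recur upstream of orthologs in ≥2 genomes.
5. **Operon extension and reporting** — co-directional genes with
   intergenic gaps ≤200 nt are chained into operons, accepted promoter
   genes are extended to their whole operon, and census / correlation
   statistics are reported.

A first-class synthetic-cohort generator plants orthologous TFs,
palindromic operators and target operons into random high-GC genomes and
records a machine-readable truth, so every stage is testable without any
downloads.  The package also ships the published distribution table of 308
carbohydrate-catabolism TFs across ten *Bifidobacterium* genomes as a
fixture for the census and correlation statistics.

## Worked example

```python
from regulonkit import evaluation, reconstruct
from regulonkit.synthetic_cohort import CohortConfig, generate_cohort

config = CohortConfig(n_genomes=4, genome_length=150_000,
                      n_tf_groups=2, decoy_fraction=0.0, seed=7)
genomes, tf_table, truth = generate_cohort(config)
recon = reconstruct(genomes, tf_table, truth.protein_seqs, truth.ortholog_map)
```

Running `python examples/build_regulons.py` (the same computation) prints:

```
orthology ARI: 1.000
OG0001: width 18, 14.0 bits, threshold 10.68, 22 accepted sites
OG0002: width 18, 15.6 bits, threshold 12.94, 20 accepted sites
site recall 1.000, precision 0.952
regulon membership F1 0.989
cohort totals: {'tfs': 8, 'tfbs': 42, 'operons': 42, 'genes': 94}
```

Both planted regulators are recovered as single orthologous groups (ARI 1.0
against the planted partition), their 18-nt palindromic operators are
re-discovered (~14–16 bits of information), and the accepted sites recover
all 40 planted operators with two extra weak calls; after extension to whole
operons, 94 member genes are predicted against 92 planted ones (F1 0.99).

Other examples: `generate_cohort.py` (what the generator plants),
`discover_motif.py` (text sequence logo of a recovered motif),
`scan_sites.py` (threshold calibration and promoter scanning),
`census_report.py` (reference census and the TF-vs-CUG correlation).

## File formats

Genomes are exchanged as FASTA plus either GFF3 or a 5-column TSV feature
table (`genome_id`, `gene_id`, `start` 1-based, `end` inclusive, `strand`,
optional `product`).  Motifs are read and written in MEME minimal format;
sites export as BED6 or a richer TSV; regulons export as TSV with one row
per accepted operon.

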