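# Methods

This note documents the models and procedures implemented in `regulonkit`,
the parameters that matter, and the design choices made where the
underlying workflow left the design open.

## The reconstruction model

A TF regulon is the set of genes and operons controlled by a common
transcription factor.  The reconstruction rests on three comparative
assumptions that hold well for sugar-catabolism regulators in closely
related bacterial genomes:

- **Co-localization.** A sugar-specific TF gene usually sits on the
  chromosome next to the operons it regulates, so the upstream regions of
  the operons around a TF gene are an enriched training set for its
  binding motif.
- **Palindromic operators.** These TFs bind as homodimers; their operator
  consensus equals its own reverse complement, with the specificity
  concentrated in two half-site contact regions around a degenerate
  spacer.
- **Cross-genome conservation.** A real operator recurs upstream of
  orthologous genes in several genomes; chance PWM hits do not.  This is
  the error-control device of the whole method: thresholds can stay
  permissive (to keep recall) because the cross-genome consistency check
  removes isolated false calls.

## Pipeline stages and parameters

### Upstream windows

Windows run from −350 to +50 nt relative to the presumed translation
start, are clipped at replicon ends, reverse-complemented for minus-strand
genes, and are *not* truncated at upstream neighbors (the scan window is
fixed; no masking of coding sequence).  Coordinates are 0-based half-open
internally; GFF3 and the TSV dialect convert at the boundary.

### Motif discovery (`motif_inference.discover_palindromic_motif`)

For each width in 14–22 nt:

- **Seeding.** Candidate words come from over-represented spaced
  half-site pairs: a 4-mer whose reverse complement recurs `width − 4`
  positions downstream in the same window.  Half-sites are ranked by the
  number of training regions containing such a pair.  If no spaced pair
  exists, the most palindromic full-width words (fewest self-reverse-
  complement mismatches, then best cross-region Hamming support) seed
  instead.
- **Refinement.** One-occurrence-per-sequence EM, at most 30 iterations,
  with the count matrix averaged with its reverse complement after every
  M-step (odd widths leave the central column unconstrained, so discovered
  matrices are reverse-complement symmetric by construction).
- **Training set.** Only confident occurrences: a region contributes its
  best site when it scores positively and at least 0.75× the median
  per-region best.  This keeps non-target promoters (e.g. a
  non-autoregulated TF's own window) from dragging the score calibration
  down; it mirrors the curated training sets the manual workflow uses.
- **Trimming and selection.** Flanking column pairs with less than 0.3
  bits are trimmed; the candidate maximizing total information content ×
  fraction of regions hit wins, with ties going to the wider motif.
- **Acceptance.** A motif is reported only if it carries ≥8 bits, hits
  ≥60% of the training regions, and is significant against an empirical
  null: the same PWM scanned over 150 background-sampled regions must not
  reach, at its 95th percentile, within 2 bits of the median training-hit
  score.  The null check is what rejects "motifs" hallucinated from
  regulator groups that control nothing (decoys); its random regions are
  the only seeded randomness in discovery.

### Threshold and weak sites (`pwm_scanner`)

Scores are additive base-2 log-odds against the genome background with
pseudocount 0.5 (the smoothing keeps weights finite; the score scale must
be positive for the threshold rule to make sense, and non-positive
training scores are rejected).  The site threshold is 0.9× the lowest
training-site score.  Scanning reports all non-overlapping local maxima at
≥0.9× threshold on both strands, collapsing overlaps to the best-scoring
hit (score ties at 1e-9 resolution resolve leftmost, then + strand — this
makes the scan bit-reproducible regardless of summation order).  Weak
candidates (between 0.9× and 1× threshold) survive only when a strong site
sits within 30 nt of the same position relative to the translation start
upstream of an ortholog in another genome, and no stronger candidate
occupies the same region.  The 30-nt tolerance is a package default; the
underlying workflow says only "similar positions".

### Consistency check and regulons (`regulon_builder`)

The pipeline keeps the best candidate per promoter window (one operator
per promoter), then accepts an orthologous gene set iff filtered
candidates precede it in at least `min_support = 2` of the genomes
carrying the TF ("several related genomes" is not quantified upstream;
2 is the package default and is configurable).  Accepted promoter genes
extend to their whole operon.  Operons chain co-directional genes with
intergenic distance (previous end to next start) ≤200 nt; an optional
conservation mode keeps a link only when the same ortholog-family
adjacency occurs in ≥2 genomes.  Only promoter (first-gene) windows are
scanned for membership; sites inside operons are not used to nominate
members, since regulation is anchored at the operon promoter.

### Ortholog grouping (`tf_catalog`)

Within each family, pairwise identities come from global alignments
(BLOSUM62, gap open −11, extend −1; identity = identical columns /
alignment length), a neighbor-joining tree is built from `1 − identity`
distances and midpoint-rooted, and the tree is cut top-down: the largest
clade wins whose members have mean pairwise identity ≥0.5 with no pair
below 0.3 (the floor keeps a single diverged protein from riding into a
cohesive clade on the average), whose context fingerprints (±5-gene
neighborhood labels) reach Jaccard ≥0.3 for a majority of pairs, and —
when motifs are supplied — whose motif similarity reaches ≥0.75 for a
majority of pairs.  All thresholds are calibration knobs, not derived
quantities.  Motif similarity is the best mean column-wise Pearson
correlation of weight columns over ungapped offsets (overlap within 4
columns of full) in both orientations, clipped to [0, 1].

## The synthetic cohort generator

`synthetic_cohort.generate_cohort` emulates the features the method
exploits:

- i.i.d. background sequence at 60% GC (high-GC gut Actinobacteria);
  1 Mb genomes, 6 genomes, 4 TF groups by default;
- operons instantiated from cohort-level templates, so gene content,
  order and ortholog labels are conserved across genomes (the synteny the
  context fingerprint and operon-conservation checks rely on);
  intra-operon gaps 20–150 nt, inter-operon gaps 620–820 nt (wide enough
  that one operon's scan window never reaches a divergent neighbor's
  operator, keeping site→promoter attribution unambiguous);
- each TF group's gene sits amid its `sites_per_regulon` target operons,
  as sugar catabolic loci do;
- TF proteins evolve from a per-group ancestor by 6% substitutions per
  genome (within-group identity ≈0.85–0.9, between-group ≈ random);
- operators are planted at a conserved position −200..−50 nt upstream of
  each target's translation start with ±10 nt per-genome jitter —
  real operator positions are conserved, and this is what makes the
  positional weak-site rescue rule exercisable;
- randomness is split into named streams (sequence, layout, motifs,
  sites, proteins, decoys) spawned from one seed, so enabling decoy sites
  never changes the genomes.

**Site model.**  The planted operator consensus is self-reverse-
complementary, with `motif_ic` realized as a conserved half-site core:
the even number of contact columns whose near-perfect conservation
carries the target information content (16 bits → 2×4 columns at ~2
bits each), with the spacer columns drawn from background per site and
per-base substitutions applied at `site_mutation_rate` (derived from the
IC target when unset).  Concentrating the information in near-perfect
contacts rather than spreading moderate degeneracy over all columns is
how real homodimer operators look, and it is the regime in which the
"10% below the weakest training site" threshold rule is well-behaved:
with the same total information spread uniformly (≈22% substitution per
column at 16 bits/18 nt), the weakest of ~30 training sites scores near
background and the min-anchored threshold collapses.  The planted PWM
records this column model; `consensus` strings mark spacer columns with
`N`, and truth comparisons treat `N` as matching anything.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: codon structure and realistic coding sequence,
phylogenetic correlation between genomes (each genome's background is
independent), gene gain/loss within regulons, tandem or overlapping
operators, horizontal transfer, and regulator families whose members bind
non-palindromic or bipartite sites.  Real upstream regions also contain
promoters, RNA structures and other motifs that raise the background
against which discovery must discriminate.

## Problem sizes and reproducibility

The test suite and the acceptance script use: the packaged ten-genome
reference table for census/correlation; 1000 random 120-nt regions and
500 random gene layouts for oracle-equivalence of the scanner and operon
caller; a benchmark cohort of six 1-Mb genomes (4 TF groups, one decoy,
width 18, 16 bits, 5 sites per regulon) for parameter recovery; and six
200-kb genomes for the decoy-site experiment and the bitwise determinism
check.  All randomness flows from explicit integer seeds; rerunning any
stage with the same seed reproduces its outputs byte for byte.

## Known limitations

- Motif discovery assumes one occurrence per training region and
  ungapped, fixed-width palindromes; bipartite or variable-spacer motifs
  are out of scope.
- The significance null models background as i.i.d.; strongly repetitive
  upstream regions could still yield spurious motifs.
- Ortholog grouping uses protein identity, not a proper evolutionary
  model, and reports no branch support; it is adequate for clade
  detection at desk scale, not for phylogenetics.
- `consistency_check` treats genomes as exchangeable; it does not weight
  support by phylogenetic distance.
- Paralogs within a genome are allowed in a group but the pipeline scans
  per group, not per paralog, so paralog-specific sub-regulons are not
  separated.
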