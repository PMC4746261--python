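"""Genome and gene-feature I/O with strand-aware coordinate arithmetic.

Coordinates are 0-based half-open internally.  GFF3 and the 5-column TSV
feature dialect (genome_id, gene_id, start 1-based, end inclusive, strand)
are converted on the way in and out.  The translation start of a gene is its
``start`` on the + strand and its ``end`` on the - strand; upstream windows
are anchored there and read left-to-right toward the start codon regardless
of strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default scanning window relative to the translation start, in nt
DEFAULT_WINDOW = (-350, 50)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}.

    Raises ``ValueError`` on any other character.  Involution:
    ``reverse_complement(reverse_complement(s)) == s``.
    """
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A gene feature on a replicon (0-based half-open interval)."""

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    locus_tag: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def translation_start(self) -> int:
        """Genomic coordinate of the presumed translation start."""
        return self.start if self.strand == "+" else self.end


@dataclass
class Genome:
    """A replicon sequence with its sorted gene features and base background."""

    genome_id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)
    background: np.ndarray | None = None

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        for g in self.genes:
            if g.end > len(self.sequence) or g.start < 0:
                raise ValueError(
                    f"gene {g.gene_id} [{g.start}, {g.end}) outside replicon "
                    f"{self.genome_id} of length {len(self.sequence)}"
                )
        if self.background is None:
            self.background = compute_background(self.sequence)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or np.any(self.background < 0):
            raise ValueError("background must be 4 nonnegative frequencies")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        self._gene_index = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r} in genome {self.genome_id}")


def compute_background(sequence: str) -> np.ndarray:
    """Per-base frequencies over A,C,G,T; N bases are excluded from the tally."""
    counts = np.array([sequence.count(b) for b in BASES], dtype=float)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


@dataclass(frozen=True)
class UpstreamRegion:
    """An upstream scanning window, oriented so that left-to-right reads
    toward the translation start.

    ``offset_of_start`` is the index of the translation start within the
    window (+350 for a full, unclipped default window).  ``genomic_start`` /
    ``genomic_end`` give the window's footprint on the forward strand of the
    replicon, and ``strand`` the strand of the anchoring gene, so hit
    coordinates can be mapped back to absolute positions.
    """

    gene_id: str
    genome_id: str
    sequence: str
    offset_of_start: int
    genomic_start: int = 0
    genomic_end: int = 0
    strand: str = "+"

    def __len__(self) -> int:
        return len(self.sequence)

    def absolute_position(self, offset: int, width: int) -> int:
        """Forward-strand coordinate of the leftmost base of a width-``width``
        word starting at ``offset`` in this region."""
        if self.strand == "+":
            return self.genomic_start + offset
        return self.genomic_end - offset - width


def upstream_region(
    genome: Genome, gene_id: str, window: tuple[int, int] = DEFAULT_WINDOW
) -> UpstreamRegion:
    """Extract the window ``(window[0], window[1])`` relative to a gene's
    translation start, clipped to the replicon and reverse-complemented for
    minus-strand genes."""
    gene = genome.gene(gene_id)
    lo, hi = window
    if gene.strand == "+":
        s = gene.translation_start
        a, b = max(0, s + lo), min(len(genome), s + hi)
        seq = genome.sequence[a:b]
        offset_of_start = s - a
    else:
        e = gene.translation_start
        a, b = max(0, e - hi), min(len(genome), e - lo)
        seq = reverse_complement(genome.sequence[a:b])
        offset_of_start = b - e
    return UpstreamRegion(
        gene_id=gene_id,
        genome_id=genome.genome_id,
        sequence=seq,
        offset_of_start=offset_of_start,
        genomic_start=a,
        genomic_end=b,
        strand=gene.strand,
    )


# ---------------------------------------------------------------------------
# feature tables: 5-column TSV dialect and GFF3


def _read_features_tsv(path: str) -> dict[str, list[Gene]]:
    per_genome: dict[str, list[Gene]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "genome_id":  # header
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{i + 1}: expected >=5 tab-separated columns")
            genome_id, gene_id, start, end, strand = fields[:5]
            product = fields[5] if len(fields) > 5 else ""
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{i + 1}: unknown strand {strand!r}")
            gene = Gene(
                gene_id=gene_id,
                start=int(start) - 1,  # 1-based inclusive -> 0-based half-open
                end=int(end),
                strand=strand,
                product=product,
                locus_tag=gene_id,
            )
            per_genome.setdefault(genome_id, []).append(gene)
    return per_genome


def _read_features_gff3(path: str) -> dict[str, list[Gene]]:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    per_genome: dict[str, list[Gene]] = {}
    for feat in db.all_features(featuretype="gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        locus = feat.attributes.get("locus_tag", [gene_id])[0]
        if feat.strand not in ("+", "-"):
            raise ValueError(f"feature {gene_id}: unknown strand {feat.strand!r}")
        per_genome.setdefault(feat.seqid, []).append(
            Gene(gene_id, feat.start - 1, feat.end, feat.strand, product, locus)
        )
    return per_genome


def read_genome(fasta_path: str, features_path: str) -> list[Genome]:
    """Read replicon sequence(s) plus a feature table into Genome objects.

    The features file may be GFF3 (``.gff``/``.gff3``) or the 5-column TSV
    dialect.  Every FASTA record yields one Genome; features referencing an
    unknown sequence id, or lying outside their replicon, are rejected.
    """
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(fasta_path)
    if not os.path.exists(features_path):
        raise FileNotFoundError(features_path)
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(fasta_path, "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    if features_path.endswith((".gff", ".gff3")):
        per_genome = _read_features_gff3(features_path)
    else:
        per_genome = _read_features_tsv(features_path)
    unknown = set(per_genome) - set(records)
    if unknown:
        raise ValueError(f"features reference unknown sequence ids: {sorted(unknown)}")
    genomes = []
    for genome_id, seq in records.items():
        genomes.append(Genome(genome_id, seq, per_genome.get(genome_id, [])))
    return genomes


def write_genome(genomes: list[Genome], fasta_path: str, features_path: str) -> None:
    """Write replicons as FASTA and features as TSV or GFF3 (by extension)."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.genome_id, description="") for g in genomes
    ]
    SeqIO.write(records, fasta_path, "fasta")
    if features_path.endswith((".gff", ".gff3")):
        with open(features_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genomes:
                for gene in g.genes:
                    attrs = f"ID={gene.gene_id};locus_tag={gene.locus_tag or gene.gene_id}"
                    if gene.product:
                        attrs += f";product={gene.product}"
                    fh.write(
                        f"{g.genome_id}\tregulonkit\tgene\t{gene.start + 1}\t"
                        f"{gene.end}\t.\t{gene.strand}\t.\t{attrs}\n"
                    )
    else:
        with open(features_path, "w") as fh:
            fh.write("genome_id\tgene_id\tstart\tend\tstrand\tproduct\n")
            for g in genomes:
                for gene in g.genes:
                    fh.write(
                        f"{g.genome_id}\t{gene.gene_id}\t{gene.start + 1}\t"
                        f"{gene.end}\t{gene.strand}\t{gene.product}\n"
                    )


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and N (or anything else) as 4."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out
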