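"""TF inventory, ortholog grouping and family census.

Orthologous groups of regulators are delineated within each TF family by
three joint criteria: the candidate set must form a clade of a
neighbor-joining tree built from pairwise protein-identity distances, share
genomic context (Jaccard similarity of the +-5-gene neighborhood labels),
and — when motifs are available — have highly similar binding-site motifs.
Clades failing any criterion are split; leftover regulators become
singletons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .motif_inference import PWM, compare_motifs

FAMILIES = ("LacI", "ROK", "DeoR", "RpiR", "SorC", "GntR", "AraC", "BglG", "TetR")


@dataclass(frozen=True)
class TFRecord:
    """One transcription factor gene with its family and genomic context."""

    genome_id: str
    gene_id: str
    family: str
    context_fingerprint: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown TF family {self.family!r}; expected one of {FAMILIES}"
            )


@dataclass
class OrthoGroup:
    """A group of orthologous TFs across genomes (paralogs allowed)."""

    group_id: str
    members: list[TFRecord]
    motif: PWM | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("OrthoGroup must be nonempty")

    @property
    def family(self) -> str:
        return self.members[0].family

    @property
    def singleton(self) -> bool:
        return len(self.members) == 1

    @property
    def genomes(self) -> list[str]:
        return sorted({m.genome_id for m in self.members})


def context_fingerprint(genome, gene_id: str, window: int = 5) -> frozenset[str]:
    """Labels (products) of the +-``window`` neighboring genes of a gene."""
    idx = next(
        i for i, g in enumerate(genome.genes) if g.gene_id == gene_id
    )
    lo, hi = max(0, idx - window), min(len(genome.genes), idx + window + 1)
    labels = {
        g.product
        for g in genome.genes[lo:hi]
        if g.gene_id != gene_id and g.product
    }
    return frozenset(labels)


def tf_records(
    genomes: list, annotation: pd.DataFrame, window: int = 5
) -> list[TFRecord]:
    """Build TFRecords from genomes plus an annotation table with columns
    genome_id, gene_id, family."""
    by_id = {g.genome_id: g for g in genomes}
    records = []
    for row in annotation.itertuples(index=False):
        genome = by_id[row.genome_id]
        records.append(
            TFRecord(
                genome_id=row.genome_id,
                gene_id=row.gene_id,
                family=row.family,
                context_fingerprint=context_fingerprint(genome, row.gene_id, window),
            )
        )
    return records


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner=None) -> float:
    """Fraction of identical columns in a global alignment with affine gaps."""
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _clade_ok(
    leaves: list[int],
    tfs: list[TFRecord],
    identity: np.ndarray,
    motifs,
    identity_threshold: float,
    context_threshold: float,
    motif_threshold: float,
) -> bool:
    pairs = list(itertools.combinations(leaves, 2))
    ids = [identity[i, j] for i, j in pairs]
    # a clade must be cohesive on average and contain no clear outlier
    if float(np.mean(ids)) < identity_threshold or min(ids) < 0.3:
        return False
    ctx_ok = sum(
        1
        for i, j in pairs
        if _jaccard(tfs[i].context_fingerprint, tfs[j].context_fingerprint)
        >= context_threshold
    )
    if ctx_ok <= len(pairs) / 2:
        return False
    if motifs is not None:
        motif_pairs = [
            (i, j)
            for i, j in pairs
            if motifs.get(tfs[i].gene_id) is not None
            and motifs.get(tfs[j].gene_id) is not None
        ]
        if motif_pairs:
            sim_ok = sum(
                1
                for i, j in motif_pairs
                if compare_motifs(
                    motifs[tfs[i].gene_id], motifs[tfs[j].gene_id]
                )
                >= motif_threshold
            )
            if sim_ok <= len(motif_pairs) / 2:
                return False
    return True


def group_orthologs(
    tfs: list[TFRecord],
    protein_seqs: dict[str, str],
    motifs: dict[str, PWM] | None = None,
    identity_threshold: float = 0.5,
    context_threshold: float = 0.3,
    motif_threshold: float = 0.75,
) -> list[OrthoGroup]:
    """Partition TFs into orthologous groups, within family only.

    A neighbor-joining tree is built per family from pairwise-identity
    distances; the tree is cut top-down, accepting the largest clades whose
    members satisfy the identity / context / motif criteria.  Ties in the
    distance matrix are broken by lexicographic gene id.  Every TF ends up
    in exactly one group; unaccepted leaves become singletons.
    """
    for tf in tfs:
        if tf.gene_id not in protein_seqs:
            raise ValueError(f"missing protein sequence for TF {tf.gene_id}")
    aligner = _make_aligner()
    groups: list[OrthoGroup] = []
    counter = itertools.count(1)

    def new_group(members: list[TFRecord]) -> None:
        groups.append(OrthoGroup(f"OG{next(counter):04d}", members))

    for family in FAMILIES:
        fam = sorted(
            (t for t in tfs if t.family == family),
            key=lambda t: (t.genome_id, t.gene_id),
        )
        if not fam:
            continue
        if len(fam) == 1:
            new_group(fam)
            continue
        n = len(fam)
        identity = np.eye(n)
        for i, j in itertools.combinations(range(n), 2):
            ident = pairwise_identity(
                protein_seqs[fam[i].gene_id], protein_seqs[fam[j].gene_id], aligner
            )
            identity[i, j] = identity[j, i] = ident
        args = (fam, identity, motifs)
        thresholds = (identity_threshold, context_threshold, motif_threshold)
        if n == 2:
            if _clade_ok([0, 1], *args, *thresholds):
                new_group(fam)
            else:
                new_group([fam[0]])
                new_group([fam[1]])
            continue
        from skbio import DistanceMatrix
        from skbio.tree import nj

        ids = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(1.0 - identity, ids)
        tree = nj(dm)
        try:
            tree = tree.root_at_midpoint()
        except Exception:
            pass
        assigned: set[int] = set()

        def visit(node) -> None:
            leaves = sorted(
                int(tip.name[1:]) for tip in node.tips(include_self=True)
            )
            if any(i in assigned for i in leaves):
                for child in node.children:
                    visit(child)
                return
            if len(leaves) >= 2 and _clade_ok(leaves, *args, *thresholds):
                new_group([fam[i] for i in leaves])
                assigned.update(leaves)
                return
            for child in node.children:
                visit(child)

        visit(tree)
        for i in range(n):
            if i not in assigned:
                new_group([fam[i]])
    return groups


# ---------------------------------------------------------------------------
# family census


@dataclass
class Census:
    """Per-genome, per-family TF counts with totals and family fractions."""

    table: pd.DataFrame  # genomes x families, plus a Total column
    grand_total: int
    family_totals: pd.Series
    family_fractions: pd.Series  # raw fractions of the grand total
    family_percent: pd.Series  # rounded to nearest integer percent
    min_genome: tuple[str, int]
    max_genome: tuple[str, int]


def census(tfs: list[TFRecord]) -> Census:
    """Exact per-genome per-family tallies of a TF inventory."""
    if tfs:
        df = pd.DataFrame(
            [(t.genome_id, t.family) for t in tfs], columns=["genome_id", "family"]
        )
        table = (
            df.groupby(["genome_id", "family"]).size().unstack(fill_value=0)
        )
    else:
        table = pd.DataFrame(dtype=int)
    return census_from_counts(table)


def census_from_counts(table: pd.DataFrame) -> Census:
    """Census statistics from an existing per-genome x per-family count
    table (e.g. a published distribution table)."""
    table = table.copy()
    if "Total" in table.columns:
        table = table.drop(columns=["Total"])
    totals = table.sum(axis=1).astype(int) if len(table) else pd.Series(dtype=int)
    family_totals = table.sum(axis=0).astype(int) if len(table.columns) else pd.Series(dtype=int)
    grand = int(family_totals.sum())
    fractions = family_totals / grand if grand else family_totals.astype(float)
    percent = (
        (fractions * 100).round().astype(int) if grand else fractions.astype(int)
    )
    out = table.copy()
    out["Total"] = totals
    if len(totals):
        min_genome = (str(totals.idxmin()), int(totals.min()))
        max_genome = (str(totals.idxmax()), int(totals.max()))
    else:
        min_genome = ("", 0)
        max_genome = ("", 0)
    return Census(
        table=out,
        grand_total=grand,
        family_totals=family_totals,
        family_fractions=fractions,
        family_percent=percent,
        min_genome=min_genome,
        max_genome=max_genome,
    )


def write_census_tsv(c: Census, path: str) -> None:
    c.table.to_csv(path, sep="\t")
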