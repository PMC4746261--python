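"""Operon calling, cross-genome consistency filtering and regulon assembly.

Genes are chained into an operon when they are co-directional with
intergenic distances (end of the upstream gene to start of the downstream
gene) not exceeding 200 nt; when cohort context is available, a chain link
is additionally required to recur — as an ortholog-family adjacency — in at
least two genomes.  Candidate regulon members are accepted only when
candidate binding sites precede orthologous genes in several genomes, and
accepted promoter-proximal genes are extended to their whole operon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Genome
from .motif_inference import PWM
from .pwm_scanner import Site
from .tf_catalog import OrthoGroup


@dataclass(frozen=True)
class Operon:
    """Co-directional run of adjacent genes sharing a promoter."""

    genome_id: str
    gene_ids: tuple[str, ...]  # transcription order
    strand: str

    @property
    def first_gene(self) -> str:
        """Promoter-proximal (5'-most in transcription direction) member."""
        return self.gene_ids[0]

    @property
    def operon_id(self) -> str:
        return f"{self.genome_id}:{self.first_gene}"


class CohortContext:
    """Ortholog-family adjacency counts across a cohort, for the operon
    conservation check."""

    def __init__(self, min_genomes: int = 2):
        self.min_genomes = min_genomes
        self._support: dict[tuple[str, str], set[str]] = {}

    @classmethod
    def build(
        cls,
        genomes: list[Genome],
        ortholog_map: dict[str, str],
        max_gap: int = 200,
        min_genomes: int = 2,
    ) -> "CohortContext":
        ctx = cls(min_genomes)
        for genome in genomes:
            genes = genome.genes
            for a, b in zip(genes, genes[1:]):
                if a.strand != b.strand or b.start - a.end > max_gap:
                    continue
                la = ortholog_map.get(a.gene_id, a.gene_id)
                lb = ortholog_map.get(b.gene_id, b.gene_id)
                key = (la, lb) if la <= lb else (lb, la)
                ctx._support.setdefault(key, set()).add(genome.genome_id)
        return ctx

    def conserved(self, label_a: str, label_b: str) -> bool:
        key = (label_a, label_b) if label_a <= label_b else (label_b, label_a)
        return len(self._support.get(key, ())) >= self.min_genomes

    def labels_for(self, ortholog_map: dict[str, str]):
        return ortholog_map


def call_operons(
    genome: Genome,
    max_gap: int = 200,
    conservation: CohortContext | None = None,
    ortholog_map: dict[str, str] | None = None,
) -> list[Operon]:
    """Greedy left-to-right chaining of co-directional genes.

    A link joins two adjacent genes when they share a strand and the
    intergenic distance is at most ``max_gap``.  With ``conservation``
    supplied, the link is kept only if the same ortholog-family adjacency
    occurs in at least ``conservation.min_genomes`` genomes.  The output is
    a partition: every gene belongs to exactly one operon.
    """
    operons: list[Operon] = []
    chain: list = []

    def flush():
        if not chain:
            return
        strand = chain[0].strand
        ordered = [g.gene_id for g in chain]
        if strand == "-":
            ordered = list(reversed(ordered))
        operons.append(Operon(genome.genome_id, tuple(ordered), strand))

    for gene in genome.genes:
        if chain:
            prev = chain[-1]
            linked = (
                gene.strand == prev.strand
                and gene.start - prev.end <= max_gap
            )
            if linked and conservation is not None:
                omap = ortholog_map or {}
                linked = conservation.conserved(
                    omap.get(prev.gene_id, prev.gene_id),
                    omap.get(gene.gene_id, gene.gene_id),
                )
            if not linked:
                flush()
                chain = []
        chain.append(gene)
    flush()
    return operons


def consistency_check(
    candidate_members: dict[str, list[tuple[str, Site]]],
    ortholog_map: dict[str, str],
    min_support: int = 2,
) -> dict[str, list[tuple[str, Site]]]:
    """Cross-genome filter on candidate regulon members.

    ``candidate_members`` maps genome -> (gene, best site) candidates in
    the genomes that carry the TF.  An orthologous gene set is accepted iff
    candidate sites precede it in at least ``min_support`` of those
    genomes; with ``min_support=1`` the filter is the identity.
    """
    genomes_with: dict[str, set[str]] = {}
    for genome_id, entries in candidate_members.items():
        for gene_id, _ in entries:
            label = ortholog_map.get(gene_id, gene_id)
            genomes_with.setdefault(label, set()).add(genome_id)
    accepted: dict[str, list[tuple[str, Site]]] = {}
    for genome_id in sorted(candidate_members):
        kept = [
            (gene_id, site)
            for gene_id, site in candidate_members[genome_id]
            if len(genomes_with[ortholog_map.get(gene_id, gene_id)])
            >= min_support
        ]
        if kept:
            accepted[genome_id] = kept
    return accepted


@dataclass
class RegulonMember:
    operon: Operon
    sites: list[Site]


@dataclass
class Regulon:
    """A TF (group) with its accepted member operons and supporting sites."""

    group: OrthoGroup
    pwm: PWM | None
    members: dict[str, list[RegulonMember]] = field(default_factory=dict)

    @property
    def n_tfs(self) -> int:
        return len(self.group.members)

    @property
    def n_sites(self) -> int:
        return sum(len(m.sites) for ms in self.members.values() for m in ms)

    @property
    def n_operons(self) -> int:
        return sum(len(ms) for ms in self.members.values())

    @property
    def n_genes(self) -> int:
        return sum(
            len(m.operon.gene_ids) for ms in self.members.values() for m in ms
        )

    def member_genes(self) -> set[tuple[str, str]]:
        return {
            (genome_id, gene_id)
            for genome_id, ms in self.members.items()
            for m in ms
            for gene_id in m.operon.gene_ids
        }


def assemble_regulons(
    groups: list[OrthoGroup],
    accepted_sites: dict[str, dict[str, list[tuple[str, Site]]]],
    operons_by_genome: dict[str, list[Operon]],
    pwms: dict[str, PWM | None] | None = None,
) -> tuple[list[Regulon], dict[str, int]]:
    """Attach accepted members to each TF group and extend them to whole
    operons.

    ``accepted_sites[group_id]`` maps genome -> accepted (gene, site)
    pairs whose gene must be the promoter-proximal gene of an operon in
    ``operons_by_genome`` (dangling references are rejected).  Returns the
    regulons plus cohort totals (TFs, TFBSs, operons, genes).
    """
    first_gene_index: dict[str, dict[str, Operon]] = {}
    for genome_id, operons in operons_by_genome.items():
        first_gene_index[genome_id] = {o.first_gene: o for o in operons}
    regulons = []
    for group in groups:
        per_group = accepted_sites.get(group.group_id, {})
        members: dict[str, list[RegulonMember]] = {}
        for genome_id in sorted(per_group):
            if genome_id not in first_gene_index:
                raise ValueError(
                    f"group {group.group_id}: unknown genome {genome_id}"
                )
            by_operon: dict[str, RegulonMember] = {}
            for gene_id, site in per_group[genome_id]:
                operon = first_gene_index[genome_id].get(gene_id)
                if operon is None:
                    raise ValueError(
                        f"group {group.group_id}: gene {gene_id} is not the "
                        f"first gene of any operon in {genome_id}"
                    )
                entry = by_operon.setdefault(
                    operon.operon_id, RegulonMember(operon, [])
                )
                entry.sites.append(site)
            if by_operon:
                members[genome_id] = [
                    by_operon[k] for k in sorted(by_operon)
                ]
        regulons.append(
            Regulon(
                group=group,
                pwm=(pwms or {}).get(group.group_id),
                members=members,
            )
        )
    totals = {
        "tfs": sum(r.n_tfs for r in regulons if r.members),
        "tfbs": sum(r.n_sites for r in regulons),
        "operons": sum(r.n_operons for r in regulons),
        "genes": sum(r.n_genes for r in regulons),
    }
    return regulons, totals


def regulons_to_tsv(regulons: list[Regulon], path: str) -> None:
    """Export regulons: one row per accepted operon with its best site."""
    with open(path, "w") as fh:
        fh.write(
            "group_id\tgenome_id\toperon_members\tsite_word\t"
            "site_rel_position\tsite_score\tsite_class\n"
        )
        for r in regulons:
            for genome_id in sorted(r.members):
                for m in r.members[genome_id]:
                    best = max(m.sites, key=lambda s: s.score)
                    fh.write(
                        f"{r.group.group_id}\t{genome_id}\t"
                        f"{','.join(m.operon.gene_ids)}\t{best.word}\t"
                        f"{best.rel_position}\t{best.score:.4f}\t"
                        f"{best.site_class}\n"
                    )
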