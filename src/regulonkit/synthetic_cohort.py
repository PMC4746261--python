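"""Synthetic multi-genome cohorts with planted regulons and ground truth.

The generator emulates a small cohort of high-GC bacterial genomes (the
default 60% GC mimics gut Actinobacteria) in which each orthologous TF
group sits next to the operons it regulates, as sugar-catabolism loci do.
For every non-decoy TF group a self-reverse-complementary consensus is
drawn, softened into a position probability matrix meeting a target
information content, and site instances are written into the upstream
windows of the group's target operons in every genome carrying the TF.
Everything planted — orthology, operon composition, site coordinates and
words — is recorded in a machine-readable truth object so each pipeline
stage can be scored without external data.

Randomness is split into fixed named streams (sequence, layout, motifs,
sites, proteins, decoys) spawned from one seed, so enabling one artifact
component never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome_io import BASES, Gene, Genome, reverse_complement, write_genome
from .motif_inference import PWM

_STREAMS = {
    "sequence": 0,
    "layout": 1,
    "motifs": 2,
    "sites": 3,
    "proteins": 4,
    "decoys": 5,
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_FAMILY_CYCLE = ("LacI", "ROK", "TetR", "DeoR", "GntR", "AraC", "RpiR", "BglG", "SorC")

# inter-operon gaps are wide enough that the -350..+50 window of one operon
# never reaches the planted operator of a divergently oriented neighbor
_INTER_OPERON_GAP = (620, 820)
_GENE_LENGTH = (600, 1200)
_TF_GENE_LENGTH = 750
_EDGE_MARGIN = 400


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``motif_ic`` is the total information content of the planted operators,
    realized as two near-perfectly conserved half-site contact regions
    around a degenerate spacer; ``site_mutation_rate`` is the per-base
    substitution probability on the conserved columns and defaults to the
    value meeting ``motif_ic`` exactly (see :func:`resolve_site_model`).
    """

    n_genomes: int = 6
    genome_length: int = 1_000_000
    gc_content: float = 0.60
    n_tf_groups: int = 4
    tfs_per_genome: int | None = None
    motif_width: int = 18
    motif_ic: float = 16.0
    sites_per_regulon: int = 5
    site_mutation_rate: float | None = None
    operon_size_range: tuple[int, int] = (1, 4)
    intergenic_gap_range: tuple[int, int] = (20, 150)
    decoy_fraction: float = 0.25
    decoy_site_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        for name in ("n_genomes", "genome_length", "n_tf_groups",
                     "sites_per_regulon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 10 <= self.motif_width <= 30:
            raise ValueError("motif_width must be within [10, 30]")
        if self.tfs_per_genome is None:
            self.tfs_per_genome = self.n_tf_groups
        if not 1 <= self.tfs_per_genome <= self.n_tf_groups:
            raise ValueError("tfs_per_genome must be in [1, n_tf_groups]")
        if self.intergenic_gap_range[1] > 200:
            raise ValueError(
                "intra-operon intergenic gaps must stay <= 200 nt"
            )

    @property
    def resolved_mutation_rate(self) -> float:
        return self.resolved_site_model()[0]

    def resolved_site_model(self) -> tuple[float, int]:
        """Per-base substitution rate on conserved columns and the number
        of conserved (half-site contact) columns realizing ``motif_ic``."""
        return resolve_site_model(
            self.motif_ic, self.motif_width, self.site_mutation_rate
        )


def _column_entropy(p: float) -> float:
    """Entropy (bits) of a column with consensus probability 1-p and the
    remaining mass split over the other three bases."""
    if p <= 0:
        return 0.0
    return -((1 - p) * math.log2(1 - p) + p * math.log2(p / 3.0))


def _rate_for_column_ic(per_col: float) -> float:
    """Solve 2 - H(p) = per_col for the substitution rate p."""
    if per_col >= 2.0:
        return 0.0
    if per_col <= 0.0:
        return 0.75
    return float(
        brentq(lambda p: (2.0 - _column_entropy(p)) - per_col, 1e-9, 0.75 - 1e-9)
    )


def resolve_site_model(
    motif_ic: float, width: int, site_mutation_rate: float | None
) -> tuple[float, int]:
    """Resolve (substitution rate, conserved-column count) for planted sites.

    Homodimeric-TF palindromes carry their information in two conserved
    half-site contact regions flanking a degenerate spacer; the planted
    model mirrors that.  ``motif_ic`` fixes the total information content:
    with the rate unset, the conserved-core size is the even column count
    whose near-perfect conservation carries ``motif_ic`` bits and the rate
    is solved so the total matches; with an explicit rate, the core size is
    chosen to meet ``motif_ic`` at that per-column conservation.  Spacer
    columns are free (background) in both cases.
    """
    max_even = width - (width % 2)
    if site_mutation_rate is None:
        k = 2 * max(1, round(motif_ic / 4.0))
        k = min(k, max_even)
        rate = _rate_for_column_ic(motif_ic / k)
        return rate, k
    rate = site_mutation_rate
    per_col = 2.0 - _column_entropy(rate)
    if per_col <= 0:
        return rate, max_even
    k = int(round(motif_ic / per_col))
    k = max(2, min(k - (k % 2), max_even))
    return rate, k


def mutate_site(consensus: str, rate: float, rng: np.random.Generator) -> str:
    """Independently substitute each position to a uniformly chosen
    different base with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be a probability")
    bases = list(consensus)
    hit = rng.random(len(bases)) < rate
    picks = rng.integers(0, 3, len(bases))
    for i, flag in enumerate(hit):
        if flag:
            options = [b for b in BASES if b != bases[i]]
            bases[i] = options[picks[i]]
    return "".join(bases)


# ---------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class TruthSite:
    genome_id: str
    group_id: str
    operon_id: str
    gene_id: str  # first (promoter-proximal) gene of the target operon
    position: int  # forward-strand leftmost base of the planted word
    strand: str
    rel_position: int
    word: str


@dataclass
class TruthOperon:
    operon_id: str
    template_id: str
    genome_id: str
    gene_ids: list[str]  # transcription order; first = promoter-proximal
    strand: str
    role: str  # "tf:<group>", "target:<group>" or "filler"


@dataclass
class TruthGroup:
    group_id: str
    family: str
    decoy: bool
    consensus: str
    pwm: PWM
    tf_genes: dict[str, str] = field(default_factory=dict)  # genome -> gene


@dataclass
class CohortTruth:
    """Everything the generator planted, for oracle-style scoring."""

    config: CohortConfig
    site_mutation_rate: float
    groups: dict[str, TruthGroup]
    sites: list[TruthSite]
    decoy_sites: list[TruthSite]
    operons: dict[str, list[TruthOperon]]
    ortholog_map: dict[str, str]  # gene_id -> ortholog family label
    protein_seqs: dict[str, str]  # TF gene_id -> protein sequence

    def regulon_members(self) -> set[tuple[str, str, str]]:
        """(group_id, genome_id, gene_id) for every planted regulon gene,
        target operons expanded to all their genes."""
        by_id = {
            o.operon_id: o for ops in self.operons.values() for o in ops
        }
        members = set()
        for site in self.sites:
            operon = by_id[site.operon_id]
            for gene_id in operon.gene_ids:
                members.add((site.group_id, site.genome_id, gene_id))
        return members


# ---------------------------------------------------------------------------
# templates


@dataclass(frozen=True)
class _OperonTemplate:
    template_id: str
    labels: tuple[str, ...]
    lengths: tuple[int, ...]
    role: str
    site_rel: int | None = None  # planted-site position template (targets)


def _draw_palindrome(width: int, core: int, rng: np.random.Generator) -> str:
    """A self-reverse-complementary consensus with ``core`` conserved
    half-site contact columns (split between the two ends) and 'N' over the
    degenerate spacer."""
    half = [BASES[b] for b in rng.integers(0, 4, width // 2)]
    left = "".join(half)
    full = left + ("N" if width % 2 else "") + reverse_complement(left)
    k = core // 2
    chars = [
        c if i < k or i >= width - k else "N" for i, c in enumerate(full)
    ]
    return "".join(chars)


def _planted_pwm(consensus: str, rate: float) -> PWM:
    """Column probabilities of the site-generating process: conserved
    columns put 1-rate on the consensus base, spacer ('N') columns are
    background-uniform."""
    width = len(consensus)
    counts = np.full((4, width), 0.25)
    for i, base in enumerate(consensus):
        if base == "N":
            continue
        counts[:, i] = rate / 3.0
        counts[BASES.index(base), i] = 1.0 - rate
    return PWM(counts, np.full(4, 0.25), pseudocount=1e-9)


def _sample_site_word(
    consensus: str, rate: float, rng: np.random.Generator
) -> str:
    """One site instance: spacer ('N') columns drawn from background,
    conserved columns substituted at the per-base rate."""
    filled = "".join(
        BASES[rng.integers(0, 4)] if c == "N" else c for c in consensus
    )
    return mutate_site(filled, rate, rng)


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    picks = rng.integers(0, len(_AA) - 1, len(chars))
    for i, flag in enumerate(hit):
        if flag:
            options = [a for a in _AA if a != chars[i]]
            chars[i] = options[picks[i]]
    return "".join(chars)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[Genome], pd.DataFrame, CohortTruth]:
    """Generate genomes, a TF annotation table and the planted truth.

    Identical configs (including seed) produce identical output, byte for
    byte once written.
    """
    rngs = {
        name: np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(key,))
        )
        for name, key in _STREAMS.items()
    }
    rate, core_columns = config.resolved_site_model()
    width = config.motif_width

    # --- cohort-level blueprint -------------------------------------------
    n_decoy_groups = int(round(config.decoy_fraction * config.n_tf_groups))
    groups: dict[str, TruthGroup] = {}
    for gi in range(config.n_tf_groups):
        group_id = f"grp{gi + 1:02d}"
        consensus = _draw_palindrome(width, core_columns, rngs["motifs"])
        groups[group_id] = TruthGroup(
            group_id=group_id,
            family=_FAMILY_CYCLE[gi % len(_FAMILY_CYCLE)],
            decoy=gi >= config.n_tf_groups - n_decoy_groups,
            consensus=consensus,
            pwm=_planted_pwm(consensus, rate),
        )
    ancestral_proteins = {
        gid: "".join(_AA[a] for a in rngs["proteins"].integers(0, len(_AA), 240))
        for gid in groups
    }

    layout_rng = rngs["layout"]
    lo_sz, hi_sz = config.operon_size_range

    def template_gene_lengths(n: int) -> tuple[int, ...]:
        return tuple(
            int(layout_rng.integers(_GENE_LENGTH[0], _GENE_LENGTH[1] + 1))
            for _ in range(n)
        )

    block_templates: dict[str, list[_OperonTemplate]] = {}
    for gid in groups:
        templates: list[_OperonTemplate] = []
        for t in range(config.sites_per_regulon):
            n_genes = int(layout_rng.integers(lo_sz, hi_sz + 1))
            rel = int(layout_rng.integers(-190, -(width + 40) + 1))
            templates.append(
                _OperonTemplate(
                    template_id=f"{gid}_t{t}",
                    labels=tuple(f"{gid}_t{t}_g{k}" for k in range(n_genes)),
                    lengths=template_gene_lengths(n_genes),
                    role=f"target:{gid}",
                    site_rel=rel,
                )
            )
        # conserved gene order across genomes, the TF gene amid its targets
        half = len(templates) // 2
        templates.insert(
            half,
            _OperonTemplate(
                template_id=f"{gid}_tf",
                labels=(f"{gid}_tf",),
                lengths=(_TF_GENE_LENGTH,),
                role=f"tf:{gid}",
            ),
        )
        block_templates[gid] = templates

    n_filler = config.genome_length // 1000 + 10
    fillers = []
    for t in range(n_filler):
        n_genes = int(layout_rng.integers(lo_sz, hi_sz + 1))
        fillers.append(
            _OperonTemplate(
                template_id=f"fil{t:04d}",
                labels=tuple(f"fil{t:04d}_g{k}" for k in range(n_genes)),
                lengths=template_gene_lengths(n_genes),
                role="filler",
            )
        )

    # capacity: every carried block must fit
    def operon_span(tpl: _OperonTemplate) -> int:
        return sum(tpl.lengths) + 85 * max(len(tpl.lengths) - 1, 0) + 720

    block_span = {
        gid: sum(operon_span(t) for t in tpls)
        for gid, tpls in block_templates.items()
    }
    worst = sum(sorted(block_span.values(), reverse=True)[: config.tfs_per_genome])
    if worst + 2 * _EDGE_MARGIN > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} cannot hold "
            f"{config.tfs_per_genome} TF neighborhoods spanning ~{worst} nt "
            f"plus {2 * _EDGE_MARGIN} nt margins"
        )

    # --- per-genome layout -------------------------------------------------
    genome_ids = [f"G{i + 1:02d}" for i in range(config.n_genomes)]
    carried: dict[str, list[str]] = {}
    group_list = sorted(groups)
    for genome_id in genome_ids:
        if config.tfs_per_genome == config.n_tf_groups:
            carried[genome_id] = list(group_list)
        else:
            picks = layout_rng.choice(
                len(group_list), size=config.tfs_per_genome, replace=False
            )
            carried[genome_id] = sorted(group_list[i] for i in sorted(picks))

    truth_operons: dict[str, list[TruthOperon]] = {}
    ortholog_map: dict[str, str] = {}
    protein_seqs: dict[str, str] = {}
    tf_rows: list[tuple[str, str, str]] = []
    planted_plan: list[tuple[str, str, TruthOperon, int]] = []
    placed_genes: dict[str, list[Gene]] = {}
    filler_instances: dict[str, list[TruthOperon]] = {}

    avg_span = int(np.mean([operon_span(t) for t in fillers]))
    est_capacity = max(config.genome_length // avg_span, 1)

    for genome_id in genome_ids:
        blocks = [list(block_templates[gid]) for gid in carried[genome_id]]
        n_block_operons = sum(len(b) for b in blocks)
        insert_max = max(int(est_capacity * 0.7) - n_block_operons, 1)
        positions = sorted(
            int(layout_rng.integers(0, insert_max)) for _ in blocks
        )
        elements: list[_OperonTemplate] = []
        fi = 0
        for slot, block in zip(positions, blocks):
            while fi < slot and fi < len(fillers):
                elements.append(fillers[fi])
                fi += 1
            elements.extend(block)
        elements.extend(fillers[fi:])

        genes: list[Gene] = []
        operons: list[TruthOperon] = []
        cursor = _EDGE_MARGIN
        gene_counter = 0
        placed_roles: set[str] = set()
        for tpl in elements:
            gap = int(layout_rng.integers(*_INTER_OPERON_GAP))
            start = cursor + gap
            intra = [
                int(
                    layout_rng.integers(
                        config.intergenic_gap_range[0],
                        config.intergenic_gap_range[1] + 1,
                    )
                )
                for _ in range(len(tpl.lengths) - 1)
            ]
            span = sum(tpl.lengths) + sum(intra)
            strand = "+" if layout_rng.integers(0, 2) == 0 else "-"
            if start + span + _EDGE_MARGIN > config.genome_length:
                if tpl.role == "filler":
                    continue
                raise ValueError(
                    f"genome {genome_id}: TF neighborhood operon "
                    f"{tpl.template_id} does not fit before position "
                    f"{config.genome_length - _EDGE_MARGIN}"
                )
            # left-to-right placement; transcription order depends on strand
            layout_labels = (
                tpl.labels if strand == "+" else tuple(reversed(tpl.labels))
            )
            layout_lengths = (
                tpl.lengths if strand == "+" else tuple(reversed(tpl.lengths))
            )
            pos = start
            left_to_right: list[str] = []
            for k, (label, length) in enumerate(
                zip(layout_labels, layout_lengths)
            ):
                gene_id = f"{genome_id}_g{gene_counter:05d}"
                gene_counter += 1
                genes.append(
                    Gene(gene_id, pos, pos + length, strand, product=label)
                )
                ortholog_map[gene_id] = label
                left_to_right.append(gene_id)
                pos += length
                if k < len(intra):
                    pos += intra[k]
            cursor = pos
            transcription_order = (
                left_to_right if strand == "+" else list(reversed(left_to_right))
            )
            operon = TruthOperon(
                operon_id=f"{genome_id}:{tpl.template_id}",
                template_id=tpl.template_id,
                genome_id=genome_id,
                gene_ids=transcription_order,
                strand=strand,
                role=tpl.role,
            )
            operons.append(operon)
            if tpl.role.startswith("tf:"):
                gid = tpl.role.split(":", 1)[1]
                tf_gene = transcription_order[0]
                groups[gid].tf_genes[genome_id] = tf_gene
                tf_rows.append((genome_id, tf_gene, groups[gid].family))
                protein_seqs[tf_gene] = _mutate_protein(
                    ancestral_proteins[gid], 0.06, rngs["proteins"]
                )
            elif tpl.role.startswith("target:"):
                gid = tpl.role.split(":", 1)[1]
                if not groups[gid].decoy:
                    planted_plan.append(
                        (gid, genome_id, operon, tpl.site_rel)
                    )
            else:
                filler_instances.setdefault(genome_id, []).append(operon)
            placed_roles.add(tpl.template_id)
        missing = [
            t.template_id
            for gid in carried[genome_id]
            for t in block_templates[gid]
            if t.template_id not in placed_roles
        ]
        if missing:
            raise ValueError(
                f"genome {genome_id}: could not place TF neighborhoods "
                f"{missing}; genome_length {config.genome_length} too small"
            )
        truth_operons[genome_id] = operons
        placed_genes[genome_id] = genes

    # --- sequences and planted sites --------------------------------------
    gc = config.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: dict[str, np.ndarray] = {}
    for genome_id in genome_ids:
        sequences[genome_id] = rngs["sequence"].choice(
            4, size=config.genome_length, p=base_probs
        ).astype(np.int8)

    gene_lookup = {
        genome_id: {g.gene_id: g for g in genes}
        for genome_id, genes in placed_genes.items()
    }

    def plant(genome_id: str, gene: Gene, rel: int, word: str) -> TruthSite:
        seq = sequences[genome_id]
        enc = np.array([BASES.index(b) for b in word], dtype=np.int8)
        if gene.strand == "+":
            left = gene.start + rel
            seq[left : left + len(word)] = enc
        else:
            left = gene.end - rel - len(word)
            rc = np.array(
                [BASES.index(b) for b in reverse_complement(word)], dtype=np.int8
            )
            seq[left : left + len(word)] = rc
        return TruthSite(
            genome_id=genome_id,
            group_id="",
            operon_id="",
            gene_id=gene.gene_id,
            position=left,
            strand=gene.strand,
            rel_position=rel,
            word=word,
        )

    sites: list[TruthSite] = []
    for gid, genome_id, operon, base_rel in planted_plan:
        jitter = int(rngs["sites"].integers(-10, 11))
        rel = base_rel + jitter
        word = _sample_site_word(groups[gid].consensus, rate, rngs["sites"])
        first_gene = gene_lookup[genome_id][operon.gene_ids[0]]
        site = plant(genome_id, first_gene, rel, word)
        sites.append(
            dataclasses.replace(
                site, group_id=gid, operon_id=operon.operon_id
            )
        )

    decoy_sites: list[TruthSite] = []
    n_decoy_sites = int(round(config.decoy_site_fraction * len(sites)))
    if n_decoy_sites:
        non_decoy = [g for g in group_list if not groups[g].decoy]
        used_templates: set[str] = set()
        rng = rngs["decoys"]
        attempts = 0
        while len(decoy_sites) < n_decoy_sites and attempts < 50 * n_decoy_sites:
            attempts += 1
            genome_id = genome_ids[int(rng.integers(0, len(genome_ids)))]
            pool = [
                o
                for o in filler_instances.get(genome_id, [])
                if o.template_id not in used_templates
            ]
            if not pool:
                continue
            operon = pool[int(rng.integers(0, len(pool)))]
            gid = non_decoy[len(decoy_sites) % len(non_decoy)]
            rel = int(rng.integers(-190, -(width + 40) + 1))
            word = _sample_site_word(groups[gid].consensus, rate, rng)
            first_gene = gene_lookup[genome_id][operon.gene_ids[0]]
            site = plant(genome_id, first_gene, rel, word)
            decoy_sites.append(
                dataclasses.replace(
                    site, group_id=gid, operon_id=operon.operon_id
                )
            )
            used_templates.add(operon.template_id)

    genomes = []
    for genome_id in genome_ids:
        seq = "".join(BASES[b] for b in sequences[genome_id])
        genomes.append(Genome(genome_id, seq, placed_genes[genome_id]))

    tf_table = pd.DataFrame(
        sorted(tf_rows), columns=["genome_id", "gene_id", "family"]
    )
    truth = CohortTruth(
        config=config,
        site_mutation_rate=rate,
        groups=groups,
        sites=sites,
        decoy_sites=decoy_sites,
        operons=truth_operons,
        ortholog_map=ortholog_map,
        protein_seqs=protein_seqs,
    )
    return genomes, tf_table, truth


# ---------------------------------------------------------------------------
# writers


def write_cohort(
    genomes: list[Genome],
    tf_table: pd.DataFrame,
    truth: CohortTruth,
    outdir: str,
) -> None:
    """Write the cohort as FASTA + feature TSV + annotation, truth and
    summary files.  Deterministic byte-for-byte given identical inputs."""
    os.makedirs(outdir, exist_ok=True)
    write_genome(
        genomes,
        os.path.join(outdir, "genomes.fna"),
        os.path.join(outdir, "features.tsv"),
    )
    tf_table.to_csv(os.path.join(outdir, "tf_table.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "proteins.faa"), "w") as fh:
        for gene_id in sorted(truth.protein_seqs):
            fh.write(f">{gene_id}\n{truth.protein_seqs[gene_id]}\n")
    with open(os.path.join(outdir, "truth_sites.tsv"), "w") as fh:
        fh.write(
            "genome_id\tgroup_id\toperon_id\tgene_id\tposition\tstrand\t"
            "rel_position\tword\tdecoy\n"
        )
        for decoy, sites in ((0, truth.sites), (1, truth.decoy_sites)):
            for s in sites:
                fh.write(
                    f"{s.genome_id}\t{s.group_id}\t{s.operon_id}\t{s.gene_id}\t"
                    f"{s.position}\t{s.strand}\t{s.rel_position}\t{s.word}\t"
                    f"{decoy}\n"
                )
    with open(os.path.join(outdir, "truth_operons.tsv"), "w") as fh:
        fh.write("genome_id\toperon_id\trole\tstrand\tgene_ids\n")
        for genome_id in sorted(truth.operons):
            for o in truth.operons[genome_id]:
                fh.write(
                    f"{genome_id}\t{o.operon_id}\t{o.role}\t{o.strand}\t"
                    f"{','.join(o.gene_ids)}\n"
                )
    with open(os.path.join(outdir, "ortholog_map.tsv"), "w") as fh:
        fh.write("gene_id\tortholog_label\n")
        for gene_id in sorted(truth.ortholog_map):
            fh.write(f"{gene_id}\t{truth.ortholog_map[gene_id]}\n")
    summary = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(truth.config).items()
        },
        "site_mutation_rate": truth.site_mutation_rate,
        "n_planted_sites": len(truth.sites),
        "n_decoy_sites": len(truth.decoy_sites),
        "groups": {
            gid: {
                "family": g.family,
                "decoy": g.decoy,
                "consensus": g.consensus,
                "tf_genes": g.tf_genes,
            }
            for gid, g in truth.groups.items()
        },
    }
    with open(os.path.join(outdir, "truth_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
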