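"""End-to-end regulon reconstruction across a genome cohort.

The driver mirrors the comparative-genomics workflow for sugar-catabolism
regulators: group TFs into orthologous groups; collect training regions
from the operons in each TF's chromosomal neighborhood (sugar regulators
overwhelmingly sit next to their target operons); infer a palindromic
motif; calibrate a PWM threshold 10% below the weakest training site; scan
the promoter windows of every operon in the genomes carrying the TF;
rescue positionally conserved weak sites; and accept members only when
candidate sites recur upstream of orthologous genes in several genomes,
finally extending accepted genes to their whole operons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome_io, motif_inference, pwm_scanner, regulon_builder, tf_catalog
from .genome_io import Genome, UpstreamRegion
from .motif_inference import PWM, MotifHit
from .pwm_scanner import STRONG, Site
from .regulon_builder import Operon, Regulon
from .tf_catalog import OrthoGroup


@dataclass
class PipelineParams:
    """Tunable parameters of the reconstruction, with the published rules
    as defaults where the source procedure states them."""

    window: tuple[int, int] = (-350, 50)
    max_operon_gap: int = 200
    min_support: int = 2  # "several related genomes"
    position_tolerance: int = 30
    width_range: tuple[int, int] = (14, 22)
    restarts: int = 5
    pseudocount: float = 0.5
    neighborhood_operons: int = 2  # TF locus radius, in operons per side
    min_total_ic: float = 8.0
    min_hit_fraction: float = 0.6
    identity_threshold: float = 0.5
    context_threshold: float = 0.3
    motif_threshold: float = 0.75
    use_operon_conservation: bool = False
    seed: int = 0


@dataclass
class GroupReconstruction:
    group: OrthoGroup
    pwm: PWM | None
    training_hits: list[MotifHit] = field(default_factory=list)
    candidate_sites: list[Site] = field(default_factory=list)
    accepted: dict[str, list[tuple[str, Site]]] = field(default_factory=dict)

    @property
    def accepted_sites(self) -> list[Site]:
        return [s for entries in self.accepted.values() for _, s in entries]


@dataclass
class Reconstruction:
    groups: list[OrthoGroup]
    per_group: dict[str, GroupReconstruction]
    operons: dict[str, list[Operon]]
    regulons: list[Regulon]
    totals: dict[str, int]


def _gene_positions(genome: Genome) -> dict[str, int]:
    return {g.gene_id: i for i, g in enumerate(genome.genes)}


def training_regions_for_group(
    group: OrthoGroup,
    genomes_by_id: dict[str, Genome],
    operons_by_genome: dict[str, list[Operon]],
    params: PipelineParams,
) -> list[UpstreamRegion]:
    """Upstream windows of the promoter-proximal genes of the operons in
    the TF's chromosomal neighborhood (the TF's own operon plus
    ``neighborhood_operons`` operons on each side), pooled over the
    genomes carrying the TF.  Sugar-catabolism regulators overwhelmingly
    sit next to their target operons, so these windows are the training
    set for motif inference."""
    regions = []
    radius = params.neighborhood_operons
    for member in sorted(group.members, key=lambda m: (m.genome_id, m.gene_id)):
        genome = genomes_by_id[member.genome_id]
        operons = operons_by_genome[member.genome_id]
        tf_pos = next(
            i for i, o in enumerate(operons) if member.gene_id in o.gene_ids
        )
        seen = set()
        for operon in operons[max(0, tf_pos - radius) : tf_pos + radius + 1]:
            if operon.first_gene in seen:
                continue
            seen.add(operon.first_gene)
            regions.append(
                genome_io.upstream_region(
                    genome, operon.first_gene, params.window
                )
            )
    return regions


def _rescue(
    candidates: list[Site],
    ortholog_map: dict[str, str],
    params: PipelineParams,
) -> list[Site]:
    """Apply the weak-site rescue rule per ortholog family."""
    by_label: dict[str, list[Site]] = {}
    for s in candidates:
        by_label.setdefault(
            ortholog_map.get(s.gene_id, s.gene_id), []
        ).append(s)
    kept: list[Site] = []
    for label in sorted(by_label):
        sites = by_label[label]
        strong_by_genome: dict[str, list[Site]] = {}
        for s in sites:
            if s.site_class == STRONG:
                strong_by_genome.setdefault(s.genome_id, []).append(s)
        kept.extend(
            pwm_scanner.rescue_weak_sites(
                sites, strong_by_genome, params.position_tolerance
            )
        )
    return kept


def reconstruct(
    genomes: list[Genome],
    tf_table: pd.DataFrame,
    protein_seqs: dict[str, str],
    ortholog_map: dict[str, str],
    params: PipelineParams | None = None,
) -> Reconstruction:
    """Run the full reconstruction over a cohort.

    ``tf_table`` has columns genome_id, gene_id, family; ``ortholog_map``
    assigns every gene an ortholog family label (computed upstream or
    supplied with the cohort).
    """
    params = params or PipelineParams()
    genomes_by_id = {g.genome_id: g for g in genomes}
    tfs = tf_catalog.tf_records(genomes, tf_table)
    groups = tf_catalog.group_orthologs(
        tfs,
        protein_seqs,
        identity_threshold=params.identity_threshold,
        context_threshold=params.context_threshold,
        motif_threshold=params.motif_threshold,
    )
    conservation = None
    if params.use_operon_conservation:
        conservation = regulon_builder.CohortContext.build(
            genomes, ortholog_map, params.max_operon_gap
        )
    operons_by_genome = {
        g.genome_id: regulon_builder.call_operons(
            g, params.max_operon_gap, conservation, ortholog_map
        )
        for g in genomes
    }

    per_group: dict[str, GroupReconstruction] = {}
    accepted_by_group: dict[str, dict[str, list[tuple[str, Site]]]] = {}
    pwms: dict[str, PWM | None] = {}
    for group in groups:
        rec = GroupReconstruction(group=group, pwm=None)
        per_group[group.group_id] = rec
        regions = training_regions_for_group(
            group, genomes_by_id, operons_by_genome, params
        )
        if len(regions) < 3:
            continue
        carrier_backgrounds = np.mean(
            [genomes_by_id[gid].background for gid in group.genomes], axis=0
        )
        pwm, hits = motif_inference.discover_palindromic_motif(
            regions,
            width_range=params.width_range,
            restarts=params.restarts,
            seed=params.seed,
            background=carrier_backgrounds,
            pseudocount=params.pseudocount,
            min_total_ic=params.min_total_ic,
            min_hit_fraction=params.min_hit_fraction,
        )
        if pwm is None:
            continue
        pwm.threshold = pwm_scanner.compute_threshold([h.score for h in hits])
        rec.pwm = pwm
        rec.training_hits = hits
        pwms[group.group_id] = pwm
        group.motif = pwm

        scan_regions = []
        for genome_id in group.genomes:
            genome = genomes_by_id[genome_id]
            for operon in operons_by_genome[genome_id]:
                scan_regions.append(
                    genome_io.upstream_region(
                        genome, operon.first_gene, params.window
                    )
                )
        candidates = pwm_scanner.scan_regions(pwm, scan_regions)
        rec.candidate_sites = candidates
        # one operator per promoter: keep the best candidate per window
        best_per_region: dict[tuple[str, str], Site] = {}
        for s in candidates:
            key = (s.genome_id, s.gene_id)
            prev = best_per_region.get(key)
            if prev is None or (s.score, -s.rel_position) > (
                prev.score, -prev.rel_position
            ):
                best_per_region[key] = s
        reduced = [best_per_region[k] for k in sorted(best_per_region)]
        filtered = _rescue(reduced, ortholog_map, params)
        by_genome: dict[str, list[tuple[str, Site]]] = {}
        for s in filtered:
            by_genome.setdefault(s.genome_id, []).append((s.gene_id, s))
        accepted = regulon_builder.consistency_check(
            by_genome, ortholog_map, params.min_support
        )
        rec.accepted = accepted
        accepted_by_group[group.group_id] = accepted

    regulons, totals = regulon_builder.assemble_regulons(
        groups, accepted_by_group, operons_by_genome, pwms
    )
    return Reconstruction(
        groups=groups,
        per_group=per_group,
        operons=operons_by_genome,
        regulons=regulons,
        totals=totals,
    )
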