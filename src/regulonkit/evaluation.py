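"""Scoring a reconstruction against the planted truth of a synthetic cohort.

Recovered orthologous groups are matched to planted groups by majority vote
over their TF genes; site- and membership-level precision/recall then
compare the pipeline's accepted output with what the generator planted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import reverse_complement
from .pipeline import Reconstruction
from .pwm_scanner import STRONG
from .synthetic_cohort import CohortTruth
from .tf_catalog import OrthoGroup

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "M": {"A", "C"}, "R": {"A", "G"}, "W": {"A", "T"},
    "S": {"C", "G"}, "Y": {"C", "T"}, "K": {"G", "T"},
    "V": {"A", "C", "G"}, "H": {"A", "C", "T"},
    "D": {"A", "G", "T"}, "B": {"C", "G", "T"},
    "N": {"A", "C", "G", "T"},
}


def consensus_distance(recovered: str, planted: str) -> int:
    """Distance between a recovered and a planted consensus (both possibly
    IUPAC-ambiguous): columns whose IUPAC base sets are disjoint, plus
    unaligned overhang, minimized over ungapped alignments in both
    orientations.  Degenerate spacer columns (N) match anything."""
    best = max(len(recovered), len(planted))
    for cand in (recovered, reverse_complement_iupac(recovered)):
        na, nb = len(cand), len(planted)
        for shift in range(-na + 1, nb):
            a_lo, b_lo = max(0, -shift), max(0, shift)
            overlap = min(na - a_lo, nb - b_lo)
            if overlap <= 0:
                continue
            mism = sum(
                1
                for i in range(overlap)
                if not (
                    _IUPAC_SETS.get(cand[a_lo + i], set())
                    & _IUPAC_SETS.get(planted[b_lo + i], set())
                )
            )
            overhang = (na - overlap) + (nb - overlap)
            best = min(best, mism + overhang)
    return best


_IUPAC_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "M": "K", "K": "M", "R": "Y", "Y": "R", "W": "W", "S": "S",
    "V": "B", "B": "V", "H": "D", "D": "H",
}


def reverse_complement_iupac(seq: str) -> str:
    return "".join(_IUPAC_COMP[c] for c in reversed(seq))


def map_groups_to_truth(
    groups: list[OrthoGroup], truth: CohortTruth
) -> dict[str, str | None]:
    """Recovered group id -> planted group id, by TF-gene majority vote."""
    tf_to_truth = {
        gene_id: gid
        for gid, g in truth.groups.items()
        for gene_id in g.tf_genes.values()
    }
    mapping: dict[str, str | None] = {}
    for group in groups:
        votes: dict[str, int] = {}
        for m in group.members:
            gid = tf_to_truth.get(m.gene_id)
            if gid is not None:
                votes[gid] = votes.get(gid, 0) + 1
        mapping[group.group_id] = (
            max(sorted(votes), key=lambda g: votes[g]) if votes else None
        )
    return mapping


def grouping_ari(groups: list[OrthoGroup], truth: CohortTruth) -> float:
    """Adjusted Rand index between recovered and planted TF partitions."""
    from sklearn.metrics import adjusted_rand_score

    tf_to_truth = {
        gene_id: gid
        for gid, g in truth.groups.items()
        for gene_id in g.tf_genes.values()
    }
    genes = sorted(tf_to_truth)
    recovered = {}
    for group in groups:
        for m in group.members:
            recovered[m.gene_id] = group.group_id
    return float(
        adjusted_rand_score(
            [tf_to_truth[g] for g in genes],
            [recovered.get(g, f"missing:{g}") for g in genes],
        )
    )


@dataclass(frozen=True)
class SiteRecovery:
    recall: float
    precision: float
    tp: int
    fp: int
    fn: int


def site_recovery(
    recon: Reconstruction,
    truth: CohortTruth,
    tolerance: int = 3,
    strong_only: bool = True,
) -> SiteRecovery:
    """Recall/precision of the pipeline's accepted sites vs planted sites,
    matched by (group, genome) and position within ``tolerance`` nt."""
    mapping = map_groups_to_truth(recon.groups, truth)
    truth_by_key: dict[tuple[str, str], list[int]] = {}
    for s in truth.sites:
        truth_by_key.setdefault((s.group_id, s.genome_id), []).append(s.position)
    matched: set[tuple[str, str, int]] = set()
    tp = fp = 0
    for group_id, rec in recon.per_group.items():
        truth_gid = mapping.get(group_id) or f"?{group_id}"
        for site in rec.accepted_sites:
            if strong_only and site.site_class != STRONG:
                continue
            positions = truth_by_key.get((truth_gid, site.genome_id), [])
            hit = None
            for idx, pos in enumerate(positions):
                key = (truth_gid, site.genome_id, idx)
                if key not in matched and abs(pos - site.position) <= tolerance:
                    hit = key
                    break
            if hit is not None:
                matched.add(hit)
                tp += 1
            else:
                fp += 1
    n_truth = len(truth.sites)
    fn = n_truth - len(matched)
    recall = len(matched) / n_truth if n_truth else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return SiteRecovery(recall, precision, tp, fp, fn)


@dataclass(frozen=True)
class MembershipScore:
    f1: float
    precision: float
    recall: float
    n_predicted: int
    n_truth: int


def regulon_membership_score(
    recon: Reconstruction, truth: CohortTruth
) -> MembershipScore:
    """F1 of predicted (group, genome, gene) regulon membership triples
    against the planted truth (target operons expanded to all genes)."""
    mapping = map_groups_to_truth(recon.groups, truth)
    predicted: set[tuple[str, str, str]] = set()
    for regulon in recon.regulons:
        truth_gid = mapping.get(regulon.group.group_id) or (
            f"?{regulon.group.group_id}"
        )
        for genome_id, gene_id in regulon.member_genes():
            predicted.add((truth_gid, genome_id, gene_id))
    truth_set = truth.regulon_members()
    tp = len(predicted & truth_set)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth_set) if truth_set else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return MembershipScore(f1, precision, recall, len(predicted), len(truth_set))


def false_positive_members(recon: Reconstruction, truth: CohortTruth) -> int:
    """Predicted (group, genome, gene) membership triples absent from the
    planted truth (decoy-driven and chance members)."""
    mapping = map_groups_to_truth(recon.groups, truth)
    predicted: set[tuple[str, str, str]] = set()
    for regulon in recon.regulons:
        truth_gid = mapping.get(regulon.group.group_id) or (
            f"?{regulon.group.group_id}"
        )
        for genome_id, gene_id in regulon.member_genes():
            predicted.add((truth_gid, genome_id, gene_id))
    return len(predicted - truth.regulon_members())
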