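"""PWM construction, threshold calibration and upstream-window scanning.

Scoring is additive base-2 log-odds against the genome background with a
pseudocount (default 0.5).  The site-score threshold is set 10% below the
lowest training-site score, and sites scoring within a further 10% of the
threshold ("weak" sites) are reported as candidates so the positional
rescue rule can be applied against orthologous strong sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import UpstreamRegion, encode, reverse_complement
from .motif_inference import PWM

STRONG = "strong"
WEAK = "weak"
WEAK_RESCUED = "weak-rescued"


@dataclass(frozen=True)
class Site:
    """A scored PWM hit upstream of a target gene.

    ``position`` is the 0-based forward-strand coordinate of the leftmost
    base of the hit; ``rel_position`` is the offset of the hit's 5'-most
    base (reading toward the gene) relative to the translation start, so a
    site centered in a typical promoter has rel_position around -40..-100.
    """

    genome_id: str
    gene_id: str
    position: int
    strand: str
    word: str
    score: float
    rel_position: int
    site_class: str = STRONG


def build_pwm(
    sites: list[str], background: np.ndarray, pseudocount: float = 0.5
) -> PWM:
    """Tally equal-length site words into a PWM.

    Raises on an empty set, fewer than 2 words, or unequal lengths.
    """
    if len(sites) < 2:
        raise ValueError("build_pwm needs at least 2 site words")
    width = len(sites[0])
    if any(len(w) != width for w in sites):
        raise ValueError("all site words must have equal length")
    counts = np.zeros((4, width))
    for word in sites:
        enc = encode(word)
        if (enc == 4).any():
            raise ValueError(f"site word contains non-ACGT base: {word}")
        for i, b in enumerate(enc):
            counts[b, i] += 1
    return PWM(counts, background, pseudocount)


def compute_threshold(training_scores: list[float]) -> float:
    """Site-score cutoff: 10% below the lowest training-site score.

    The rule is only meaningful on a positive score scale; non-positive
    training scores are rejected so the caller can re-anchor scoring.
    """
    if len(training_scores) == 0:
        raise ValueError("training score set is empty")
    if any(s <= 0 for s in training_scores):
        raise ValueError(
            "threshold rule is ill-defined for non-positive training scores"
        )
    return 0.9 * min(training_scores)


def _strand_scores(pwm: PWM, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-strand scores for every offset of a region."""
    w = pwm.width
    cols = np.arange(w)
    windows = sliding_window_view(enc, w)
    w5f = np.vstack([pwm.weights, np.zeros(w)])
    w5r = np.vstack([pwm.reverse_complement().weights, np.zeros(w)])
    fwd = w5f[windows, cols].sum(axis=1)
    rev = w5r[windows, cols].sum(axis=1)
    return fwd, rev


def scan_window(pwm: PWM, region: UpstreamRegion) -> list[Site]:
    """Scan one upstream window on both strands.

    Reports local maxima scoring at least 0.9 x threshold, with overlapping
    hits collapsed to the single best-scoring one (ties resolved leftmost,
    then + strand).  Positions are reported relative to the translation
    start and as absolute forward-strand coordinates.  A region shorter
    than the PWM width yields an empty list.
    """
    if pwm.threshold is None:
        raise ValueError("pwm.threshold must be set before scanning")
    if len(region) < pwm.width:
        return []
    weak_level = 0.9 * pwm.threshold
    enc = encode(region.sequence)
    fwd, rev = _strand_scores(pwm, enc)
    # collapse ordering quantizes scores at 1e-9 so ties resolve by
    # position then strand, independent of summation order
    candidates = []  # (-score, offset, strand_order)
    for strand_order, scores in enumerate((fwd, rev)):
        above = np.nonzero(scores >= weak_level)[0]
        for j in above:
            candidates.append(
                (-round(float(scores[j]), 9), int(j), strand_order)
            )
    candidates.sort()
    accepted: list[tuple[float, int, int]] = []
    occupied: list[tuple[int, int]] = []
    w = pwm.width
    for negscore, offset, strand_order in candidates:
        if any(offset < e and offset + w > s for s, e in occupied):
            continue
        accepted.append((-negscore, offset, strand_order))
        occupied.append((offset, offset + w))
    sites = []
    for score, offset, strand_order in accepted:
        region_strand = "+" if strand_order == 0 else "-"
        if region.strand == "+":
            genome_strand = region_strand
        else:
            genome_strand = "-" if region_strand == "+" else "+"
        word = region.sequence[offset : offset + w]
        if region_strand == "-":
            word = reverse_complement(word)
        sites.append(
            Site(
                genome_id=region.genome_id,
                gene_id=region.gene_id,
                position=region.absolute_position(offset, w),
                strand=genome_strand,
                word=word,
                score=score,
                rel_position=offset - region.offset_of_start,
                site_class=STRONG if score >= pwm.threshold else WEAK,
            )
        )
    sites.sort(key=lambda s: s.rel_position)
    return sites


def scan_regions(pwm: PWM, regions: list[UpstreamRegion]) -> list[Site]:
    """Scan many windows; concatenated per-region results."""
    out: list[Site] = []
    for region in regions:
        out.extend(scan_window(pwm, region))
    return out


def rescue_weak_sites(
    candidates: list[Site],
    ortholog_sites: dict[str, list[Site]],
    position_tolerance: int = 30,
) -> list[Site]:
    """Apply the weak-site rescue rule.

    Strong candidates pass unconditionally.  A weak candidate (score below
    threshold but within 10% of it) is kept, as class ``weak-rescued``, only
    if (i) a strong site upstream of an orthologous gene in another genome
    lies within ``position_tolerance`` nt of the candidate's position
    relative to the translation start, and (ii) no higher-scoring candidate
    exists in the same region.  ``ortholog_sites`` maps each genome to the
    sites found upstream of orthologs of the candidate's target gene.
    """
    best_in_region: dict[tuple[str, str], float] = {}
    for s in candidates:
        key = (s.genome_id, s.gene_id)
        best_in_region[key] = max(best_in_region.get(key, -np.inf), s.score)
    kept: list[Site] = []
    for s in candidates:
        if s.site_class == STRONG:
            kept.append(s)
            continue
        if s.score < best_in_region[(s.genome_id, s.gene_id)]:
            continue  # competing stronger candidate in the same region
        supported = False
        for genome_id, strong in ortholog_sites.items():
            if genome_id == s.genome_id:
                continue
            for other in strong:
                if (
                    other.site_class == STRONG
                    and abs(other.rel_position - s.rel_position)
                    <= position_tolerance
                ):
                    supported = True
                    break
            if supported:
                break
        if supported:
            kept.append(replace(s, site_class=WEAK_RESCUED))
    return kept


def sites_to_bed(sites: list[Site], path: str) -> None:
    """Export sites as BED6 (score column = bits x 100, rounded)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.genome_id}\t{s.position}\t{s.position + len(s.word)}\t"
                f"{s.gene_id}\t{int(round(s.score * 100))}\t{s.strand}\n"
            )


def sites_to_tsv(sites: list[Site], path: str) -> None:
    """Export sites with relative position, class and matched word."""
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tgene_id\tposition\tstrand\trel_position\tscore\t"
            "class\tword\n"
        )
        for s in sites:
            fh.write(
                f"{s.genome_id}\t{s.gene_id}\t{s.position}\t{s.strand}\t"
                f"{s.rel_position}\t{s.score:.4f}\t{s.site_class}\t{s.word}\n"
            )
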