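import math

import numpy as np
import pytest

from regulonkit.genome_io import UpstreamRegion, reverse_complement
from regulonkit.pwm_scanner import (
    STRONG,
    WEAK,
    WEAK_RESCUED,
    Site,
    build_pwm,
    compute_threshold,
    rescue_weak_sites,
    scan_window,
)

UNIFORM = np.full(4, 0.25)


def _region(seq, name="r", genome="G", offset_of_start=None):
    return UpstreamRegion(
        gene_id=name,
        genome_id=genome,
        sequence=seq,
        offset_of_start=len(seq) if offset_of_start is None else offset_of_start,
        genomic_start=0,
        genomic_end=len(seq),
    )


class TestBuildPwm:
    def test_identical_words_consensus_score(self):
        pwm = build_pwm(["TGTGAGCGCTCACA"] * 4, UNIFORM, pseudocount=0.0)
        assert pwm.max_score() == pytest.approx(28.0)

    def test_single_difference_yields_two_base_iupac(self):
        pwm = build_pwm(["ACGTAC", "ACTTAC"], UNIFORM)
        assert pwm.consensus[2] == "K"  # G/T

    def test_weight_matrix_cell_by_cell(self):
        # independent oracle: apply the smoothing formula with plain loops
        words = ["ACGTAC", "ACGTAA", "TCGTAC", "ACGAAC"]
        background = [0.2, 0.3, 0.3, 0.2]
        pc = 0.5
        pwm = build_pwm(words, np.array(background), pseudocount=pc)
        for i in range(6):
            for b, base in enumerate("ACGT"):
                count = sum(1 for w in words if w[i] == base)
                expected = math.log2(
                    ((count + pc * background[b]) / (len(words) + pc))
                    / background[b]
                )
                assert pwm.weights[b, i] == pytest.approx(expected)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            build_pwm([], UNIFORM)
        with pytest.raises(ValueError):
            build_pwm(["ACGT"], UNIFORM)
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"], UNIFORM)


class TestComputeThreshold:
    def test_ten_percent_below_lowest_training_score(self):
        assert compute_threshold([20.0, 18.5, 22.1]) == pytest.approx(16.65)

    def test_single_site_edge(self):
        assert compute_threshold([10.0]) == pytest.approx(9.0)

    def test_rejects_non_positive_scores(self):
        with pytest.raises(ValueError):
            compute_threshold([5.0, -1.0])
        with pytest.raises(ValueError):
            compute_threshold([])


def _sharp_pwm(word="TGTGAGCGCTCACA", n=6):
    pwm = build_pwm([word] * n, UNIFORM)
    pwm.threshold = 0.8 * pwm.max_score()
    return pwm


class TestScanWindow:
    def test_consensus_found_at_planted_offset(self, rng):
        pwm = _sharp_pwm()
        flank = "".join(rng.choice(list("ACGT"), size=60))
        seq = flank + "TGTGAGCGCTCACA" + flank
        sites = scan_window(pwm, _region(seq))
        assert len(sites) == 1
        assert sites[0].position == 60
        assert sites[0].score == pytest.approx(pwm.max_score())
        assert sites[0].site_class == STRONG

    def test_palindromic_pwm_scores_both_strands_equally(self, rng):
        pwm = _sharp_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=200))
        fwd = scan_window(pwm, _region(seq))
        rev = scan_window(pwm, _region(reverse_complement(seq)))
        assert sorted(round(s.score, 6) for s in fwd) == sorted(
            round(s.score, 6) for s in rev
        )

    def test_short_region_yields_empty(self):
        assert scan_window(_sharp_pwm(), _region("ACGT")) == []

    def test_raising_threshold_never_adds_sites(self, rng):
        pwm = _sharp_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=400))
        counts = []
        for frac in (0.5, 0.65, 0.8, 0.95):
            pwm.threshold = frac * pwm.max_score()
            counts.append(len(scan_window(pwm, _region(seq))))
        assert counts == sorted(counts, reverse=True)


def naive_scan(pwm, region):
    """Brute-force oracle: enumerate every offset and strand, apply the
    weak-level cutoff and greedy best-first overlap collapsing."""
    w = pwm.width
    cands = []
    for strand_order, weights in enumerate(
        (pwm.weights, pwm.reverse_complement().weights)
    ):
        for off in range(len(region.sequence) - w + 1):
            word = region.sequence[off : off + w]
            score = 0.0
            for i, base in enumerate(word):
                if base in "ACGT":
                    score += weights["ACGT".index(base), i]
            if score >= 0.9 * pwm.threshold:
                cands.append((-round(score, 9), off, strand_order))
    cands.sort()
    taken, spans = [], []
    for negs, off, so in cands:
        if any(off < e and off + w > s for s, e in spans):
            continue
        taken.append((-negs, off, so))
        spans.append((off, off + w))
    return sorted(taken, key=lambda t: t[1])


def test_scan_window_matches_bruteforce_oracle_on_random_regions():
    rng = np.random.default_rng(77)
    words = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(5)]
    pwm = build_pwm(words, UNIFORM)
    pwm.threshold = 0.35 * pwm.max_score()  # permissive: many hits per region
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        region = _region(seq)
        got = [
            (round(s.score, 9), s.position, 0 if s.strand == "+" else 1)
            for s in scan_window(pwm, region)
        ]
        assert got == naive_scan(pwm, region)


def _site(genome, gene, rel, score, klass, word="TGTGAGCGCTCACA"):
    return Site(
        genome_id=genome, gene_id=gene, position=1000 + rel, strand="+",
        word=word, score=score, rel_position=rel, site_class=klass,
    )


class TestRescueWeakSites:
    def test_positionally_conserved_weak_site_is_rescued(self):
        weak = _site("G1", "a", -75, 9.5, WEAK)
        strong = _site("G2", "a2", -80, 12.0, STRONG)
        kept = rescue_weak_sites([weak], {"G2": [strong]})
        assert len(kept) == 1
        assert kept[0].site_class == WEAK_RESCUED

    def test_weak_site_with_stronger_competitor_is_dropped(self):
        weak = _site("G1", "a", -75, 9.5, WEAK)
        competitor = _site("G1", "a", -140, 9.9, WEAK)
        strong = _site("G2", "a2", -80, 12.0, STRONG)
        kept = rescue_weak_sites([weak, competitor], {"G2": [strong]})
        assert all(s.rel_position != -75 for s in kept)

    def test_weak_site_without_orthologous_support_is_dropped(self):
        weak = _site("G1", "a", -75, 9.5, WEAK)
        kept = rescue_weak_sites([weak], {})
        assert kept == []

    def test_strong_sites_pass_unconditionally(self):
        strong = _site("G1", "a", -75, 12.5, STRONG)
        assert rescue_weak_sites([strong], {}) == [strong]
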