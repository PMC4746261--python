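import numpy as np
import pytest

from regulonkit.genome_io import UpstreamRegion, reverse_complement
from regulonkit.motif_inference import (
    PWM,
    compare_motifs,
    discover_palindromic_motif,
    footprint_validate,
    palindromicity,
    read_meme,
    text_logo,
    write_meme,
)
from regulonkit.pwm_scanner import build_pwm

UNIFORM = np.full(4, 0.25)


def _region(seq, name="r", genome="G"):
    return UpstreamRegion(
        gene_id=name, genome_id=genome, sequence=seq,
        offset_of_start=len(seq), genomic_start=0, genomic_end=len(seq),
    )


class TestPalindromicity:
    @pytest.mark.parametrize(
        "word", ["TGTGAGCGCTCACA", "TGATAAAACGTTTTATCA"]
    )
    def test_printed_consensi_are_perfect_palindromes(self, word):
        assert palindromicity(word) == 0

    def test_homopolymer_word(self):
        assert palindromicity("AAAA") == 4

    def test_symmetric_pwm_has_zero_divergence(self):
        pwm = build_pwm(
            ["TGATAAAACGTTTTATCA"] * 4, UNIFORM, pseudocount=0.5
        )
        assert palindromicity(pwm) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_pwm_is_flagged(self):
        pwm = build_pwm(["AAAAAA", "AAAAAA", "AAAAAT"], UNIFORM)
        assert palindromicity(pwm) > 0


class TestPWM:
    def test_identical_sites_zero_pseudocount_reach_two_bits_per_column(self):
        pwm = build_pwm(["TGTGAGCGCTCACA"] * 6, UNIFORM, pseudocount=0.0)
        assert pwm.information_content() == pytest.approx(2 * pwm.width)

    def test_consensus_word_scores_the_maximum(self, rng):
        words = [
            "".join(rng.choice(list("ACGT"), size=12)) for _ in range(8)
        ]
        pwm = build_pwm(words, UNIFORM)
        consensus = "".join(
            "ACGT"[i] for i in pwm.counts.argmax(axis=0)
        )
        assert pwm.score_word(consensus) == pytest.approx(pwm.max_score())

    def test_reverse_complement_round_trip(self):
        pwm = build_pwm(["ACGTACGTAC", "ACGTACGAAC"], UNIFORM)
        back = pwm.reverse_complement().reverse_complement()
        assert np.allclose(back.counts, pwm.counts)


class TestCompareMotifs:
    def test_self_similarity_is_one(self):
        pwm = build_pwm(["TGATAAAACGTTTTATCA"] * 3, UNIFORM)
        assert compare_motifs(pwm, pwm) == pytest.approx(1.0)

    def test_orientation_invariance(self, rng):
        words = ["".join(rng.choice(list("ACGT"), size=18)) for _ in range(5)]
        pwm = build_pwm(words, UNIFORM)
        assert compare_motifs(pwm, pwm.reverse_complement()) == pytest.approx(
            1.0
        )

    def test_unrelated_motifs_score_low(self):
        # Monte-Carlo null: independent random PWMs should look dissimilar
        rng = np.random.default_rng(515)

        def rand_pwm():
            counts = rng.dirichlet(np.full(4, 0.7), size=18).T * 20
            return PWM(counts, UNIFORM)

        low = sum(
            compare_motifs(rand_pwm(), rand_pwm()) < 0.5 for _ in range(1000)
        )
        assert low >= 950


def _planted_regions(rng, consensus="TGATAAAACGTTTTATCA", n=8, length=120):
    """Random regions each containing the consensus with 0-2 substitutions."""
    regions = []
    for i in range(n):
        seq = list(rng.choice(list("ACGT"), size=length))
        word = list(consensus)
        for j in rng.choice(len(word), size=rng.integers(0, 3), replace=False):
            word[j] = rng.choice([b for b in "ACGT" if b != word[j]])
        pos = int(rng.integers(0, length - len(word)))
        seq[pos : pos + len(word)] = word
        regions.append(_region("".join(seq), f"r{i}"))
    return regions


def _oracle_best_18mer(regions):
    """Exhaustive oracle: the 18-mer with the best summed per-region match
    count (either orientation)."""
    words = set()
    for r in regions:
        for i in range(len(r.sequence) - 17):
            words.add(r.sequence[i : i + 18])
    best_word, best_total = None, -1
    for w in sorted(words):
        total = 0
        for r in regions:
            m = 0
            for i in range(len(r.sequence) - 17):
                window = r.sequence[i : i + 18]
                m = max(
                    m,
                    sum(a == b for a, b in zip(w, window)),
                    sum(
                        a == b
                        for a, b in zip(reverse_complement(w), window)
                    ),
                )
            total += m
        if total > best_total:
            best_word, best_total = w, total
    return best_word


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def test_discovery_recovers_planted_ribose_operator(rng):
    consensus = "TGATAAAACGTTTTATCA"
    regions = _planted_regions(rng, consensus)
    oracle = _oracle_best_18mer(regions)
    assert _hamming(oracle, consensus) <= 2  # the signal is recoverable
    pwm, hits = discover_palindromic_motif(
        regions, width_range=(14, 22), seed=0, background=UNIFORM
    )
    assert pwm is not None
    assert min(
        _hamming(pwm.consensus, consensus),
        _hamming(
            pwm.consensus, reverse_complement(consensus)
        ),
    ) <= 2
    assert len(hits) >= 7


def test_discovery_reports_no_motif_on_homopolymer():
    regions = [_region("A" * 80, f"r{i}") for i in range(6)]
    pwm, hits = discover_palindromic_motif(regions, seed=0)
    assert pwm is None and hits == []


def test_discovery_is_deterministic(rng):
    regions = _planted_regions(rng)
    a, _ = discover_palindromic_motif(regions, seed=5, background=UNIFORM)
    b, _ = discover_palindromic_motif(regions, seed=5, background=UNIFORM)
    assert a is not None
    assert np.array_equal(a.counts, b.counts)


def test_discovered_pwm_is_reverse_complement_symmetric(rng):
    regions = _planted_regions(rng)
    pwm, _ = discover_palindromic_motif(regions, seed=0, background=UNIFORM)
    assert pwm is not None
    assert palindromicity(pwm) < 0.2


def test_discovery_rejects_too_few_regions():
    with pytest.raises(ValueError):
        discover_palindromic_motif([_region("ACGT" * 30)])


class TestFootprintValidate:
    def _pwm(self):
        pwm = build_pwm(["TGTGAGCGCTCACA"] * 4, UNIFORM)
        pwm.threshold = 0.9 * pwm.max_score()
        return pwm

    def test_conserved_site_is_supported(self, rng):
        pwm = self._pwm()
        flank = "".join(rng.choice(list("ACGT"), size=40))
        regions = [
            _region(flank + "TGTGAGCGCTCACA" + flank, genome=f"G{i}")
            for i in range(3)
        ]
        supported, evidence = footprint_validate(pwm, None, regions, 2)
        assert supported and len(evidence) == 3

    def test_focal_only_site_is_not_supported(self, rng):
        pwm = self._pwm()
        regions = [
            _region("".join(rng.choice(list("ACGT"), size=90)), genome=f"G{i}")
            for i in range(3)
        ]
        supported, _ = footprint_validate(pwm, None, regions, 2)
        assert not supported


def test_meme_round_trip(tmp_path, rng):
    words = ["".join(rng.choice(list("ACGT"), size=16)) for _ in range(6)]
    pwm = build_pwm(words, np.array([0.2, 0.3, 0.3, 0.2]))
    path = tmp_path / "motifs.meme"
    write_meme({"m1": pwm}, str(path))
    back = read_meme(str(path))["m1"]
    assert back.width == pwm.width
    assert np.allclose(
        back.counts / back.counts.sum(axis=0),
        pwm.counts / pwm.counts.sum(axis=0),
        atol=1e-4,
    )


def test_text_logo_mentions_every_column(rng):
    pwm = build_pwm(["TGTGAGCGCTCACA"] * 3, UNIFORM)
    logo = text_logo(pwm)
    assert len(logo.splitlines()) == pwm.width + 1
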