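"""Palindromic TFBS motif inference and motif comparison.

The binding sites of homodimeric sugar-catabolism regulators (LacI, ROK,
TetR, DeoR families) are palindromes: the motif equals its own reverse
complement.  Discovery therefore runs expectation-maximization over a
one-occurrence-per-sequence model in which the position weight matrix is
constrained to column-wise reverse-complement symmetry (odd widths leave the
central column unconstrained).  Seeding targets the spaced-palindrome
structure of homodimer sites: half-site k-mers whose reverse complement
recurs at the motif's span, ranked by cross-region support.  The best
(width, seed) candidate by total information content x fraction of regions
hit wins.  Motifs weaker than a minimum information bound, hitting too few
training regions, or indistinguishable from a background null are reported
as "no motif".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import BASES, UpstreamRegion, encode, reverse_complement

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


@dataclass
class PWM:
    """Nucleotide position weight matrix with log-odds scoring.

    ``counts`` is a 4 x width matrix (rows A, C, G, T).  Weights are base-2
    log-odds against ``background`` after pseudocount smoothing:

        w[b, i] = log2( ((counts[b, i] + pc * bg[b]) / (n + pc)) / bg[b] )

    ``threshold`` is the calibrated site-score cutoff (set from training
    scores, see :func:`regulonkit.pwm_scanner.compute_threshold`).
    """

    counts: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.5
    threshold: float | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.background.shape != (4,) or abs(self.background.sum() - 1) > 1e-6:
            raise ValueError("background must be 4 frequencies summing to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def n_training_sites(self) -> float:
        return float(self.counts[:, 0].sum())

    @property
    def weights(self) -> np.ndarray:
        n = self.counts.sum(axis=0, keepdims=True)
        bg = self.background[:, None]
        probs = (self.counts + self.pseudocount * bg) / (n + self.pseudocount)
        with np.errstate(divide="ignore"):
            return np.log2(probs / bg)

    @property
    def probabilities(self) -> np.ndarray:
        n = self.counts.sum(axis=0, keepdims=True)
        bg = self.background[:, None]
        return (self.counts + self.pseudocount * bg) / (n + self.pseudocount)

    def information_content(self) -> float:
        """Total relative-entropy information content in bits (vs background).

        With zero pseudocount this is sum_i sum_b p log2(p / bg); zero
        probabilities contribute zero.
        """
        n = self.counts.sum(axis=0, keepdims=True)
        bg = self.background[:, None]
        if self.pseudocount > 0:
            p = (self.counts + self.pseudocount * bg) / (n + self.pseudocount)
        else:
            p = self.counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / bg), 0.0)
        return float(terms.sum())

    def column_information(self) -> np.ndarray:
        n = self.counts.sum(axis=0, keepdims=True)
        bg = self.background[:, None]
        p = (self.counts + self.pseudocount * bg) / (n + self.pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / bg), 0.0)
        return terms.sum(axis=0)

    @property
    def consensus(self) -> str:
        """IUPAC consensus; a column's code covers every base tying for the
        maximal count."""
        out = []
        for i in range(self.width):
            col = self.counts[:, i]
            top = col.max()
            bases = frozenset(BASES[b] for b in range(4) if col[b] == top)
            out.append(_IUPAC[bases])
        return "".join(out)

    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    def score_word(self, word: str) -> float:
        """Additive log-odds score of a single word; N bases score 0."""
        if len(word) != self.width:
            raise ValueError("word length must equal PWM width")
        w5 = np.vstack([self.weights, np.zeros(self.width)])
        return float(w5[encode(word), np.arange(self.width)].sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            counts=self.counts[::-1, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
            threshold=self.threshold,
        )


@dataclass(frozen=True)
class MotifHit:
    """A training-phase site: best motif occurrence within one region."""

    region: UpstreamRegion
    offset: int
    strand: str
    word: str
    score: float


def palindromicity(x) -> float:
    """Deviation from reverse-complement self-symmetry.

    For a DNA word: the number of positions at which the word differs from
    its reverse complement (0 iff perfectly self-reverse-complementary).
    For a :class:`PWM`: the mean column-wise L1 distance between the weight
    matrix and its reverse complement; for odd widths the unconstrained
    central column is excluded.
    """
    if isinstance(x, PWM):
        w = x.weights
        wrc = w[::-1, ::-1]
        diff = np.abs(w - wrc).sum(axis=0)
        if x.width % 2 == 1:
            diff = np.delete(diff, x.width // 2)
        if diff.size == 0:
            return 0.0
        return float(diff.mean())
    word = str(x)
    rc = reverse_complement(word)
    return float(sum(a != b for a, b in zip(word, rc)))


def _symmetrize(counts: np.ndarray) -> np.ndarray:
    """Average a count matrix with its reverse complement; odd widths keep
    the central column free."""
    w = counts.shape[1]
    sym = 0.5 * (counts + counts[::-1, ::-1])
    if w % 2 == 1:
        sym[:, w // 2] = counts[:, w // 2]
    return sym


def _palindromize(word: str) -> str:
    """Force a word to exact reverse-complement symmetry by mirroring its
    left half (the center of odd-width words is kept)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    chars = list(word)
    w = len(chars)
    for i in range(w // 2):
        chars[w - 1 - i] = comp[chars[i]]
    return "".join(chars)


def _region_background(regions) -> np.ndarray:
    counts = np.zeros(4)
    for r in regions:
        e = encode(r.sequence)
        for b in range(4):
            counts[b] += int((e == b).sum())
    freqs = counts / max(counts.sum(), 1.0)
    freqs = np.clip(freqs, 0.01, None)
    return freqs / freqs.sum()


def _window_scores(weights: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Scores of every forward-strand offset of a region (N scores 0)."""
    w = weights.shape[1]
    w5 = np.vstack([weights, np.zeros(w)])
    windows = sliding_window_view(enc, w)
    return w5[windows, np.arange(w)].sum(axis=1)


def _em(
    init_counts: np.ndarray,
    enc_regions: list[np.ndarray],
    background: np.ndarray,
    pseudocount: float,
    iters: int,
    tol: float,
) -> np.ndarray:
    """One-occurrence-per-sequence EM with the count matrix symmetrized
    after every M-step.  Deterministic."""
    counts = init_counts.copy()
    width = counts.shape[1]
    bg = background[:, None]
    windows = [sliding_window_view(e, width) for e in enc_regions]
    cols = np.arange(width)
    for _ in range(iters):
        n = counts.sum(axis=0, keepdims=True)
        probs = (counts + pseudocount * bg) / (n + pseudocount)
        weights = np.log2(probs / bg)
        w5 = np.vstack([weights, np.zeros(width)])
        new = np.zeros_like(counts)
        for win in windows:
            scores = w5[win, cols].sum(axis=1)
            m = scores.max()
            resp = np.exp2(scores - m)
            resp /= resp.sum()
            for b in range(4):
                new[b] += resp @ (win == b)
        new = _symmetrize(new)
        if np.abs(new - counts).max() < tol * max(len(enc_regions), 1):
            counts = new
            break
        counts = new
    return counts


def _best_hits(
    pwm: PWM,
    regions,
    enc_regions: list[np.ndarray],
    hit_score_fraction: float = 0.75,
) -> list[MotifHit]:
    """Best confident occurrence per region (ties -> leftmost).

    Only confident occurrences enter the training set: a region
    contributes its best site when that site scores positively and at
    least ``hit_score_fraction`` of the cohort's typical site score (the
    median per-region best), so regions without a real occurrence (e.g.
    the TF's own promoter when it is not autoregulated) are left out
    rather than dragging the score calibration down.
    """
    best: list[tuple[int, float]] = []
    for enc in enc_regions:
        scores = _window_scores(pwm.weights, enc)
        j = int(np.argmax(scores))
        best.append((j, float(scores[j])))
    median = float(np.median([s for _, s in best]))
    floor = max(hit_score_fraction * median, 0.0)
    hits = []
    for region, (j, score) in zip(regions, best):
        if score > floor:
            word = region.sequence[j : j + pwm.width]
            if "N" not in word:
                hits.append(MotifHit(region, j, "+", word, score))
    return hits


def _pwm_from_hits(
    hits: list[MotifHit], background: np.ndarray, pseudocount: float
) -> PWM:
    width = len(hits[0].word)
    counts = np.zeros((4, width))
    for h in hits:
        enc = encode(h.word)
        for i, b in enumerate(enc):
            counts[b, i] += 1
    return PWM(_symmetrize(counts), background, pseudocount)


def _seed_words(
    window_list: list[np.ndarray],
    width: int,
    restarts: int,
    n_fallback: int,
    half: int = 4,
) -> list[str]:
    """Candidate starting words for EM refinement.

    Primary seeding targets the spaced-palindrome structure of homodimer
    sites: a ``half``-mer whose reverse complement recurs ``width - half``
    positions downstream.  Half-sites are ranked by the number of regions
    containing such a pair, and each contributes the actual window word of
    its first occurrence.  If no spaced pair exists, the most palindromic
    full-width words (ranked by self-reverse-complement mismatches, then
    cross-region support) are used instead.
    """
    half = min(half, width // 2)
    support: dict[bytes, set[int]] = {}
    first_occurrence: dict[bytes, np.ndarray] = {}
    for r, win in enumerate(window_list):
        ok = (win < 4).all(axis=1)
        left = win[:, :half]
        right = win[:, width - half :]
        paired = ok & (left == (3 - right)[:, ::-1]).all(axis=1)
        for j in np.nonzero(paired)[0]:
            key = left[j].tobytes()
            support.setdefault(key, set()).add(r)
            if key not in first_occurrence:
                first_occurrence[key] = win[j].copy()
    if support:
        ranked = sorted(
            support, key=lambda k: (-len(support[k]), k)
        )
        return [
            "".join(BASES[b] for b in first_occurrence[k])
            for k in ranked[:restarts]
        ]
    # fallback: most palindromic full-width words with best cross-region
    # Hamming support
    allw = np.concatenate(window_list, axis=0)
    clean = allw[(allw < 4).all(axis=1)]
    if len(clean) == 0:
        return []
    rc = (3 - clean)[:, ::-1]
    mism = (clean != rc).sum(axis=1)
    idx = np.argsort(mism, kind="stable")
    cand_rows: list[np.ndarray] = []
    seen: set[bytes] = set()
    for j in idx:
        key = clean[j].tobytes()
        if key not in seen:
            seen.add(key)
            cand_rows.append(clean[j])
        if len(cand_rows) >= n_fallback:
            break
    cand = np.stack(cand_rows)
    hamming = np.zeros(len(cand))
    for win in window_list:
        w_ok = win[(win < 4).all(axis=1)]
        if len(w_ok) == 0:
            continue
        dist = (w_ok[None, :, :] != cand[:, None, :]).sum(axis=2)
        hamming += dist.min(axis=1)
    cand_mism = np.array([int((c != (3 - c)[::-1]).sum()) for c in cand])
    rank = np.lexsort((hamming, cand_mism))
    return ["".join(BASES[b] for b in cand[k]) for k in rank[:restarts]]


def _null_best_scores(
    pwm: PWM,
    background: np.ndarray,
    n_regions: int,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Best-window scores of the PWM over regions sampled i.i.d. from the
    background — the no-signal reference for significance checking."""
    out = np.empty(n_regions)
    for i in range(n_regions):
        enc = rng.choice(4, size=length, p=background).astype(np.int8)
        out[i] = float(_window_scores(pwm.weights, enc).max())
    return out


def _trim_flanks(counts: np.ndarray, background: np.ndarray,
                 pseudocount: float, min_col_ic: float, min_width: int):
    """Drop symmetric low-information flanking column pairs."""
    c = counts
    while c.shape[1] > min_width + 1:
        ic = PWM(c, background, pseudocount).column_information()
        if ic[0] < min_col_ic and ic[-1] < min_col_ic:
            c = c[:, 1:-1]
        else:
            break
    return c


def discover_palindromic_motif(
    regions: list[UpstreamRegion],
    width_range: tuple[int, int] = (14, 22),
    restarts: int = 5,
    seed: int = 0,
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
    min_total_ic: float = 8.0,
    min_hit_fraction: float = 0.6,
    n_seed_candidates: int = 120,
    em_iters: int = 30,
    trim_col_ic: float = 0.30,
    hit_score_fraction: float = 0.75,
    null_regions: int = 150,
    signal_margin: float = 2.0,
) -> tuple[PWM | None, list[MotifHit]]:
    """Discover a reverse-complement-symmetric motif shared by the regions.

    For every width in ``width_range``, seed words are drawn from
    over-represented spaced half-site pairs (falling back to the most
    palindromic full-width words), and the top ``restarts`` are refined by
    symmetric EM.  Low-information flanks are trimmed, and the candidate
    maximizing total information content x fraction of regions hit is
    returned together with its per-region best hits.  Returns
    ``(None, [])`` when no candidate reaches ``min_total_ic`` bits, hits
    at least ``min_hit_fraction`` of the regions, or scores significantly
    above a background null (the same PWM scanned over ``null_regions``
    background-sampled regions; the median training-hit score must exceed
    the null's 95th percentile by ``signal_margin`` bits).  Deterministic
    given the inputs and seed (the seed drives only the null sampling).
    """
    if len(regions) < 3:
        raise ValueError("motif discovery needs at least 3 training regions")
    wmin, wmax = width_range
    if all(len(r) < wmin for r in regions):
        raise ValueError(f"all regions shorter than minimum width {wmin}")
    if background is None:
        background = _region_background(regions)
    else:
        background = np.clip(np.asarray(background, dtype=float), 0.01, None)
        background = background / background.sum()

    enc_all = [encode(r.sequence) for r in regions]
    best = None  # (metric, -width, order, pwm, hits)
    order = 0
    for width in range(wmin, wmax + 1):
        usable = [
            (r, e) for r, e in zip(regions, enc_all) if len(e) >= width
        ]
        if len(usable) < 3:
            continue
        regs = [r for r, _ in usable]
        encs = [e for _, e in usable]
        window_list = [sliding_window_view(e, width) for e in encs]
        seed_words = _seed_words(
            window_list, width, restarts, n_seed_candidates
        )
        for word in seed_words:
            pal = _palindromize(word)
            init = np.full((4, width), 0.1 * len(regs))
            for i, b in enumerate(encode(pal)):
                init[b, i] += 0.6 * len(regs)
            init = _symmetrize(init)
            counts = _em(init, encs, background, pseudocount, em_iters, 1e-5)
            pwm0 = PWM(counts, background, pseudocount)
            hits0 = _best_hits(pwm0, regs, encs, hit_score_fraction)
            if len(hits0) < 2:
                order += 1
                continue
            tallied = _pwm_from_hits(hits0, background, pseudocount)
            trimmed = _trim_flanks(
                tallied.counts, background, pseudocount, trim_col_ic, wmin
            )
            pwm = PWM(trimmed, background, pseudocount)
            hits = _best_hits(pwm, regs, encs, hit_score_fraction)
            if len(hits) < 2:
                order += 1
                continue
            pwm = _pwm_from_hits(hits, background, pseudocount)
            hits = [
                MotifHit(h.region, h.offset, h.strand, h.word,
                         pwm.score_word(h.word))
                for h in _best_hits(pwm, regs, encs, hit_score_fraction)
            ]
            if not hits:
                order += 1
                continue
            hit_fraction = len(hits) / len(regs)
            metric = pwm.information_content() * hit_fraction
            entry = (metric, -pwm.width, -order, pwm, hits, hit_fraction)
            if best is None or entry[:3] > best[:3]:
                best = entry
            order += 1
    if best is None:
        return None, []
    metric, _, _, pwm, hits, hit_fraction = best
    if pwm.information_content() < min_total_ic or hit_fraction < min_hit_fraction:
        return None, []
    if null_regions > 0:
        rng = np.random.default_rng(seed)
        length = int(np.median([len(r) for r in regions]))
        null = _null_best_scores(pwm, background, null_regions, length, rng)
        signal = float(np.median([h.score for h in hits]))
        if signal < float(np.quantile(null, 0.95)) + signal_margin:
            return None, []
    return pwm, hits


def compare_motifs(a: PWM, b: PWM, max_shift: int = 4) -> float:
    """Orientation- and shift-invariant motif similarity in [0, 1].

    The best mean column-wise Pearson correlation of weight columns over all
    ungapped offsets (overlap at least ``min(width) - max_shift`` columns) of
    both orientations of ``b``, clipped to [0, 1].  A motif against itself
    or its reverse complement scores 1.
    """
    wa, wb = a.weights, b.weights
    min_overlap = max(4, min(wa.shape[1], wb.shape[1]) - max_shift)

    def _standardize(w: np.ndarray):
        c = w - w.mean(axis=0, keepdims=True)
        s = np.sqrt((c**2).sum(axis=0))
        degenerate = s < 1e-12
        s = np.where(degenerate, 1.0, s)
        return c / s, degenerate, c

    za, dega, ca = _standardize(wa)
    best = -1.0
    for bw in (wb, b.reverse_complement().weights):
        zb, degb, cb = _standardize(bw)
        na, nb = za.shape[1], zb.shape[1]
        for shift in range(-(nb - min_overlap), na - min_overlap + 1):
            a_lo, b_lo = max(0, shift), max(0, -shift)
            overlap = min(na - a_lo, nb - b_lo)
            if overlap < min_overlap:
                continue
            xa = za[:, a_lo : a_lo + overlap]
            xb = zb[:, b_lo : b_lo + overlap]
            corr = (xa * xb).sum(axis=0)
            both_deg = dega[a_lo : a_lo + overlap] & degb[b_lo : b_lo + overlap]
            if both_deg.any():
                same = np.isclose(
                    ca[:, a_lo : a_lo + overlap], cb[:, b_lo : b_lo + overlap]
                ).all(axis=0)
                corr = np.where(both_deg, np.where(same, 1.0, 0.0), corr)
            best = max(best, float(corr.mean()))
    return float(np.clip(best, 0.0, 1.0))


def footprint_validate(
    pwm: PWM,
    focal_site,
    ortholog_regions: list[UpstreamRegion],
    min_support: int = 2,
) -> tuple[bool, dict[str, float]]:
    """Cross-genome conservation check for one site.

    A focal site is supported when at least ``min_support`` upstream regions
    of orthologs of its target gene contain a hit scoring at least 0.9 x the
    PWM threshold (the weak-site level).  Returns the verdict plus the best
    score per ortholog genome.
    """
    if pwm.threshold is None:
        raise ValueError("pwm.threshold must be set before footprinting")
    level = 0.9 * pwm.threshold
    evidence: dict[str, float] = {}
    n_support = 0
    for region in ortholog_regions:
        if len(region) < pwm.width:
            continue
        enc = encode(region.sequence)
        fwd = _window_scores(pwm.weights, enc)
        rev = _window_scores(pwm.reverse_complement().weights, enc)
        score = float(max(fwd.max(), rev.max()))
        evidence[region.genome_id] = score
        if score >= level:
            n_support += 1
    return n_support >= min_support, evidence


# ---------------------------------------------------------------------------
# MEME minimal motif format and text logos


def write_meme(pwms: dict[str, PWM], path: str) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    first = next(iter(pwms.values()))
    bg = first.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(BASES)) + "\n\n"
        )
        for name, pwm in pwms.items():
            n = max(int(round(pwm.n_training_sites)), 1)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {n} E= 0\n"
            )
            probs = pwm.counts / pwm.counts.sum(axis=0, keepdims=True)
            for i in range(pwm.width):
                fh.write(" " + " ".join(f"{probs[b, i]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")


def read_meme(path: str, pseudocount: float = 0.5) -> dict[str, PWM]:
    """Read MEME minimal format back into PWMs (counts = nsites x probs)."""
    pwms: dict[str, PWM] = {}
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array(
                [float(parts[parts.index(b) + 1]) for b in BASES]
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i].strip()
            tokens = header.replace(":", " ").split()
            w = int(tokens[tokens.index("w=") + 1])
            n = int(tokens[tokens.index("nsites=") + 1])
            rows = []
            i += 1
            for _ in range(w):
                rows.append([float(x) for x in lines[i].split()])
                i += 1
            probs = np.array(rows).T  # 4 x w
            pwms[name] = PWM(probs * n, background, pseudocount)
            continue
        i += 1
    return pwms


def text_logo(pwm: PWM, bar_width: int = 20) -> str:
    """A plain-text sequence logo: per-column information content bars and
    the IUPAC consensus."""
    ic = pwm.column_information()
    consensus = pwm.consensus
    lines = [f"width={pwm.width} total_IC={pwm.information_content():.2f} bits"]
    for i in range(pwm.width):
        bar = "#" * int(round(bar_width * min(ic[i], 2.0) / 2.0))
        lines.append(f"{i + 1:3d} {consensus[i]} {ic[i]:5.2f} {bar}")
    return "\n".join(lines)
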