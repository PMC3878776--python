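"""Binding-site motif models and discovery.

Two motif architectures dominate carbohydrate-utilization regulators in
*Bacteroides*-type genomes and are modelled here explicitly:

* **direct repeats (spaced dyads)** — two similar boxes in the same
  orientation separated by a fixed-length non-conserved spacer, bound by
  dimers sitting on the same face of the DNA (e.g. two 16-bp boxes with a
  5-bp spacer, 21 bp center-to-center);
* **palindromes** — reverse-complement-symmetric motifs bound by
  head-to-head dimers (e.g. a 22-bp Crp-like box).

PWMs are log-odds matrices with an additive background-weighted pseudocount:

    pwm[b][j] = log2( (count[b][j] + p * bg[b]) / (n + p) / bg[b] )

and per-column information content sum_b f[b][j] * log2(f[b][j] / bg[b])
with f the pseudocounted frequencies.  Spacer columns of direct repeats are
never scored; only the two boxes, at their fixed separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import IUPAC_SETS, decode, encode, iupac_revcomp

NEG_INF = float("-inf")

#: printed motif geometries of the reference regulon collection
HTCS_MAN_GEOMETRY = ("direct_repeat", 16, 5)
HTCS_RGU1_GEOMETRY = ("direct_repeat", 12, 9)
HTCS_RGU2_GEOMETRY = ("direct_repeat", 14, 6)
SUSR_CENTER_DISTANCES = (67, 77)
HTCS_MEAN_CENTER_DISTANCE = 21
CRP_PALINDROME_LENGTH = 22


class DiscoveryError(RuntimeError):
    """Motif discovery failed to produce a stable model."""


@dataclass(frozen=True)
class MotifGeometry:
    kind: str  # direct_repeat | palindrome | generic
    box_len: int | None = None
    spacer: int | None = None
    total_len: int | None = None

    def __post_init__(self):
        if self.kind == "direct_repeat":
            if self.box_len is None or self.spacer is None:
                raise ValueError("direct_repeat geometry needs box_len and spacer")
            object.__setattr__(self, "total_len", 2 * self.box_len + self.spacer)
        elif self.total_len is None:
            raise ValueError(f"{self.kind} geometry needs total_len")

    @property
    def center_distance(self) -> int | None:
        """Start-to-start (= center-to-center) distance of the two boxes."""
        if self.kind != "direct_repeat":
            return None
        return self.box_len + self.spacer

    @property
    def scoring_length(self) -> int:
        return 2 * self.box_len if self.kind == "direct_repeat" else self.total_len

    def scored_offsets(self) -> np.ndarray:
        """Offsets within the full site that are scored (spacer excluded)."""
        if self.kind == "direct_repeat":
            b, s = self.box_len, self.spacer
            return np.concatenate([np.arange(b), np.arange(b + s, 2 * b + s)])
        return np.arange(self.total_len)


@dataclass
class MotifModel:
    geometry: MotifGeometry
    counts: np.ndarray          # 4 x scoring_length
    background: np.ndarray      # length-4, strictly positive, sums to 1
    pseudocount: float = 0.5
    training_sites: list = field(default_factory=list)  # site strings or SiteHits
    freqs_override: np.ndarray | None = None  # e.g. symmetrized EM frequencies

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must be 4 x L")
        if (self.background <= 0).any():
            raise ValueError("background entries must be strictly positive")

    @property
    def n_sites(self) -> float:
        return float(self.counts[:, 0].sum())

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Pseudocounted position frequency matrix."""
        if self.freqs_override is not None:
            return self.freqs_override
        n = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount * self.background[:, None]) / (
            n + self.pseudocount)

    @property
    def pwm(self) -> np.ndarray:
        """Log-odds matrix in bits."""
        return np.log2(self.freqs / self.background[:, None])

    @property
    def information_content(self) -> np.ndarray:
        """Per-column IC in bits relative to the background."""
        f = self.freqs
        return (f * np.log2(f / self.background[:, None])).sum(axis=0)

    @property
    def total_information(self) -> float:
        return float(self.information_content.sum())

    def score_word(self, word: str) -> float:
        return score_word(self, word)

    def score_site(self, site: str) -> float:
        """Score a full-length site (spacer included for direct repeats)."""
        if len(site) != self.geometry.total_len:
            raise ValueError(
                f"site length {len(site)} != motif length {self.geometry.total_len}")
        codes = encode(site)[self.geometry.scored_offsets()]
        if (codes > 3).any():
            return NEG_INF
        return float(self.pwm[codes, np.arange(self.width)].sum())

    def consensus(self, strong: float = 0.7, weak_pair: float = 0.8) -> str:
        return consensus(self, strong, weak_pair)


def estimate_background(sequences) -> np.ndarray:
    """Base frequencies of the input sequences (ambiguous bases ignored)."""
    counts = np.zeros(4)
    for s in sequences:
        codes = encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise DiscoveryError("no unambiguous bases in input sequences")
    # floor to keep the background strictly positive
    freqs = np.maximum(counts / total, 1e-6)
    return freqs / freqs.sum()


def build_pwm(sites, background=None, pseudocount: float = 0.5,
              geometry: MotifGeometry | None = None) -> MotifModel:
    """Build a motif model from equal-length training sites.

    ``sites`` may be scoring-length words (boxes concatenated for a direct
    repeat) or, when a direct-repeat geometry is given, full-length sites
    whose spacer columns are stripped before counting.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("build_pwm requires at least one site")
    lengths = {len(s) for s in sites}
    if len(lengths) != 1:
        raise ValueError(f"sites have unequal lengths {sorted(lengths)}")
    L = lengths.pop()
    if geometry is None:
        geometry = MotifGeometry("generic", total_len=L)
    if L == geometry.total_len:
        offsets = geometry.scored_offsets()
    elif L == geometry.scoring_length:
        offsets = np.arange(L)
    else:
        raise ValueError(
            f"site length {L} matches neither total ({geometry.total_len}) "
            f"nor scoring ({geometry.scoring_length}) length")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if (background <= 0).any():
        raise ValueError("background entries must be strictly positive")
    counts = np.zeros((4, len(offsets)))
    for s in sites:
        codes = encode(s.upper())[offsets]
        if (codes > 3).any():
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        counts[codes, np.arange(len(offsets))] += 1
    return MotifModel(geometry=geometry, counts=counts, background=background,
                      pseudocount=pseudocount, training_sites=sites)


def score_word(model: MotifModel, word: str) -> float:
    """Sum of per-position log-odds over the scoring-length word; N -> -inf."""
    if len(word) != model.width:
        raise ValueError(f"word length {len(word)} != scoring length {model.width}")
    codes = encode(word.upper())
    if (codes > 3).any():
        return NEG_INF
    return float(model.pwm[codes, np.arange(model.width)].sum())


def _window_scores(codes: np.ndarray, pwm: np.ndarray,
                   offsets: np.ndarray) -> np.ndarray:
    """Scores of all full-length windows of a coded sequence; N -> -inf."""
    total = int(offsets[-1]) + 1
    n = len(codes) - total + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    safe = np.minimum(codes, 3)
    for j, off in enumerate(offsets):
        col = codes[off:off + n]
        scores += pwm[safe[off:off + n], j]
        bad |= col > 3
    scores[bad] = NEG_INF
    return scores


def _repeat_similarity(codes: np.ndarray, box_len: int, gap: int) -> np.ndarray:
    """Matches between the two boxes of every candidate dyad start."""
    d = box_len + gap
    eq = (codes[:-d] == codes[d:]) & (codes[:-d] < 4)
    if len(eq) < box_len:
        return np.empty(0, dtype=int)
    kern = np.ones(box_len, dtype=int)
    sims = np.convolve(eq.astype(int), kern, mode="valid")
    # candidate start p needs the full window p .. p+2b+gap
    n = len(codes) - (2 * box_len + gap) + 1
    return sims[:n]


def discover_direct_repeat(sequences, box_len_range=(10, 18),
                           spacer_range=(3, 12), n_seeds: int = 5,
                           seed: int = 0, pseudocount: float = 0.5,
                           background=None, col_penalty: float = 0.5,
                           max_iter: int = 50,
                           extended_centers=None) -> MotifModel:
    """Grid search for the best spaced-dyad motif.

    For every (box_len, spacer) geometry in the grid, candidate dyads are
    seeded greedily from positions where the two boxes already resemble each
    other, then refined by one-occurrence-per-sequence iteration (re-pick the
    best-scoring occurrence in every sequence, rebuild the PWM) to an
    occupancy fixed point.  The returned model maximizes the penalized
    information content sum_j (IC_j - col_penalty): the per-column penalty
    removes the length bias that raw total IC has on finite samples, so box
    boundaries land on the conserved columns.  ``extended_centers`` adds
    long-range geometries (e.g. center distances 60-80 for SusR-type dimers).
    Deterministic given ``seed``.
    """
    sequences = [s.upper() for s in sequences]
    if len(sequences) < 3:
        raise ValueError("discover_direct_repeat requires >= 3 sequences")
    coded = [encode(s) for s in sequences]
    if all((c > 3).all() for c in coded):
        raise DiscoveryError("all input sequences are ambiguous")
    if background is None:
        background = estimate_background(sequences)
    geometries = [
        MotifGeometry("direct_repeat", b, s)
        for b in range(box_len_range[0], box_len_range[1] + 1)
        for s in range(spacer_range[0], spacer_range[1] + 1)
    ]
    if extended_centers is not None:
        for b in range(box_len_range[0], box_len_range[1] + 1):
            for center in extended_centers:
                if center - b >= 1:
                    geometries.append(MotifGeometry("direct_repeat", b, center - b))
    rng = np.random.default_rng(seed)  # reserved for stochastic seeding modes
    del rng
    best = None
    for geom in geometries:
        model = _refine_geometry(coded, geom, n_seeds, pseudocount, background,
                                 col_penalty, max_iter)
        if model is None:
            continue
        objective = _dyad_objective(model, col_penalty)
        key = (objective, -geom.box_len, -geom.spacer)
        if best is None or key > best[0]:
            best = (key, model)
    if best is None:
        raise DiscoveryError("no geometry fits the input sequences")
    return best[1]


def _dyad_objective(model: MotifModel, col_penalty: float) -> float:
    """Penalized information content of the pooled box model.

    A direct repeat is one recognition box bound twice, so the two box
    occurrences of every site are pooled column-wise before measuring IC.
    Pooling is what makes box boundaries identifiable: a column that is
    conserved in only one box (e.g. a conserved flanking base swept in by an
    over-wide box) mixes with the other box's unconserved column and loses
    its information, while true box columns stay sharp in both copies.
    """
    b = model.geometry.box_len
    pooled = model.counts[:, :b] + model.counts[:, b:]
    n = pooled[:, 0].sum()
    bg = model.background[:, None]
    f = (pooled + model.pseudocount * bg) / (n + model.pseudocount)
    ic = (f * np.log2(f / bg)).sum(axis=0)
    return 2.0 * float((ic - col_penalty).sum())


def _refine_geometry(coded, geom, n_seeds, pseudocount, background,
                     col_penalty, max_iter):
    b, s = geom.box_len, geom.spacer
    total = geom.total_len
    offsets = geom.scored_offsets()
    width = len(offsets)
    cols = np.arange(width)
    usable = [c for c in coded if len(c) >= total]
    if len(usable) < 3:
        return None
    # precompute the scored window matrix of every sequence once per geometry
    windows = []  # (W: n x width codes, bad: n bools)
    for c in usable:
        sw = np.lib.stride_tricks.sliding_window_view(c, total)[:, offsets]
        windows.append((np.minimum(sw, 3), (sw > 3).any(axis=1)))
    # seeds: dyad starts whose boxes best match each other
    cands = []
    for si, c in enumerate(usable):
        sims = _repeat_similarity(c, b, s)
        for p in np.argsort(sims, kind="stable")[::-1][:n_seeds]:
            cands.append((int(sims[p]), si, int(p)))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    seeds = cands[:n_seeds]
    bg_col = background[:, None]
    best = None
    for _, si, p in seeds:
        occupancy = {si: p}
        counts = _counts_from_occupancy(usable, occupancy, offsets)
        n_occ = 1.0
        for _ in range(max_iter):
            f = (counts + pseudocount * bg_col) / (n_occ + pseudocount)
            pwm = np.log2(f / bg_col)
            new_occ = {}
            for sj, (W, bad) in enumerate(windows):
                scores = pwm[W, cols].sum(axis=1)
                scores[bad] = NEG_INF
                new_occ[sj] = int(np.argmax(scores))
            if new_occ == occupancy:
                occupancy = new_occ
                break
            occupancy = new_occ
            counts = _counts_from_occupancy(usable, occupancy, offsets)
            n_occ = float(len(occupancy))
        model = MotifModel(geom, _counts_from_occupancy(usable, occupancy, offsets),
                           background, pseudocount)
        model.training_sites = [
            decode(usable[sj][p:p + total]) for sj, p in sorted(occupancy.items())]
        objective = _dyad_objective(model, col_penalty)
        if best is None or objective > best[0]:
            best = (objective, model)
    return None if best is None else best[1]


def _counts_from_occupancy(coded, occupancy, offsets):
    counts = np.zeros((4, len(offsets)))
    for si, p in occupancy.items():
        codes = np.minimum(coded[si][p + offsets], 3)
        counts[codes, np.arange(len(offsets))] += 1
    return counts


def _symmetrize(f: np.ndarray) -> np.ndarray:
    """Average a frequency matrix with its reverse complement (exact)."""
    comp = f[::-1, ::-1]  # complement base order is the reverse of A,C,G,T
    return (f + comp) / 2


def discover_palindrome_em(sequences, motif_len: int = 22,
                           n_restarts: int = 20, seed: int = 0,
                           mode: str = "oops", pseudocount: float = 0.5,
                           background=None, tol: float = 1e-6,
                           max_iter: int = 200) -> MotifModel:
    """EM discovery of a palindrome-constrained motif.

    A one-occurrence-per-sequence (OOPS) missing-data model: the E-step
    computes the posterior over start positions in every sequence, the M-step
    re-estimates the frequency matrix from expected counts and then averages
    it with its own reverse complement, so the motif is exactly
    reverse-complement symmetric after every iteration.  ``mode='zoops'``
    adds a no-occurrence component.  Best of ``n_restarts`` random
    initializations by information content; deterministic given ``seed``.
    """
    sequences = [s.upper() for s in sequences]
    if len(sequences) < 3:
        raise ValueError("discover_palindrome_em requires >= 3 sequences")
    if motif_len > min(len(s) for s in sequences):
        raise ValueError("motif_len exceeds the shortest sequence")
    if mode not in ("oops", "zoops"):
        raise ValueError("mode must be 'oops' or 'zoops'")
    coded = [encode(s) for s in sequences]
    if background is None:
        background = estimate_background(sequences)
    background = np.asarray(background, dtype=float)
    geom = MotifGeometry("palindrome", total_len=motif_len)
    offsets = np.arange(motif_len)
    rng = np.random.default_rng(seed)
    log_bg = np.log2(background)
    best = None
    for _ in range(n_restarts):
        # init from one random window per sequence
        occ = {si: int(rng.integers(0, len(c) - motif_len + 1))
               for si, c in enumerate(coded)}
        counts = _counts_from_occupancy(coded, occ, offsets)
        f = (counts + pseudocount * background[:, None]) / (
            len(coded) + pseudocount)
        f = _symmetrize(f)
        gamma = 0.5  # zoops occurrence prior
        for _ in range(max_iter):
            logf = np.log2(f)
            exp_counts = np.zeros((4, motif_len))
            total_occ = 0.0
            for c in coded:
                n = len(c) - motif_len + 1
                safe = np.minimum(c, 3)
                llr = np.zeros(n)
                for j in range(motif_len):
                    llr += logf[safe[j:j + n], j] - log_bg[safe[j:j + n]]
                w = np.exp2(llr - llr.max())
                if mode == "zoops":
                    null_w = np.exp2(-llr.max()) * (1 - gamma) * n / max(gamma, 1e-9)
                    z = w / (w.sum() + null_w)
                else:
                    z = w / w.sum()
                total_occ += z.sum()
                for j in range(motif_len):
                    exp_counts[:, j] += np.bincount(
                        safe[j:j + n], weights=z, minlength=4)
            if mode == "zoops":
                gamma = min(max(total_occ / len(coded), 1e-3), 1 - 1e-3)
            denom = total_occ + pseudocount
            f_new = _symmetrize(
                (exp_counts + pseudocount * background[:, None]) / denom)
            delta = np.abs(f_new - f).max()
            f = f_new
            if delta < tol:
                break
        model = MotifModel(geom, np.zeros((4, motif_len)), background,
                           pseudocount, freqs_override=f)
        ic = model.total_information
        if best is None or ic > best[0]:
            best = (ic, f)
    f = best[1]
    # hard-assign the best occurrence per sequence as training sites
    model = MotifModel(geom, np.zeros((4, motif_len)), background, pseudocount,
                       freqs_override=f)
    occ = {}
    for si, c in enumerate(coded):
        scores = _window_scores(c, model.pwm, offsets)
        occ[si] = int(np.argmax(scores))
    counts = _counts_from_occupancy(coded, occ, offsets)
    final = MotifModel(geom, counts, background, pseudocount,
                       freqs_override=f)
    final.training_sites = [
        decode(coded[si][p:p + motif_len]) for si, p in sorted(occ.items())]
    return final


_PAIR_CODES = {
    frozenset("AG"): "r", frozenset("CT"): "y", frozenset("CG"): "s",
    frozenset("AT"): "w", frozenset("GT"): "k", frozenset("AC"): "m",
}


def consensus(model: MotifModel, strong: float = 0.7,
              weak_pair: float = 0.8) -> str:
    """IUPAC consensus: a capital base where one base dominates, a lowercase
    two-base code where a pair dominates, else 'n'.  Direct-repeat spacers
    appear as 'n's so the string has the motif's full printed length."""
    f = model.freqs
    letters = []
    for j in range(f.shape[1]):
        order = np.argsort(f[:, j], kind="stable")[::-1]
        if f[order[0], j] >= strong:
            letters.append("ACGT"[order[0]])
        elif f[order[0], j] + f[order[1], j] >= weak_pair:
            pair = frozenset("ACGT"[k] for k in order[:2])
            letters.append(_PAIR_CODES[pair])
        else:
            letters.append("n")
    if model.geometry.kind == "direct_repeat":
        b = model.geometry.box_len
        return "".join(letters[:b]) + "n" * model.geometry.spacer + \
            "".join(letters[b:])
    return "".join(letters)


def is_palindromic(c: str) -> bool:
    """True iff the IUPAC string equals its IUPAC reverse complement."""
    cu = c.upper()
    bad = set(cu) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"invalid IUPAC symbols {sorted(bad)}")
    return cu == iupac_revcomp(cu)


def to_meme(models: dict[str, MotifModel]) -> str:
    """MEME minimal-format motif text."""
    first = next(iter(models.values()))
    bg = first.background
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
             "Background letter frequencies",
             f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}", ""]
    for name, m in models.items():
        f = m.freqs
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.width} "
            f"nsites= {max(int(round(m.n_sites)), 1)} E= 0")
        for j in range(m.width):
            lines.append(" ".join(f"{f[b, j]:.6f}" for b in range(4)))
        lines.append("")
    return "\n".join(lines)


def to_transfac(name: str, model: MotifModel) -> str:
    """TRANSFAC-style count matrix."""
    lines = ["ID " + name, "BF synthetic", "P0\tA\tC\tG\tT"]
    for j in range(model.width):
        vals = "\t".join(f"{model.counts[b, j]:.0f}" for b in range(4))
        lines.append(f"{j + 1:02d}\t{vals}")
    lines.append("XX")
    lines.append("//")
    return "\n".join(lines) + "\n"


def text_logo(model: MotifModel, width: int = 40) -> str:
    """Plain-text logo: per-column IC bars plus the consensus letter."""
    ic = model.information_content
    cons = consensus(model)
    if model.geometry.kind == "direct_repeat":
        cons = cons[:model.geometry.box_len] + cons[
            model.geometry.box_len + model.geometry.spacer:]
    lines = []
    for j, (bits, letter) in enumerate(zip(ic, cons)):
        bar = "#" * int(round(bits / 2 * width))
        lines.append(f"{j + 1:3d} {letter} {bits:5.2f} {bar}")
    return "\n".join(lines) + "\n"
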