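"""Phylogenetic footprinting: align orthologous upstream regions, find
islands of conservation, and emit candidate binding sites.

Functional DNA (binding sites) diverges more slowly than intergenic spacer
sequence, so conserved blocks in a multiple alignment of orthologous upstream
regions are candidate regulatory sites.  The built-in aligner is a
deterministic progressive global aligner (guide tree from pairwise distances;
match +1, mismatch -1, gap -2); any aligner whose output degaps back to the
input sequences can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree

from ._seq import encode

GAP = "-"
# row order: A C G T N gap
_CHAR_IDX = {c: i for i, c in enumerate("ACGTN-")}


@dataclass
class UpstreamAlignment:
    region_ids: list[str]
    rows: list[str]
    regions: list = field(default_factory=list)  # parallel UpstreamRegion list

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass
class ConservationIsland:
    span: tuple[int, int]  # alignment column span, half-open
    mean_identity: float
    #: region_id -> (start, end, subsequence) in region (ungapped) coordinates
    row_segments: dict[str, tuple[int, int, str]]

    @property
    def center(self) -> float:
        return (self.span[0] + self.span[1]) / 2


def _nw_matrix(colscore: np.ndarray, gap: float) -> np.ndarray:
    """Full global-alignment score matrix under linear gap costs.

    The left-dependency of each DP row is resolved in closed form: with
    cur[j] = max(best[j-1], cur[j-1] + gap), the shifted quantity
    t[j] = cur[j] - gap*j is a running maximum, so each row is a single
    ``np.maximum.accumulate``.
    """
    la, lb = colscore.shape
    S = np.empty((la + 1, lb + 1))
    j = np.arange(1, lb + 1)
    S[0] = gap * np.arange(lb + 1)
    for i in range(1, la + 1):
        diag = S[i - 1, :-1] + colscore[i - 1]
        up = S[i - 1, 1:] + gap
        best = np.maximum(diag, up)
        cur0 = gap * i
        t = np.maximum.accumulate(np.concatenate(([cur0], best - gap * j)))
        S[i, 0] = cur0
        S[i, 1:] = t[1:] + gap * j
    return S


def _pairwise_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Global NW score of two sequences."""
    xa, xb = encode(a), encode(b)
    colscore = np.where(xa[:, None] == xb[None, :], match, mismatch)
    return float(_nw_matrix(colscore, gap)[-1, -1])


def _profile(rows: list[str]) -> np.ndarray:
    """6 x L column frequency profile over A,C,G,T,N,gap."""
    arr = np.array([[_CHAR_IDX[c] for c in r] for r in rows], dtype=np.int8)
    prof = np.zeros((6, arr.shape[1]))
    for k in range(6):
        prof[k] = (arr == k).mean(axis=0)
    return prof


# substitution scores between profile symbols (N matches nothing specially)
_SCORE6 = np.full((6, 6), -1.0)
np.fill_diagonal(_SCORE6, 1.0)
_SCORE6[4, :] = _SCORE6[:, 4] = 0.0   # N: neutral
_SCORE6[5, :] = _SCORE6[:, 5] = -2.0  # residue vs gap char
_SCORE6[5, 5] = 0.0


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    gap=-2.0) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment; returns the two gapped row blocks."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[1], pb.shape[1]
    # column-column expected substitution score
    colscore = pa.T @ _SCORE6 @ pb
    S = _nw_matrix(colscore, gap)
    # traceback; move preference diag > up > left for determinism
    eps = 1e-9
    i, j = la, lb
    ops = []  # 0 diag, 1 up (column from a), 2 left (column from b)
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(S[i, j] - (S[i - 1, j - 1] + colscore[i - 1, j - 1])) <= eps:
            ops.append(0)
            i, j = i - 1, j - 1
        elif i > 0 and abs(S[i, j] - (S[i - 1, j] + gap)) <= eps:
            ops.append(1)
            i -= 1
        else:
            ops.append(2)
            j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for p in ops:
        if p in (0, 1):
            for r, row in zip(rows_a, out_a):
                row.append(r[ia])
            ia += 1
        else:
            for row in out_a:
                row.append(GAP)
        if p in (0, 2):
            for r, row in zip(rows_b, out_b):
                row.append(r[ib])
            ib += 1
        else:
            for row in out_b:
                row.append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def align_upstreams(regions) -> UpstreamAlignment:
    """Progressive global multiple alignment of upstream regions.

    Guide tree: average-linkage clustering of pairwise NW distances.
    Deterministic given input order.
    """
    if len(regions) < 2:
        raise ValueError("align_upstreams requires >= 2 regions")
    ids = [f"{r.genome_id}:{r.gene_id}" for r in regions]
    seqs = [r.sequence.upper() for r in regions]
    n = len(seqs)
    if n == 2:
        a, b = _align_profiles([seqs[0]], [seqs[1]])
        return UpstreamAlignment(ids, [a[0], b[0]], list(regions))
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = _pairwise_score(seqs[i], seqs[j])
            # convert score to a distance: higher score -> smaller distance
            dist[i, j] = dist[j, i] = max(len(seqs[i]), len(seqs[j])) - s
    iu = np.triu_indices(n, 1)
    z = linkage(dist[iu], method="average")
    root = to_tree(z)

    def merge(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return [node.id], [seqs[node.id]]
        idx_l, rows_l = merge(node.left)
        idx_r, rows_r = merge(node.right)
        out_l, out_r = _align_profiles(rows_l, rows_r)
        return idx_l + idx_r, out_l + out_r

    order, rows = merge(root)
    by_input = [None] * n
    for pos, idx in enumerate(order):
        by_input[idx] = rows[pos]
    return UpstreamAlignment(ids, by_input, list(regions))


def column_identities(aln: UpstreamAlignment) -> np.ndarray:
    """Per-column identity: majority non-gap character frequency among
    non-gap rows; columns with more than 50% gaps score 0."""
    rows = aln.rows
    n = len(rows)
    L = aln.n_columns
    ident = np.zeros(L)
    for c in range(L):
        chars = [r[c] for r in rows]
        nongap = [x for x in chars if x != GAP]
        if len(nongap) * 2 < n:  # more than 50% gaps
            continue
        counts: dict[str, int] = {}
        for x in nongap:
            counts[x] = counts.get(x, 0) + 1
        ident[c] = max(counts.values()) / len(nongap)
    return ident


def find_islands(aln: UpstreamAlignment, window_len: int = 10,
                 min_identity: float = 0.8) -> list[ConservationIsland]:
    """Maximal runs of conserved columns supported by a qualifying window.

    A column belongs to an island iff its own identity >= ``min_identity`` and
    it lies inside at least one window of ``window_len`` columns whose mean
    identity >= ``min_identity``.  Runs shorter than one window are dropped:
    at the window scale they are indistinguishable from background.  Islands
    therefore satisfy the detection threshold column-wise and are invariant
    to row order.
    """
    L = aln.n_columns
    if window_len > L:
        raise ValueError("window_len exceeds alignment length")
    ident = column_identities(aln)
    win_ok = np.zeros(L, dtype=bool)
    means = np.convolve(ident, np.ones(window_len) / window_len, mode="valid")
    for start in np.flatnonzero(means >= min_identity - 1e-12):
        win_ok[start:start + window_len] = True
    marked = win_ok & (ident >= min_identity - 1e-12)
    islands = []
    c = 0
    while c < L:
        if not marked[c]:
            c += 1
            continue
        d = c
        while d < L and marked[d]:
            d += 1
        if d - c >= window_len:
            islands.append(_make_island(aln, c, d, float(ident[c:d].mean())))
        c = d
    return islands


def _make_island(aln, start, end, mean_ident) -> ConservationIsland:
    segments = {}
    for rid, row in zip(aln.region_ids, aln.rows):
        before = sum(1 for x in row[:start] if x != GAP)
        sub = row[start:end].replace(GAP, "")
        segments[rid] = (before, before + len(sub), sub)
    return ConservationIsland((start, end), mean_ident, segments)


def candidate_sites_from_islands(islands, geometry=None, sequences=None,
                                 tol: int = 2) -> list[str]:
    """Turn islands into motif-discovery input.

    Without a geometry, emit each island's per-row ungapped subsequences.
    With a direct-repeat geometry, pair islands whose center distance is
    within ``tol`` of the expected box-start spacing and emit concatenated
    two-box candidates (requires ``sequences``: region_id -> full region).
    """
    if not islands:
        raise ValueError("no islands supplied")
    if geometry is None:
        out = []
        for isl in islands:
            for rid in sorted(isl.row_segments):
                seq = isl.row_segments[rid][2]
                if seq:
                    out.append(seq)
        return out
    if sequences is None:
        raise ValueError("pairing islands by geometry requires region sequences")
    b = geometry.box_len
    expected = geometry.center_distance
    out = []
    for i in range(len(islands)):
        for j in range(i + 1, len(islands)):
            for rid in sorted(set(islands[i].row_segments)
                              & set(islands[j].row_segments)):
                s1, e1, sub1 = islands[i].row_segments[rid]
                s2, e2, sub2 = islands[j].row_segments[rid]
                if not sub1 or not sub2:
                    continue
                c1, c2 = (s1 + e1) / 2, (s2 + e2) / 2
                if c1 > c2:
                    c1, c2 = c2, c1
                if abs((c2 - c1) - expected) > tol:
                    continue
                seq = sequences[rid]
                a1 = int(round(c1 - b / 2))
                a2 = int(round(c2 - b / 2))
                if a1 < 0 or a2 + b > len(seq):
                    continue
                out.append(seq[a1:a1 + b] + seq[a2:a2 + b])
    return out


def alignment_to_fasta(aln: UpstreamAlignment) -> str:
    """Aligned FASTA (gap character '-')."""
    out = []
    for rid, row in zip(aln.region_ids, aln.rows):
        out.append(f">{rid}")
        for i in range(0, len(row), 70):
            out.append(row[i:i + 70])
    return "\n".join(out) + "\n"


def alignment_from_fasta(text: str) -> UpstreamAlignment:
    """Read an aligned FASTA produced by any aligner; rows must be equal
    length (the degapping invariant is the caller's contract)."""
    ids, rows, cur = [], [], []
    for line in text.splitlines():
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur))
                cur = []
            ids.append(line[1:].strip())
        elif line.strip():
            cur.append(line.strip().upper())
    if cur:
        rows.append("".join(cur))
    if len({len(r) for r in rows}) > 1:
        raise ValueError("aligned FASTA rows have unequal lengths")
    return UpstreamAlignment(ids, rows)


def islands_to_tsv(islands) -> str:
    lines = ["aln_start\taln_end\tmean_identity\tregion_id\tstart\tend\tsequence"]
    for isl in islands:
        for rid in sorted(isl.row_segments):
            s, e, sub = isl.row_segments[rid]
            lines.append(f"{isl.span[0]}\t{isl.span[1]}\t"
                         f"{isl.mean_identity:.4f}\t{rid}\t{s}\t{e}\t{sub}")
    return "\n".join(lines) + "\n"
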