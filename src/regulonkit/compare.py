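"""Pairwise PWM similarity and hierarchical clustering of motifs.

Two motifs are compared by sliding one frequency matrix along the other (both
orientations), computing the Pearson correlation of the flattened aligned
column blocks at every offset with enough overlap, and keeping the best.
Significance comes from a seeded column-shuffle permutation test, so the
whole comparison is self-contained and reproducible.  Average-linkage
clustering on d = 1 - r groups regulators with similar binding motifs, the
way paralogous transcription factor families cluster by their sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import squareform


@dataclass
class MotifSimilarity:
    motif_a: str
    motif_b: str
    best_offset: int
    orientation: str  # 'forward' | 'reverse'
    correlation: float
    p_value: float


@dataclass
class MotifDendrogram:
    leaf_ids: list[str]
    linkage_matrix: np.ndarray
    cophenetic: np.ndarray       # square matrix, leaf order = leaf_ids
    leaf_order: list[str]        # dendrogram display order

    def ordered_distance_tsv(self, dist: np.ndarray) -> str:
        """Ordered distance matrix for heat-map rendering."""
        idx = [self.leaf_ids.index(l) for l in self.leaf_order]
        lines = ["\t" + "\t".join(self.leaf_order)]
        for i in idx:
            row = "\t".join(f"{dist[i, j]:.4f}" for j in idx)
            lines.append(f"{self.leaf_ids[i]}\t{row}")
        return "\n".join(lines) + "\n"

    def newick(self) -> str:
        n = len(self.leaf_ids)
        z = self.linkage_matrix
        names = {i: self.leaf_ids[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _c) in enumerate(z):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            names[n + k] = f"({names[a]}:{la:.6f},{names[b]}:{lb:.6f})"
            heights[n + k] = h
        return names[n + len(z) - 1] + ";"


def _revcomp_freqs(f: np.ndarray) -> np.ndarray:
    """Reverse-complement a 4 x L frequency matrix (base order A,C,G,T)."""
    return f[::-1, ::-1]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def _best_alignment(fa: np.ndarray, fb: np.ndarray, min_overlap: int):
    """Best (r, offset, orientation) over all placements of b against a.

    Offset o places b's first column at a's column o (negative = b sticks out
    left).  Ties broken by smaller |offset|, then forward orientation.
    """
    la, lb = fa.shape[1], fb.shape[1]
    best = None
    for orientation, fb_or in (("forward", fb), ("reverse", _revcomp_freqs(fb))):
        for offset in range(-(lb - min_overlap), la - min_overlap + 1):
            a0, a1 = max(0, offset), min(la, offset + lb)
            if a1 - a0 < min_overlap:
                continue
            b0 = a0 - offset
            sub_a = fa[:, a0:a1].ravel()
            sub_b = fb_or[:, b0:b0 + (a1 - a0)].ravel()
            r = _pearson(sub_a, sub_b)
            key = (r, -abs(offset), orientation == "forward")
            if best is None or key > best[0]:
                best = (key, r, offset, orientation)
    if best is None:
        raise ValueError("no offset yields the required overlap")
    return best[1], best[2], best[3]


def compare_pwms(a, b, min_overlap: int = 4, n_shuffles: int = 1000,
                 seed: int = 0, name_a: str = "a",
                 name_b: str = "b") -> MotifSimilarity:
    """Best-offset Pearson correlation of two motif frequency matrices.

    The permutation p-value shuffles b's columns ``n_shuffles`` times and
    recomputes the best correlation each time; p = (1 + #better) / (1 + n).
    """
    if min_overlap < 4:
        raise ValueError("min_overlap must be >= 4")
    fa, fb = np.asarray(a.freqs), np.asarray(b.freqs)
    if min(fa.shape[1], fb.shape[1]) < min_overlap:
        raise ValueError("overlap impossible: motif shorter than min_overlap")
    r_obs, offset, orientation = _best_alignment(fa, fb, min_overlap)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(fb.shape[1])
        r_perm, _o, _ori = _best_alignment(fa, fb[:, perm], min_overlap)
        if r_perm >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_shuffles)
    return MotifSimilarity(motif_a=name_a, motif_b=name_b, best_offset=offset,
                           orientation=orientation, correlation=r_obs,
                           p_value=p)


def similarity_matrix(models: dict, min_overlap: int = 4,
                      n_shuffles: int = 200, seed: int = 0):
    """All-pairs similarities; returns (names, r-matrix, list of records)."""
    names = sorted(models)
    n = len(names)
    r = np.eye(n)
    records = []
    for i in range(n):
        for j in range(i + 1, n):
            sim = compare_pwms(models[names[i]], models[names[j]],
                               min_overlap=min_overlap, n_shuffles=n_shuffles,
                               seed=seed + 1000 * i + j,
                               name_a=names[i], name_b=names[j])
            r[i, j] = r[j, i] = sim.correlation
            records.append(sim)
    return names, r, records


def cluster_motifs(names: list[str], r: np.ndarray) -> MotifDendrogram:
    """Average-linkage clustering on d = 1 - r.

    Requires the complete pairwise matrix.  Deterministic given input; leaf
    ids are used in sorted order so the result is input-order invariant.
    """
    r = np.asarray(r, dtype=float)
    n = len(names)
    if r.shape != (n, n):
        raise ValueError("similarity matrix shape does not match names")
    if np.isnan(r).any():
        raise ValueError("missing pairwise similarity")
    order = np.argsort(names, kind="stable")
    names_sorted = [names[i] for i in order]
    d = 1.0 - r[np.ix_(order, order)]
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    if n == 1:
        return MotifDendrogram(names_sorted, np.empty((0, 4)),
                               np.zeros((1, 1)), names_sorted)
    z = linkage(squareform(d, checks=False), method="average")
    coph = squareform(cophenet(z))
    leaf_order = [names_sorted[i] for i in leaves_list(z)]
    return MotifDendrogram(names_sorted, z, coph, leaf_order)


def similarities_to_tsv(records: list[MotifSimilarity]) -> str:
    lines = ["motif_a\tmotif_b\toffset\torientation\tcorrelation\tp_value"]
    for s in records:
        lines.append(f"{s.motif_a}\t{s.motif_b}\t{s.best_offset}\t"
                     f"{s.orientation}\t{s.correlation:.4f}\t{s.p_value:.4g}")
    return "\n".join(lines) + "\n"
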