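"""Ortholog detection by reciprocal best hits and distance trees of regulators.

Orthology between genomes is called by bidirectional best hits (BBH) of
Smith-Waterman local protein alignments at a 30% identity threshold.  Trees of
regulator DNA-binding domains are neighbor-joining trees on Poisson-corrected
alignment distances: deterministic and adequate for clustering paralogs into
orthologous groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj

DEFAULT_MIN_IDENTITY = 0.30


@dataclass
class AlignmentResult:
    score: float
    identity: float
    aligned_length: int
    query_id: str = ""
    subject_id: str = ""


@dataclass
class OrthologGroup:
    group_id: str
    members: list[tuple[str, str]]  # (genome_id, locus_tag)
    seed_gene: tuple[str, str]

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class DistanceTree:
    leaves: list[str]
    newick: str
    tree: object  # skbio TreeNode


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0,
                 gap_extend: float = 1.0, mode: str = "local") -> Align.PairwiseAligner:
    """Affine-gap aligner; a gap of length k costs open + extend*(k-1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(a: str, b: str, matrix: str = "BLOSUM62", gap_open: float = 11.0,
                gap_extend: float = 1.0, query_id: str = "",
                subject_id: str = "") -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Identity is identical aligned pairs divided by aligned columns, gap
    columns inside the local alignment span counted in the denominator.
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    aligner = make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / cols if cols else 0.0
    return AlignmentResult(
        score=float(aln.score), identity=identity, aligned_length=cols,
        query_id=query_id, subject_id=subject_id,
    )


def _score_matrix(aligner, prots_a, prots_b):
    m = np.empty((len(prots_a), len(prots_b)))
    for i, pa in enumerate(prots_a):
        for j, pb in enumerate(prots_b):
            m[i, j] = aligner.score(pa, pb)
    return m


def _best_hits(scores: np.ndarray, subject_tags: list[str]) -> list[int]:
    """Row-wise argmax; score ties broken by lexicographic subject locus_tag."""
    best = []
    for row in scores:
        top = row.max()
        cand = np.flatnonzero(row == top)
        best.append(min(cand, key=lambda j: subject_tags[j]))
    return best


def find_bbh(genome_a, genome_b, min_identity: float = DEFAULT_MIN_IDENTITY,
             matrix: str = "BLOSUM62", gap_open: float = 11.0,
             gap_extend: float = 1.0) -> list[tuple[str, str, float, float]]:
    """Bidirectional best hits between two genomes.

    Returns tuples ``(locus_a, locus_b, identity, score)`` for every pair
    where each gene is the other's top-scoring hit and identity >=
    ``min_identity`` (inclusive).
    """
    aligner = make_aligner(matrix, gap_open, gap_extend)
    tags_a = [f.locus_tag for f in genome_a.features]
    tags_b = [f.locus_tag for f in genome_b.features]
    prots_a = [f.translation for f in genome_a.features]
    prots_b = [f.translation for f in genome_b.features]
    if not tags_a or not tags_b:
        return []
    scores = _score_matrix(aligner, prots_a, prots_b)
    best_ab = _best_hits(scores, tags_b)
    best_ba = _best_hits(scores.T, tags_a)
    pairs = []
    for i, j in enumerate(best_ab):
        if best_ba[j] != i:
            continue
        res = local_align(prots_a[i], prots_b[j], matrix, gap_open, gap_extend,
                          query_id=tags_a[i], subject_id=tags_b[j])
        if res.identity >= min_identity:
            pairs.append((tags_a[i], tags_b[j], res.identity, res.score))
    pairs.sort(key=lambda p: p[0])
    return pairs


class BBHCache:
    """Caches pairwise BBH maps over a genome collection."""

    def __init__(self, genomes, min_identity: float = DEFAULT_MIN_IDENTITY):
        self.genomes = {g.genome_id: g for g in genomes}
        self.min_identity = min_identity
        self._maps: dict[tuple[str, str], dict[str, tuple[str, float]]] = {}

    def partner_map(self, gid_a: str, gid_b: str) -> dict[str, tuple[str, float]]:
        """locus in genome a -> (BBH partner locus in genome b, score)."""
        key = (gid_a, gid_b)
        if key not in self._maps:
            pairs = find_bbh(self.genomes[gid_a], self.genomes[gid_b],
                             self.min_identity)
            self._maps[(gid_a, gid_b)] = {a: (b, s) for a, b, _i, s in pairs}
            self._maps[(gid_b, gid_a)] = {b: (a, s) for a, b, _i, s in pairs}
        return self._maps[key]


def build_ortholog_groups(genomes, seed_genes,
                          min_identity: float = DEFAULT_MIN_IDENTITY,
                          cache: BBHCache | None = None) -> list[OrthologGroup]:
    """Transitively collect BBH partners of each seed across genomes.

    At most one member per genome; when two candidates land in one genome the
    one with the higher alignment score to the seed wins (ties by lexicographic
    locus_tag).  Membership is invariant to genome input order.
    """
    cache = cache or BBHCache(genomes, min_identity)
    gids = sorted(cache.genomes)
    aligner = make_aligner()
    groups = []
    for k, (seed_gid, seed_tag) in enumerate(seed_genes):
        seed_prot = cache.genomes[seed_gid].feature(seed_tag).translation
        members = {seed_gid: seed_tag}
        frontier = [(seed_gid, seed_tag)]
        candidates: dict[str, list[str]] = {}
        while frontier:
            gid, tag = frontier.pop(0)
            for other in gids:
                if other == gid or other in members:
                    continue
                hit = cache.partner_map(gid, other).get(tag)
                if hit is not None:
                    candidates.setdefault(other, []).append(hit[0])
        for other in sorted(candidates):
            cands = sorted(set(candidates[other]))
            scores = {t: aligner.score(
                seed_prot, cache.genomes[other].feature(t).translation)
                for t in cands}
            top = max(scores.values())
            members[other] = min(t for t in cands if scores[t] == top)
        groups.append(OrthologGroup(
            group_id=f"og{k:04d}",
            members=sorted(members.items()),
            seed_gene=(seed_gid, seed_tag),
        ))
    return groups


def genome_wide_ortholog_map(genomes, cache: BBHCache | None = None,
                             min_identity: float = DEFAULT_MIN_IDENTITY,
                             loci: dict[str, list[str]] | None = None,
                             ) -> dict[tuple[str, str], str]:
    """Map (genome_id, locus_tag) -> component id of the cross-genome BBH graph.

    Connected components of the union of pairwise BBH edges; deterministic
    component ids derived from the lexicographically smallest member.
    """
    cache = cache or BBHCache(genomes, min_identity)
    gids = sorted(cache.genomes)
    if loci is None:
        loci = {gid: [f.locus_tag for f in cache.genomes[gid].features]
                for gid in gids}
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    for i, ga in enumerate(gids):
        for gb in gids[i + 1:]:
            pmap = cache.partner_map(ga, gb)
            for a in loci.get(ga, []):
                hit = pmap.get(a)
                if hit is not None:
                    union((ga, a), (gb, hit[0]))
    comp: dict[tuple[str, str], str] = {}
    for gid in gids:
        for tag in loci.get(gid, []):
            root = find((gid, tag))
            comp[(gid, tag)] = f"{root[0]}:{root[1]}"
    return comp


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing positions over columns where both are non-gap."""
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(x != y for x, y in pairs) / len(pairs)


def poisson_distance(p: float, cap: float = 0.95) -> float:
    """Poisson-corrected distance -ln(1 - p); saturating p is capped."""
    return -math.log(1.0 - min(p, cap))


def build_distance_tree(members: dict[str, str]) -> DistanceTree:
    """Neighbor-joining tree from aligned (equal-length) member sequences.

    Distances are Poisson-corrected p-distances; negative NJ branch lengths
    are clamped to zero.  Deterministic given input order.
    """
    ids = list(members)
    if len(ids) < 2:
        raise ValueError("build_distance_tree requires >= 2 members")
    lengths = {len(s) for s in members.values()}
    if len(lengths) != 1:
        raise ValueError("member sequences must be aligned to equal length")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(
                p_distance(members[ids[i]], members[ids[j]]))
    if n == 2:
        half = d[0, 1] / 2
        newick = f"({ids[0]}:{half:.6f},{ids[1]}:{half:.6f});"
        return DistanceTree(leaves=ids, newick=newick, tree=None)
    tree = nj(DistanceMatrix(d, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    newick = str(tree).strip()
    return DistanceTree(leaves=ids, newick=newick, tree=tree)


def groups_to_tsv(groups: list[OrthologGroup]) -> str:
    lines = ["genome_id\tlocus_tag\tgroup_id"]
    for g in groups:
        for gid, tag in g.members:
            lines.append(f"{gid}\t{tag}\t{g.group_id}")
    return "\n".join(lines) + "\n"
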