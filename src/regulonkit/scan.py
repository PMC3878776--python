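"""PWM genome scanning, cross-genome consistency filtering, regulon assembly.

The scan threshold follows the training-set rule: the smallest score among the
training sites.  A candidate site then counts as real only if conserved —
present upstream of a gene *and* upstream of its orthologs in at least
``min_support`` genomes that carry the orthologous regulator; genes sharing an
operon with such a conserved site inherit membership.  Isolated high-scoring
sites scattered through a genome are treated as false positives, the central
assumption of consistency-check regulon reconstruction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from .motifs import MotifModel, _window_scores

logger = logging.getLogger(__name__)


@dataclass
class SiteHit:
    genome_id: str
    contig_id: str
    position: int          # 0-based start of the site on the contig
    strand: str
    score: float
    sequence: str          # boxes + spacer, read 5'->3' on the hit strand
    target_gene: str
    target_operon: str = ""

    def sort_key(self):
        return (self.genome_id, self.contig_id, self.position, self.strand)


@dataclass
class AcceptedMember:
    genome_id: str
    operon_id: str
    gene_id: str
    support: int
    accepted_via: str  # conserved_site | operon_inheritance | functional_link


@dataclass
class Regulon:
    regulator: object          # OrthologGroup
    members: list[AcceptedMember]
    sites: list[SiteHit]
    model: MotifModel | None = None
    converged: bool = True

    def member_operons(self) -> set[tuple[str, str]]:
        return {(m.genome_id, m.operon_id) for m in self.members}

    def to_json(self) -> str:
        payload = {
            "regulator": {
                "group_id": getattr(self.regulator, "group_id", ""),
                "members": sorted(getattr(self.regulator, "members", [])),
            },
            "converged": self.converged,
            "members": [
                {"genome": m.genome_id, "operon": m.operon_id,
                 "gene": m.gene_id, "support": m.support,
                 "accepted_via": m.accepted_via}
                for m in sorted(self.members,
                                key=lambda m: (m.genome_id, m.operon_id, m.gene_id))
            ],
            "sites": [
                {"genome": h.genome_id, "contig": h.contig_id,
                 "position": h.position, "strand": h.strand,
                 "score": round(h.score, 4), "sequence": h.sequence,
                 "target_gene": h.target_gene, "target_operon": h.target_operon}
                for h in sorted(self.sites, key=SiteHit.sort_key)
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def training_threshold(model: MotifModel, loo: bool = False) -> float:
    """Smallest training-site score under the model (the scan threshold).

    With ``loo``, each training site is scored under the PWM built from the
    *other* training sites (leave-one-out).  Self-scoring inflates every
    training score — a site's own bases are part of the counts — so the plain
    minimum is biased high and misses genuine sites of comparable quality;
    the LOO minimum removes that bias.  Because a self-score always exceeds
    the site's LOO score, every training site still passes the LOO threshold.
    Models whose frequencies are EM estimates rather than site counts fall
    back to the plain rule.
    """
    if not model.training_sites:
        raise ValueError("model has no training sites")
    seqs = [s.sequence if isinstance(s, SiteHit) else s
            for s in model.training_sites]
    offsets = model.geometry.scored_offsets()

    def codes_of(s):
        c = encode(s.upper())
        return c[offsets] if len(s) == model.geometry.total_len else c

    n = len(seqs)
    if loo and n >= 2 and model.freqs_override is None:
        cols = np.arange(model.width)
        bg = model.background[:, None]
        scores = []
        for s in seqs:
            codes = np.minimum(codes_of(s), 3)
            counts = model.counts.copy()
            counts[codes, cols] -= 1
            f = (counts + model.pseudocount * bg) / (n - 1 + model.pseudocount)
            pwm = np.log2(f / bg)
            scores.append(float(pwm[codes, cols].sum()))
        return min(scores)
    scores = []
    for s in seqs:
        if len(s) == model.geometry.total_len:
            scores.append(model.score_site(s))
        else:
            scores.append(model.score_word(s))
    return min(scores)


def _region_hit(region, offset: int, rel_strand: str, total: int):
    """Map a region-local hit to absolute contig coordinates and strand."""
    ctg, start, end, region_strand = region.absolute_span
    if region_strand == "+":
        if rel_strand == "+":
            return ctg, start + offset, "+"
        return ctg, end - offset - total, "-"
    if rel_strand == "+":
        return ctg, end - offset - total, "-"
    return ctg, start + offset, "+"


def scan_regions(model: MotifModel, regions, threshold: float,
                 both_strands: bool = True, collapse: bool = True,
                 operon_of: dict | None = None) -> list[SiteHit]:
    """Report every window scoring >= threshold in the given regions.

    Direct-repeat models are scanned on both strands with their boxes at the
    fixed spacer.  With ``collapse``, overlapping hits within one center
    distance of each other in the same region keep only the best-scoring one
    (ties: + strand, then smaller position).  Hits are sorted by
    (genome, contig, position).  The comparison allows a 1e-9 tolerance so a
    site scoring exactly the training minimum is never lost to float
    summation order.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    threshold = threshold - 1e-9
    geom = model.geometry
    total = geom.total_len
    offsets = geom.scored_offsets()
    pwm = model.pwm
    hits: list[SiteHit] = []
    for region in regions:
        seq = region.sequence.upper()
        if len(seq) < total:
            continue
        coded = encode(seq)
        strands = [("+", coded, seq)]
        if both_strands:
            rc = revcomp(seq)
            strands.append(("-", encode(rc), rc))
        region_hits = []
        for rel_strand, codes, s in strands:
            scores = _window_scores(codes, pwm, offsets)
            for p in np.flatnonzero(scores >= threshold):
                p = int(p)
                ctg, pos, strand = _region_hit(region, p, rel_strand, total)
                region_hits.append(SiteHit(
                    genome_id=region.genome_id, contig_id=ctg, position=pos,
                    strand=strand, score=float(scores[p]),
                    sequence=s[p:p + total], target_gene=region.gene_id,
                    target_operon=(operon_of or {}).get(
                        (region.genome_id, region.gene_id), ""),
                ))
        if collapse:
            region_hits = _collapse_hits(region_hits, geom)
        hits.extend(region_hits)
    hits.sort(key=SiteHit.sort_key)
    return hits


def _collapse_hits(region_hits: list[SiteHit], geom) -> list[SiteHit]:
    """Keep the best hit within each cluster of overlapping positions."""
    if not region_hits:
        return region_hits
    radius = geom.center_distance or geom.total_len
    ordered = sorted(region_hits, key=lambda h: (h.position, h.strand))
    kept: list[SiteHit] = []
    cluster: list[SiteHit] = []

    def flush():
        if cluster:
            kept.append(max(
                cluster, key=lambda h: (h.score, h.strand == "+", -h.position)))

    for h in ordered:
        if cluster and h.position - cluster[-1].position > radius:
            flush()
            cluster = []
        cluster.append(h)
    flush()
    return kept


def consistency_filter(hits, ortholog_map, regulator_group,
                       min_support: int = 2, operons=None,
                       functional_link: bool = False,
                       threshold: float | None = None,
                       link_bonus: float = 2.0,
                       annotations=None) -> list[AcceptedMember]:
    """Accept target operons with cross-genome conserved sites.

    A target operon is accepted iff sites occur upstream of it and upstream of
    its orthologs in >= ``min_support`` genomes carrying the orthologous
    regulator (support counts all such genomes, the queried one included).
    Other genes in an accepted operon are accepted via operon inheritance.
    With ``functional_link`` on, a non-conserved site scoring at least
    ``threshold + link_bonus`` upstream of a gene sharing a
    ``functional_category`` annotation with an accepted member is accepted
    too (off by default; this mechanizes expert judgment explicitly).
    """
    reg_genomes = regulator_group.genomes
    usable = []
    for h in hits:
        if h.genome_id not in reg_genomes:
            logger.warning(
                "ignoring hit in %s: genome lacks the orthologous regulator",
                h.genome_id)
            continue
        usable.append(h)
    by_group: dict[str, list[SiteHit]] = {}
    for h in usable:
        gid = ortholog_map.get((h.genome_id, h.target_gene),
                               f"__singleton__{h.genome_id}:{h.target_gene}")
        by_group.setdefault(gid, []).append(h)
    operon_lookup = {}
    if operons:
        for op in operons:
            operon_lookup[(op.genome_id, op.operon_id)] = op
    accepted: list[AcceptedMember] = []
    accepted_ops: set[tuple[str, str]] = set()
    for gid in sorted(by_group):
        group_hits = by_group[gid]
        genomes_with_site = {h.genome_id for h in group_hits}
        support = len(genomes_with_site)
        if support < min_support:
            continue
        for key in sorted({(h.genome_id, h.target_operon, h.target_gene)
                           for h in group_hits}):
            genome_id, operon_id, gene_id = key
            if (genome_id, operon_id, gene_id) in {
                    (m.genome_id, m.operon_id, m.gene_id) for m in accepted}:
                continue
            accepted.append(AcceptedMember(
                genome_id, operon_id, gene_id, support, "conserved_site"))
            accepted_ops.add((genome_id, operon_id))
            op = operon_lookup.get((genome_id, operon_id))
            if op is not None:
                for g in op.gene_ids:
                    if g != gene_id:
                        accepted.append(AcceptedMember(
                            genome_id, operon_id, g, support,
                            "operon_inheritance"))
    if functional_link:
        if threshold is None:
            raise ValueError("functional_link mode requires the scan threshold")
        accepted_tags = set()
        for m in accepted:
            tags = (annotations or {}).get((m.genome_id, m.gene_id), {})
            cat = tags.get("functional_category")
            if cat:
                accepted_tags.add(cat)
        for h in usable:
            if (h.genome_id, h.target_operon) in accepted_ops:
                continue
            if h.score < threshold + link_bonus:
                continue
            tags = (annotations or {}).get((h.genome_id, h.target_gene), {})
            cat = tags.get("functional_category")
            if cat and cat in accepted_tags:
                accepted.append(AcceptedMember(
                    h.genome_id, h.target_operon, h.target_gene, 1,
                    "functional_link"))
                accepted_ops.add((h.genome_id, h.target_operon))
    return accepted


def assemble_regulon(model: MotifModel, regulator_group, accepted, hits,
                     regions, ortholog_map, min_support: int = 2,
                     operons=None, max_rounds: int = 10,
                     operon_of: dict | None = None,
                     loo: bool = True) -> Regulon:
    """Iterate PWM refinement to a fixed point of the accepted set.

    Rebuild the PWM from the union of the original training sites and the
    sites of accepted members, rescan with the training-minimum threshold,
    re-filter, and repeat until the accepted set stops changing (or
    ``max_rounds``, returning a ``converged=False`` regulon on oscillation).
    The original training sites stay in the training set: they are identified
    sites, and keeping them anchors the threshold so refinement cannot
    ratchet itself up to only its strongest hits.
    """
    if not accepted:
        raise ValueError("assemble_regulon requires a non-empty accepted set")
    geom = model.geometry
    anchor = {s.sequence if isinstance(s, SiteHit) else s
              for s in model.training_sites
              if len(s.sequence if isinstance(s, SiteHit) else s)
              == geom.total_len}
    current = list(accepted)
    current_hits = list(hits)
    current_model = model
    seen_states = [frozenset(
        (m.genome_id, m.operon_id, m.gene_id) for m in current)]
    converged = False
    for _ in range(max_rounds):
        accepted_keys = {(m.genome_id, m.operon_id) for m in current}
        site_seqs = sorted(anchor | {
            h.sequence for h in current_hits
            if (h.genome_id, h.target_operon) in accepted_keys})
        if not site_seqs:
            break
        current_model = MotifModel(
            geom,
            _counts_from_sites(site_seqs, geom),
            model.background, model.pseudocount,
            training_sites=site_seqs)
        thr = training_threshold(current_model, loo=loo)
        current_hits = scan_regions(current_model, regions, thr,
                                    operon_of=operon_of)
        current = consistency_filter(current_hits, ortholog_map,
                                     regulator_group, min_support,
                                     operons=operons)
        state = frozenset((m.genome_id, m.operon_id, m.gene_id) for m in current)
        if seen_states and state == seen_states[-1]:
            converged = True
            break
        seen_states.append(state)
    final_ops = {(m.genome_id, m.operon_id) for m in current}
    final_sites = [h for h in current_hits
                   if (h.genome_id, h.target_operon) in final_ops]
    return Regulon(regulator=regulator_group, members=current,
                   sites=final_sites, model=current_model, converged=converged)


def _counts_from_sites(site_seqs, geom):
    offsets = geom.scored_offsets()
    counts = np.zeros((4, len(offsets)))
    for s in site_seqs:
        codes = np.minimum(encode(s.upper())[offsets], 3)
        counts[codes, np.arange(len(offsets))] += 1
    return counts


def hits_to_bed(hits) -> str:
    """BED6: score scaled x100 (clamped at 0), name = target gene."""
    lines = []
    for h in sorted(hits, key=SiteHit.sort_key):
        score = 0 if not np.isfinite(h.score) else max(int(round(h.score * 100)), 0)
        lines.append(f"{h.contig_id}\t{h.position}\t"
                     f"{h.position + len(h.sequence)}\t{h.target_gene}\t"
                     f"{score}\t{h.strand}")
    return "\n".join(lines) + "\n" if lines else ""


def hits_to_tsv(hits) -> str:
    lines = ["genome\tcontig\tposition\tstrand\tscore\tsequence\t"
             "target_gene\ttarget_operon"]
    for h in sorted(hits, key=SiteHit.sort_key):
        lines.append(f"{h.genome_id}\t{h.contig_id}\t{h.position}\t{h.strand}"
                     f"\t{h.score:.4f}\t{h.sequence}\t{h.target_gene}\t"
                     f"{h.target_operon}")
    return "\n".join(lines) + "\n"
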