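"""End-to-end regulon reconstruction workflows.

Workflow 1 (footprint/direct-repeat route, for membrane-anchored regulators
with spaced-dyad sites): orthology -> upstream extraction -> phylogenetic
footprinting -> direct-repeat discovery -> PWM -> genome scan -> cross-genome
consistency filter -> fixed-point refinement.

Workflow 2 (EM/palindrome route, for cytoplasmic one-component regulators):
upstream extraction of candidate co-regulated genes -> palindrome-constrained
EM -> PWM -> scan with the training-minimum threshold -> consistency filter.

Every run writes a parameter/seed manifest; identical config and seed give
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .footprint import align_upstreams, find_islands, islands_to_tsv
from .genome import extract_upstream, predict_operons, regions_to_bed
from .motifs import (MotifGeometry, consensus, discover_direct_repeat,
                     discover_palindrome_em, to_meme, to_transfac)
from .orthology import (BBHCache, build_ortholog_groups,
                        genome_wide_ortholog_map)
from .scan import (Regulon, assemble_regulon, consistency_filter, hits_to_bed,
                   hits_to_tsv, scan_regions, training_threshold)


@dataclass
class PipelineConfig:
    workflow: str = "footprint_repeat"   # or "palindrome_em"
    upstream_window: tuple[int, int] = (-400, 50)
    operon_max_gap: int = 100
    min_identity: float = 0.30
    island_window: int = 10
    island_min_identity: float = 0.8
    box_len_range: tuple[int, int] = (10, 18)
    spacer_range: tuple[int, int] = (3, 12)
    extended_centers: tuple[int, ...] | None = None  # e.g. SusR-style 60..80
    n_seeds: int = 5
    motif_len: int = 22
    n_restarts: int = 20
    pseudocount: float = 0.5
    min_support: int = 2
    seed: int = 0
    run_footprinting: bool = True
    output_dir: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class WorkflowResult:
    regulon: Regulon
    model: object
    hits: list
    regions: list
    islands: list = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)


def _leader_regions(genomes, operons_by_genome, window):
    """Upstream regions of every operon leader, plus gene->operon lookup."""
    regions = []
    operon_of = {}
    for g in genomes:
        for op in operons_by_genome[g.genome_id]:
            for gene in op.gene_ids:
                operon_of[(g.genome_id, gene)] = op.operon_id
            regions.append(extract_upstream(g, op.leader_gene, window))
    return regions, operon_of


def _neighbor_operons(operons, locus_tag):
    """The operon containing a gene plus its immediate up/downstream operons."""
    idx = next(i for i, op in enumerate(operons)
               if locus_tag in op.gene_ids)
    lo, hi = max(0, idx - 1), min(len(operons), idx + 2)
    return operons[lo:hi]


def run_workflow1(genomes, seed_genes, config: PipelineConfig | None = None,
                  cache: BBHCache | None = None) -> WorkflowResult:
    """Reconstruct a direct-repeat regulon from regulator seed genes.

    ``seed_genes``: list of (genome_id, locus_tag) naming the regulator in at
    least one genome.  Training sequences are the upstream regions of the
    regulator's operon and its two flanking operons in every genome carrying
    an ortholog of the regulator.
    """
    config = config or PipelineConfig()
    if len(genomes) < 2:
        raise ValueError("workflow 1 requires >= 2 genomes "
                         "(cross-genome consistency is impossible with one)")
    if not seed_genes:
        raise ValueError("workflow 1 requires regulator seed genes")
    by_id = {g.genome_id: g for g in genomes}
    operons_by_genome = {g.genome_id: predict_operons(g, config.operon_max_gap)
                         for g in genomes}
    regions, operon_of = _leader_regions(genomes, operons_by_genome,
                                         config.upstream_window)
    cache = cache or BBHCache(genomes, config.min_identity)
    try:
        group = build_ortholog_groups(genomes, seed_genes, cache=cache)[0]
    except Exception as exc:
        raise RuntimeError(f"orthology stage failed for seeds {seed_genes}: "
                           f"{exc}") from exc
    leaders = {gid: [op.leader_gene for op in ops]
               for gid, ops in operons_by_genome.items()}
    ortholog_map = genome_wide_ortholog_map(genomes, cache=cache, loci=leaders)

    training_regions = []
    for gid, tag in sorted(group.members):
        for op in _neighbor_operons(operons_by_genome[gid], tag):
            training_regions.append(
                extract_upstream(by_id[gid], op.leader_gene,
                                 config.upstream_window))
    islands = []
    if config.run_footprinting and len(training_regions) >= 2:
        try:
            aln = align_upstreams(training_regions)
            islands = find_islands(aln, config.island_window,
                                   config.island_min_identity)
        except Exception as exc:
            raise RuntimeError(f"footprinting stage failed: {exc}") from exc
    try:
        model = discover_direct_repeat(
            [r.sequence for r in training_regions],
            box_len_range=config.box_len_range,
            spacer_range=config.spacer_range,
            n_seeds=config.n_seeds, seed=config.seed,
            pseudocount=config.pseudocount,
            extended_centers=config.extended_centers)
    except Exception as exc:
        raise RuntimeError(f"motif discovery stage failed: {exc}") from exc
    threshold = training_threshold(model, loo=True)
    hits = scan_regions(model, regions, threshold, operon_of=operon_of)
    all_operons = [op for ops in operons_by_genome.values() for op in ops]
    accepted = consistency_filter(hits, ortholog_map, group,
                                  config.min_support, operons=all_operons)
    if accepted:
        regulon = assemble_regulon(model, group, accepted, hits, regions,
                                   ortholog_map, config.min_support,
                                   operons=all_operons, operon_of=operon_of)
    else:
        regulon = Regulon(regulator=group, members=[], sites=[], model=model)
    result = WorkflowResult(regulon=regulon, model=regulon.model or model,
                            hits=hits, regions=regions, islands=islands)
    if config.output_dir:
        _write_artifacts(result, config, "workflow1")
    return result


def run_workflow2(genomes, candidate_genes, config: PipelineConfig | None = None,
                  regulator_group=None) -> WorkflowResult:
    """Reconstruct a palindrome regulon from candidate co-regulated genes.

    ``candidate_genes``: list of (genome_id, locus_tag) whose upstream regions
    form the EM training set.  ``regulator_group`` (an OrthologGroup or any
    object with ``.genomes``) defines which genomes carry the regulator; by
    default all input genomes do.
    """
    config = config or PipelineConfig(workflow="palindrome_em")
    if not candidate_genes:
        raise ValueError("workflow 2 requires a non-empty candidate gene set")
    by_id = {g.genome_id: g for g in genomes}
    operons_by_genome = {g.genome_id: predict_operons(g, config.operon_max_gap)
                         for g in genomes}
    regions, operon_of = _leader_regions(genomes, operons_by_genome,
                                         config.upstream_window)
    training_regions = [
        extract_upstream(by_id[gid], tag, config.upstream_window)
        for gid, tag in candidate_genes]
    try:
        model = discover_palindrome_em(
            [r.sequence for r in training_regions],
            motif_len=config.motif_len, n_restarts=config.n_restarts,
            seed=config.seed, pseudocount=config.pseudocount)
    except Exception as exc:
        raise RuntimeError(f"palindrome EM stage failed: {exc}") from exc
    threshold = training_threshold(model, loo=True)
    hits = scan_regions(model, regions, threshold, operon_of=operon_of)
    if regulator_group is None:
        regulator_group = _AllGenomes(sorted(by_id))
    ortholog_map = genome_wide_ortholog_map(
        genomes, loci={gid: [op.leader_gene for op in ops]
                       for gid, ops in operons_by_genome.items()})
    all_operons = [op for ops in operons_by_genome.values() for op in ops]
    accepted = consistency_filter(hits, ortholog_map, regulator_group,
                                  config.min_support, operons=all_operons)
    regulon = Regulon(regulator=regulator_group, members=accepted,
                      sites=[h for h in hits], model=model)
    result = WorkflowResult(regulon=regulon, model=model, hits=hits,
                            regions=regions)
    if config.output_dir:
        _write_artifacts(result, config, "workflow2")
    return result


@dataclass
class _AllGenomes:
    genome_ids: list[str]
    group_id: str = "regulator"

    @property
    def genomes(self):
        return set(self.genome_ids)

    @property
    def members(self):
        return [(g, "") for g in self.genome_ids]


def _write_artifacts(result: WorkflowResult, config: PipelineConfig,
                     name: str) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = result.model
    files = {
        f"{name}_motif.meme": to_meme({name: model}),
        f"{name}_motif.transfac": to_transfac(name, model),
        f"{name}_hits.tsv": hits_to_tsv(result.hits),
        f"{name}_hits.bed": hits_to_bed(result.hits),
        f"{name}_regulon.json": result.regulon.to_json(),
        f"{name}_regions.bed": regions_to_bed(result.regions),
        f"{name}_consensus.txt": consensus(model) + "\n",
    }
    if result.islands:
        files[f"{name}_islands.tsv"] = islands_to_tsv(result.islands)
    params = {k: v for k, v in dataclasses.asdict(config).items()
              if k != "output_dir"}  # a location, not a parameter
    manifest = {
        "workflow": name,
        "package_version": __version__,
        "parameters": params,
        "n_genomes": len({r.genome_id for r in result.regions}),
    }
    files[f"{name}_run_manifest.json"] = json.dumps(
        manifest, indent=2, sort_keys=True, default=list) + "\n"
    for fname, text in sorted(files.items()):
        (out / fname).write_text(text)
    result.artifacts = {k: str(out / k) for k in files}


def membership_f1(regulon: Regulon, manifest, regulator: str,
                  operon_of: dict) -> float:
    """F1 of predicted regulon membership against planted truth.

    Membership is compared at the operon level over genomes that carry the
    regulator: truth operons are those whose leader received a planted site.
    """
    truth = set()
    for site in manifest.sites_for(regulator):
        op = operon_of.get((site.genome_id, site.gene_id))
        if op is not None:
            truth.add((site.genome_id, op))
    predicted = regulon.member_operons()
    if not truth and not predicted:
        return 1.0
    tp = len(truth & predicted)
    prec = tp / len(predicted) if predicted else 0.0
    rec = tp / len(truth) if truth else 0.0
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)
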