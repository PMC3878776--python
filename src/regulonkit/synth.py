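"""Synthetic multi-genome benchmarks with planted regulators and sites.

The generator emulates the study design the pipeline targets: a clade of
related bacterial genomes sharing ortholog families, where a handful of
regulator genes have binding sites of known geometry planted upstream of
their target operons.  An ancestral genome of protein-coding genes is drawn
at a configurable GC content; each descendant genome applies independent
per-base substitutions at the divergence rate (star phylogeny); sites are
then sampled per genome from the regulator's motif model and written into
the upstream windows of its target-operon leaders.  A ground-truth manifest
records every planted site, the ortholog family map, and the motif
parameters, so recovery can be scored exactly.

Deliberately not modelled: genome rearrangement, gene gain/loss, codon
bias, repeats — background is i.i.d. given GC, the simplest null matching
the scanner's assumptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._seq import decode
from .genome import GeneFeature, GenomeRecord, translate_cds
from .motifs import MotifGeometry

#: codons (as code triples) that terminate translation in the bacterial code
_STOPS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA TAG TGA


@dataclass
class RegulatorSpec:
    name: str
    geometry: MotifGeometry
    consensus: str | None = None     # box consensus/full consensus; drawn if None
    n_target_operons: int = 6
    site_rate: float = 1.0           # probability a target operon gets a site
    site_fidelity: float = 0.85      # per-position probability of the consensus base
    #: cap on the fraction of non-consensus scored positions per site; sites
    #: are resampled past it (functional sites keep most of their contacts)
    site_max_divergence: float = 0.25
    present_in: list[int] | None = None  # genome indices carrying the regulator


@dataclass
class SyntheticConfig:
    n_genomes: int = 5
    genes_per_genome: int = 40
    gc_content: float = 0.43         # Bacteroides-like
    divergence: float = 0.2          # substitutions/site from the ancestor
    regulators: list[RegulatorSpec] = field(default_factory=list)
    global_palindrome: str | None = None
    palindrome_n_targets: int = 8
    seed: int = 0
    gene_len_codons: tuple[int, int] = (80, 140)
    operon_sizes: tuple[int, ...] = (1, 2, 3)
    intra_operon_gap: tuple[int, int] = (20, 60)
    inter_operon_gap: tuple[int, int] = (250, 420)
    site_window: tuple[int, int] = (-350, -30)  # relative to leader start

    def validate(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0,1]")
        for r in self.regulators:
            if not 0 <= r.site_rate <= 1:
                raise ValueError(f"{r.name}: site_rate must be in [0,1]")
            lo, hi = self.site_window
            if r.geometry.total_len > hi - lo:
                raise ValueError(
                    f"{r.name}: site ({r.geometry.total_len} bp) longer than "
                    f"the planting window ({hi - lo} bp)")
        if self.global_palindrome is not None:
            lo, hi = self.site_window
            if len(self.global_palindrome) > hi - lo:
                raise ValueError("global palindrome longer than planting window")


@dataclass
class PlantedSite:
    regulator: str
    genome_id: str
    contig_id: str
    gene_id: str           # leader gene whose upstream carries the site
    operon_index: int      # ancestral operon index
    position: int          # absolute 0-based start on the contig
    strand: str
    sequence: str


@dataclass
class TruthManifest:
    config: dict
    #: ancestral gene index -> {genome_id: locus_tag}
    ortholog_families: dict[int, dict[str, str]]
    #: regulator name -> {genome_id: locus_tag}
    regulator_genes: dict[str, dict[str, str]]
    #: regulator name -> list of ancestral operon indices targeted
    target_operons: dict[str, list[int]]
    #: ancestral operon index -> {genome_id: (operon gene locus_tags)}
    operon_map: dict[int, dict[str, list[str]]]
    sites: list[PlantedSite]
    motif_params: dict[str, dict]

    def sites_for(self, regulator: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.regulator == regulator]

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _random_gene(rng, n_codons: int, p: np.ndarray) -> np.ndarray:
    """Coding sequence: ATG + non-stop codons + stop, bases drawn from p."""
    codons = [np.array([0, 3, 2])]  # ATG
    while len(codons) < n_codons - 1:
        c = rng.choice(4, size=3, p=p)
        if tuple(c) in _STOPS:
            continue
        codons.append(c)
    codons.append(np.array([3, 0, 0]))  # TAA
    return np.concatenate(codons)


def _background(rng, n: int, p: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=p).astype(np.int8)


def _mutate(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    """Independent per-base substitution to a uniformly chosen other base."""
    out = codes.copy()
    hit = np.flatnonzero(rng.random(len(codes)) < rate)
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit))
        out[hit] = (out[hit] + shift) % 4
    return out


def _draw_consensus(rng, geometry: MotifGeometry) -> str:
    """Random consensus at scoring length; a direct repeat is one box twice
    (the same recognition sequence tandem-bound by a homodimer)."""
    if geometry.kind == "direct_repeat":
        box = decode(rng.integers(0, 4, size=geometry.box_len).astype(np.int8))
        return box + box
    return decode(rng.integers(0, 4, size=geometry.scoring_length).astype(np.int8))


def _sample_site(rng, spec: RegulatorSpec, bg_p: np.ndarray) -> str:
    """Sample a full-length site: boxes from the motif model, random spacer.

    Sites with more than ``site_max_divergence`` non-consensus scored
    positions are redrawn: a binding site that loses too many contacts is no
    longer functional and would not be maintained by selection.
    """
    geom = spec.geometry
    max_mm = int(spec.site_max_divergence * len(spec.consensus))
    while True:
        boxes = []
        mm = 0
        for ch in spec.consensus:
            if rng.random() < spec.site_fidelity:
                boxes.append(ch)
            else:
                alt = "ACGT"[int(rng.integers(0, 4))]
                mm += alt != ch
                boxes.append(alt)
        if mm <= max_mm:
            break
    word = "".join(boxes)
    if geom.kind == "direct_repeat":
        b = geom.box_len
        spacer = decode(_background(rng, geom.spacer, bg_p))
        return word[:b] + spacer + word[b:]
    return word


def generate_collection(config: SyntheticConfig):
    """Generate the genome collection and its ground-truth manifest.

    Returns ``(list of GenomeRecord, TruthManifest)``.  Byte-identical for a
    fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    # --- ancestral gene layout -------------------------------------------
    n_genes = config.genes_per_genome
    genes = []
    for _ in range(n_genes):
        n_codons = int(rng.integers(*config.gene_len_codons))
        genes.append(_random_gene(rng, n_codons, p))
    operons: list[list[int]] = []
    i = 0
    while i < n_genes:
        size = int(rng.choice(config.operon_sizes))
        operons.append(list(range(i, min(i + size, n_genes))))
        i += size

    # --- regulator wiring -------------------------------------------------
    for spec in config.regulators:
        if spec.consensus is None:
            spec.consensus = _draw_consensus(rng, spec.geometry)
    reg_operon_idx: dict[str, int] = {}
    target_idx: dict[str, list[int]] = {}
    pool = list(range(len(operons)))
    for spec in config.regulators:
        # regulators live inside their regulated locus: the regulator's own
        # operon and its chromosomal neighbors are targets first (the genome
        # context that seeds regulon reconstruction), the rest lie distant
        ri = int(rng.choice(pool))
        pool.remove(ri)
        reg_operon_idx[spec.name] = ri
        chosen = [ri]
        for nb in (ri - 1, ri + 1):
            if nb in pool and len(chosen) < spec.n_target_operons:
                chosen.append(nb)
                pool.remove(nb)
        n_rest = min(spec.n_target_operons - len(chosen), len(pool))
        if n_rest > 0:
            rest = rng.choice(pool, size=n_rest, replace=False).tolist()
            for c in rest:
                pool.remove(c)
            chosen.extend(int(c) for c in rest)
        target_idx[spec.name] = sorted(chosen)
    palindrome_targets: list[int] = []
    if config.global_palindrome is not None:
        n_t = min(config.palindrome_n_targets, len(pool))
        palindrome_targets = sorted(
            rng.choice(pool, size=n_t, replace=False).tolist())
        for c in palindrome_targets:
            pool.remove(c)

    # --- ancestral contig assembly (coordinates shared by all genomes) ---
    parts: list[np.ndarray] = []
    coords: list[tuple[int, int, int]] = []  # (ancestral gene idx, start, end)
    pos = int(rng.integers(*config.inter_operon_gap))
    parts.append(_background(rng, pos, p))
    leader_start: dict[int, int] = {}
    for oi, op_genes in enumerate(operons):
        leader_start[oi] = pos
        for k, ganc in enumerate(op_genes):
            seq = genes[ganc]
            coords.append((ganc, pos, pos + len(seq)))
            parts.append(seq)
            pos += len(seq)
            if k < len(op_genes) - 1:
                gap = int(rng.integers(*config.intra_operon_gap))
            else:
                gap = int(rng.integers(*config.inter_operon_gap))
            parts.append(_background(rng, gap, p))
            pos += gap
    ancestral = np.concatenate(parts)

    # site positions are ancestral too: regulatory sites are inherited, only
    # their sequence turns over, so orthologous upstream regions stay alignable
    def _site_position(oi: int, L: int) -> int | None:
        lo, hi = config.site_window
        a = max(leader_start[oi] + lo, 0)
        bmax = leader_start[oi] + hi - L
        if bmax <= a:
            return None
        return int(rng.integers(a, bmax + 1))

    site_positions: dict[tuple[str, int], int] = {}
    for spec in config.regulators:
        for oi in target_idx[spec.name]:
            sp = _site_position(oi, spec.geometry.total_len)
            if sp is not None:
                site_positions[(spec.name, oi)] = sp
    if config.global_palindrome is not None:
        for oi in palindrome_targets:
            sp = _site_position(oi, len(config.global_palindrome))
            if sp is not None:
                site_positions[("global_palindrome", oi)] = sp

    # --- per-genome assembly ---------------------------------------------
    genomes: list[GenomeRecord] = []
    families: dict[int, dict[str, str]] = {g: {} for g in range(n_genes)}
    operon_map: dict[int, dict[str, list[str]]] = {
        k: {} for k in range(len(operons))}
    sites: list[PlantedSite] = []
    reg_genes: dict[str, dict[str, str]] = {s.name: {} for s in config.regulators}
    if config.global_palindrome is not None:
        reg_genes["global_palindrome"] = {}

    for gi in range(config.n_genomes):
        gid = f"g{gi:02d}"
        ctg = f"{gid}_c1"
        contig = _mutate(ancestral, config.divergence, rng)
        feats: list[GeneFeature] = []
        for ganc, start, end in coords:
            tag = f"{gid}_{ganc:04d}"
            feats.append(GeneFeature(tag, ctg, start, end, "+"))
            families[ganc][gid] = tag
        for oi, op_genes in enumerate(operons):
            operon_map[oi][gid] = [f"{gid}_{ga:04d}" for ga in op_genes]

        def plant(name, sample, targets, carries):
            if not carries:
                return
            for oi in targets:
                key = (name, oi)
                if key not in site_positions:
                    continue
                site = sample(oi)
                if site is None:
                    continue
                sp = site_positions[key]
                contig[sp:sp + len(site)] = _codes_of(site)
                sites.append(PlantedSite(
                    regulator=name, genome_id=gid, contig_id=ctg,
                    gene_id=operon_map[oi][gid][0], operon_index=oi,
                    position=sp, strand="+", sequence=site))

        for spec in config.regulators:
            carries = spec.present_in is None or gi in spec.present_in
            if carries:
                reg_genes[spec.name][gid] = \
                    operon_map[reg_operon_idx[spec.name]][gid][0]
            plant(spec.name,
                  lambda oi, s=spec: (_sample_site(rng, s, p)
                                      if rng.random() < s.site_rate else None),
                  target_idx[spec.name], carries)
        if config.global_palindrome is not None:
            cons = config.global_palindrome

            def pal_site(oi):
                out = []
                for ch in cons.upper():
                    if ch in "ACGT":
                        out.append(ch)
                    elif ch == "W":
                        out.append("AT"[int(rng.integers(0, 2))])
                    else:  # N or other degenerate: uniform
                        out.append("ACGT"[int(rng.integers(0, 4))])
                return "".join(out)

            plant("global_palindrome", pal_site, palindrome_targets, True)

        seq_str = decode(contig.astype(np.int8))
        genome = GenomeRecord(gid, [(ctg, seq_str)], feats)
        for f in genome.features:
            f.translation = translate_cds(genome.cds_sequence(f.locus_tag))
        genomes.append(genome)

    motif_params = {
        s.name: {"kind": s.geometry.kind, "box_len": s.geometry.box_len,
                 "spacer": s.geometry.spacer,
                 "total_len": s.geometry.total_len,
                 "consensus": s.consensus, "site_fidelity": s.site_fidelity}
        for s in config.regulators}
    if config.global_palindrome is not None:
        motif_params["global_palindrome"] = {
            "kind": "palindrome", "total_len": len(config.global_palindrome),
            "consensus": config.global_palindrome}
        target_idx = dict(target_idx)
        target_idx["global_palindrome"] = palindrome_targets
        reg_genes["global_palindrome"] = {}
    manifest = TruthManifest(
        config={k: v for k, v in asdict(config).items() if k != "regulators"},
        ortholog_families=families,
        regulator_genes=reg_genes,
        target_operons=target_idx,
        operon_map=operon_map,
        sites=sites,
        motif_params=motif_params,
    )
    return genomes, manifest


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _codes_of(s: str) -> np.ndarray:
    return np.array([_CODE[c] for c in s], dtype=np.int8)


def corrupt_sites(genomes, manifest: TruthManifest, noise: float = 0.0,
                  dropout: float = 0.0, seed: int = 0):
    """Mutate or drop planted sites; returns updated (genomes, manifest).

    ``noise`` is a per-base substitution rate inside planted sites;
    ``dropout`` removes a site entirely, replacing it with fresh background.
    """
    if not 0 <= noise <= 1 or not 0 <= dropout <= 1:
        raise ValueError("rates must be in [0,1]")
    rng = np.random.default_rng(seed)
    contigs = {(g.genome_id, c): np.array(list(map(_CODE.get, seq)),
                                          dtype=np.int8)
               for g in genomes for c, seq in g.contigs}
    gc = manifest.config.get("gc_content", 0.5)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    kept: list[PlantedSite] = []
    for site in manifest.sites:
        arr = contigs[(site.genome_id, site.contig_id)]
        L = len(site.sequence)
        if rng.random() < dropout:
            arr[site.position:site.position + L] = _background(rng, L, p)
            continue
        seg = _mutate(arr[site.position:site.position + L], noise, rng)
        arr[site.position:site.position + L] = seg
        kept.append(PlantedSite(
            regulator=site.regulator, genome_id=site.genome_id,
            contig_id=site.contig_id, gene_id=site.gene_id,
            operon_index=site.operon_index, position=site.position,
            strand=site.strand, sequence=decode(seg)))
    new_genomes = []
    for g in genomes:
        new_contigs = [(c, decode(contigs[(g.genome_id, c)]))
                       for c, _ in g.contigs]
        ng = GenomeRecord(g.genome_id, new_contigs, [
            GeneFeature(f.locus_tag, f.contig_id, f.start, f.end, f.strand,
                        f.product, f.translation, dict(f.annotations))
            for f in g.features])
        new_genomes.append(ng)
    new_manifest = TruthManifest(
        config=manifest.config,
        ortholog_families=manifest.ortholog_families,
        regulator_genes=manifest.regulator_genes,
        target_operons=manifest.target_operons,
        operon_map=manifest.operon_map,
        sites=kept,
        motif_params=manifest.motif_params,
    )
    return new_genomes, new_manifest
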