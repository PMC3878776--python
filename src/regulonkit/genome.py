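"""Genome data model, readers/writers, operon prediction, upstream extraction.

Coordinates are 0-based, half-open throughout.  GenBank's 1-based inclusive
coordinates are converted at the parser boundary.  Upstream regulatory windows
default to (-400, +50) relative to the translation start, the window used for
phylogenetic footprinting of bacterial promoter regions.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from ._seq import revcomp

DEFAULT_UPSTREAM_WINDOW = (-400, 50)

#: NCBI translation table for bacteria/archaea
BACTERIAL_TABLE = 11

FEATURE_TSV_COLUMNS = [
    "locus_tag", "contig", "start", "end", "strand", "product", "translation",
]


class GenomeError(ValueError):
    """Malformed genome input (coordinates, duplicate ids, bad alphabet)."""


@dataclass
class GeneFeature:
    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    translation: str | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise GenomeError(f"feature {self.locus_tag}: non-integer coordinates")
        if self.start >= self.end:
            raise GenomeError(
                f"feature {self.locus_tag}: start {self.start} >= end {self.end}"
            )
        if self.strand not in "+-":
            raise GenomeError(f"feature {self.locus_tag}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: list[tuple[str, str]]
    features: list[GeneFeature]

    def __post_init__(self) -> None:
        self._contig_map = dict(self.contigs)
        if len(self._contig_map) != len(self.contigs):
            raise GenomeError(f"{self.genome_id}: duplicate contig ids")
        seen = set()
        for ctg, seq in self.contigs:
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise GenomeError(f"{self.genome_id}/{ctg}: invalid characters {bad}")
        for f in self.features:
            if f.locus_tag in seen:
                raise GenomeError(f"{self.genome_id}: duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)
            if f.contig_id not in self._contig_map:
                raise GenomeError(
                    f"feature {f.locus_tag}: unknown contig {f.contig_id}"
                )
            if f.end > len(self._contig_map[f.contig_id]):
                raise GenomeError(
                    f"feature {f.locus_tag}: end {f.end} beyond contig "
                    f"{f.contig_id} length {len(self._contig_map[f.contig_id])}"
                )
        self._feature_map = {f.locus_tag: f for f in self.features}

    def contig_seq(self, contig_id: str) -> str:
        return self._contig_map[contig_id]

    def feature(self, locus_tag: str) -> GeneFeature:
        try:
            return self._feature_map[locus_tag]
        except KeyError:
            raise KeyError(f"{self.genome_id}: unknown locus_tag {locus_tag}") from None

    def cds_sequence(self, locus_tag: str) -> str:
        f = self.feature(locus_tag)
        seg = self.contig_seq(f.contig_id)[f.start:f.end]
        return seg if f.strand == "+" else revcomp(seg)


@dataclass
class Operon:
    operon_id: str
    gene_ids: list[str]
    leader_gene: str
    genome_id: str = ""
    contig_id: str = ""
    strand: str = "+"


@dataclass
class UpstreamRegion:
    genome_id: str
    gene_id: str
    window: tuple[int, int]
    sequence: str
    absolute_span: tuple[str, int, int, str]  # (contig, start, end, strand)

    def __len__(self) -> int:
        return len(self.sequence)


def translate_cds(dna: str) -> str:
    """Translate a CDS with the bacterial code, trimming the terminal stop."""
    prot = str(Seq(dna).translate(table=BACTERIAL_TABLE))
    return prot[:-1] if prot.endswith("*") else prot


def _derive_translations(genome: GenomeRecord) -> None:
    for f in genome.features:
        if not f.translation:
            f.translation = translate_cds(genome.cds_sequence(f.locus_tag))


def read_genome(path, annotations=None, genome_id: str | None = None) -> GenomeRecord:
    """Read an annotated genome from GenBank, or FASTA plus a feature TSV.

    Parameters
    ----------
    path : str or Path
        GenBank flat file (``.gb``/``.gbk``/``.gbff``) or FASTA.
    annotations : str or Path, optional
        Tabular feature file (required for FASTA input) with columns
        ``locus_tag contig start end strand product translation``.
    """
    path = Path(path)
    gid = genome_id or path.stem
    if path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        contigs, features = [], []
        for rec in SeqIO.parse(str(path), "genbank"):
            contigs.append((rec.id, str(rec.seq).upper()))
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                tag = feat.qualifiers.get("locus_tag", [None])[0]
                if tag is None:
                    raise GenomeError(f"{path}: CDS without locus_tag at {feat.location}")
                features.append(GeneFeature(
                    locus_tag=tag,
                    contig_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand != -1 else "-",
                    product=feat.qualifiers.get("product", [""])[0],
                    translation=feat.qualifiers.get("translation", [None])[0],
                ))
        genome = GenomeRecord(gid, contigs, features)
    else:
        if annotations is None:
            raise GenomeError(f"{path}: FASTA input requires a feature table")
        contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        features = read_feature_tsv(annotations)
        genome = GenomeRecord(gid, contigs, features)
    _derive_translations(genome)
    return genome


def read_feature_tsv(path) -> list[GeneFeature]:
    features = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            try:
                start, end = int(row["start"]), int(row["end"])
            except (KeyError, ValueError) as exc:
                raise GenomeError(
                    f"{path} row {i + 1} ({row.get('locus_tag', '?')}): "
                    f"malformed coordinates"
                ) from exc
            features.append(GeneFeature(
                locus_tag=row["locus_tag"],
                contig_id=row["contig"],
                start=start,
                end=end,
                strand=row["strand"],
                product=row.get("product", "") or "",
                translation=row.get("translation") or None,
            ))
    return features


def write_genome(genome: GenomeRecord, fasta_path, features_path) -> None:
    """Write FASTA + feature TSV; a read back round-trips all declared fields."""
    with open(fasta_path, "w") as fh:
        for ctg, seq in genome.contigs:
            fh.write(f">{ctg}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(features_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FEATURE_TSV_COLUMNS)
        for f in genome.features:
            writer.writerow([
                f.locus_tag, f.contig_id, f.start, f.end, f.strand,
                f.product, f.translation or "",
            ])


def predict_operons(genome: GenomeRecord, max_gap: int = 100) -> list[Operon]:
    """Group consecutive same-strand genes with intergenic gap <= max_gap.

    A standard prokaryotic distance heuristic: genes on the same strand of the
    same contig whose intergenic distance does not exceed ``max_gap`` are
    assumed co-transcribed.  The leader is the 5'-most gene in transcription
    order.  Every gene lands in exactly one operon (singletons for isolated
    genes).
    """
    operons: list[Operon] = []
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in genome.features:
        by_contig.setdefault(f.contig_id, []).append(f)
    n = 0
    for ctg in sorted(by_contig):
        feats = sorted(by_contig[ctg], key=lambda f: (f.start, f.locus_tag))
        run: list[GeneFeature] = []
        def flush(run):
            nonlocal n
            if not run:
                return
            if run[0].strand == "+":
                ordered = [f.locus_tag for f in run]
            else:
                ordered = [f.locus_tag for f in sorted(
                    run, key=lambda f: -f.end)]
            operons.append(Operon(
                operon_id=f"{genome.genome_id}.op{n:04d}",
                gene_ids=ordered,
                leader_gene=ordered[0],
                genome_id=genome.genome_id,
                contig_id=ctg,
                strand=run[0].strand,
            ))
            n += 1
        for f in feats:
            if run and (f.strand != run[-1].strand or f.start - run[-1].end > max_gap):
                flush(run)
                run = []
            run.append(f)
        flush(run)
    return operons


def extract_upstream(
    genome: GenomeRecord,
    gene: str,
    window: tuple[int, int] = DEFAULT_UPSTREAM_WINDOW,
    truncate_at_upstream_gene: bool = False,
) -> UpstreamRegion:
    """Extract the regulatory window around a gene's translation start.

    For a + strand gene starting at ``s`` the absolute span is
    ``[s + window[0], s + window[1])`` clamped to the contig; for a - strand
    gene ending at ``e`` it is ``[e - window[1], e - window[0])`` reverse
    complemented, so the returned sequence always reads 5'->3' toward the gene.

    By default the window may run into upstream coding sequence; with
    ``truncate_at_upstream_gene`` it stops at the nearest upstream feature
    boundary on the same contig.
    """
    f = genome.feature(gene)
    contig = genome.contig_seq(f.contig_id)
    lo, hi = window
    if f.strand == "+":
        start, end = f.start + lo, f.start + hi
    else:
        start, end = f.end - hi, f.end - lo
    if truncate_at_upstream_gene:
        if f.strand == "+":
            bounds = [g.end for g in genome.features
                      if g.contig_id == f.contig_id and g.locus_tag != gene
                      and g.end <= f.start]
            if bounds:
                start = max(start, max(bounds))
        else:
            bounds = [g.start for g in genome.features
                      if g.contig_id == f.contig_id and g.locus_tag != gene
                      and g.start >= f.end]
            if bounds:
                end = min(end, min(bounds))
    start, end = max(0, start), min(len(contig), end)
    seg = contig[start:end]
    if f.strand == "-":
        seg = revcomp(seg)
    return UpstreamRegion(
        genome_id=genome.genome_id,
        gene_id=gene,
        window=window,
        sequence=seg,
        absolute_span=(f.contig_id, start, end, f.strand),
    )


def regions_to_bed(regions: list[UpstreamRegion]) -> str:
    """BED6 for upstream regions (0-based half-open, score 0, name = locus_tag)."""
    out = io.StringIO()
    for r in regions:
        ctg, start, end, strand = r.absolute_span
        out.write(f"{ctg}\t{start}\t{end}\t{r.gene_id}\t0\t{strand}\n")
    return out.getvalue()
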