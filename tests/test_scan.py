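import math

import numpy as np
import pytest

from regulonkit._seq import revcomp
from regulonkit.genome import Operon, UpstreamRegion
from regulonkit.motifs import MotifGeometry, build_pwm
from regulonkit.orthology import OrthologGroup
from regulonkit.scan import (SiteHit, assemble_regulon, consistency_filter,
                             hits_to_bed, scan_regions, training_threshold)
from conftest import random_dna


def region(seq, gid="g", gene="x", start=0):
    return UpstreamRegion(genome_id=gid, gene_id=gene, window=(-400, 50),
                          sequence=seq,
                          absolute_span=("c1", start, start + len(seq), "+"))


def brute_force_scan(model, regions, threshold):
    """Position-by-position oracle from the scoring definition alone."""
    f, bg = model.freqs, model.background
    geom = model.geometry
    total = geom.total_len
    out = []
    for r in regions:
        for rel_strand, seq in (("+", r.sequence.upper()),
                                ("-", revcomp(r.sequence.upper()))):
            for p in range(len(seq) - total + 1):
                site = seq[p:p + total]
                word = (site[:geom.box_len] + site[geom.box_len + geom.spacer:]
                        if geom.kind == "direct_repeat" else site)
                if any(c not in "ACGT" for c in word):
                    continue
                s = sum(math.log2(f["ACGT".index(c), j] / bg["ACGT".index(c)])
                        for j, c in enumerate(word))
                if s >= threshold:
                    ctg, start, end, _ = r.absolute_span
                    pos = start + p if rel_strand == "+" else end - p - total
                    out.append((r.genome_id, ctg, pos, rel_strand,
                                round(s, 9), site))
    return sorted(out)


class TestTrainingThreshold:
    def test_minimum_of_training_scores(self):
        m = build_pwm(["ACGT", "ACGA", "TCGT"])
        scores = [m.score_word(s) for s in m.training_sites]
        assert training_threshold(m) == min(scores)

    def test_single_site_threshold_is_own_score(self):
        m = build_pwm(["ACGTAC"])
        assert training_threshold(m) == m.score_word("ACGTAC")

    def test_all_training_sites_pass_self_threshold(self, rng):
        sites = [random_dna(rng, 8) for _ in range(6)]
        m = build_pwm(sites)
        thr = training_threshold(m)
        assert all(m.score_word(s) >= thr for s in sites)

    def test_loo_threshold_below_plain_and_still_passed(self, rng):
        sites = [random_dna(rng, 8) for _ in range(6)]
        m = build_pwm(sites)
        plain = training_threshold(m)
        loo = training_threshold(m, loo=True)
        assert loo < plain
        assert all(m.score_word(s) >= loo for s in sites)

    def test_empty_training_set_rejected(self):
        m = build_pwm(["ACGT"])
        m.training_sites = []
        with pytest.raises(ValueError):
            training_threshold(m)


class TestScanRegions:
    def test_matches_brute_force_on_random_regions(self, rng):
        geom = MotifGeometry("direct_repeat", 6, 3)
        sites = [random_dna(rng, 12) for _ in range(5)]
        model = build_pwm(sites, geometry=geom)
        regions = [region(random_dna(rng, 500), gid=f"g{i}", gene=f"x{i}",
                          start=100 * i) for i in range(10)]
        thr = -5.0
        hits = scan_regions(model, regions, thr, collapse=False)
        got = sorted((h.genome_id, h.contig_id, h.position, h.strand,
                      round(h.score, 9), h.sequence) for h in hits)
        assert got == brute_force_scan(model, regions, thr)

    def test_planted_training_sites_found_at_threshold(self, rng):
        geom = MotifGeometry("direct_repeat", 8, 4)
        box = random_dna(rng, 8)
        full_sites, regions = [], []
        for i in range(5):
            site = box + random_dna(rng, 4) + box
            bg = random_dna(rng, 200)
            regions.append(region(bg[:90] + site + bg[90 + 20:],
                                  gid=f"g{i}", gene=f"x{i}"))
            full_sites.append(site)
        model = build_pwm(full_sites, geometry=geom)
        thr = training_threshold(model)
        hits = scan_regions(model, regions, thr)
        found = {(h.genome_id, h.sequence) for h in hits}
        for i, s in enumerate(full_sites):
            assert (f"g{i}", s) in found

    def test_all_n_region_yields_no_hits(self):
        model = build_pwm(["ACGTAC"])
        assert scan_regions(model, [region("N" * 100)], -100.0) == []

    def test_collapse_keeps_best_overlapping_hit(self):
        model = build_pwm(["AAAA"])
        thr = model.score_word("AAAA") - 1e-6
        # AAAAA contains two overlapping AAAA words; collapse keeps one
        hits = scan_regions(model, [region("GGGAAAAAGGG")], thr,
                            both_strands=False, collapse=True)
        assert len(hits) == 1
        full = scan_regions(model, [region("GGGAAAAAGGG")], thr,
                            both_strands=False, collapse=False)
        assert len(full) == 2

    def test_infinite_threshold_rejected(self):
        model = build_pwm(["ACGT"])
        with pytest.raises(ValueError):
            scan_regions(model, [], float("-inf"))

    def test_bed_output_is_sorted_bed6(self):
        h = SiteHit("g", "c1", 10, "+", 7.5, "ACGTACGT", "geneA", "op1")
        assert hits_to_bed([h]) == "c1\t10\t18\tgeneA\t750\t+\n"


def hit(gid, gene, operon, score=10.0, pos=0):
    return SiteHit(gid, "c1", pos, "+", score, "ACGT", gene, operon)


class TestConsistencyFilter:
    GROUP = OrthologGroup("og0", [("A", "regA"), ("B", "regB")], ("A", "regA"))

    def test_conserved_in_two_genomes_accepted(self):
        hits = [hit("A", "g", "opA"), hit("B", "gp", "opB")]
        omap = {("A", "g"): "fam1", ("B", "gp"): "fam1"}
        acc = consistency_filter(hits, omap, self.GROUP, min_support=2)
        assert {(m.genome_id, m.operon_id) for m in acc} == \
            {("A", "opA"), ("B", "opB")}
        assert all(m.support == 2 and m.accepted_via == "conserved_site"
                   for m in acc)

    def test_single_genome_site_rejected(self):
        acc = consistency_filter([hit("A", "g", "opA")], {("A", "g"): "fam1"},
                                 self.GROUP, min_support=2)
        assert acc == []

    def test_operon_inheritance(self):
        hits = [hit("A", "g", "opA"), hit("B", "gp", "opB")]
        omap = {("A", "g"): "fam1", ("B", "gp"): "fam1"}
        operons = [Operon("opA", ["g", "g2"], "g", genome_id="A"),
                   Operon("opB", ["gp"], "gp", genome_id="B")]
        acc = consistency_filter(hits, omap, self.GROUP, 2, operons=operons)
        by_gene = {(m.genome_id, m.gene_id): m.accepted_via for m in acc}
        assert by_gene[("A", "g")] == "conserved_site"
        assert by_gene[("A", "g2")] == "operon_inheritance"

    def test_hits_in_genomes_without_regulator_ignored(self, caplog):
        hits = [hit("A", "g", "opA"), hit("Z", "gz", "opZ")]
        omap = {("A", "g"): "fam1", ("Z", "gz"): "fam1"}
        acc = consistency_filter(hits, omap, self.GROUP, min_support=2)
        assert acc == []  # Z does not carry the regulator: support stays 1

    def test_monotone_in_min_support(self, rng):
        genomes = ["A", "B", "C", "D"]
        group = OrthologGroup("og0", [(g, f"reg{g}") for g in genomes],
                              ("A", "regA"))
        hits, omap = [], {}
        for fam in range(6):
            for g in genomes:
                if rng.random() < 0.6:
                    hits.append(hit(g, f"x{fam}{g}", f"op{fam}{g}"))
                    omap[(g, f"x{fam}{g}")] = f"fam{fam}"
        prev = None
        for support in (1, 2, 3, 4):
            acc = {(m.genome_id, m.operon_id)
                   for m in consistency_filter(hits, omap, group, support)}
            if prev is not None:
                assert acc <= prev
            prev = acc

    def test_functional_link_requires_tag_and_margin(self):
        hits = [hit("A", "g", "opA"), hit("B", "gp", "opB"),
                hit("A", "solo", "opS", score=20.0)]
        omap = {("A", "g"): "fam1", ("B", "gp"): "fam1",
                ("A", "solo"): "fam2"}
        ann = {("A", "g"): {"functional_category": "PUL"},
               ("A", "solo"): {"functional_category": "PUL"}}
        acc = consistency_filter(hits, omap, self.GROUP, 2,
                                 functional_link=True, threshold=10.0,
                                 annotations=ann)
        via = {(m.genome_id, m.operon_id): m.accepted_via for m in acc}
        assert via[("A", "opS")] == "functional_link"
        # without the annotation tag the strong site stays rejected
        acc2 = consistency_filter(hits, omap, self.GROUP, 2,
                                  functional_link=True, threshold=10.0,
                                  annotations={("A", "g"):
                                               {"functional_category": "PUL"}})
        assert ("A", "opS") not in {(m.genome_id, m.operon_id) for m in acc2}


class TestAssembleRegulon:
    def build_fixture(self, rng):
        geom = MotifGeometry("direct_repeat", 8, 4)
        box = random_dna(rng, 8)
        regions, sites = [], []
        for i, gid in enumerate(["A", "B", "C"]):
            site = box + random_dna(rng, 4) + box
            bg = random_dna(rng, 150)
            regions.append(UpstreamRegion(
                gid, f"x{i}", (-400, 50), bg[:70] + site + bg[90:],
                ("c1", 0, 150, "+")))
            sites.append(site)
        model = build_pwm(sites, geometry=geom)
        omap = {(gid, f"x{i}"): "fam0"
                for i, gid in enumerate(["A", "B", "C"])}
        operon_of = {(gid, f"x{i}"): f"op{gid}"
                     for i, gid in enumerate(["A", "B", "C"])}
        group = OrthologGroup("og0", [(g, f"r{g}") for g in "ABC"],
                              ("A", "rA"))
        return model, regions, omap, operon_of, group

    def test_fixed_point_returns_converged_regulon(self, rng):
        model, regions, omap, operon_of, group = self.build_fixture(rng)
        thr = training_threshold(model)
        hits = scan_regions(model, regions, thr, operon_of=operon_of)
        acc = consistency_filter(hits, omap, group, 2)
        reg = assemble_regulon(model, group, acc, hits, regions, omap, 2,
                               operon_of=operon_of)
        assert reg.converged
        assert reg.member_operons() == {("A", "opA"), ("B", "opB"),
                                        ("C", "opC")}

    def test_empty_accepted_rejected(self, rng):
        model, regions, omap, operon_of, group = self.build_fixture(rng)
        with pytest.raises(ValueError):
            assemble_regulon(model, group, [], [], regions, omap)

    def test_regulon_json_is_deterministic(self, rng):
        model, regions, omap, operon_of, group = self.build_fixture(rng)
        thr = training_threshold(model)
        hits = scan_regions(model, regions, thr, operon_of=operon_of)
        acc = consistency_filter(hits, omap, group, 2)
        r1 = assemble_regulon(model, group, acc, hits, regions, omap, 2,
                              operon_of=operon_of)
        r2 = assemble_regulon(model, group, acc, hits, regions, omap, 2,
                              operon_of=operon_of)
        assert r1.to_json() == r2.to_json()
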